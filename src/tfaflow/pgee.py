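"""SCAD-penalized generalized estimating equations for longitudinal
feature selection.

The marginal model is binomial with logit link: the probability that a
sample belongs to the GVHD outcome class is regressed on standardized gene
(or module) abundances, with repeated measures within a patient handled
through a working correlation structure (exchangeable by default, AR-1
available).  A SCAD penalty (a = 3.7) shrinks small coefficients exactly
to zero, so estimation and feature selection happen simultaneously; the
intercept is never penalized.  The tuning parameter lambda is chosen by
patient-level cross-validation on held-out deviance.

Solved by Newton-type iterations with a local quadratic approximation of
the penalty: at iterate beta, the penalized estimating equation

    U(beta) - n * E(beta) beta = 0,   E = diag(p'_lambda(|b_j|) / (|b_j| + eps))

is updated via beta <- beta + (H + n E)^-1 (U - n E beta), where U and H
are the GEE score and Fisher-type information and n is the number of
clusters.  After convergence, coefficients below a zero threshold are set
to exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from tfaflow.clinical import classify_phases, filter_confounded, prepare_series, ACTIVE, NEVER, PRE
from tfaflow.syndata import ConfigError


def scad_deriv(t: np.ndarray, lam: float, a: float = 3.7) -> np.ndarray:
    """Derivative of the SCAD penalty at |t| (t >= 0)."""
    t = np.asarray(t, dtype=float)
    small = t <= lam
    mid = (t > lam) & (t <= a * lam)
    out = np.zeros_like(t)
    out[small] = lam
    if lam > 0:
        out[mid] = np.maximum(a * lam - t[mid], 0.0) / (a - 1.0)
    return out


@dataclass
class PgeeFit:
    """Fitted penalized GEE with its selection set."""

    coef: pd.Series                # per-feature, on the standardized scale
    intercept: float
    selected: list[str]
    lam: float
    corstr: str
    rho: float
    penalty: str
    a: float
    n_iter: int
    converged: bool
    separation: bool = False
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = (X[self.coef.index] - self.feature_means) / self.feature_sds
        return expit(self.intercept + z.to_numpy(dtype=float) @ self.coef.to_numpy())


def _working_corr_inverse(n_i: int, rho: float, corstr: str) -> np.ndarray:
    if corstr == "independence" or n_i == 1 or rho == 0.0:
        return np.eye(n_i)
    if corstr == "exchangeable":
        r = (1 - rho) * np.eye(n_i) + rho * np.ones((n_i, n_i))
        return np.linalg.inv(r)
    if corstr == "ar1":
        r = rho ** np.abs(np.subtract.outer(np.arange(n_i), np.arange(n_i)))
        return np.linalg.inv(r)
    raise ConfigError(f"unknown working correlation {corstr!r}")


def _estimate_rho(resid_by_cluster: list[np.ndarray], n_params: int,
                  corstr: str) -> float:
    """Moment estimate of the working-correlation parameter from Pearson
    residuals; clamped inside the positive-definite range."""
    n_total = sum(len(e) for e in resid_by_cluster)
    phi = sum(float(e @ e) for e in resid_by_cluster) / max(n_total - n_params, 1)
    max_n = max(len(e) for e in resid_by_cluster)
    if corstr == "independence" or max_n == 1:
        return 0.0
    if corstr == "exchangeable":
        num, denom = 0.0, 0
        for e in resid_by_cluster:
            k = len(e)
            if k < 2:
                continue
            num += (e.sum() ** 2 - e @ e) / 2.0
            denom += k * (k - 1) // 2
        if denom == 0:
            return 0.0
        rho = num / (max(denom - n_params, 1) * phi)
    else:  # ar1: lag-1 moment
        num, denom = 0.0, 0
        for e in resid_by_cluster:
            if len(e) < 2:
                continue
            num += float(e[:-1] @ e[1:])
            denom += len(e) - 1
        if denom == 0:
            return 0.0
        rho = num / (max(denom - n_params, 1) * phi)
    lo = -1.0 / (max_n - 1) + 1e-6 if max_n > 1 else -0.95
    return float(np.clip(rho, lo, 0.95))


def _solve(xmat: np.ndarray, yv: np.ndarray, cluster_idx: list[np.ndarray],
           beta0: np.ndarray, lam: float, corstr: str, penalty: str, a: float,
           max_iter: int, tol: float, zero_threshold: float,
           ridge: float = 0.0):
    """Newton iterations for the (penalized) estimating equations.

    Penalized coefficients that fall below the zero threshold are clamped
    to exactly 0 for the rest of the iteration: under the local-quadratic
    approximation their penalty weight diverges, so they cannot recover,
    and clamping stabilizes the updates.
    """
    p = xmat.shape[1]
    n_clusters = len(cluster_idx)
    beta = beta0.copy()
    rho = 0.0
    eps = 1e-6
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = xmat @ beta
        if np.max(np.abs(eta)) > 30:
            separation = True
        eta = np.clip(eta, -30, 30)
        mus = expit(eta)
        sqrt_a = np.sqrt(mus * (1 - mus))
        pearson = [(yv[idx] - mus[idx]) / sqrt_a[idx] for idx in cluster_idx]
        rho = _estimate_rho(pearson, p, corstr)

        u = np.zeros(p)
        h = np.zeros((p, p))
        for idx in cluster_idx:
            xi = xmat[idx]
            sa = sqrt_a[idx]
            rinv = _working_corr_inverse(len(idx), rho, corstr)
            # D'V^-1 = (A X)' A^-1/2 R^-1 A^-1/2 = X' A^1/2 R^-1 A^-1/2
            left = (xi * sa[:, None]).T @ rinv
            u += left @ ((yv[idx] - mus[idx]) / sa)
            h += left @ (xi * sa[:, None])
        if penalty == "scad":
            pen = scad_deriv(np.abs(beta[1:]), lam, a)
        elif penalty == "lasso":
            pen = np.full(p - 1, lam)
        else:
            raise ConfigError(f"unknown penalty {penalty!r}")
        e_diag = np.concatenate([[0.0], pen / (np.abs(beta[1:]) + eps)])
        if ridge > 0:  # L2 stabilizer (warm starts; guards separation)
            e_diag = e_diag + np.concatenate([[0.0],
                                              np.full(p - 1, ridge)])
        lhs = h + n_clusters * np.diag(e_diag)
        rhs = u - n_clusters * e_diag * beta
        try:
            step = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        scale = 1.0
        for _ in range(8):  # step-halving against overshoot
            cand = beta + scale * step
            if np.all(np.isfinite(cand)) and np.max(np.abs(cand)) < 1e4:
                break
            scale *= 0.5
        beta = beta + scale * step
        if lam > 0:
            beta[1:][np.abs(beta[1:]) < zero_threshold] = 0.0
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    return beta, rho, it, converged, separation


def fit_pgee(X: pd.DataFrame, y: pd.Series, clusters: pd.Series, lam: float,
             corstr: str = "exchangeable", penalty: str = "scad", a: float = 3.7,
             max_iter: int = 100, tol: float = 1e-6,
             zero_threshold: float = 1e-3, standardize: bool = True,
             beta_init: np.ndarray | None = None) -> PgeeFit:
    """Fit the penalized GEE for a binary outcome.

    ``X`` is samples x features; rows with any missing feature or outcome
    are dropped from the estimating equations.  Features are standardized
    internally (mean 0, sd 1); coefficients are reported on that scale.
    Non-convergence returns the last iterate flagged ``converged=False``;
    quasi-complete separation (|linear predictor| > 30) sets a warning flag.
    """
    df = pd.concat([X, y.rename("_y"), clusters.rename("_cl")], axis=1).dropna()
    if df.empty:
        raise ConfigError("no complete observations")
    yv = df["_y"].to_numpy(dtype=float)
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ConfigError("outcome must be binary 0/1")
    feats = list(X.columns)
    xraw = df[feats].to_numpy(dtype=float)
    if standardize:
        mu = xraw.mean(axis=0)
        sd = xraw.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(len(feats)), np.ones(len(feats))
    xs = (xraw - mu) / sd
    xmat = np.column_stack([np.ones(len(xs)), xs])
    cl = df["_cl"].to_numpy()
    cluster_idx = [np.flatnonzero(cl == c) for c in pd.unique(cl)]

    if beta_init is not None:
        beta0 = np.asarray(beta_init, dtype=float).copy()
        if beta0.shape != (xmat.shape[1],):
            raise ConfigError("beta_init has wrong length")
    else:
        beta0 = np.zeros(xmat.shape[1])
        prev = float(np.mean(yv))
        beta0[0] = logit(min(max(prev, 1e-6), 1 - 1e-6))
        if lam > 0:
            # warm start at a lightly ridge-regularized GEE estimate so the
            # local-quadratic SCAD approximation shrinks from a consistent,
            # bounded iterate: a pure unpenalized start diverges under
            # quasi-complete separation and would land beyond the SCAD
            # flat region where no shrinkage applies
            beta0, *_ = _solve(xmat, yv, cluster_idx, beta0, 0.0, corstr,
                               penalty, a, min(30, max_iter), tol,
                               zero_threshold, ridge=0.1)
    beta, rho, it, converged, separation = _solve(
        xmat, yv, cluster_idx, beta0, lam, corstr, penalty, a, max_iter, tol,
        zero_threshold)
    if not converged:
        warnings.warn(f"PGEE did not converge in {max_iter} iterations "
                      f"(lambda={lam})")
    coef = beta[1:].copy()
    coef[np.abs(coef) < zero_threshold] = 0.0
    coef_s = pd.Series(coef, index=feats, name="coef")
    return PgeeFit(coef=coef_s, intercept=float(beta[0]),
                   selected=[f for f, c in coef_s.items() if c != 0.0],
                   lam=lam, corstr=corstr, rho=rho, penalty=penalty, a=a,
                   n_iter=it, converged=converged, separation=separation,
                   feature_means=pd.Series(mu, index=feats),
                   feature_sds=pd.Series(sd, index=feats))


@dataclass
class CvCurve:
    """Cross-validation curve over the lambda grid."""

    lambdas: np.ndarray
    deviance: np.ndarray      # mean held-out deviance per lambda
    chosen: float
    deviance_se: np.ndarray | None = None  # SE of the mean across folds
    rule: str = "1se"
    folds: list[list] = field(default_factory=list)


def _held_out_deviance(fit: PgeeFit, xs: np.ndarray, yv: np.ndarray) -> float:
    eta = np.clip(fit.intercept + xs @ fit.coef.to_numpy(), -30, 30)
    mu = expit(eta)
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(yv * np.log(mu) + (1 - yv) * np.log(1 - mu)))


def select_lambda_cv(X: pd.DataFrame, y: pd.Series, clusters: pd.Series,
                     lambda_grid, folds: int = 5, seed: int = 0,
                     rule: str = "1se", **fit_kwargs) -> CvCurve:
    """Choose lambda by patient-level cross-validation.

    Folds partition patients (a patient is never split across folds); the
    score is mean held-out binomial deviance.  ``rule="1se"`` (default)
    picks the largest lambda whose mean deviance is within one standard
    error of the minimum — the usual convention when the fit is used for
    feature selection, where the bare minimizer systematically overselects;
    ``rule="min"`` picks the minimizer, ties going to the larger lambda
    (sparser model).  A training fold with a single outcome class is
    re-randomized with a warning (up to 20 attempts).
    """
    if rule not in ("min", "1se"):
        raise ConfigError(f"unknown CV rule {rule!r}")
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ConfigError("empty lambda grid")
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    patients = pd.unique(clusters.dropna())
    if len(patients) < folds:
        raise ConfigError(f"{len(patients)} patients cannot fill {folds} folds")
    rng = np.random.default_rng(seed)

    def make_folds():
        perm = rng.permutation(len(patients))
        return [sorted(patients[perm[i::folds]].tolist()) for i in range(folds)]

    fold_sets = make_folds()
    for attempt in range(20):
        ok = True
        for f in fold_sets:
            train_mask = ~clusters.isin(f)
            if y[train_mask].nunique() < 2:
                ok = False
                break
        if ok:
            break
        warnings.warn("fold with a single outcome class in training data; refolding")
        fold_sets = make_folds()

    dev = np.zeros((len(fold_sets), lambda_grid.size))
    for k, f in enumerate(fold_sets):
        test_mask = clusters.isin(f).to_numpy()
        xtr, ytr, ctr = X.loc[~test_mask], y.loc[~test_mask], clusters.loc[~test_mask]
        df_te = pd.concat([X.loc[test_mask], y.loc[test_mask].rename("_y")], axis=1).dropna()
        for i, lam in enumerate(lambda_grid):
            fit = fit_pgee(xtr, ytr, ctr, lam, **fit_kwargs)
            xs_te = ((df_te[X.columns] - fit.feature_means) / fit.feature_sds
                     ).to_numpy(dtype=float)
            dev[k, i] = _held_out_deviance(fit, xs_te, df_te["_y"].to_numpy(dtype=float))
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0]) if dev.shape[0] > 1 \
        else np.zeros_like(mean)
    i_min = int(np.argmin(mean))
    if rule == "min":
        best = float(np.max(lambda_grid[mean <= mean[i_min] + 1e-12]))
    else:
        best = float(np.max(lambda_grid[mean <= mean[i_min] + se[i_min]]))
    return CvCurve(lambdas=lambda_grid, deviance=mean, chosen=best,
                   deviance_se=se, rule=rule, folds=fold_sets)


def apply_pgee_protocol(log2: pd.DataFrame, annotations: pd.DataFrame,
                        episodes: pd.DataFrame, mode: str = "cohort",
                        max_timepoint: int | None = 19,
                        lambda_grid=None, folds: int = 5, seed: int = 0,
                        repertoire=None, corstr: str = "exchangeable",
                        rule: str = "1se") -> tuple[PgeeFit, dict]:
    """Outcome construction, timepoint truncation, CV and the final fit.

    Modes: "cohort" labels every sample of a GVHD patient 1 and of a
    never-GVHD patient 0; "active" contrasts active-GVHD samples (1)
    against never + pre-GVHD samples (0), dropping post-GVHD samples;
    "pure" is cohort mode after excluding infection/relapse timepoints.
    Timepoints beyond ``max_timepoint`` are removed first.
    """
    if mode not in ("cohort", "active", "pure"):
        raise ConfigError(f"unknown mode {mode!r}")
    ann = annotations[annotations.day >= 0].copy()  # post-transplant samples
    ann, _ = prepare_series(ann, min_points=0, max_timepoint=max_timepoint)
    if mode == "pure":
        ann, excl = filter_confounded(ann)
    else:
        excl = pd.DataFrame(columns=["sample_id", "reason"])
    ann = ann[ann.sample_id.isin(log2.index)].reset_index(drop=True)
    phases = classify_phases(ann, episodes)
    gvhd_patients = set(episodes.patient_id.astype(str))
    if mode == "active":
        keep = phases.isin([ACTIVE, NEVER, PRE]).to_numpy()
        ann = ann[keep].reset_index(drop=True)
        phases = phases[keep].reset_index(drop=True)
        y = (phases == ACTIVE).astype(float)
    else:
        y = ann.patient_id.astype(str).isin(gvhd_patients).astype(float)
    y = pd.Series(y.to_numpy(), index=ann.index)
    for cls in (0.0, 1.0):
        n_pat = ann.loc[y == cls, "patient_id"].nunique()
        if n_pat < 2:
            raise ConfigError(f"mode {mode!r}: only {n_pat} patients in class {int(cls)}")
    X = log2.loc[ann.sample_id].set_axis(ann.index, axis=0)
    clusters = ann.patient_id
    yy = y
    if lambda_grid is None:
        lambda_grid = np.geomspace(0.01, 1.0, 8)
    curve = select_lambda_cv(X, yy, clusters, lambda_grid, folds=folds,
                             seed=seed, corstr=corstr, rule=rule)
    fit = fit_pgee(X, yy, clusters, curve.chosen, corstr=corstr)
    sel = pd.DataFrame({"feature": fit.selected,
                        "coef": [fit.coef[f] for f in fit.selected]})
    if repertoire is not None and len(sel):
        t = repertoire.table.set_index("gene")
        sel["module_id"] = [t.module_id.get(f, "") for f in sel.feature]
        sel["aggregate_id"] = [t.aggregate_id.get(f, "") for f in sel.feature]
    report = {"mode": mode, "n_samples": len(ann),
              "n_patients": clusters.nunique(), "chosen_lambda": curve.chosen,
              "cv_curve": curve, "selected": sel, "excluded_confounded": excl}
    return fit, report
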