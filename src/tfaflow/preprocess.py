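"""Raw Ct tables -> batch-corrected expression matrices.

Processing order: QC-filter samples on RNA purity/integrity metadata, censor
Ct values outside the detectable range to missing, normalize each target
gene to the housekeeping pool (log2 expression = mean housekeeping Ct minus
target Ct, i.e. -dCt; linear = 2**(-dCt)), then remove batch effects on the
log2 scale with a parametric empirical-Bayes location/scale adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfaflow.syndata import ConfigError

META_COLS = ("sample_id", "patient_id", "day", "batch")


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized abundance.

    ``log2`` holds -dCt values (unitless, log2 scale); ``linear`` is the
    anti-logged matrix 2**log2 with missing entries propagated.  ``meta``
    carries sample_id/patient_id/day/batch, aligned on the same index.
    """

    log2: pd.DataFrame
    meta: pd.DataFrame
    batch_corrected: bool = False
    excluded_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"]))

    @property
    def linear(self) -> pd.DataFrame:
        return 2.0 ** self.log2

    @property
    def genes(self) -> list[str]:
        return list(self.log2.columns)


def qc_filter(annotations: pd.DataFrame, purity_min: float = 1.7,
              rin_min: float = 6.0, override_col: str = "bioanalyzer_ok",
              missing_policy: str = "keep") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain samples with purity > purity_min and RIN > rin_min.

    A truthy ``override_col`` entry (Bioanalyzer verification showing
    discrete RNA bands) retains a sample regardless of the thresholds; the
    override is recorded in the drop log with action "kept-override".
    Samples with missing QC metadata are kept with a warning under the
    default policy ("keep"), or dropped under policy "drop".

    Returns (retained annotations, drop log with sample_id/reason/action).
    """
    if missing_policy not in ("keep", "drop"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    log_rows = []
    keep_mask = []
    for _, row in annotations.iterrows():
        override = bool(row.get(override_col, 0))
        purity, rin = row.get("purity", np.nan), row.get("rin", np.nan)
        if pd.isna(purity) or pd.isna(rin):
            if missing_policy == "keep":
                warnings.warn(f"sample {row['sample_id']}: missing QC metadata, kept")
                keep_mask.append(True)
            else:
                log_rows.append({"sample_id": row["sample_id"],
                                 "reason": "missing QC metadata", "action": "dropped"})
                keep_mask.append(False)
            continue
        ok = purity > purity_min and rin > rin_min
        if ok:
            keep_mask.append(True)
        elif override:
            log_rows.append({"sample_id": row["sample_id"],
                             "reason": f"purity={purity} rin={rin} below threshold",
                             "action": "kept-override"})
            keep_mask.append(True)
        else:
            reasons = []
            if not purity > purity_min:
                reasons.append(f"purity {purity} <= {purity_min}")
            if not rin > rin_min:
                reasons.append(f"RIN {rin} <= {rin_min}")
            log_rows.append({"sample_id": row["sample_id"],
                             "reason": "; ".join(reasons), "action": "dropped"})
            keep_mask.append(False)
    retained = annotations.loc[np.asarray(keep_mask, dtype=bool)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["sample_id", "reason", "action"])
    return retained, log


def mask_undetectable(ct: pd.DataFrame, ct_min: float = 5.0,
                      ct_max: float = 35.0) -> tuple[pd.DataFrame, dict]:
    """Censor Ct values outside [ct_min, ct_max] to missing.

    Returns the masked table plus a report: per-assay censored counts and
    the list of assays left with no detectable value in any sample.
    """
    if ct_min >= ct_max:
        raise ConfigError("ct_min must be < ct_max")
    assay_cols = [c for c in ct.columns if c not in META_COLS]
    masked = ct.copy()
    vals = masked[assay_cols].to_numpy(dtype=float)
    out_of_range = (~np.isnan(vals)) & ((vals < ct_min) | (vals > ct_max))
    vals[out_of_range] = np.nan
    masked[assay_cols] = vals
    per_assay = pd.Series(out_of_range.sum(axis=0), index=assay_cols)
    all_missing = ([g for g, m in zip(assay_cols, np.isnan(vals).all(axis=0)) if m]
                   if len(vals) else [])
    report = {
        "censored_total": int(out_of_range.sum()),
        "censored_per_assay": per_assay[per_assay > 0].to_dict(),
        "all_missing_assays": all_missing,
    }
    return masked, report


def normalize_hk(ct: pd.DataFrame, hk_genes: list[str],
                 min_hk_fraction: float = 0.5) -> ExpressionMatrix:
    """Normalize target Ct values to the housekeeping pool.

    Per sample, hk_ref = arithmetic mean of the present housekeeping Ct
    values (equivalently the geometric mean on the linear scale); log2
    expression of gene g is hk_ref - Ct_g (-dCt).  Samples with fewer than
    ``min_hk_fraction`` of the pool present are excluded and logged.
    """
    assay_cols = [c for c in ct.columns if c not in META_COLS]
    unknown = [g for g in hk_genes if g not in assay_cols]
    if unknown:
        raise ConfigError(f"unknown housekeeping assay ids: {unknown}")
    target_cols = [c for c in assay_cols if c not in hk_genes]
    hk = ct[hk_genes].to_numpy(dtype=float)
    n_present = (~np.isnan(hk)).sum(axis=1)
    ok = n_present >= max(1, int(np.ceil(min_hk_fraction * len(hk_genes))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled via ok
        hk_ref = np.nanmean(hk, axis=1)
    excluded = pd.DataFrame({
        "sample_id": ct.loc[~ok, "sample_id"].tolist(),
        "reason": [f"only {int(k)}/{len(hk_genes)} housekeeping assays present"
                   for k in n_present[~ok]],
    })
    kept = ct.loc[ok].reset_index(drop=True)
    log2 = kept[target_cols].to_numpy(dtype=float)
    log2 = hk_ref[ok][:, None] - log2
    log2_df = pd.DataFrame(log2, columns=target_cols, index=kept["sample_id"])
    meta_cols = [c for c in META_COLS if c in kept.columns]
    meta = kept[meta_cols].set_index(kept["sample_id"])
    return ExpressionMatrix(log2=log2_df, meta=meta, excluded_samples=excluded)


def _eb_fit_batch(z: np.ndarray, batch_idx: list[np.ndarray], shrink: bool,
                  max_iter: int = 100, tol: float = 1e-6):
    """Empirical-Bayes batch location/scale estimates on standardized data.

    ``z`` is samples x genes, standardized gene-wise.  Returns per-batch
    gamma* (location) and delta2* (scale), each batches x genes.  With
    ``shrink=False`` the raw per-batch moments are returned (direct
    standardization, the large-batch limit of the EB solution).
    """
    n_batch = len(batch_idx)
    n_gene = z.shape[1]
    gamma_hat = np.zeros((n_batch, n_gene))
    delta2_hat = np.ones((n_batch, n_gene))
    for b, idx in enumerate(batch_idx):
        zb = z[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat[b] = np.nanmean(zb, axis=0)
            # ddof=0 matches the pooled-variance denominator, which makes
            # re-running the correction on homogenized data an identity
            d = np.nanvar(zb, axis=0, ddof=0)
        gamma_hat[b] = np.nan_to_num(gamma_hat[b])
        delta2_hat[b] = np.where(np.isnan(d) | (d <= 0), 1.0, d)
    if not shrink:
        return gamma_hat, delta2_hat

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for b, idx in enumerate(batch_idx):
        zb = z[idx]
        n_obs = (~np.isnan(zb)).sum(axis=0).astype(float)
        n_obs = np.maximum(n_obs, 1.0)
        # hyperpriors across genes (method of moments)
        gbar = gamma_hat[b].mean()
        t2 = gamma_hat[b].var()
        dbar = delta2_hat[b].mean()
        s2 = delta2_hat[b].var()
        # inverse-gamma moments; guard flat-prior degeneracies
        a_prior = (2 * s2 + dbar ** 2) / s2 if s2 > 0 else 2.0 + 1e-8
        b_prior = (dbar * s2 + dbar ** 3) / s2 if s2 > 0 else dbar
        if t2 <= 0:
            t2 = 1e-8
        g_new, d_new = gamma_hat[b].copy(), delta2_hat[b].copy()
        for _ in range(max_iter):
            g_old, d_old = g_new.copy(), d_new.copy()
            g_new = (t2 * n_obs * gamma_hat[b] + d_new * gbar) / (t2 * n_obs + d_new)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sse = np.nansum((zb - g_new[None, :]) ** 2, axis=0)
            d_new = (0.5 * sse + b_prior) / (n_obs / 2.0 + a_prior - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            if max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))) < tol:
                break
        gamma_star[b], delta2_star[b] = g_new, d_new
    return gamma_star, delta2_star


def batch_correct(expr: ExpressionMatrix, shrink: bool = True) -> ExpressionMatrix:
    """Remove per-gene batch location/scale effects on the log2 scale.

    Parametric empirical-Bayes adjustment: gene-wise standardize, estimate
    per-batch location and scale, shrink them toward cross-gene priors
    (normal prior on location, inverse-gamma on scale), remove them, and
    restore the gene-wise grand mean and pooled scale.  Missing entries are
    ignored in all moment estimates and stay missing.  A single batch is a
    no-op; batches with one sample are passed through with a warning.

    ``shrink=False`` applies the direct per-batch standardization instead
    (no EB pooling), the limit the EB estimates approach as batches grow.
    """
    if "batch" not in expr.meta.columns:
        raise ConfigError("expression metadata lacks a 'batch' column")
    batches = expr.meta["batch"].to_numpy()
    uniq = pd.unique(batches)
    if len(uniq) <= 1:
        out = ExpressionMatrix(expr.log2.copy(), expr.meta.copy(), batch_corrected=True,
                               excluded_samples=expr.excluded_samples)
        return out

    y = expr.log2.to_numpy(dtype=float).copy()
    counts = {b: int((batches == b).sum()) for b in uniq}
    singletons = [b for b, c in counts.items() if c < 2]
    if singletons:
        warnings.warn(f"batches with a single sample passed through uncorrected: {singletons}")
    use_batches = [b for b in uniq if counts[b] >= 2]
    batch_idx = [np.flatnonzero(batches == b) for b in use_batches]
    rows_used = np.concatenate(batch_idx) if batch_idx else np.array([], dtype=int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # grand mean weighted by batch (equal batch weight, ComBat-style)
        batch_means = np.stack([np.nanmean(y[idx], axis=0) for idx in batch_idx])
        n_per_batch = np.array([len(idx) for idx in batch_idx], dtype=float)
        alpha = np.nansum(batch_means * (n_per_batch[:, None] / n_per_batch.sum()), axis=0)
        # pooled variance of residuals around batch means
        resid = y.copy()
        for b, idx in enumerate(batch_idx):
            resid[idx] -= batch_means[b][None, :]
        n_obs_tot = (~np.isnan(resid[rows_used])).sum(axis=0).astype(float)
        sigma2 = np.nansum(resid[rows_used] ** 2, axis=0) / np.maximum(n_obs_tot, 1.0)
    sigma2 = np.where(sigma2 <= 0, 1e-12, sigma2)
    sigma = np.sqrt(sigma2)

    z = (y - alpha[None, :]) / sigma[None, :]
    gamma_star, delta2_star = _eb_fit_batch(z, batch_idx, shrink=shrink)
    corrected = y.copy()
    for b, idx in enumerate(batch_idx):
        zb = (z[idx] - gamma_star[b][None, :]) / np.sqrt(delta2_star[b])[None, :]
        corrected[idx] = zb * sigma[None, :] + alpha[None, :]
    out_df = pd.DataFrame(corrected, columns=expr.log2.columns, index=expr.log2.index)
    return ExpressionMatrix(out_df, expr.meta.copy(), batch_corrected=True,
                            excluded_samples=expr.excluded_samples)


def preprocess_pipeline(ct: pd.DataFrame, annotations: pd.DataFrame,
                        hk_genes: list[str], purity_min: float = 1.7,
                        rin_min: float = 6.0, ct_min: float = 5.0,
                        ct_max: float = 35.0, correct_batches: bool = True
                        ) -> tuple[ExpressionMatrix, dict]:
    """QC-filter -> mask -> housekeeping-normalize -> batch-correct.

    Returns the expression matrix and a report of drop/censoring counts.
    """
    retained, qc_log = qc_filter(annotations, purity_min, rin_min)
    ct_kept = ct[ct.sample_id.isin(retained.sample_id)].reset_index(drop=True)
    masked, mask_report = mask_undetectable(ct_kept, ct_min, ct_max)
    expr = normalize_hk(masked, hk_genes)
    if correct_batches:
        expr = batch_correct(expr)
    report = {
        "qc_dropped": int((qc_log.action == "dropped").sum()),
        "qc_log": qc_log,
        "mask": mask_report,
        "hk_excluded": len(expr.excluded_samples),
        "n_samples": expr.log2.shape[0],
        "n_genes": expr.log2.shape[1],
    }
    return expr, report
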