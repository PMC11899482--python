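"""Cross-sectional DEG detection, hierarchical clustering and the
time x group linear mixed model.

A gene is differentially expressed between two sample groups when a Welch
two-sample t-test on log2 values gives p < 0.05 AND the linear-scale
fold change between group means exceeds 1.5 in either direction.  Both
gates are required; neither alone flags a gene.  No multiple-testing
correction is applied by default (Benjamini-Hochberg available by flag).

The longitudinal model per gene is
    log2 expr ~ time + group + time:group + (1 | patient)
fitted by REML, with time coded in units of 100 days for numerically
stable fixed-effect estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass

from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist, squareform

from tfaflow.syndata import ConfigError

MAX_CORR_DIST = 2.0  # correlation distance of perfectly anti-correlated rows


def deg_test(log2: pd.DataFrame, groups: pd.Series, p_max: float = 0.05,
             fc_min: float = 1.5, mode: str = "ratio",
             bh_correct: bool = False) -> pd.DataFrame:
    """Two-group DEG table over the columns (genes) of ``log2``.

    ``groups`` maps sample id -> group label (exactly two labels).  The fold
    change is the ratio of linear-scale group means (first label over
    second, labels in sorted order unless ``groups`` is categorical with an
    explicit order); with ``mode="log2diff"`` the gate is applied to the
    absolute difference of log2 means instead of the ratio.
    Genes with fewer than two observed values in either group are reported
    with ``tested=False``.
    """
    groups = groups.reindex(log2.index)
    labels = sorted(pd.unique(groups.dropna()))  # deterministic orientation
    if len(labels) != 2:
        raise ConfigError(f"deg_test needs exactly two groups, got {labels}")
    g1, g2 = labels
    a = log2[groups == g1].to_numpy(dtype=float)
    b = log2[groups == g2].to_numpy(dtype=float)
    rows = []
    for j, gene in enumerate(log2.columns):
        x, y = a[:, j], b[:, j]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            rows.append({"gene": gene, "mean_1": np.nan, "mean_2": np.nan,
                         "fc": np.nan, "log2fc": np.nan, "p": np.nan,
                         "deg": False, "tested": False})
            continue
        m1, m2 = float(np.mean(2.0 ** x)), float(np.mean(2.0 ** y))
        log2fc = float(np.mean(x) - np.mean(y))
        fc = m1 / m2
        t = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"gene": gene, "mean_1": m1, "mean_2": m2, "fc": fc,
                     "log2fc": log2fc, "p": float(t.pvalue),
                     "deg": False, "tested": True})
    out = pd.DataFrame(rows)
    out.attrs["group_order"] = (g1, g2)
    tested = out.tested
    p = out.p.copy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        idx = np.flatnonzero(tested.to_numpy())
        if len(idx):
            p.iloc[idx] = multipletests(out.p.iloc[idx], method="fdr_bh")[1]
    out["p_adj"] = p if bh_correct else np.nan
    p_gate = (p < p_max) if bh_correct else (out.p < p_max)
    if mode == "ratio":
        fc_gate = (out.fc > fc_min) | (out.fc < 1.0 / fc_min)
    elif mode == "log2diff":
        fc_gate = out.log2fc.abs() > fc_min
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    out["deg"] = tested & p_gate & fc_gate
    out["neg_log10_p"] = -np.log10(out.p)
    return out


def hier_cluster(matrix: pd.DataFrame, axis: int = 0,
                 metric: str = "correlation", method: str = "average"
                 ) -> tuple[list, np.ndarray]:
    """Hierarchical clustering of rows (axis=0) or columns (axis=1).

    Returns (leaf order as index labels, scipy linkage matrix).  Rows with
    zero variance have undefined correlation distance and are placed at the
    maximum distance (2) from everything; all-missing rows are an error.
    """
    data = matrix.T if axis == 1 else matrix
    labels = list(data.index)
    if len(labels) < 1:
        raise ConfigError("nothing to cluster")
    x = data.to_numpy(dtype=float)
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        raise ValueError(f"all-missing row: {labels[int(np.flatnonzero(all_missing)[0])]}")
    if len(labels) == 1:
        return labels, np.empty((0, 4))
    if metric == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(x, metric="correlation")
        d = np.nan_to_num(d, nan=MAX_CORR_DIST)
    else:
        d = pdist(x, metric=metric)
    z = linkage(d, method=method)
    order = [labels[i] for i in leaves_list(z)]
    return order, z


def top_split(z: np.ndarray, n: int) -> tuple[set[int], set[int]]:
    """The two-cluster partition induced by cutting the tree at its root."""
    from scipy.cluster.hierarchy import fcluster
    assign = fcluster(z, t=2, criterion="maxclust")
    return ({i for i in range(n) if assign[i] == 1},
            {i for i in range(n) if assign[i] == 2})


@dataclass
class LmmResult:
    """Fixed effects of the per-gene longitudinal model."""

    gene: str
    estimates: dict[str, float]     # intercept, time, group, time:group
    pvalues: dict[str, float]
    stderrs: dict[str, float]
    re_var: float
    converged: bool
    fallback_ols: bool = False
    n_obs: int = 0
    df: float = np.nan


def fit_lmm(values: pd.Series, day: pd.Series, group: pd.Series,
            patient: pd.Series, gene: str = "", time_scale: float = 100.0
            ) -> LmmResult:
    """REML random-intercept model for one gene's longitudinal series.

    ``group`` must be binary (reference = first sorted label, coded 0).
    Time enters as day / ``time_scale`` (per-100-days by default).  Wald
    p-values use a t reference with a between-within style denominator
    df = n_obs - 4 - (n_patients - 1); a singular or failed fit falls back
    to OLS with cluster-robust (by patient) standard errors, flagged.
    """
    import statsmodels.api as sm

    df_in = pd.DataFrame({"y": values, "day": day, "group": group,
                          "patient": patient}).dropna()
    labels = sorted(pd.unique(df_in.group))
    if len(labels) != 2:
        raise ConfigError(f"fit_lmm needs a binary group, got {labels}")
    per_group = df_in.groupby("group")["patient"].nunique()
    if (per_group < 2).any():
        raise ConfigError("need >= 2 patients per group")
    if df_in.day.nunique() < 3:
        raise ConfigError("need >= 3 distinct timepoints")
    t = df_in.day.to_numpy(dtype=float) / time_scale
    g = (df_in.group == labels[1]).to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(df_in)), t, g, t * g])
    names = ["intercept", "time", "group", "time:group"]
    n_pat = df_in.patient.nunique()
    dof = max(float(len(df_in) - x.shape[1] - (n_pat - 1)), 1.0)

    def _pack(params, bse, re_var, converged, fallback):
        pv = {}
        for i, nm in enumerate(names):
            tt = params[i] / bse[i] if bse[i] > 0 else np.inf
            pv[nm] = float(np.clip(2.0 * stats.t.sf(abs(tt), dof), 1e-300, 1.0))
        return LmmResult(gene=gene,
                         estimates={nm: float(params[i]) for i, nm in enumerate(names)},
                         pvalues=pv,
                         stderrs={nm: float(bse[i]) for i, nm in enumerate(names)},
                         re_var=float(re_var), converged=converged,
                         fallback_ols=fallback, n_obs=len(df_in), df=dof)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df_in.y.to_numpy(dtype=float), x,
                               groups=df_in.patient.to_numpy())
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        re_var = float(np.asarray(fit.cov_re).ravel()[0])
        singular = (not fit.converged) or not np.all(np.isfinite(fit.bse_fe[:4]))
        if not singular:
            return _pack(fit.fe_params[:4], np.asarray(fit.bse_fe)[:4], re_var,
                         bool(fit.converged), False)
    except (np.linalg.LinAlgError, ValueError):
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = sm.OLS(df_in.y.to_numpy(dtype=float), x).fit(
            cov_type="cluster", cov_kwds={"groups": df_in.patient.to_numpy()})
    return _pack(ols.params, ols.bse, 0.0, True, True)


def fit_lmm_genewise(log2: pd.DataFrame, annotations: pd.DataFrame,
                     group: pd.Series, genes: list[str] | None = None,
                     time_scale: float = 100.0) -> pd.DataFrame:
    """Run :func:`fit_lmm` over genes; one row per gene with estimates and
    p-values for time, group and the time x group interaction."""
    ann = annotations.set_index("sample_id").reindex(log2.index)
    genes = list(log2.columns) if genes is None else genes
    rows = []
    for gene in genes:
        res = fit_lmm(log2[gene], ann.day, group.reindex(log2.index),
                      ann.patient_id, gene=gene, time_scale=time_scale)
        row = {"gene": gene, "re_var": res.re_var, "fallback_ols": res.fallback_ols,
               "n_obs": res.n_obs}
        for nm in ("time", "group", "time:group"):
            row[f"est_{nm}"] = res.estimates[nm]
            row[f"p_{nm}"] = res.pvalues[nm]
            row[f"se_{nm}"] = res.stderrs[nm]
        rows.append(row)
    return pd.DataFrame(rows)
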