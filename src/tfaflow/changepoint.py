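"""Per-series change-point detection in mean and variance (CDP analysis).

Each gene's per-patient trajectory is segmented by PELT (pruned exact
linear time) under a Gaussian likelihood cost that charges both mean and
variance shifts, with an MBIC-style penalty.  The segmentation minimizes

    sum over segments [ n_s * log(sigma2_hat_s) + log(n_s) ]  +  beta * m

with beta = 3 * log(n) for MBIC (three parameters per extra segment: mean,
variance, position), m the number of changepoints, and a variance floor so
constant segments are well defined.  Pruning uses a slack of -log(n) under
MBIC so the pruned search remains exactly optimal despite the per-segment
log-length term.

Positions are reported in the coordinates of the series index (clinical
timepoint indices), so mapping changepoints onto GVHD onsets is
unambiguous.  The onset shortlist keeps, per patient, genes whose
changepoints fall exclusively at the timepoint immediately preceding a
GVHD onset or at the first on-GVHD timepoint, and removes genes that also
change in any no-GVHD control series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfaflow.clinical import ACUTE_TYPES, CHRONIC_TYPES
from tfaflow.syndata import ConfigError

VAR_FLOOR = 1e-8


class SeriesTooShortError(ValueError):
    """Series below the eligibility length for change-point analysis."""


@dataclass
class ChangePointResult:
    """Segmentation of one (patient, gene) series."""

    patient_id: str
    gene: str
    positions: list            # index labels where a new segment starts
    segments: list[dict]       # start/end labels, n, mean, var per segment
    criterion: float           # minimized penalized cost
    n_points: int = 0
    dropped_missing: list = field(default_factory=list)

    @property
    def has_change(self) -> bool:
        return len(self.positions) > 0


def _segment_cost(cum: np.ndarray, cum2: np.ndarray, s: int, t: int,
                  cost: str) -> float:
    """Cost of the half-open segment [s, t)."""
    n = t - s
    total = cum[t] - cum[s]
    total2 = cum2[t] - cum2[s]
    mean = total / n
    var = max(total2 / n - mean * mean, VAR_FLOOR)
    if cost == "meanvar":
        return n * math.log(var)
    if cost == "mean":  # known-variance cost: residual sum of squares
        return total2 - total * total / n
    raise ConfigError(f"unknown cost {cost!r}")


def _pelt(y: np.ndarray, beta: float, min_seg: int, cost: str,
          mbic_term: bool) -> tuple[list[int], float]:
    """Optimal penalized segmentation; returns (changepoint starts, value).

    Exact: the pruning slack is 0 for plain penalties and -log(n) when the
    MBIC per-segment log-length term is active, which preserves optimality.
    """
    n = len(y)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    slack = -math.log(n) if mbic_term else 0.0

    def seg(s: int, t: int) -> float:
        c = _segment_cost(cum, cum2, s, t, cost)
        return c + math.log(t - s) if mbic_term else c

    f = np.full(n + 1, np.inf)
    f[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    # pruning is delayed by min_seg: the suboptimality argument for a
    # candidate pruned at time t only covers t' >= t + min_seg, and with a
    # minimum segment length the candidate may still be optimal before that
    candidates = [0]
    removal: dict[int, int] = {}
    for t in range(min_seg, n + 1):
        candidates = [s for s in candidates if removal.get(s, n + 2) > t]
        best, arg = np.inf, 0
        for s in candidates:
            if t - s < min_seg:
                continue
            val = f[s] + seg(s, t) + beta
            if val < best:
                best, arg = val, s
        f[t] = best
        last[t] = arg
        for s in candidates:
            if t - s >= min_seg and s not in removal \
                    and f[s] + seg(s, t) + slack > f[t]:
                removal[s] = t + min_seg
        s_new = t - min_seg + 1  # becomes eligible at time t + 1
        if s_new > 0 and s_new >= min_seg:
            candidates.append(s_new)
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), float(f[n])


def detect_changepoints(series: pd.Series, method: str = "pelt",
                        cost: str = "meanvar", penalty: str | float = "mbic",
                        min_seg: int = 2, min_points: int = 10,
                        patient_id: str = "", gene: str = "") -> ChangePointResult:
    """Segment one ordered series (index = clinical timepoint labels).

    Missing values are dropped with their positions recorded; the series
    must keep at least ``min_points`` observations (the eligibility rule for
    per-series analysis).  ``penalty`` is "mbic", "bic" or a numeric value.
    Deterministic; a constant series yields no changepoints.
    """
    if method != "pelt":
        raise ConfigError(f"unknown method {method!r}")
    vals = series.to_numpy(dtype=float)
    keep = ~np.isnan(vals)
    dropped = [series.index[i] for i in np.flatnonzero(~keep)]
    y = vals[keep]
    labels = [series.index[i] for i in np.flatnonzero(keep)]
    if len(y) < min_points:
        raise SeriesTooShortError(
            f"series has {len(y)} points after dropping missing; need >= {min_points}")
    n = len(y)
    mbic_term = penalty == "mbic"
    if isinstance(penalty, str):
        if penalty not in ("mbic", "bic"):
            raise ConfigError(f"unknown penalty {penalty!r}")
        beta = 3.0 * math.log(n)
    else:
        beta = float(penalty)
    cps, value = _pelt(y, beta, min_seg, cost, mbic_term)
    bounds = [0] + cps + [n]
    segments = []
    for s, t in zip(bounds[:-1], bounds[1:]):
        seg_y = y[s:t]
        segments.append({"start": labels[s], "end": labels[t - 1], "n": t - s,
                         "mean": float(np.mean(seg_y)),
                         "var": float(np.var(seg_y))})
    return ChangePointResult(patient_id=patient_id, gene=gene,
                             positions=[labels[i] for i in cps],
                             segments=segments, criterion=value,
                             n_points=n, dropped_missing=dropped)


def detect_cohort(log2: pd.DataFrame, annotations: pd.DataFrame,
                  genes: list[str] | None = None, min_points: int = 10,
                  **kwargs) -> list[ChangePointResult]:
    """Run change-point detection per (patient, gene) over a cohort.

    Series are ordered by day and indexed by timepoint_index; patients whose
    series are too short are skipped (handled upstream by prepare_series).
    """
    genes = list(log2.columns) if genes is None else genes
    ann = annotations.sort_values(["patient_id", "day"])
    results = []
    for patient, grp in ann.groupby("patient_id", sort=False):
        sids = [s for s in grp.sample_id if s in log2.index]
        tps = grp.set_index("sample_id").loc[sids, "timepoint_index"]
        for gene in genes:
            series = pd.Series(log2.loc[sids, gene].to_numpy(),
                               index=tps.to_numpy())
            try:
                results.append(detect_changepoints(
                    series, min_points=min_points, patient_id=str(patient),
                    gene=gene, **kwargs))
            except SeriesTooShortError:
                continue
    return results


def onset_timepoints(annotations: pd.DataFrame, episodes: pd.DataFrame
                     ) -> dict[str, set]:
    """Per patient: the timepoint indices at which a changepoint counts as
    onset-linked — the last timepoint strictly before each episode onset and
    the first timepoint at/after it."""
    allowed: dict[str, set] = {}
    ann = annotations.sort_values(["patient_id", "day"])
    for _, ep in episodes.iterrows():
        grp = ann[ann.patient_id == ep.patient_id]
        days = grp.day.to_numpy(dtype=float)
        tps = grp.timepoint_index.to_numpy()
        pre = np.flatnonzero(days < ep.onset_day)
        on = np.flatnonzero(days >= ep.onset_day)
        s = allowed.setdefault(str(ep.patient_id), set())
        if len(pre):
            s.add(tps[pre[-1]])
        if len(on):
            s.add(tps[on[0]])
    return allowed


def shortlist_onset_genes(results: list[ChangePointResult],
                          annotations: pd.DataFrame, episodes: pd.DataFrame,
                          control_results: list[ChangePointResult] | None = None
                          ) -> pd.DataFrame:
    """Genes whose changepoints appear exclusively at onset-linked timepoints.

    A gene is shortlisted for a patient iff it has at least one changepoint
    and every changepoint falls at the timepoint immediately preceding one
    of the patient's GVHD onsets or at the first on-GVHD timepoint.  Genes
    with a changepoint in any no-GVHD control series are removed.  Output
    rows carry the patient's GVHD stream (acute / acute+chronic).
    """
    allowed = onset_timepoints(annotations, episodes)
    types_of: dict[str, set] = {}
    for _, ep in episodes.iterrows():
        stream = "acute" if ep.type in ACUTE_TYPES else (
            "chronic" if ep.type in CHRONIC_TYPES else ep.type)
        types_of.setdefault(str(ep.patient_id), set()).add(stream)
    control_genes = {r.gene for r in (control_results or []) if r.has_change}
    rows = []
    for r in results:
        if not r.has_change or r.gene in control_genes:
            continue
        ok = allowed.get(r.patient_id, set())
        if all(p in ok for p in r.positions):
            streams = types_of.get(r.patient_id, set())
            gvhd_type = "acute+chronic" if {"acute", "chronic"} <= streams else \
                ("acute" if "acute" in streams else "+".join(sorted(streams)) or "none")
            rows.append({"patient_id": r.patient_id, "gene": r.gene,
                         "gvhd_type": gvhd_type,
                         "positions": ",".join(str(p) for p in r.positions)})
    return pd.DataFrame(rows, columns=["patient_id", "gene", "gvhd_type", "positions"])


def cdp_summary(results: list[ChangePointResult],
                patient_groups: pd.Series,
                repertoire=None) -> pd.DataFrame:
    """Percentage of analyzed series per cohort in which each gene changed.

    ``patient_groups`` maps patient id -> cohort label (e.g. "NO GVHD",
    "aGVHD", "aGVHD and cGVHD").  A gene changing in 3 of 12 series of a
    cohort scores 25 for that cohort; module membership is annotated when a
    repertoire is given.
    """
    if not results:
        return pd.DataFrame(columns=["gene", "cohort", "n_series",
                                     "n_changed", "percent"])
    rows = []
    for r in results:
        rows.append({"gene": r.gene,
                     "cohort": patient_groups.get(r.patient_id, "unknown"),
                     "changed": int(r.has_change)})
    df = pd.DataFrame(rows)
    out = (df.groupby(["gene", "cohort"])
           .agg(n_series=("changed", "size"), n_changed=("changed", "sum"))
           .reset_index())
    out["percent"] = 100.0 * out.n_changed / out.n_series
    if repertoire is not None:
        mod = repertoire.module_of()
        out["module_id"] = out.gene.map(mod)
    return out
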