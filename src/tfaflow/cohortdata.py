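"""Published summaries of the study cohort, shipped as package data.

``cohort_series_summary`` is the per-patient longitudinal sampling summary
(series span in days after transplant, number of post-transplant samples,
GVHD group, maximum grade, infection and relapse annotations).
``cohort_subtypes`` is the GVHD subtype breakdown of the 31-patient
pre-transplant cohort.  Both are inputs to desk-scale computations such as
the median sampling span, the total post-transplant sample count and the
change-point eligibility count under the >= 10-timepoint rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("tfaflow") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def cohort_series_summary() -> pd.DataFrame:
    """Per-patient sampling/annotation summary of the longitudinal cohort."""
    return _read("cohort_series_summary.tsv")


def cohort_subtypes() -> pd.DataFrame:
    """GVHD subtype breakdown of the pre-transplant cohort."""
    return _read("cohort_subtypes.tsv")


def cohort_desk_stats(min_points: int = 10) -> dict:
    """Desk-scale quantities derived from the cohort tables.

    Returns median sampling span (days), total post-transplant samples,
    the number of series eligible for per-series change-point analysis
    (>= ``min_points`` samples) and the number excluded, plus the GVHD
    patient total from the subtype breakdown.
    """
    series = cohort_series_summary()
    subtypes = cohort_subtypes()
    eligible = (series.n_samples >= min_points).sum()
    return {
        "median_span_days": float(series.span_days.median()),
        "total_post_tx_samples": int(series.n_samples.sum()),
        "cdp_eligible_patients": int(eligible),
        "cdp_excluded_patients": int(len(series) - eligible),
        "gvhd_patients_total": int(subtypes.loc[subtypes.gvhd == "yes",
                                                "n_patients"].sum()),
    }
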