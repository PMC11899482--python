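"""Clinical annotation logic: GVHD phases, confounders, series eligibility,
episode alignment.

Phase semantics: a sample is NEVER if its patient had no GVHD episode,
ACTIVE if its collection day falls inside any episode's [onset, resolution]
interval (closed on both ends; an unresolved episode extends to the end of
follow-up), PRE if it precedes the patient's first onset, POST otherwise.
Samples with conflicting annotations are UNCLEAR and excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NEVER, PRE, ACTIVE, POST, UNCLEAR = "NEVER", "PRE", "ACTIVE", "POST", "UNCLEAR"
PHASES = (NEVER, PRE, ACTIVE, POST, UNCLEAR)

# late-acute and overlap presentations run through the acute analysis stream
ACUTE_TYPES = ("acute", "late-acute", "overlap", "flare")
CHRONIC_TYPES = ("chronic",)


@dataclass(frozen=True)
class GvhdEpisode:
    """A single GVHD episode; flares are separate episodes."""

    patient_id: str
    type: str
    onset_day: float
    resolution_day: float | None = None  # None = unresolved at last follow-up
    grade: str = ""

    def contains(self, day: float) -> bool:
        if day < self.onset_day:
            return False
        return self.resolution_day is None or day <= self.resolution_day


def episodes_from_frame(episodes: pd.DataFrame) -> dict[str, list[GvhdEpisode]]:
    """Group an episodes table into per-patient validated episode lists."""
    out: dict[str, list[GvhdEpisode]] = {}
    for _, row in episodes.iterrows():
        res = row.get("resolution_day")
        res = None if pd.isna(res) else float(res)
        ep = GvhdEpisode(str(row["patient_id"]), str(row["type"]),
                         float(row["onset_day"]), res, str(row.get("grade", "")))
        if ep.resolution_day is not None and ep.onset_day > ep.resolution_day:
            raise ValueError(f"episode with onset after resolution: {ep}")
        out.setdefault(ep.patient_id, []).append(ep)
    for eps in out.values():
        eps.sort(key=lambda e: e.onset_day)
    return out


def classify_phase(day: float, episodes: list[GvhdEpisode],
                   unclear: bool = False) -> str:
    """Phase of one sample given its patient's episode list."""
    if unclear:
        return UNCLEAR
    if not episodes:
        return NEVER
    if any(ep.contains(day) for ep in episodes):
        return ACTIVE
    first_onset = min(ep.onset_day for ep in episodes)
    return PRE if day < first_onset else POST


def classify_phases(annotations: pd.DataFrame, episodes: pd.DataFrame,
                    unclear_col: str = "gvhd_unclear") -> pd.Series:
    """Vectorized phase labels for an annotations table."""
    by_patient = episodes_from_frame(episodes)
    unclear = annotations[unclear_col] if unclear_col in annotations.columns else None
    labels = []
    for i, row in annotations.iterrows():
        flag = bool(unclear.loc[i]) if unclear is not None else False
        labels.append(classify_phase(float(row["day"]),
                                     by_patient.get(str(row["patient_id"]), []),
                                     unclear=flag))
    return pd.Series(labels, index=annotations.index, name="phase")


def filter_confounded(annotations: pd.DataFrame,
                      infection_windows: pd.DataFrame | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples confounded by active infection or relapse.

    A sample is excluded if its day lies inside any of its patient's
    infection windows [onset_day, clearance_day] (both bounds inclusive —
    the clearance-day sample still reflects the infection) or if its
    relapse_flag is set.  Without ``infection_windows`` the per-sample
    infection_flag column is used.  Returns (retained, exclusion log).
    """
    reasons = {}
    if infection_windows is not None and len(infection_windows):
        bad = infection_windows[infection_windows.onset_day > infection_windows.clearance_day]
        if len(bad):
            raise ValueError("infection window with onset after clearance")
        for _, row in annotations.iterrows():
            w = infection_windows[
                (infection_windows.patient_id == row["patient_id"])
                & (infection_windows.onset_day <= row["day"])
                & (row["day"] <= infection_windows.clearance_day)]
            if len(w):
                reasons.setdefault(row["sample_id"], []).append("infection")
    elif "infection_flag" in annotations.columns:
        for sid in annotations.loc[annotations.infection_flag.astype(bool), "sample_id"]:
            reasons.setdefault(sid, []).append("infection")
    if "relapse_flag" in annotations.columns:
        for sid in annotations.loc[annotations.relapse_flag.astype(bool), "sample_id"]:
            reasons.setdefault(sid, []).append("relapse")
    log = pd.DataFrame(
        [{"sample_id": s, "reason": "+".join(r)} for s, r in reasons.items()],
        columns=["sample_id", "reason"])
    retained = annotations[~annotations.sample_id.isin(reasons)].reset_index(drop=True)
    return retained, log


def prepare_series(annotations: pd.DataFrame, min_points: int = 10,
                   max_timepoint: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Series eligibility and timepoint truncation for group analyses.

    Patients with fewer than ``min_points`` samples are dropped (change-point
    eligibility); with ``max_timepoint`` set, samples whose within-patient
    timepoint index exceeds it are removed first (dataset consolidation, so
    late sparse tails from a few long-followed patients do not dominate).
    Returns (eligible annotations, per-patient drop log).
    """
    ann = annotations.sort_values(["patient_id", "day"]).copy()
    if "timepoint_index" not in ann.columns:
        ann["timepoint_index"] = ann.groupby("patient_id").cumcount()
    if max_timepoint is not None:
        ann = ann[ann.timepoint_index <= max_timepoint]
    sizes = ann.groupby("patient_id").size()
    short = sizes[sizes < min_points]
    log = pd.DataFrame({"patient_id": short.index,
                        "n_points": short.to_numpy(),
                        "reason": [f"fewer than {min_points} timepoints"] * len(short)})
    eligible = ann[~ann.patient_id.isin(short.index)].reset_index(drop=True)
    return eligible, log.reset_index(drop=True)


@dataclass
class AlignedTrajectory:
    """Per-episode values re-indexed to days relative to onset (time zero)."""

    points: pd.DataFrame       # episode_id, patient_id, sample_id, aligned_day, rank, value
    mean_curve: pd.DataFrame   # rank, mean_aligned_day, mean_value, n_episodes
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["episode_id", "reason"]))


def align_to_onset(values: pd.Series, annotations: pd.DataFrame,
                   episodes: pd.DataFrame, require_pre: int = 1,
                   types: tuple[str, ...] | None = None) -> AlignedTrajectory:
    """Align per-sample values to each episode's onset (aligned day 0).

    ``values`` is indexed by sample_id (one gene's expression or one module's
    score).  Each episode of the requested ``types`` (default: all)
    contributes its patient's samples re-indexed as day - onset_day; episodes
    with fewer than ``require_pre`` pre-onset samples are excluded and
    logged.  Samples are ranked per episode with rank 0 at the first on/after
    -onset sample, negative ranks before; the mean curve averages values and
    aligned days per rank across episodes.
    """
    rows, excluded = [], []
    ep_df = episodes if types is None else episodes[episodes.type.isin(types)]
    for _, ep in ep_df.iterrows():
        eid = f"{ep.patient_id}:{ep.type}:{int(ep.onset_day)}"
        ann = annotations[annotations.patient_id == ep.patient_id]
        ann = ann[ann.sample_id.isin(values.index)].sort_values("day")
        aligned = ann.day.to_numpy(dtype=float) - float(ep.onset_day)
        n_pre = int((aligned < 0).sum())
        if n_pre < require_pre:
            excluded.append({"episode_id": eid,
                             "reason": f"only {n_pre} pre-onset samples "
                                       f"(require {require_pre})"})
            continue
        on_idx = int(np.searchsorted(aligned, 0.0, side="left"))
        for j, (sid, ad) in enumerate(zip(ann.sample_id, aligned)):
            rows.append({"episode_id": eid, "patient_id": ep.patient_id,
                         "sample_id": sid, "aligned_day": ad,
                         "rank": j - on_idx, "value": values.loc[sid]})
    points = pd.DataFrame(rows, columns=["episode_id", "patient_id", "sample_id",
                                         "aligned_day", "rank", "value"])
    if len(points):
        mean_curve = (points.groupby("rank")
                      .agg(mean_aligned_day=("aligned_day", "mean"),
                           mean_value=("value", "mean"),
                           n_episodes=("episode_id", "nunique"))
                      .reset_index())
    else:
        mean_curve = pd.DataFrame(columns=["rank", "mean_aligned_day",
                                           "mean_value", "n_episodes"])
    return AlignedTrajectory(points=points, mean_curve=mean_curve,
                             excluded=pd.DataFrame(excluded,
                                                   columns=["episode_id", "reason"]))
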