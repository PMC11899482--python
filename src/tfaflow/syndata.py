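"""Synthetic longitudinal allo-HCT cohorts with GVHD phase structure.

The generator emulates the data a transcriptional fingerprint assay (TFA)
study produces: a raw Ct table from multiplex qPCR (264 target genes plus a
pool of 8 housekeeping genes), per-sample clinical annotations with GVHD
episodes, infection windows and relapse flags, and the modular repertoire
(gene -> 4-gene module -> aggregate, with functional labels).  Patients are
sampled once pre-transplant, then weekly from engraftment until day 100 and
every two weeks thereafter.

Expression is simulated on the log2 scale and mapped to the Ct scale
(higher abundance = lower Ct).  Phase-linked effect templates add a log2
shift to all genes of the modules carrying a given functional signature
inside a day window relative to episode onset, so downstream recovery of the
injected signatures is well defined.  Ground truth (episodes, effect gene
sets, batch assignment) is returned alongside the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

HOUSEKEEPING_GENES = (
    "DOCK2", "EEF1A1", "OTULIN", "FTL", "MYL6", "MYL12B", "RPS10", "RPS25",
)

# functional vocabulary of the module repertoire; cycled over modules so that
# every label owns several modules in the default 66-module panel
FUNCTION_LABELS = (
    "interferon", "erythroid", "neutrophil activation", "inflammation",
    "protein synthesis", "cytokines/chemokines", "cell cycle", "monocytes",
    "B cells", "cytotoxicity", "TBD",
)

GRADE_LABELS_ACUTE = ("aGVHD I", "aGVHD II", "aGVHD III")
GRADE_LABELS_CHRONIC = ("cGVHD mild", "cGVHD moderate")


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass(frozen=True)
class EffectTemplate:
    """A phase-linked expression effect.

    ``signature`` names a function label of the repertoire; every gene of
    every module carrying that label receives ``log2_effect`` inside the day
    window ``[window[0], window[1]]`` relative to each episode onset.
    """

    signature: str
    window: tuple[float, float]
    log2_effect: float


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the structure of the longitudinal study cohort: 15
    patients of whom 11 develop GVHD, follow-up 215 days (cohort median),
    264 target genes in 66 four-gene modules plus 8 housekeeping assays,
    weekly-then-biweekly sampling from engraftment (day 21) with one
    pre-transplant sample at day -7.
    """

    n_patients: int = 15
    frac_gvhd: float = 11 / 15
    engraftment_day: int = 21
    followup_days: int = 215
    pre_tx_day: int = -7
    n_genes: int = 264
    n_housekeeping: int = 8
    module_size: int = 4
    modules_per_aggregate: int = 3
    effect_templates: tuple[EffectTemplate, ...] = (
        EffectTemplate("interferon", (-7.0, 30.0), 1.0),
        EffectTemplate("erythroid", (0.0, 60.0), 0.8),
    )
    infection_rate: float = 0.6
    relapse_rate: float = 0.2
    batch_count: int = 3
    batch_shift_sd: float = 0.5     # Ct units, per gene per batch
    residual_sd: float = 0.5        # log2 units
    module_factor_sd: float = 0.3   # shared within-module latent factor, log2
    missing_rate: float = 0.05      # MCAR, on top of detection censoring
    ct_detect_min: float = 5.0
    ct_detect_max: float = 35.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes % self.module_size != 0:
            raise ConfigError(
                f"n_genes={self.n_genes} not divisible by module_size={self.module_size}")
        for name in ("frac_gvhd", "infection_rate", "relapse_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be positive")
        if not 0 < self.engraftment_day <= self.followup_days:
            raise ConfigError("require 0 < engraftment_day <= followup_days")
        if self.pre_tx_day >= 0:
            raise ConfigError("pre_tx_day must be negative (pre-transplant)")
        if self.n_patients < 0 or self.batch_count < 1:
            raise ConfigError("n_patients must be >= 0 and batch_count >= 1")
        if self.ct_detect_min >= self.ct_detect_max:
            raise ConfigError("ct_detect_min must be < ct_detect_max")


@dataclass
class SimulatedCohort:
    """Bundle of generated tables plus ground truth."""

    ct: pd.DataFrame             # sample_id, patient_id, day, batch + assay columns
    annotations: pd.DataFrame    # one row per sample
    episodes: pd.DataFrame       # one row per GVHD episode
    repertoire: pd.DataFrame     # gene, module_id, aggregate_id, function_label
    truth: dict                  # episodes, effect genes, batches, infections

    @property
    def assay_columns(self) -> list[str]:
        meta = {"sample_id", "patient_id", "day", "batch"}
        return [c for c in self.ct.columns if c not in meta]


def sampling_schedule(engraftment_day: int, followup_days: int,
                      pre_tx_day: int = -7) -> list[int]:
    """Collection days: one pre-transplant day, then weekly until day 100
    and biweekly thereafter.

    The interval length is decided by the day it starts from: a visit on day
    d <= 100 is followed 7 days later, a visit on day d > 100 is followed 14
    days later.  Days beyond ``followup_days`` are not emitted.
    """
    if followup_days <= 0:
        raise ConfigError("followup_days must be positive")
    if not 0 < engraftment_day <= followup_days:
        raise ConfigError("require 0 < engraftment_day <= followup_days")
    if pre_tx_day >= 0:
        raise ConfigError("pre_tx_day must be negative")
    days = [pre_tx_day]
    d = engraftment_day
    while d <= followup_days:
        days.append(d)
        d += 7 if d <= 100 else 14
    return days


def build_repertoire(n_genes: int = 264, module_size: int = 4,
                     modules_per_aggregate: int = 3,
                     n_housekeeping: int = 8) -> pd.DataFrame:
    """Gene -> module -> aggregate table with cycled function labels.

    Housekeeping genes are listed with module_id ``HK`` and are never
    members of a scored module.
    """
    n_modules = n_genes // module_size
    rows = []
    for m in range(n_modules):
        agg = m // modules_per_aggregate + 1
        label = FUNCTION_LABELS[m % len(FUNCTION_LABELS)]
        module_id = f"M{agg}.{m % modules_per_aggregate + 1}"
        for g in range(module_size):
            rows.append({
                "gene": f"G{m * module_size + g + 1:03d}",
                "module_id": module_id,
                "aggregate_id": f"A{agg}",
                "function_label": label,
            })
    for hk in HOUSEKEEPING_GENES[:n_housekeeping]:
        rows.append({"gene": hk, "module_id": "HK", "aggregate_id": "HK",
                     "function_label": "housekeeping"})
    return pd.DataFrame(rows)


def _draw_episodes(rng: np.random.Generator, patient: str, cfg: SimConfig) -> list[dict]:
    """One acute episode per GVHD patient; 40% also get a chronic episode."""
    episodes = []
    lo, hi = cfg.engraftment_day, min(100, cfg.followup_days)
    onset = int(rng.integers(lo, hi + 1))
    resolution = onset + max(7, int(rng.exponential(30.0)))
    episodes.append({
        "patient_id": patient, "type": "acute", "onset_day": onset,
        "resolution_day": min(resolution, cfg.followup_days),
        "grade": GRADE_LABELS_ACUTE[int(rng.integers(len(GRADE_LABELS_ACUTE)))],
    })
    if cfg.followup_days > 100 and rng.random() < 0.4:
        c_onset = int(rng.integers(100, cfg.followup_days + 1))
        c_res = c_onset + max(14, int(rng.exponential(30.0)))
        episodes.append({
            "patient_id": patient, "type": "chronic", "onset_day": c_onset,
            "resolution_day": min(c_res, cfg.followup_days),
            "grade": GRADE_LABELS_CHRONIC[int(rng.integers(len(GRADE_LABELS_CHRONIC)))],
        })
    return episodes


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Identical config (including seed) gives identical output.  Effect
    templates must name function labels present in the repertoire.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rep = build_repertoire(config.n_genes, config.module_size,
                           config.modules_per_aggregate, config.n_housekeeping)
    target = rep[rep.module_id != "HK"]
    genes = target.gene.tolist()
    hk_genes = rep.loc[rep.module_id == "HK", "gene"].tolist()
    labels = set(target.function_label)
    for tpl in config.effect_templates:
        if tpl.signature not in labels:
            raise ConfigError(
                f"effect template signature {tpl.signature!r} absent from repertoire")

    module_of = dict(zip(target.gene, target.module_id))
    modules = target.module_id.unique().tolist()
    effect_genes = {
        tpl.signature: target.loc[target.function_label == tpl.signature, "gene"].tolist()
        for tpl in config.effect_templates
    }

    schedule = sampling_schedule(config.engraftment_day, config.followup_days,
                                 config.pre_tx_day)
    n_gvhd = int(round(config.n_patients * config.frac_gvhd))
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    gvhd_patients = set(patients[:n_gvhd])

    # per-gene baseline Ct (targets around 25 cycles, housekeeping tighter ~20)
    base_ct = {g: rng.normal(25.0, 2.0) for g in genes}
    base_ct.update({g: rng.normal(20.0, 0.5) for g in hk_genes})
    # per-batch per-assay Ct offsets; gene-specific so they survive dCt
    all_assays = genes + hk_genes
    batch_shift = rng.normal(0.0, config.batch_shift_sd,
                             size=(config.batch_count, len(all_assays)))

    episodes_rows: list[dict] = []
    ann_rows: list[dict] = []
    ct_rows: list[dict] = []
    infections: dict[str, list[tuple[int, int]]] = {}
    relapse_day: dict[str, int | None] = {}
    batch_of_sample: dict[str, int] = {}

    for patient in patients:
        eps = _draw_episodes(rng, patient, config) if patient in gvhd_patients else []
        episodes_rows.extend(eps)
        windows: list[tuple[int, int]] = []
        if rng.random() < config.infection_rate:
            i_on = int(rng.integers(config.engraftment_day,
                                    max(config.engraftment_day + 1,
                                        config.followup_days - 14)))
            windows.append((i_on, i_on + int(rng.integers(7, 22))))
        infections[patient] = windows
        r_day = None
        if config.followup_days > 100 and rng.random() < config.relapse_rate:
            r_day = int(rng.integers(100, config.followup_days + 1))
        relapse_day[patient] = r_day

        for tp_index, day in enumerate(schedule):
            sample = f"{patient}_T{tp_index:02d}"
            batch = int(rng.integers(config.batch_count))
            batch_of_sample[sample] = batch
            infected = any(a <= day <= b for a, b in windows)
            relapsed = r_day is not None and day >= r_day
            ann_rows.append({
                "sample_id": sample, "patient_id": patient, "day": day,
                "timepoint_index": tp_index,
                "infection_flag": int(infected), "relapse_flag": int(relapsed),
                "purity": round(max(1.2, rng.normal(2.0, 0.15)), 3),
                "rin": round(min(10.0, max(2.0, rng.normal(8.0, 1.0))), 2),
                "bioanalyzer_ok": 0,
            })

            module_factor = {m: rng.normal(0.0, config.module_factor_sd)
                             for m in modules}
            sample_shift = rng.normal(0.0, 0.3)  # common to all assays, removed by dCt
            row: dict[str, float | str | int] = {
                "sample_id": sample, "patient_id": patient, "day": day,
                "batch": batch,
            }
            effect_by_gene: dict[str, float] = {}
            for tpl in config.effect_templates:
                for ep in eps:
                    lo_w = ep["onset_day"] + tpl.window[0]
                    hi_w = ep["onset_day"] + tpl.window[1]
                    if lo_w <= day <= hi_w:
                        for g in effect_genes[tpl.signature]:
                            effect_by_gene[g] = effect_by_gene.get(g, 0.0) + tpl.log2_effect
                        break
            for j, g in enumerate(all_assays):
                if g in hk_genes:
                    x = 0.0
                else:
                    x = (module_factor[module_of[g]]
                         + effect_by_gene.get(g, 0.0)
                         + rng.normal(0.0, config.residual_sd))
                ct = base_ct[g] + sample_shift + batch_shift[batch, j] - x
                if rng.random() < config.missing_rate:
                    ct = np.nan
                elif ct > config.ct_detect_max or ct < config.ct_detect_min:
                    ct = np.nan
                row[g] = ct
            ct_rows.append(row)

    assay_cols = all_assays
    ct = pd.DataFrame(ct_rows, columns=["sample_id", "patient_id", "day", "batch"] + assay_cols)
    annotations = pd.DataFrame(ann_rows,
                               columns=["sample_id", "patient_id", "day",
                                        "timepoint_index", "infection_flag",
                                        "relapse_flag", "purity", "rin",
                                        "bioanalyzer_ok"])
    episodes = pd.DataFrame(episodes_rows,
                            columns=["patient_id", "type", "onset_day",
                                     "resolution_day", "grade"])
    truth = {
        "gvhd_patients": sorted(gvhd_patients),
        "episodes": episodes_rows,
        "effect_genes": effect_genes,
        "effect_templates": [asdict(t) for t in config.effect_templates],
        "infections": {p: [list(w) for w in ws] for p, ws in infections.items()},
        "relapse_day": relapse_day,
        "batch_of_sample": batch_of_sample,
        "schedule": schedule,
    }
    return SimulatedCohort(ct=ct, annotations=annotations, episodes=episodes,
                           repertoire=rep, truth=truth)


def emit_tables(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write ct_table.csv, annotations.csv, episodes.csv, repertoire.tsv and
    truth.json under ``directory``; missing Ct values serialize as empty
    fields and round-trip exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_table": directory / "ct_table.csv",
        "annotations": directory / "annotations.csv",
        "episodes": directory / "episodes.csv",
        "repertoire": directory / "repertoire.tsv",
        "truth": directory / "truth.json",
    }
    cohort.ct.to_csv(paths["ct_table"], index=False)
    cohort.annotations.to_csv(paths["annotations"], index=False)
    cohort.episodes.to_csv(paths["episodes"], index=False)
    cohort.repertoire.to_csv(paths["repertoire"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, default=str)
    return paths


def read_tables(directory: str | Path) -> SimulatedCohort:
    """Load a cohort previously written by :func:`emit_tables`."""
    directory = Path(directory)
    ct = pd.read_csv(directory / "ct_table.csv")
    annotations = pd.read_csv(directory / "annotations.csv")
    episodes = pd.read_csv(directory / "episodes.csv")
    repertoire = pd.read_csv(directory / "repertoire.tsv", sep="\t")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SimulatedCohort(ct=ct, annotations=annotations, episodes=episodes,
                           repertoire=repertoire, truth=truth)
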