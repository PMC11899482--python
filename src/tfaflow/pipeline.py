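"""End-to-end orchestration: preprocess -> score -> phases -> DEG/LMM ->
CDP -> PGEE -> onset alignment, with a run manifest.

The pipeline either loads the CSV/TSV dialects written by
:mod:`tfaflow.syndata` or simulates a cohort in place.  Every stage writes
its result tables (TSV) into the output directory exactly once; the
manifest records the seed, parameters and SHA-256 checksums of all inputs
and outputs, so identical config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tfaflow import changepoint, clinical, differential, pgee, preprocess, repertoire, syndata
from tfaflow.syndata import ConfigError

log = logging.getLogger("tfaflow")

_STAGES = ("preprocess", "score", "phases", "deg", "lmm", "cdp", "pgee", "align")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters of one pipeline run."""

    out_dir: str = "tfaflow_run"
    ct_table: str | None = None        # None => simulate
    annotations: str | None = None
    episodes: str | None = None
    repertoire: str | None = None
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    preprocess: dict = field(default_factory=dict)  # purity_min, rin_min, ct_min, ct_max
    deg: dict = field(default_factory=dict)         # p_max, fc_min
    lmm: dict = field(default_factory=dict)         # max_genes
    cdp: dict = field(default_factory=dict)         # min_points, penalty, max_genes
    pgee: dict = field(default_factory=dict)        # mode, max_timepoint, folds, max_genes
    align: dict = field(default_factory=dict)       # signature, require_pre

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        stages = {s: True for s in _STAGES}
        stages.update(cfg.stages or {})
        bad = set(stages) - set(_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        cfg.stages = stages
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the output directory.

    Stage artifacts are written once; a failure stops the run with the
    manifest marking the failed stage and partial outputs kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {},
                      "outputs": {}, "parameters": {
                          k: getattr(config, k) for k in
                          ("simulate", "preprocess", "deg", "lmm", "cdp",
                           "pgee", "align")}}
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = _write(df, out / f"{name}.tsv")
        if name in outputs:
            raise RuntimeError(f"stage output {name} written twice")
        outputs[name] = path

    def finish(status: str, failed: str | None = None) -> None:
        manifest["outputs"] = {n: _sha256(p) for n, p in outputs.items()}
        manifest["status"] = status
        if failed:
            manifest["failed_stage"] = failed
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    stage = "load"
    try:
        if config.ct_table is None:
            sim_kwargs = dict(config.simulate)
            if "effect_templates" in sim_kwargs:
                sim_kwargs["effect_templates"] = tuple(
                    syndata.EffectTemplate(t["signature"], tuple(t["window"]),
                                           t["log2_effect"])
                    for t in sim_kwargs["effect_templates"])
            sim = syndata.SimConfig(seed=config.seed, **sim_kwargs)
            cohort = syndata.simulate_cohort(sim)
            syndata.emit_tables(cohort, out / "input")
            for name in ("ct_table.csv", "annotations.csv", "episodes.csv",
                         "repertoire.tsv"):
                manifest["inputs"][name] = _sha256(out / "input" / name)
        else:
            for key in ("ct_table", "annotations", "episodes", "repertoire"):
                p = getattr(config, key)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input path missing for {key}: {p}")
                manifest["inputs"][key] = _sha256(Path(p))
            cohort = syndata.SimulatedCohort(
                ct=pd.read_csv(config.ct_table),
                annotations=pd.read_csv(config.annotations),
                episodes=pd.read_csv(config.episodes),
                repertoire=pd.read_csv(config.repertoire, sep="\t"),
                truth={})
        rep = repertoire.ModuleRepertoire(cohort.repertoire)
        hk = cohort.repertoire.loc[cohort.repertoire.module_id == "HK", "gene"].tolist()
        manifest["stages"]["load"] = "ok"

        stage = "preprocess"
        if config.stages.get("preprocess", True):
            expr, prep_report = preprocess.preprocess_pipeline(
                cohort.ct, cohort.annotations, hk, **config.preprocess)
            emit("expression_log2",
                 expr.log2.reset_index().rename(columns={"index": "sample_id"}))
            emit("preprocess_qc_log", prep_report["qc_log"])
            manifest["stages"]["preprocess"] = "ok"
        else:
            raise ConfigError("preprocess stage cannot be disabled")
        ann = cohort.annotations[
            cohort.annotations.sample_id.isin(expr.log2.index)].reset_index(drop=True)

        stage = "score"
        if config.stages.get("score", True):
            fp_mod = repertoire.score_activity(expr, rep, level="module")
            fp_agg = repertoire.score_activity(expr, rep, level="aggregate")
            repertoire.fingerprint_export(fp_mod, out / "fingerprint_modules.tsv")
            repertoire.fingerprint_export(fp_agg, out / "fingerprint_aggregates.tsv")
            outputs["fingerprint_modules"] = out / "fingerprint_modules.tsv"
            outputs["fingerprint_aggregates"] = out / "fingerprint_aggregates.tsv"
            manifest["stages"]["score"] = "ok"
        else:
            manifest["stages"]["score"] = "skipped"

        stage = "phases"
        phases = clinical.classify_phases(ann, cohort.episodes)
        phase_table = ann[["sample_id", "patient_id", "day"]].assign(phase=phases)
        if config.stages.get("phases", True):
            emit("phases", phase_table)
            counts = phases.value_counts().reindex(clinical.PHASES, fill_value=0)
            manifest["stages"]["phases"] = {"counts": counts.to_dict()}
        else:
            manifest["stages"]["phases"] = "skipped"

        stage = "deg"
        active_mask = (phases == clinical.ACTIVE).to_numpy()
        control_mask = phases.isin([clinical.NEVER, clinical.PRE]).to_numpy()
        deg_table = None
        if config.stages.get("deg", True):
            groups = pd.Series(np.where(active_mask, "active", "control"),
                               index=ann.sample_id)
            sel = active_mask | control_mask
            sub = expr.log2.loc[ann.sample_id[sel]]
            deg_table = differential.deg_test(sub, groups[sel], **config.deg)
            emit("deg", deg_table)
            manifest["stages"]["deg"] = {"n_deg": int(deg_table.deg.sum())}
        else:
            manifest["stages"]["deg"] = "skipped"

        stage = "lmm"
        if config.stages.get("lmm", True):
            max_genes = config.lmm.get("max_genes", 10)
            if deg_table is not None and deg_table.deg.any():
                genes = deg_table[deg_table.deg].gene.tolist()[:max_genes]
            else:
                genes = list(expr.log2.columns[:max_genes])
            gvhd_pat = set(cohort.episodes.patient_id.astype(str))
            group = pd.Series(
                np.where(ann.patient_id.astype(str).isin(gvhd_pat), "gvhd", "no_gvhd"),
                index=ann.sample_id)
            lmm_table = differential.fit_lmm_genewise(
                expr.log2.loc[ann.sample_id], ann, group, genes=genes)
            emit("lmm", lmm_table)
            manifest["stages"]["lmm"] = {"n_genes": len(genes)}
        else:
            manifest["stages"]["lmm"] = "skipped"

        stage = "cdp"
        if config.stages.get("cdp", True):
            cdp_cfg = dict(config.cdp)
            max_genes = cdp_cfg.pop("max_genes", 20)
            min_points = cdp_cfg.pop("min_points", 10)
            eligible, drop_log = clinical.prepare_series(ann, min_points=min_points)
            genes = list(expr.log2.columns[:max_genes])
            results = changepoint.detect_cohort(expr.log2, eligible, genes=genes,
                                                min_points=min_points, **cdp_cfg)
            gvhd_pat = set(cohort.episodes.patient_id.astype(str))
            ctrl = [r for r in results if r.patient_id not in gvhd_pat]
            case = [r for r in results if r.patient_id in gvhd_pat]
            shortlist = changepoint.shortlist_onset_genes(
                case, eligible, cohort.episodes, control_results=ctrl)
            groups = pd.Series({p: ("GVHD" if p in gvhd_pat else "NO GVHD")
                                for p in eligible.patient_id.unique()})
            summary = changepoint.cdp_summary(results, groups, rep)
            emit("cdp_shortlist", shortlist)
            emit("cdp_summary", summary)
            emit("cdp_excluded_series", drop_log)
            manifest["stages"]["cdp"] = {
                "n_series": len(results), "n_shortlisted": len(shortlist)}
        else:
            manifest["stages"]["cdp"] = "skipped"

        stage = "pgee"
        if config.stages.get("pgee", True):
            pg_cfg = dict(config.pgee)
            max_genes = pg_cfg.pop("max_genes", 30)
            genes = list(expr.log2.columns[:max_genes])
            fit, pg_report = pgee.apply_pgee_protocol(
                expr.log2[genes], ann, cohort.episodes, seed=config.seed,
                repertoire=rep, **pg_cfg)
            emit("pgee_selected", pg_report["selected"])
            curve = pg_report["cv_curve"]
            emit("pgee_cv_curve", pd.DataFrame({"lambda": curve.lambdas,
                                                "deviance": curve.deviance}))
            manifest["stages"]["pgee"] = {
                "chosen_lambda": curve.chosen,
                "n_selected": len(fit.selected)}
        else:
            manifest["stages"]["pgee"] = "skipped"

        stage = "align"
        if config.stages.get("align", True):
            al_cfg = dict(config.align)
            signature = al_cfg.pop("signature", "interferon")
            fp_mod = repertoire.score_activity(expr, rep, level="module")
            sig_modules = fp_mod.annotations[
                fp_mod.annotations.function_label == signature].id.tolist()
            if sig_modules:
                values = fp_mod.scores.loc[sig_modules].mean(axis=0)
            else:
                values = expr.log2.mean(axis=1)
            traj = clinical.align_to_onset(values, ann, cohort.episodes, **al_cfg)
            emit("aligned_points", traj.points)
            emit("aligned_mean_curve", traj.mean_curve)
            manifest["stages"]["align"] = {
                "n_episodes": int(traj.points.episode_id.nunique()) if len(traj.points) else 0,
                "signature": signature}
        else:
            manifest["stages"]["align"] = "skipped"

        finish("ok")
        return out
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        finish("failed", failed=stage)
        raise


def report(out_dir: str | Path) -> dict:
    """Machine-readable per-stage summary of a completed (or partial) run."""
    out = Path(out_dir)
    summary: dict = {"out_dir": str(out), "warnings": []}
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        summary["warnings"].append("no manifest found (run incomplete or missing)")
        return summary
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    summary["status"] = manifest.get("status", "unknown")
    summary["seed"] = manifest.get("seed")
    summary["stages"] = manifest.get("stages", {})
    for stage in _STAGES:
        if stage not in summary["stages"]:
            summary["warnings"].append(f"stage {stage} missing from manifest")
    def _count(name):
        p = out / f"{name}.tsv"
        if p.exists():
            return max(sum(1 for _ in open(p)) - 1, 0)
        return None
    summary["counts"] = {
        "samples": _count("phases"),
        "deg": None,
        "cdp_shortlist": _count("cdp_shortlist"),
        "pgee_selected": _count("pgee_selected"),
    }
    deg_path = out / "deg.tsv"
    if deg_path.exists():
        deg = pd.read_csv(deg_path, sep="\t")
        summary["counts"]["deg"] = int(deg.deg.sum()) if "deg" in deg else None
    return summary
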