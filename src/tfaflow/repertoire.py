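"""Modular fingerprint framework: gene -> module -> aggregate scoring.

The blood transcriptional module repertoire groups panel genes into fixed
co-expression modules (four genes each on this panel) that nest into
aggregates sharing activity profiles and functional labels (e.g.
"interferon", "erythroid", "TBD" for uncharacterized).  Module activity is
summarized per sample either as the mean log2 expression of member genes or
as a percent response: the percentage of member genes up-regulated beyond a
fold-change threshold against a reference sample group minus the percentage
down-regulated, bounded in [-100, +100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tfaflow.preprocess import ExpressionMatrix
from tfaflow.syndata import ConfigError


class RepertoireError(ValueError):
    """Malformed module repertoire."""


@dataclass
class ModuleRepertoire:
    """Validated gene/module/aggregate mapping."""

    table: pd.DataFrame  # gene, module_id, aggregate_id, function_label

    def __post_init__(self) -> None:
        required = {"gene", "module_id", "aggregate_id", "function_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise RepertoireError(f"repertoire missing columns: {sorted(missing)}")
        dup = self.table.gene[self.table.gene.duplicated()]
        if len(dup):
            raise RepertoireError(f"gene listed in more than one module: {dup.iloc[0]}")
        agg_per_module = self.table.groupby("module_id")["aggregate_id"].nunique()
        bad = agg_per_module[agg_per_module > 1]
        if len(bad):
            raise RepertoireError(f"module in more than one aggregate: {bad.index[0]}")
        self.table = self.table.copy()
        self.table["function_label"] = self.table["function_label"].fillna("TBD")

    @property
    def targets(self) -> pd.DataFrame:
        return self.table[self.table.module_id != "HK"]

    @property
    def modules(self) -> list[str]:
        return self.targets.module_id.unique().tolist()

    @property
    def aggregates(self) -> list[str]:
        return self.targets.aggregate_id.unique().tolist()

    def genes_of(self, module_id: str) -> list[str]:
        return self.table.loc[self.table.module_id == module_id, "gene"].tolist()

    def module_of(self) -> pd.Series:
        return self.targets.set_index("gene")["module_id"]

    def counts(self) -> dict:
        t = self.targets
        return {"genes": len(t), "modules": t.module_id.nunique(),
                "aggregates": t.aggregate_id.nunique()}


def load_repertoire(path: str | Path, expected_module_size: int | None = 4,
                    strict: bool = False) -> ModuleRepertoire:
    """Read a repertoire TSV (gene, module_id, aggregate_id, function_label).

    Modules whose member count differs from ``expected_module_size`` raise in
    strict mode and warn otherwise.  Missing function labels load as "TBD".
    """
    table = pd.read_csv(path, sep="\t")
    rep = ModuleRepertoire(table)
    if expected_module_size is not None:
        sizes = rep.targets.groupby("module_id").size()
        off = sizes[sizes != expected_module_size]
        if len(off):
            msg = (f"{len(off)} modules deviate from the expected size "
                   f"{expected_module_size}: {off.index.tolist()[:5]}")
            if strict:
                raise RepertoireError(msg)
            warnings.warn(msg)
    return rep


@dataclass
class FingerprintMatrix:
    """Module (or aggregate) x sample activity scores."""

    scores: pd.DataFrame          # rows: module/aggregate ids; cols: sample ids
    level: str                    # "module" | "aggregate"
    method: str                   # "mean-log2" | "percent-response"
    annotations: pd.DataFrame     # id, aggregate_id, function_label
    reference: list[str] | None = None


def _mean_log2_scores(log2: pd.DataFrame, members: dict[str, list[str]]) -> pd.DataFrame:
    rows = {}
    for mid, genes in members.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[mid] = np.nanmean(log2[genes].to_numpy(dtype=float), axis=1)
    return pd.DataFrame(rows, index=log2.index).T


def _percent_response_scores(linear: pd.DataFrame, members: dict[str, list[str]],
                             reference: list[str], fc_min: float) -> pd.DataFrame:
    ref = linear.loc[linear.index.isin(reference)]
    if ref.empty:
        raise ConfigError("reference group matches no samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_mean = np.nanmean(ref.to_numpy(dtype=float), axis=0)
    fc = linear.to_numpy(dtype=float) / ref_mean[None, :]
    up = fc > fc_min
    down = fc < 1.0 / fc_min
    present = ~np.isnan(fc)
    cols = {g: i for i, g in enumerate(linear.columns)}
    rows = {}
    for mid, genes in members.items():
        idx = [cols[g] for g in genes]
        n = present[:, idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = 100.0 * (up[:, idx].sum(axis=1) - down[:, idx].sum(axis=1)) / n
        score[n == 0] = np.nan
        rows[mid] = score
    return pd.DataFrame(rows, index=linear.index).T


def score_activity(expr: ExpressionMatrix, rep: ModuleRepertoire,
                   level: str = "module", method: str = "mean-log2",
                   reference: list[str] | None = None,
                   fc_min: float = 1.5) -> FingerprintMatrix:
    """Score module or aggregate activity per sample.

    mean-log2: mean of member-gene log2 values, missing ignored.
    percent-response: (% members with FC > fc_min up vs the reference-group
    mean) - (% members down), in [-100, +100]; requires ``reference``.
    Aggregate level averages the member-module scores (unweighted).
    Repertoire genes absent from the expression matrix are excluded from
    their module's score with a warning.
    """
    if level not in ("module", "aggregate"):
        raise ConfigError(f"unknown level {level!r}")
    if method not in ("mean-log2", "percent-response"):
        raise ConfigError(f"unknown method {method!r}")
    if method == "percent-response" and not reference:
        raise ConfigError("percent-response scoring requires a reference sample group")

    targets = rep.targets
    missing = sorted(set(targets.gene) - set(expr.log2.columns))
    if missing:
        warnings.warn(f"{len(missing)} repertoire genes absent from expression "
                      f"matrix, excluded from scores: {missing[:5]}")
    usable = targets[targets.gene.isin(expr.log2.columns)]
    members = {m: g.gene.tolist() for m, g in usable.groupby("module_id", sort=False)}
    members = {m: g for m, g in members.items() if g}

    if method == "mean-log2":
        mod_scores = _mean_log2_scores(expr.log2, members)
    else:
        mod_scores = _percent_response_scores(expr.linear, members, reference, fc_min)

    mod_ann = (usable.groupby("module_id", sort=False)
               .agg(aggregate_id=("aggregate_id", "first"),
                    function_label=("function_label", "first")).reset_index())
    if level == "aggregate":
        agg_of = mod_ann.set_index("module_id")["aggregate_id"]
        scores = mod_scores.groupby(agg_of.reindex(mod_scores.index)).mean()
        scores.index.name = "aggregate_id"
        ann = (mod_ann.groupby("aggregate_id", sort=False)
               .agg(function_label=("function_label",
                                    lambda s: "/".join(pd.unique(s)[:3])))
               .reset_index())
        ann.insert(0, "id", ann.aggregate_id)
        order = sorted(scores.index, key=str)
    else:
        scores = mod_scores
        scores.index.name = "module_id"
        ann = mod_ann.rename(columns={"module_id": "id"})
        # rows ordered by aggregate then module
        key = ann.set_index("id")["aggregate_id"]
        order = sorted(scores.index, key=lambda m: (str(key.get(m, "")), str(m)))
    scores = scores.loc[order]
    ann = ann.set_index("id").loc[order].reset_index()
    return FingerprintMatrix(scores=scores, level=level, method=method,
                             annotations=ann, reference=list(reference) if reference else None)


def fingerprint_export(fp: FingerprintMatrix, path: str | Path) -> Path:
    """Write a fingerprint matrix as TSV with annotation leading columns."""
    path = Path(path)
    out = fp.annotations.merge(
        fp.scores.reset_index().rename(columns={fp.scores.index.name: "id"}),
        on="id", how="right")
    out.to_csv(path, sep="\t", index=False)
    return path


def fingerprint_read(path: str | Path, level: str = "module",
                     method: str = "mean-log2") -> FingerprintMatrix:
    """Load a fingerprint TSV written by :func:`fingerprint_export`."""
    df = pd.read_csv(path, sep="\t")
    ann_cols = [c for c in ("id", "aggregate_id", "function_label") if c in df.columns]
    scores = df.drop(columns=[c for c in ann_cols if c != "id"]).set_index("id")
    scores.index.name = "module_id" if level == "module" else "aggregate_id"
    return FingerprintMatrix(scores=scores, level=level, method=method,
                             annotations=df[ann_cols])
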