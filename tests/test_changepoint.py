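"""Change-point detection: PELT vs exhaustive dynamic programming,
invariances, penalty monotonicity, onset shortlisting and cohort summary."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tfaflow.changepoint import (VAR_FLOOR, ChangePointResult, cdp_summary,
                                 detect_changepoints, onset_timepoints,
                                 shortlist_onset_genes, SeriesTooShortError)


# ---------------------------------------------------------------- DP oracle

def _cost(y, s, t, cost="meanvar", mbic=True):
    seg = y[s:t]
    n = len(seg)
    if cost == "meanvar":
        var = max(np.var(seg), VAR_FLOOR)
        c = n * math.log(var)
    else:
        c = float(np.sum((seg - seg.mean()) ** 2))
    return c + (math.log(n) if mbic else 0.0)


def oracle_segmentation(y, beta, min_seg=2, cost="meanvar", mbic=True):
    """O(n^2) exhaustive dynamic program over all segmentations."""
    n = len(y)
    f = [math.inf] * (n + 1)
    f[0] = -beta
    last = [0] * (n + 1)
    for t in range(min_seg, n + 1):
        for s in [0] + list(range(min_seg, t - min_seg + 1)):
            if f[s] == math.inf:
                continue
            val = f[s] + _cost(y, s, t, cost, mbic) + beta
            if val < f[t]:
                f[t], last[t] = val, s
    cps, t = [], n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), f[n]


def _series(y):
    return pd.Series(np.asarray(y, dtype=float), index=range(len(y)))


class TestDetectChangepoints:
    def test_constant_series_no_changepoints(self):
        r = detect_changepoints(_series([3.0] * 12))
        assert r.positions == [] and len(r.segments) == 1

    def test_large_mean_step_found_at_exact_position(self, rng):
        y = np.concatenate([rng.normal(0, 1, 11), rng.normal(5, 1, 9)])
        r = detect_changepoints(_series(y))
        assert r.positions == [11]
        # exhaustive search over single-split segmentations agrees
        best = min(range(2, 19),
                   key=lambda k: _cost(y, 0, k) + _cost(y, k, 20))
        assert best == 11

    def test_variance_change_needs_meanvar_cost(self, rng):
        y = np.concatenate([rng.normal(0, 0.5, 10), rng.normal(0, 4.5, 10)])
        r_mv = detect_changepoints(_series(y), cost="meanvar")
        assert 10 in r_mv.positions
        # a mean-only cost misses the pure variance shift (negative control)
        r_mean = detect_changepoints(_series(y), cost="mean", penalty=50.0)
        assert 10 not in r_mean.positions

    def test_pelt_equals_exhaustive_dp_on_random_series(self):
        # oracle equivalence over assorted lengths, signals and penalties
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(10, 26))
            y = rng.normal(0, 1, n)
            if trial % 3 == 1:  # inject a mean step
                k = int(rng.integers(3, n - 3))
                y[k:] += rng.uniform(1, 5)
            if trial % 3 == 2:  # inject a variance step
                k = int(rng.integers(3, n - 3))
                y[k:] *= rng.uniform(2, 4)
            for penalty in ("mbic", 5.0):
                r = detect_changepoints(_series(y), penalty=penalty, min_points=5)
                mbic = penalty == "mbic"
                beta = 3.0 * math.log(n) if mbic else penalty
                cps, val = oracle_segmentation(y, beta, mbic=mbic)
                assert r.positions == cps, (trial, penalty)
                assert r.criterion == pytest.approx(val, abs=1e-6)

    def test_shift_and_scale_invariance_of_positions(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(4, 2, 10)])
        base = detect_changepoints(_series(y))
        shifted = detect_changepoints(_series(y + 100.0))
        scaled = detect_changepoints(_series(y * 7.0))
        assert base.positions == shifted.positions == scaled.positions

    def test_penalty_monotonicity(self, rng):
        y = rng.normal(0, 1, 24)
        y[8:] += 3
        y[16:] -= 5
        counts = []
        for beta in (1.0, 4.0, 10.0, 30.0, 100.0):
            r = detect_changepoints(_series(y), penalty=beta)
            counts.append(len(r.positions))
        assert counts == sorted(counts, reverse=True)

    def test_missing_values_dropped_and_recorded(self, rng):
        y = list(rng.normal(0, 1, 8)) + [np.nan] + list(rng.normal(6, 1, 6))
        r = detect_changepoints(_series(y), min_points=10)
        assert r.dropped_missing == [8]
        assert r.n_points == 14
        assert r.positions == [9]  # clinical timepoint label after the gap

    def test_min_points_eligibility(self, rng):
        with pytest.raises(SeriesTooShortError):
            detect_changepoints(_series(rng.normal(size=9)))
        detect_changepoints(_series(rng.normal(size=10)))  # boundary passes

    def test_min_segment_length_respected(self, rng):
        y = rng.normal(0, 0.1, 15)
        y[7] = 50.0  # single outlier cannot form a 1-point segment
        r = detect_changepoints(_series(y), min_seg=2)
        for seg in r.segments:
            assert seg["n"] >= 2


# ------------------------------------------------------- onset shortlisting

def _ann(days_by_patient):
    rows = []
    for p, days in days_by_patient.items():
        for i, d in enumerate(days):
            rows.append({"sample_id": f"{p}_{i}", "patient_id": p, "day": d,
                         "timepoint_index": i})
    return pd.DataFrame(rows)


def _result(patient, gene, positions):
    return ChangePointResult(patient_id=patient, gene=gene,
                             positions=positions, segments=[], criterion=0.0)


class TestShortlistOnsetGenes:
    ann = _ann({"p1": [0, 10, 20, 30, 40, 50], "ctrl": [0, 10, 20, 30]})
    eps = pd.DataFrame([{"patient_id": "p1", "type": "acute", "onset_day": 25,
                         "resolution_day": 45, "grade": "aGVHD II"}])

    def test_onset_timepoint_mapping(self):
        allowed = onset_timepoints(self.ann, self.eps)
        # last sample before day 25 is index 2 (day 20); first at/after is 3
        assert allowed["p1"] == {2, 3}

    def test_changepoint_at_onset_shortlisted(self):
        out = shortlist_onset_genes([_result("p1", "gA", [3])], self.ann, self.eps)
        assert out.gene.tolist() == ["gA"]
        assert out.gvhd_type.tolist() == ["acute"]

    def test_extra_late_changepoint_violates_exclusivity(self):
        out = shortlist_onset_genes([_result("p1", "gA", [3, 5])],
                                    self.ann, self.eps)
        assert len(out) == 0

    def test_gene_changing_in_control_removed(self):
        out = shortlist_onset_genes(
            [_result("p1", "gA", [3])], self.ann, self.eps,
            control_results=[_result("ctrl", "gA", [1])])
        assert len(out) == 0

    def test_control_without_changes_does_not_remove(self):
        out = shortlist_onset_genes(
            [_result("p1", "gA", [2])], self.ann, self.eps,
            control_results=[_result("ctrl", "gA", [])])
        assert out.gene.tolist() == ["gA"]


class TestCdpSummary:
    def test_percentages(self):
        results = ([_result(f"p{i}", "gA", [2] if i < 3 else []) for i in range(12)])
        groups = pd.Series({f"p{i}": "GVHD" for i in range(12)})
        out = cdp_summary(results, groups)
        row = out[(out.gene == "gA") & (out.cohort == "GVHD")].iloc[0]
        assert row.percent == pytest.approx(25.0)
        assert row.n_series == 12

    def test_all_series_changed_is_100(self):
        results = [_result(f"p{i}", "gB", [1]) for i in range(4)]
        groups = pd.Series({f"p{i}": "aGVHD" for i in range(4)})
        out = cdp_summary(results, groups)
        assert out.percent.iloc[0] == pytest.approx(100.0)

    def test_empty_cohort_empty_table(self):
        out = cdp_summary([], pd.Series(dtype=object))
        assert len(out) == 0
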