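"""Ct preprocessing: QC gates, detectable-range masking, housekeeping
normalization arithmetic and empirical-Bayes batch correction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tfaflow.preprocess import (ExpressionMatrix, batch_correct,
                                mask_undetectable, normalize_hk, qc_filter)
from tfaflow.syndata import ConfigError


def _ann(rows):
    return pd.DataFrame(rows, columns=["sample_id", "purity", "rin",
                                       "bioanalyzer_ok"])


class TestQcFilter:
    @pytest.mark.parametrize("purity,rin,override,kept", [
        (1.6, 8.0, 0, False),   # purity at/below 1.7 fails
        (1.9, 6.5, 0, True),    # both above thresholds pass
        (1.7, 8.0, 0, False),   # boundary: strict inequality
        (1.9, 6.0, 0, False),
        (1.5, 3.0, 1, True),    # Bioanalyzer override retains
    ])
    def test_purity_and_rin_gates(self, purity, rin, override, kept):
        ann = _ann([("s1", purity, rin, override)])
        retained, log = qc_filter(ann)
        assert ("s1" in set(retained.sample_id)) is kept
        if override and kept:
            assert (log.action == "kept-override").any()

    def test_missing_metadata_kept_with_warning(self):
        ann = _ann([("s1", np.nan, 8.0, 0)])
        with pytest.warns(UserWarning, match="missing QC"):
            retained, _ = qc_filter(ann)
        assert len(retained) == 1


class TestMaskUndetectable:
    def test_out_of_range_censored_in_range_unchanged(self):
        ct = pd.DataFrame({"sample_id": ["a", "b"], "batch": [0, 0],
                           "g1": [36.0, 20.0], "g2": [4.0, 30.0]})
        masked, report = mask_undetectable(ct, 5, 35)
        assert np.isnan(masked.g1[0]) and masked.g1[1] == 20.0
        assert np.isnan(masked.g2[0]) and masked.g2[1] == 30.0
        assert report["censored_total"] == 2

    def test_fully_undetectable_gene_reported(self):
        ct = pd.DataFrame({"sample_id": ["a", "b"],
                           "g1": [40.0, 39.0], "g2": [20.0, 21.0]})
        _, report = mask_undetectable(ct)
        assert report["all_missing_assays"] == ["g1"]

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigError):
            mask_undetectable(pd.DataFrame({"sample_id": []}), 35, 5)


class TestNormalizeHk:
    def _ct(self, g_vals, hk_vals):
        row = {"sample_id": "s1", "batch": 0}
        row.update({f"g{i}": v for i, v in enumerate(g_vals)})
        row.update({f"hk{i}": v for i, v in enumerate(hk_vals)})
        return pd.DataFrame([row])

    def test_neg_delta_ct_arithmetic(self):
        ct = self._ct([25.0], [20.0, 20.0])
        expr = normalize_hk(ct, ["hk0", "hk1"])
        assert expr.log2.loc["s1", "g0"] == pytest.approx(-5.0)
        assert expr.linear.loc["s1", "g0"] == pytest.approx(0.03125)

    def test_gene_equal_to_pool_has_linear_one(self):
        ct = self._ct([21.0], [20.0, 22.0])
        expr = normalize_hk(ct, ["hk0", "hk1"])
        assert expr.linear.loc["s1", "g0"] == pytest.approx(1.0)

    def test_missing_ct_propagates(self):
        ct = self._ct([np.nan], [20.0, 20.0])
        expr = normalize_hk(ct, ["hk0", "hk1"])
        assert np.isnan(expr.log2.loc["s1", "g0"])

    def test_invariant_to_global_sample_shift(self, rng):
        # adding a constant to every Ct of a sample leaves -dCt unchanged
        base = self._ct(list(rng.uniform(18, 30, 5)), list(rng.uniform(19, 21, 4)))
        shifted = base.copy()
        cols = [c for c in base.columns if c not in ("sample_id", "batch")]
        shifted[cols] = shifted[cols] + 3.7
        hk = [c for c in cols if c.startswith("hk")]
        np.testing.assert_allclose(normalize_hk(base, hk).log2.to_numpy(),
                                   normalize_hk(shifted, hk).log2.to_numpy(),
                                   rtol=0, atol=1e-12)

    def test_sample_with_sparse_housekeeping_pool_excluded(self):
        ct = self._ct([25.0], [20.0, np.nan, np.nan, np.nan])
        expr = normalize_hk(ct, ["hk0", "hk1", "hk2", "hk3"])
        assert len(expr.log2) == 0
        assert len(expr.excluded_samples) == 1

    def test_unknown_housekeeping_assay_rejected(self):
        ct = self._ct([25.0], [20.0])
        with pytest.raises(ConfigError, match="unknown housekeeping"):
            normalize_hk(ct, ["hk0", "nope"])


def _expr_from_matrix(y, batches):
    idx = [f"s{i}" for i in range(y.shape[0])]
    log2 = pd.DataFrame(y, index=idx,
                        columns=[f"g{j}" for j in range(y.shape[1])])
    meta = pd.DataFrame({"sample_id": idx, "batch": batches}, index=idx)
    return ExpressionMatrix(log2=log2, meta=meta)


class TestBatchCorrect:
    def test_single_batch_identity(self, rng):
        y = rng.normal(size=(10, 6))
        expr = _expr_from_matrix(y, [0] * 10)
        out = batch_correct(expr)
        np.testing.assert_allclose(out.log2.to_numpy(), y, atol=1e-12)
        assert out.batch_corrected

    def test_constant_additive_offset_equalized(self, rng):
        # batch 2 = batch 1 residual pattern + 2 Ct; homoscedastic genes
        n, g = 12, 8
        resid = rng.normal(0, 0.5, size=n)          # shared residual column
        base = rng.uniform(-2, 2, size=g)           # gene levels
        y1 = base[None, :] + resid[:, None]
        y2 = y1 + 2.0
        y = np.vstack([y1, y2])
        expr = _expr_from_matrix(y, [0] * n + [1] * n)
        out = batch_correct(expr)
        m0 = out.log2.iloc[:n].mean(axis=0)
        m1 = out.log2.iloc[n:].mean(axis=0)
        np.testing.assert_allclose(m0.to_numpy(), m1.to_numpy(), atol=1e-6)

    def test_eb_converges_to_standardization_oracle_for_large_batches(self, rng):
        # batch scale factor 2: the EB result must approach the direct
        # per-batch standardization oracle as batch size grows
        g = 12
        gene_sd = rng.uniform(0.5, 2.0, size=g)  # heteroscedastic genes

        def max_dev(n):
            y1 = rng.normal(0, 1.0, size=(n, g)) * gene_sd
            y2 = rng.normal(0.5, 2.0, size=(n, g)) * gene_sd
            y = np.vstack([y1, y2])
            expr = _expr_from_matrix(y, [0] * n + [1] * n)
            eb = batch_correct(expr, shrink=True).log2.to_numpy()
            oracle = batch_correct(expr, shrink=False).log2.to_numpy()
            v_or = [oracle[:n].var(axis=0, ddof=1), oracle[n:].var(axis=0, ddof=1)]
            np.testing.assert_allclose(v_or[0], v_or[1], rtol=1e-10)
            return float(np.sqrt(np.mean((eb - oracle) ** 2)))

        d_small, d_large = max_dev(50), max_dev(800)
        assert d_large < d_small
        assert d_large < 0.05

    def test_grand_mean_preserved(self, rng):
        y = rng.normal(size=(40, 5))
        y[20:] += 1.5
        expr = _expr_from_matrix(y, [0] * 20 + [1] * 20)
        out = batch_correct(expr)
        np.testing.assert_allclose(out.log2.mean(axis=0), y.mean(axis=0), atol=0.05)

    def test_missing_entries_stay_missing(self, rng):
        y = rng.normal(size=(10, 4))
        y[0, 0] = np.nan
        expr = _expr_from_matrix(y, [0] * 5 + [1] * 5)
        out = batch_correct(expr)
        assert np.isnan(out.log2.iloc[0, 0])
        assert out.log2.isna().sum().sum() == 1

    def test_rerun_on_homogenized_data_is_stable(self, rng):
        n = 50
        y = np.vstack([rng.normal(0, 1, (n, 6)), rng.normal(1, 2, (n, 6))])
        expr = _expr_from_matrix(y, [0] * n + [1] * n)
        once = batch_correct(expr, shrink=False)
        twice = batch_correct(once, shrink=False)
        np.testing.assert_allclose(once.log2.to_numpy(), twice.log2.to_numpy(),
                                   atol=1e-6)

    def test_singleton_batch_passed_through_with_warning(self, rng):
        y = rng.normal(size=(5, 3))
        expr = _expr_from_matrix(y, [0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="single sample"):
            out = batch_correct(expr)
        np.testing.assert_allclose(out.log2.iloc[4].to_numpy(), y[4], atol=1e-12)

    def test_cross_check_against_reference_combat(self, rng):
        # independent implementation check on complete data
        scanpy = pytest.importorskip("scanpy")
        import anndata as ad
        n, g = 40, 12
        y = np.vstack([rng.normal(0, 1, (n, g)), rng.normal(1.2, 1.8, (n, g))])
        batches = np.array(["a"] * n + ["b"] * n)
        expr = _expr_from_matrix(y, list(batches))
        mine = batch_correct(expr).log2.to_numpy()
        adata = ad.AnnData(y.copy())
        adata.obs["batch"] = pd.Categorical(batches)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scanpy.pp.combat(adata, key="batch")
        theirs = adata.X
        assert np.corrcoef(mine.ravel(), theirs.ravel())[0, 1] > 0.999
        assert np.max(np.abs(mine - theirs)) < 0.2
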