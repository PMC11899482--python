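"""DEG dual-threshold testing, hierarchical clustering and the
longitudinal mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfaflow.differential import deg_test, fit_lmm, hier_cluster, top_split
from tfaflow.syndata import ConfigError


def _frame(a, b, genes=None):
    """Two-group log2 matrix: a and b are (n_samples, n_genes) arrays."""
    x = np.vstack([a, b])
    genes = genes or [f"g{j}" for j in range(x.shape[1])]
    idx = [f"s{i}" for i in range(x.shape[0])]
    log2 = pd.DataFrame(x, index=idx, columns=genes)
    groups = pd.Series(["A"] * len(a) + ["B"] * len(b), index=idx)
    return log2, groups


class TestDegTest:
    def test_dual_gate_fold_change_alone_insufficient(self, rng):
        # strong p, FC below 1.5 -> not a DEG
        a = rng.normal(0.4, 0.01, size=(30, 1))
        b = rng.normal(0.0, 0.01, size=(30, 1))   # FC = 2^0.4 ~ 1.32
        log2, groups = _frame(a, b)
        out = deg_test(log2, groups)
        assert out.p[0] < 1e-8 and not out.deg[0]

    def test_p_gate_alone_insufficient(self, rng):
        # big fold change, tiny sample overlap -> happens to be non-significant
        a = rng.normal(1.2, 3.0, size=(3, 1))
        b = rng.normal(0.0, 3.0, size=(3, 1))
        log2, groups = _frame(a, b)
        out = deg_test(log2, groups)
        if out.fc[0] > 1.5:  # construction guarantees FC most of the time
            assert bool(out.deg[0]) == bool(out.p[0] < 0.05)

    def test_welch_against_scipy_oracle(self, rng):
        a = rng.normal(0, 1, size=(12, 4))
        b = rng.normal(0.5, 2, size=(8, 4))
        log2, groups = _frame(a, b)
        out = deg_test(log2, groups)
        for j in range(4):
            p_oracle = stats.ttest_ind(a[:, j], b[:, j], equal_var=False).pvalue
            assert out.p[j] == pytest.approx(p_oracle, rel=1e-12)

    def test_label_swap_inverts_fold_change(self, rng):
        a = rng.normal(1, 0.5, size=(10, 3))
        b = rng.normal(0, 0.5, size=(10, 3))
        log2, groups = _frame(a, b)
        fwd = deg_test(log2, groups)
        swapped = groups.map({"A": "B", "B": "A"})
        rev = deg_test(log2, swapped)
        np.testing.assert_allclose(fwd.fc, 1.0 / rev.fc, rtol=1e-10)
        np.testing.assert_allclose(fwd.p, rev.p, rtol=1e-10)

    def test_power_for_twofold_shift(self):
        # 2-fold shift, n=30/30, residual sd 0.25 log2: essentially always hit
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(900 + s)
            a = rng.normal(1.0, 0.25, size=(30, 1))
            b = rng.normal(0.0, 0.25, size=(30, 1))
            log2, groups = _frame(a, b)
            out = deg_test(log2, groups)
            hits += int(out.deg[0])
        assert hits >= 39

    def test_undersized_gene_reported_untested(self):
        log2, groups = _frame(np.array([[1.0], [np.nan]]),
                              np.array([[0.0], [0.1]]))
        out = deg_test(log2, groups)
        assert not out.tested[0] and not out.deg[0]

    def test_single_group_rejected(self, rng):
        log2, groups = _frame(rng.normal(size=(4, 2)), rng.normal(size=(0, 2)))
        with pytest.raises(ConfigError):
            deg_test(log2, pd.Series("A", index=log2.index))


class TestHierCluster:
    def test_identical_columns_merge_at_zero(self, rng):
        base = rng.normal(size=6)
        m = pd.DataFrame({"x": base, "y": base, "z": rng.normal(size=6)})
        order, z = hier_cluster(m, axis=1)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first_pair = {order.index("x"), order.index("y")}
        assert abs(max(first_pair) - min(first_pair)) == 1  # adjacent leaves

    def test_block_structure_top_split_matches_bruteforce(self, rng):
        # two uncorrelated blocks; exhaustive minimum-linkage 2-partition
        t = np.linspace(0, 4 * np.pi, 30)
        block1 = [np.sin(t) + rng.normal(0, 0.05, 30) for _ in range(4)]
        block2 = [np.cos(3 * t) + rng.normal(0, 0.05, 30) for _ in range(4)]
        m = pd.DataFrame(block1 + block2)
        order, z = hier_cluster(m)
        left, right = top_split(z, 8)
        expected = [{0, 1, 2, 3}, {4, 5, 6, 7}]
        assert sorted([left, right], key=min) == expected

        # brute-force oracle: best 2-partition under average correlation
        # linkage = the one minimizing mean between-cluster similarity
        from itertools import combinations
        x = m.to_numpy()
        corr = np.corrcoef(x)
        best, best_val = None, np.inf
        items = set(range(8))
        for k in range(1, 4 + 1):
            for sub in combinations(range(8), k):
                sa, sb = set(sub), items - set(sub)
                val = np.mean([corr[i, j] for i in sa for j in sb])
                if val < best_val:
                    best_val, best = val, sorted([sa, sb], key=min)
        assert best == expected

    def test_single_item_trivial_tree(self):
        order, z = hier_cluster(pd.DataFrame({"a": [1.0, 2.0]}).T)
        assert order == ["a"] and z.shape == (0, 4)

    def test_zero_variance_row_handled(self, rng):
        m = pd.DataFrame(np.vstack([np.ones(5), rng.normal(size=(3, 5))]))
        order, z = hier_cluster(m)
        assert len(order) == 4  # no crash; constant row clustered last
        assert z[-1, 2] >= z[0, 2]

    def test_all_missing_row_named_in_error(self):
        m = pd.DataFrame([[np.nan] * 4, [1, 2, 3, 4]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            hier_cluster(m)

    def test_merge_heights_nondecreasing(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 20)))
        _, z = hier_cluster(m)
        assert np.all(np.diff(z[:, 2]) >= -1e-12)


def _lmm_data(delta, seed, n_per=8, n_tp=10, sd=0.4, re_sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, grp in enumerate(("A", "B")):
        for i in range(n_per):
            pid = f"{grp}{i}"
            b0 = rng.normal(0, re_sd)
            slope = 0.3 + delta * gi  # log2 per 100 days
            for d in np.arange(n_tp) * 14.0:
                rows.append((pid, grp, d, b0 + slope * d / 100 + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["patient", "group", "day", "y"])


class TestFitLmm:
    def test_identical_trajectories_give_null_interaction(self):
        df = _lmm_data(0.0, seed=4)
        r = fit_lmm(df.y, df.day, df.group, df.patient)
        est, se = r.estimates["time:group"], r.stderrs["time:group"]
        assert abs(est) < 3 * se

    def test_zero_random_variance_matches_ols_oracle(self):
        import statsmodels.api as sm
        df = _lmm_data(0.5, seed=5, re_sd=0.0)
        r = fit_lmm(df.y, df.day, df.group, df.patient)
        t = df.day.to_numpy() / 100.0
        g = (df.group == "B").to_numpy(float)
        x = np.column_stack([np.ones(len(df)), t, g, t * g])
        ols = sm.OLS(df.y.to_numpy(), x).fit()
        assert r.estimates["time:group"] == pytest.approx(ols.params[3], abs=1e-6)

    def test_interaction_invariant_to_time_centering(self):
        df = _lmm_data(0.5, seed=6)
        r1 = fit_lmm(df.y, df.day, df.group, df.patient)
        r2 = fit_lmm(df.y, df.day - df.day.mean(), df.group, df.patient)
        assert r1.estimates["time:group"] == pytest.approx(
            r2.estimates["time:group"], abs=1e-5)

    def test_slope_difference_recovery_short(self):
        # reduced version of the recovery study (full run in acceptance)
        ests = []
        for s in range(20):
            df = _lmm_data(0.5, seed=100 + s, n_per=10, n_tp=12)
            r = fit_lmm(df.y, df.day, df.group, df.patient)
            ests.append(r.estimates["time:group"])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.08)

    def test_preconditions(self):
        df = _lmm_data(0.0, seed=7, n_per=1)
        with pytest.raises(ConfigError, match="2 patients"):
            fit_lmm(df.y, df.day, df.group, df.patient)
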