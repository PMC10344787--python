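"""Unit tests for the differential phosphoproteomics operations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitophos.errors import ConfigurationError, DataError
from mitophos.phospho import (
    PhosphoPeptideTable,
    bh_adjust,
    call_significance,
    cluster_sites,
    compare_cluster_groups,
    delta_ps,
    detect_anticonservative,
    differential_analysis,
    preprocess,
    report_fractions,
    welch_test,
    zscore_sites,
)
from mitophos.synthdata import PhosphoSimConfig, simulate_phospho_table


def brute_force_bh(p):
    """Independent step-up oracle: p_adj[i] = min over j with p[j] >= p[i] of m*p[j]/rank[j]."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, m * p[i] / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestWelch:
    def test_identical_groups_degenerate(self):
        assert welch_test([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_hand_computed_example(self):
        # means 2 vs 5, each var 1, n=3: se = sqrt(2/3), t = -3/se, df = 4
        t, p = welch_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-4)
        assert t == pytest.approx(-3.6742, abs=1e-4)
        # p from the t distribution with Welch-Satterthwaite df = 4
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(3.6742, df=4), rel=1e-3)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = welch_test([1, 2, 3], [4, 5, 7])
        t2, p2 = welch_test([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_small_group_raises(self):
        with pytest.raises(DataError):
            welch_test([1.0], [2.0, 3.0])


class TestBH:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.03, 0.04, 0.05]), [0.04, 0.05, 0.05, 0.05], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])

    def test_exhaustive_small_instance_oracle(self):
        grid = [0.001, 0.01, 0.05, 0.2, 0.5, 0.9]
        for n in range(1, 4):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(bh_adjust(combo), brute_force_bh(combo), atol=1e-12)
        # longer vectors: order is irrelevant to correctness, check all multisets
        for n in (4, 5, 6):
            for combo in itertools.combinations_with_replacement(grid, n):
                np.testing.assert_allclose(bh_adjust(combo), brute_force_bh(combo), atol=1e-12)


class TestAnticonservative:
    def test_uniform_not_flagged(self):
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(size=1000)
            assert detect_anticonservative(p) is False

    def test_excess_mass_flagged(self):
        p = np.concatenate([np.full(30, 0.01), np.linspace(0.1, 1, 70)])
        assert detect_anticonservative(p) is True

    def test_all_large_not_flagged(self):
        assert detect_anticonservative(np.linspace(0.5, 1.0, 100)) is False

    def test_too_few_raises(self):
        with pytest.raises(DataError, match="BH"):
            detect_anticonservative(np.full(10, 0.01))


class TestCallSignificance:
    @staticmethod
    def _frame(p, fc):
        return pd.DataFrame({"p": p, "log2fc": fc, "p_adj": bh_adjust(p)})

    def test_bh_hit_blocks_fallback(self):
        df = self._frame([0.0001] + [0.5] * 60, [3.0] + [0.0] * 60)
        out = call_significance(df)
        assert out["procedure"].eq("BH").all()
        assert out["significant"].sum() == 1 and out["significant"].iloc[0]

    def test_fallback_applies_p_and_fc(self):
        # anti-conservative p's, no BH hit: only p<0.05 AND |FC|>1.5 called
        filler_p = np.linspace(0.011, 0.049, 17).tolist() + np.linspace(0.3, 1, 40).tolist()
        p = [0.04, 0.04, 0.2] + filler_p
        fc = [np.log2(1.6), np.log2(1.2), np.log2(3.0)] + [0.0] * len(filler_p)
        df = self._frame(p, fc)
        assert (df["p_adj"] < 0.05).sum() == 0
        out = call_significance(df)
        assert out["procedure"].eq("fallback").all()
        assert out["significant"].tolist()[:3] == [True, False, False]
        assert out["significant"].sum() == 1

    def test_uniform_p_keeps_bh_with_no_hits(self):
        p = np.linspace(0.05, 1.0, 100)
        df = self._frame(p, np.zeros(100))
        out = call_significance(df)
        assert out["procedure"].eq("BH").all()
        assert out["significant"].sum() == 0


class TestDeltaPs:
    def test_no_significant_site_scores_zero(self):
        res = pd.DataFrame({"protein_id": ["A", "A"], "log2fc": [1.0, 2.0], "p": [0.2, 0.6]})
        out = delta_ps(res)
        assert out.loc["A", "delta_ps"] == 0.0
        assert out.loc["A", "klass"] == "none"

    def test_hand_computed_sum(self):
        res = pd.DataFrame(
            {"protein_id": ["A"] * 3, "log2fc": [1.0, -0.5, 2.0], "p": [0.01, 0.2, 0.04]}
        )
        out = delta_ps(res)
        assert out.loc["A", "delta_ps"] == pytest.approx(3.0)
        assert out.loc["A", "n_sig"] == 2

    def test_two_sigma_classification(self):
        # cohort [0,0,0,0,10]: population sd 4, 2 sigma = 8, the 10 is hyper
        res = pd.DataFrame(
            {
                "protein_id": ["A", "B", "C", "D", "E"],
                "log2fc": [1.0, 1.0, 1.0, 1.0, 10.0],
                "p": [0.5, 0.5, 0.5, 0.5, 0.01],
            }
        )
        out = delta_ps(res)
        assert out.attrs["two_sigma"] == pytest.approx(8.0)
        assert out.loc["E", "klass"] == "hyper"
        assert (out.drop("E")["klass"] == "none").all()

    def test_empty_input(self):
        out = delta_ps(pd.DataFrame(columns=["protein_id", "log2fc", "p"]))
        assert len(out) == 0


class TestZscore:
    def test_hand_computed_row(self):
        z = zscore_sites(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_row_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            z = zscore_sites(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(z[0], [0.0, 0.0, 0.0])

    def test_row_means_vanish(self):
        rng = np.random.default_rng(0)
        z = zscore_sites(rng.normal(size=(50, 8)))
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.allclose(z.std(axis=1), 1.0)


class TestReportFractions:
    @pytest.mark.parametrize(
        "n_sig,n_total,expected",
        [(863, 2160, 39.95), (309, 4553, 6.79), (212, 1712, 12.38), (0, 100, 0.0)],
    )
    def test_printed_percentages(self, n_sig, n_total, expected):
        assert report_fractions(n_sig, n_total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            report_fractions(0, 0)


def _small_table(values, design=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    design = design or {s: ("control" if i < values.shape[1] // 2 else "treated")
                        for i, s in enumerate(samples)}
    df = pd.DataFrame(values, index=[f"P0_S{i}" for i in range(values.shape[0])], columns=samples)
    prot = pd.Series(["P0"] * values.shape[0], index=df.index)
    return PhosphoPeptideTable(intensities=df, proteins=prot, design=design)


class TestPreprocess:
    def test_constant_matrix_maps_to_zero(self):
        table = _small_table(np.full((4, 4), 1024.0))
        out = preprocess(table, seed=0)
        np.testing.assert_allclose(out.intensities.to_numpy(), 0.0, atol=1e-12)

    def test_complete_matrix_imputation_noop(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(8, 1, size=(20, 6)))
        table = _small_table(vals)
        out1 = preprocess(table, seed=0)
        out2 = preprocess(table, seed=99)
        # different seeds agree because nothing is imputed
        pd.testing.assert_frame_equal(out1.intensities, out2.intensities)
        expected = np.log2(vals) - np.median(np.log2(vals), axis=0, keepdims=True)
        np.testing.assert_allclose(out1.intensities.to_numpy(), expected)

    def test_imputed_values_fall_below_observed_median(self):
        rng = np.random.default_rng(2)
        below = 0
        total = 0
        for seed in range(10):
            vals = np.power(2.0, rng.normal(25, 2, size=(200, 6)))
            miss = rng.uniform(size=vals.shape) < 0.2
            vals_missing = vals.copy()
            vals_missing[miss] = np.nan
            table = _small_table(vals_missing)
            out = preprocess(table, seed=seed)
            x = out.intensities.to_numpy()
            for j in range(x.shape[1]):
                col_obs = np.log2(vals[:, j][~miss[:, j]])
                col_obs = col_obs - np.median(np.log2(vals[:, j][~miss[:, j]]))
                med = np.median(col_obs)
                below += int((x[:, j][miss[:, j]] < med).sum())
                total += int(miss[:, j].sum())
        assert below / total >= 0.95

    def test_all_missing_sample_names_sample(self):
        vals = np.full((5, 4), 100.0)
        vals[:, 2] = np.nan
        table = _small_table(vals)
        with pytest.raises(DataError, match="s2"):
            preprocess(table, seed=0)


def test_sample_permutation_leaves_statistics_unchanged():
    table, _ = simulate_phospho_table(PhosphoSimConfig(seed=11, n_proteins=30))
    proc = preprocess(table, seed=5)
    res = differential_analysis(proc, "control", "group2")
    perm = proc.intensities[list(reversed(proc.intensities.columns))]
    table_perm = PhosphoPeptideTable(
        intensities=perm, proteins=proc.proteins, design=dict(proc.design), log_scale=True
    )
    res_perm = differential_analysis(table_perm, "control", "group2")
    pd.testing.assert_frame_equal(res, res_perm)


class TestClustering:
    def test_planted_profiles_recovered(self):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        up = np.tile([2.0, 2.0, -2.0, -2.0], (30, 1))
        down = -up
        data = np.vstack([up, down]) + rng.normal(0, 0.1, size=(60, 4))
        z = zscore_sites(pd.DataFrame(data, index=[f"s{i}" for i in range(60)],
                                      columns=list("abcd")))
        summary = cluster_sites(z, k=2)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, summary.assignments.to_numpy()) == 1.0

    def test_k1_single_cluster(self):
        z = pd.DataFrame(np.eye(4), index=list("wxyz"), columns=list("abcd"))
        summary = cluster_sites(z, k=1)
        assert set(summary.assignments) == {1}

    def test_duplicate_rows_same_cluster(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 5))
        data = np.vstack([base, base[:1]])  # row 10 duplicates row 0
        z = pd.DataFrame(data, index=[f"r{i}" for i in range(11)], columns=list("abcde"))
        summary = cluster_sites(z, k=3)
        assert summary.assignments["r10"] == summary.assignments["r0"]

    def test_k_too_large_rejected(self):
        z = pd.DataFrame(np.eye(3), index=list("xyz"), columns=list("abc"))
        with pytest.raises(ConfigurationError):
            cluster_sites(z, k=5)

    def test_group_means_reported(self):
        z = pd.DataFrame(
            [[1.0, 1.0, -1.0, -1.0], [1.0, 1.0, -1.0, -1.0]],
            index=["s1", "s2"],
            columns=["a1", "a2", "b1", "b2"],
        )
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        summary = cluster_sites(z, k=1, design=design)
        assert summary.group_means.loc[1, "A"] == pytest.approx(1.0)
        assert summary.group_means.loc[1, "B"] == pytest.approx(-1.0)


def test_compare_cluster_groups_detects_separation():
    rng = np.random.default_rng(4)
    n_sites = 20
    cols = [f"g{g}_r{r}" for g in range(3) for r in range(5)]
    design = {c: c.split("_")[0] for c in cols}
    shift = {"g0": 0.0, "g1": 0.0, "g2": 3.0}
    data = np.array([[shift[design[c]] + rng.normal(0, 0.3) for c in cols] for _ in range(n_sites)])
    z = pd.DataFrame(data, index=[f"s{i}" for i in range(n_sites)], columns=cols)
    assignments = pd.Series(1, index=z.index)
    out = compare_cluster_groups(z, assignments, design, cluster=1)
    assert out.attrs["kruskal_p"] < 0.05
    row = out[(out.group_a == "g0") & (out.group_b == "g2")]
    assert row["p_adj"].iloc[0] < 0.05
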