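"""Per-feature testing, BH adjustment, FDP and concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from screenorm import (
    bh_adjust,
    call_hits,
    concordance,
    false_discovery_proportion,
    make_design,
    per_feature_test,
)


def long_from_matrix(mat: np.ndarray, replicates: list[str]) -> pd.DataFrame:
    n, k = mat.shape
    rows = []
    for j, rep in enumerate(replicates):
        for i in range(n):
            rows.append((f"f{i}", "lib", rep.split("_")[0], rep, None, mat[i, j]))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "well_type", "cell_line", "replicate", "plate", "score"],
    )


@pytest.fixture
def two_group_design():
    reps = [f"a_{i}" for i in range(9)] + [f"b_{i}" for i in range(9)]
    return reps, make_design({r: r.split("_")[0] for r in reps})


class TestPerFeatureTest:
    def test_flat_feature_gives_zero_estimate_p_one(self, two_group_design):
        reps, design = two_group_design
        mat = np.vstack([np.tile([1.0, 2.0, 3.0], 6)])
        table = per_feature_test(long_from_matrix(mat, reps), design)
        assert table["estimate"].iloc[0] == pytest.approx(0.0)
        assert table["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_strong_separation_is_overwhelming(self, two_group_design):
        reps, design = two_group_design
        spread = np.array([-0.1] * 4 + [0.0] + [0.1] * 4)  # within-group sd 0.1
        feature = np.concatenate([spread, 10 + spread])
        table = per_feature_test(long_from_matrix(feature[None, :], reps), design)
        assert table["estimate"].iloc[0] == pytest.approx(10.0)
        assert table["pvalue"].iloc[0] < 1e-6

    def test_label_swap_flips_sign_keeps_p(self, two_group_design):
        reps, design = two_group_design
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(20, 18))
        table = per_feature_test(long_from_matrix(mat, reps), design)
        swapped = design.copy()
        swapped["group"] = np.where(swapped["group"] == "a", "b", "a")
        table2 = per_feature_test(long_from_matrix(mat, reps), swapped)
        np.testing.assert_allclose(table2["estimate"], -table["estimate"])
        np.testing.assert_allclose(table2["pvalue"], table["pvalue"])

    def test_degenerate_feature_flagged_without_moderation(self, two_group_design):
        reps, design = two_group_design
        mat = np.vstack([np.zeros(18), np.random.default_rng(1).normal(size=18)])
        table = per_feature_test(long_from_matrix(mat, reps), design)
        assert bool(table["degenerate"].iloc[0])
        assert np.isnan(table["pvalue"].iloc[0])

    def test_pooled_moderation_rescues_degenerate_feature(self, two_group_design):
        reps, design = two_group_design
        mat = np.vstack([np.zeros(18), np.random.default_rng(1).normal(size=18)])
        table = per_feature_test(
            long_from_matrix(mat, reps), design, moderation="pooled"
        )
        assert not table["degenerate"].any()
        assert np.isfinite(table["pvalue"]).all()

    def test_moderation_shrinks_variance_spread(self, two_group_design):
        reps, design = two_group_design
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(50, 18)) * rng.uniform(0.1, 3, size=(50, 1))
        plain = per_feature_test(long_from_matrix(mat, reps), design)
        mod = per_feature_test(long_from_matrix(mat, reps), design,
                               moderation="pooled")
        assert mod["se"].std() < plain["se"].std()


def brute_force_bh(p: np.ndarray, level: float) -> np.ndarray:
    """Step-up definition: reject 1..k for the largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * level / m:
            k_max = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


class TestBHAdjust:
    def test_all_equal_pvalues_unchanged(self):
        adj, _ = bh_adjust(np.full(7, 0.03))
        np.testing.assert_allclose(adj, 0.03)

    def test_single_pvalue_passthrough(self):
        adj, _ = bh_adjust([0.02])
        assert adj[0] == pytest.approx(0.02)

    def test_textbook_vector(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05] + [0.9] * 5)
        adj, flags = bh_adjust(p, level=0.1)
        assert adj[0] == pytest.approx(0.1)
        assert flags[:5].all() and not flags[5:].any()

    def test_matches_brute_force_step_up_on_grid(self):
        grid = [0.001, 0.02, 0.2, 0.5, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                p = np.array(combo)
                for level in (0.05, 0.2):
                    _, flags = bh_adjust(p, level=level)
                    np.testing.assert_array_equal(
                        flags, brute_force_bh(p, level), err_msg=f"{combo} {level}"
                    )

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        adj, _ = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_nan_passthrough(self):
        adj, flags = bh_adjust([0.01, np.nan])
        assert np.isnan(adj[1]) and not flags[1]


class TestFDP:
    def test_no_discoveries_is_zero(self):
        assert false_discovery_proportion([False, False], [True, False]) == 0.0

    def test_two_of_five_false(self):
        flags = [True] * 5 + [False]
        truth = [True, True, True, False, False, False]
        assert false_discovery_proportion(flags, truth) == pytest.approx(0.4)

    def test_all_false_discoveries(self):
        assert false_discovery_proportion([True, True], [False, False]) == 1.0


def hit_table(sig_flags):
    return pd.DataFrame(
        {"significant": sig_flags},
        index=[f"f{i}" for i in range(len(sig_flags))],
    )


def crosstab_tables(n_ss, n_s_ns, n_ns_s, n_ns_ns):
    """Hit-table pair realizing a printed 2x2 cross-tabulation (A = primary)."""
    a = [True] * (n_ss + n_s_ns) + [False] * (n_ns_s + n_ns_ns)
    b = (
        [True] * n_ss + [False] * n_s_ns + [True] * n_ns_s + [False] * n_ns_ns
    )
    return hit_table(a), hit_table(b)


class TestConcordance:
    def test_identical_tables(self):
        t = hit_table([True, False, True])
        summary = concordance(t, t)
        assert summary.agreement == 1.0
        assert summary.discordance == 0.0

    def test_agreement_discordance_symmetric_under_swap(self):
        a, b = crosstab_tables(10, 5, 7, 20)
        ab, ba = concordance(a, b), concordance(b, a)
        assert ab.agreement == ba.agreement
        assert ab.discordance == ba.discordance
        # confirmation fractions are relative to the primary table
        assert ab.hit_confirmation != ba.hit_confirmation

    def test_counts_sum_to_total(self):
        a, b = crosstab_tables(3, 4, 5, 6)
        s = concordance(a, b)
        assert s.n_sig_both + s.n_sig_a_only + s.n_sig_b_only + s.n_ns_both == 18
        assert s.agreement + s.discordance == pytest.approx(1.0)

    def test_disjoint_feature_sets_error(self):
        a = hit_table([True])
        b = hit_table([True])
        b.index = ["other"]
        with pytest.raises(ValueError, match="no features"):
            concordance(a, b)


class TestCallHits:
    def test_significance_flag_consistent_with_padj(self, tmp_path=None):
        rng = np.random.default_rng(9)
        reps = [f"a_{i}" for i in range(3)] + [f"b_{i}" for i in range(3)]
        design = make_design({r: r.split("_")[0] for r in reps})
        mat = rng.normal(size=(30, 6))
        mat[:3, 3:] += 8  # three strong hits
        table = call_hits(long_from_matrix(mat, reps), design, level=0.05)
        assert (table["significant"] == (table["padj"] <= 0.05)).all()
        assert table["significant"].iloc[:3].all()
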