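import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from oracles import oracle_mw_exact_p

from crispramp.qpcr import (
    DEFAULT_EFFICIENCIES,
    collapse_replicates,
    efficiency_table,
    exact_mann_whitney_enumeration,
    fold_change,
    group_comparison,
    mann_whitney,
)
from crispramp.simulate import simulate_ct_table


class TestCollapseReplicates:
    def test_mean_of_duplicates(self):
        assert collapse_replicates([20.0, 20.2])[0] == pytest.approx(20.1)

    def test_single_replicate(self):
        mean, sd, flag = collapse_replicates([20.0])
        assert (mean, sd, flag) == (20.0, 0.0, False)

    def test_high_sd_flagged(self):
        mean, sd, flag = collapse_replicates([20.0, 21.5])
        assert mean == pytest.approx(20.75)
        assert flag

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            collapse_replicates([float("nan")])


def _ct_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "tissue", "gene", "ct_rep1", "ct_rep2"]
    )


def _two_sample_table(goi_shift=0.0):
    rows = []
    for sid, grp, shift in (
        ("c1", "control_wt", 0.0),
        ("c2", "control_albino", 0.0),
        ("k1", "crispant", goi_shift),
    ):
        rows.append((sid, grp, "head_kidney", "mIgM", 24.0 + shift, 24.0 + shift))
        rows.append((sid, grp, "head_kidney", "Ef1a", 18.0, 18.0))
    return _ct_frame(rows)


class TestFoldChange:
    def test_ddct_zero_gives_fc_one(self):
        expr = fold_change(_two_sample_table(0.0))
        assert expr["fold_change"].to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_e2_ddct_minus_one_gives_fc_two(self):
        eff = {("mIgM", "head_kidney"): 2.0, ("Ef1a", "head_kidney"): 2.0}
        expr = fold_change(_two_sample_table(-1.0), eff)
        fc = expr.set_index("sample_id")["fold_change"]
        assert fc["k1"] == pytest.approx(2.0)

    def test_published_efficiency_worked_example(self):
        # E = 2.05 with ΔΔCt = +3 cycles → FC = 2.05**-3 ≈ 0.116
        eff = {("mIgM", "head_kidney"): 2.05, ("Ef1a", "head_kidney"): 2.05}
        expr = fold_change(_two_sample_table(3.0), eff)
        fc = expr.set_index("sample_id")["fold_change"]
        assert fc["k1"] == pytest.approx(2.05**-3)
        assert fc["k1"] == pytest.approx(0.116, abs=5e-4)

    def test_control_geometric_mean_is_one(self):
        ct = simulate_ct_table(5, n_crispant=6, n_control=5)
        expr = fold_change(ct)
        ctrl = expr[expr.group.isin(("control_wt", "control_albino"))]
        for _, sub in ctrl.groupby(["gene", "tissue"]):
            geo = np.exp(np.log(sub["fold_change"]).mean())
            assert geo == pytest.approx(1.0, abs=1e-9)

    def test_modes_agree_when_efficiencies_equal(self):
        ct = simulate_ct_table(5, n_crispant=6, n_control=5)
        eff = {(g, t): 2.0 for (g, t) in DEFAULT_EFFICIENCIES}
        single = fold_change(ct, eff, mode="single_efficiency")
        full = fold_change(ct, eff, mode="pfaffl_full")
        assert np.allclose(single["fold_change"], full["fold_change"], atol=1e-9)

    def test_fold_change_strictly_decreasing_in_ddct(self):
        shifts = [-2.0, -1.0, 0.0, 1.0, 2.0]
        fcs = [
            fold_change(_two_sample_table(s)).set_index("sample_id")["fold_change"]["k1"]
            for s in shifts
        ]
        assert all(a > b for a, b in zip(fcs, fcs[1:]))

    def test_missing_reference_gene_names_sample(self):
        df = _two_sample_table()
        df = df[~((df.sample_id == "k1") & (df.gene == "Ef1a"))]
        with pytest.raises(ValueError, match="k1"):
            fold_change(df)

    def test_missing_efficiency_raises(self):
        with pytest.raises(ValueError, match="mIgM"):
            fold_change(_two_sample_table(), {("Ef1a", "head_kidney"): 2.0})

    def test_efficiency_range_validated(self):
        with pytest.raises(ValueError):
            efficiency_table({("mIgM", "head_kidney"): 2.5})


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        u, p = mann_whitney([1, 2], [1, 2])
        assert p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_scipy_on_random_tie_free_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            na, nb = rng.integers(1, 8, 2)
            vals = rng.permutation(1000)[: na + nb].astype(float)
            a, b = vals[:na], vals[na:]
            _, p = mann_whitney(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_exact_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            na, nb = rng.integers(1, 6, 2)
            vals = rng.permutation(1000)[: na + nb].astype(float)
            a, b = vals[:na], vals[na:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(oracle_mw_exact_p(a, b), abs=1e-12)
            assert p == pytest.approx(exact_mann_whitney_enumeration(a, b), abs=1e-12)

    def test_type_one_error_rate_under_null(self):
        """Two same-distribution groups reject at ~4-5% for alpha=0.05."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_asymptotic_path_close_to_scipy_for_large_samples(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(0.5, size=25)
        _, p = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=0.05)


class TestGroupComparison:
    def test_knockdown_detected_in_synthetic_cohort(self):
        ct = simulate_ct_table(11, n_crispant=10, n_control=6)
        expr = fold_change(ct)
        comp = group_comparison(expr).set_index(["gene", "tissue"])
        migm = comp.loc[("mIgM", "head_kidney")]
        assert migm["median_fc_test"] < 0.25
        assert migm["p_value"] < 0.001
        # null gene: sIgM in spleen has no true shift
        s = comp.loc[("sIgM", "spleen")]
        assert s["p_value"] > 0.05

    def test_crispant_shift_of_three_cycles_with_e2(self):
        rows = []
        for i in range(4):
            rows.append((f"c{i}", "control_wt", "spleen", "mIgM", 24.0 + 0.01 * i, 24.0))
            rows.append((f"c{i}", "control_wt", "spleen", "Ef1a", 18.0, 18.0))
            rows.append((f"k{i}", "crispant", "spleen", "mIgM", 27.0 + 0.01 * i, 27.0))
            rows.append((f"k{i}", "crispant", "spleen", "Ef1a", 18.0, 18.0))
        eff = {("mIgM", "spleen"): 2.0, ("Ef1a", "spleen"): 2.0}
        expr = fold_change(_ct_frame(rows), eff)
        comp = group_comparison(expr)
        assert comp["median_fc_test"].iloc[0] == pytest.approx(0.125, rel=0.02)
        assert comp["median_fc_control"].iloc[0] == pytest.approx(1.0, rel=0.02)
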