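import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_annotation, make_beta
from retrometh.diffmeth import (
    BetaMatrix,
    bh_adjust,
    beta_to_m,
    call_dmps,
    family_methylation,
    total_re_methylation,
    welch_t_test,
)


class TestBetaToM:
    def test_half_is_zero(self):
        assert beta_to_m(0.5) == pytest.approx(0.0, abs=1e-9)

    def test_point_eight(self):
        # oracle: log2(0.8 / 0.2) = 2 with negligible epsilon
        assert beta_to_m(0.8) == pytest.approx(2.0, abs=1e-5)

    def test_antisymmetry(self):
        assert beta_to_m(0.2) == pytest.approx(-beta_to_m(0.8), abs=1e-9)

    def test_monotone(self):
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(beta_to_m(grid)) > 0)

    def test_bounds_guarded(self):
        assert np.isfinite(beta_to_m(0.0)) and np.isfinite(beta_to_m(1.0))

    def test_bad_epsilon(self):
        with pytest.raises(ValueError):
            beta_to_m(0.5, epsilon=0)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == 1

    def test_hand_computed_example(self):
        # se = sqrt(0.01/3 + 0.01/3); t = -0.3/se ~= -3.674; Welch df = 4
        res = welch_t_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res.t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_degenerate_equal(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.t == 0 and res.p == 1

    def test_degenerate_unequal(self):
        res = welch_t_test([2.0, 2.0], [3.0, 3.0])
        assert res.degenerate and res.p == 0

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(size=rng.integers(2, 30))
            res = welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_pooled_matches_scipy(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=8)
            res = welch_t_test(x, y, pooled=True)
            ref = stats.ttest_ind(x, y, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.df == 16

    def test_monte_carlo_type_one_error(self):
        # 10,000 null replicates at n=10 vs 10: rejection rate 5% +/- 1%
        rng = np.random.default_rng(99)
        from retrometh.diffmeth import t_test_rows

        x = rng.normal(size=(10_000, 10))
        y = rng.normal(size=(10_000, 10))
        _, _, p, _ = t_test_rows(x, y)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j >= i} min(1, p_(j) * n / j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order):
        q[idx] = min(
            min(1.0, p[order[j]] * n / (j + 1)) for j in range(rank_pos, n)
        )
    return q


class TestBH:
    def test_worked_example(self):
        # oracle: brute-force step-up on n=4 gives 0.04 everywhere
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_outside_unit_interval(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_and_bounded(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert np.all(q >= p) and np.all(q <= 1)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50)))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), rel=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_property_matches_brute_force(self, p):
        assert bh_adjust(p) == pytest.approx(brute_force_bh(p), rel=1e-12)


class TestTotal:
    def test_constant_matrix(self):
        ann = make_annotation(["AluY", "L1PA3"])
        bm = make_beta(np.full((2, 8), 0.5), ["case"] * 4 + ["ctrl"] * 4)
        res = total_re_methylation(bm, ann, "case", "ctrl")
        assert res.delta_beta == 0 and res.p == 1

    def test_shifted_groups(self, rng):
        ann = make_annotation(["AluY", "L1PA3", "HAL1"])
        vals = np.concatenate(
            [0.7 + rng.normal(0, 1e-3, (3, 5)), 0.5 + rng.normal(0, 1e-3, (3, 5))], axis=1
        )
        bm = make_beta(np.clip(vals, 0, 1), ["case"] * 5 + ["ctrl"] * 5)
        res = total_re_methylation(bm, ann, "case", "ctrl")
        assert res.delta_beta == pytest.approx(0.2, abs=0.01)

    def test_delta_equals_group_mean_difference(self, rng):
        ann = make_annotation(["AluY", "L1M5", "", "AluSx"])
        bm = make_beta(rng.random((4, 10)), ["case"] * 5 + ["ctrl"] * 5)
        res = total_re_methylation(bm, ann, "case", "ctrl")
        case_means = res.per_sample_means[bm.samples_in("case")]
        ctrl_means = res.per_sample_means[bm.samples_in("ctrl")]
        assert res.delta_beta == pytest.approx(case_means.mean() - ctrl_means.mean())

    def test_no_resident_probes_errors(self, rng):
        ann = make_annotation(["", ""])
        bm = make_beta(rng.random((2, 6)), ["case"] * 3 + ["ctrl"] * 3)
        with pytest.raises(ValueError):
            total_re_methylation(bm, ann, "case", "ctrl")


class TestFamily:
    def test_identical_groups(self):
        ann = make_annotation(["AluY", "AluY", "L1PA3"])
        bm = make_beta(np.tile([[0.4], [0.6], [0.5]], (1, 8)), ["case"] * 4 + ["ctrl"] * 4)
        fam = family_methylation(bm, ann, "case", "ctrl")
        assert set(fam["family"]) == {"AluY", "L1PA"}
        assert (fam["delta_beta"] == 0).all() and (fam["p"] == 1).all()

    def test_unclassified_families_absent(self, rng):
        ann = make_annotation(["AluY", "MER41B", ""])
        bm = make_beta(rng.random((3, 8)), ["case"] * 4 + ["ctrl"] * 4)
        fam = family_methylation(bm, ann, "case", "ctrl")
        assert set(fam["family"]) == {"AluY"}

    def test_age_class_grouping(self, rng):
        ann = make_annotation(["AluY", "L1PA3", "AluJo", "HAL1"])
        bm = make_beta(rng.random((4, 8)), ["case"] * 4 + ["ctrl"] * 4)
        fam = family_methylation(bm, ann, "case", "ctrl", group_by="age_class")
        assert set(fam["age_class"]) == {"young", "old", "related"}

    def test_delta_is_difference_of_per_sample_family_means(self, rng):
        names = ["AluY", "AluY", "AluY", "L1M5", "L1M5"]
        ann = make_annotation(names)
        vals = rng.random((5, 12))
        labels = ["case"] * 7 + ["ctrl"] * 5
        bm = make_beta(vals, labels)
        fam = family_methylation(bm, ann, "case", "ctrl").set_index("family")
        # independent recomputation from raw values
        aluy = vals[:3].mean(axis=0)
        expected = aluy[:7].mean() - aluy[7:].mean()
        assert fam.at["AluY", "delta_beta"] == pytest.approx(expected, rel=1e-12)

    def test_planted_family_effect_flagged(self):
        rng = np.random.default_rng(42)
        names = ["AluSx"] * 30 + ["AluJo"] * 30 + ["AluY"] * 30
        ann = make_annotation(names)
        labels = ["case"] * 52 + ["ctrl"] * 48
        vals = np.clip(0.8 + rng.normal(0, 0.04, (90, 100)), 0.01, 0.99)
        vals[:30, :52] += 0.05  # AluS only, case samples only
        bm = make_beta(np.clip(vals, 0, 1), labels)
        fam = family_methylation(bm, ann, "case", "ctrl").set_index("family")
        assert fam.at["AluS", "p"] < 0.05
        assert fam.at["AluS", "delta_beta"] == pytest.approx(0.05, abs=0.02)

    def test_bad_group_by(self, rng):
        ann = make_annotation(["AluY"])
        bm = make_beta(rng.random((1, 4)), ["case", "case", "ctrl", "ctrl"])
        with pytest.raises(ValueError):
            family_methylation(bm, ann, "case", "ctrl", group_by="bogus")


class TestCallDmps:
    def test_antisymmetry_of_labels(self, rng):
        ann = make_annotation(["AluY", "L1PA3", "AluSx", "HAL1"])
        bm = make_beta(rng.random((4, 12)), ["case"] * 6 + ["ctrl"] * 6)
        fwd = call_dmps(bm, ann, "case", "ctrl")
        rev = call_dmps(bm, ann, "ctrl", "case")
        assert fwd["delta_beta"].to_numpy() == pytest.approx(-rev["delta_beta"].to_numpy())
        assert fwd["p"].to_numpy() == pytest.approx(rev["p"].to_numpy())

    def test_constant_probes_flagged_not_called(self):
        ann = make_annotation(["AluY", "L1PA3"])
        bm = make_beta(np.full((2, 8), 0.3), ["case"] * 4 + ["ctrl"] * 4)
        dmps = call_dmps(bm, ann, "case", "ctrl")
        assert dmps["degenerate"].all()
        assert not dmps["significant"].any()

    def test_direction_matches_sign(self, rng):
        ann = make_annotation(["AluY", "L1PA3", "AluSx"])
        bm = make_beta(rng.random((3, 10)), ["case"] * 5 + ["ctrl"] * 5)
        dmps = call_dmps(bm, ann, "case", "ctrl")
        for _, row in dmps.iterrows():
            if row["delta_beta"] > 0:
                assert row["direction"] == "hyper"
            elif row["delta_beta"] < 0:
                assert row["direction"] == "hypo"

    def test_p_fdr_at_least_p(self, rng):
        ann = make_annotation(["AluY", "L1PA3", "AluSx", "L1M5", "MER41B"])
        bm = make_beta(rng.random((5, 10)), ["case"] * 5 + ["ctrl"] * 5)
        for stratify in (True, False):
            dmps = call_dmps(bm, ann, "case", "ctrl", stratify_fdr=stratify)
            assert (dmps["p_fdr"] >= dmps["p"] - 1e-15).all()

    def test_stratified_fdr_equals_per_class_bh(self, rng):
        names = ["AluY", "AluSx", "L1PA3", "L1M5", "HAL1", "MER41B"] * 5
        ann = make_annotation(names)
        bm = make_beta(rng.random((len(names), 20)), ["case"] * 10 + ["ctrl"] * 10)
        dmps = call_dmps(bm, ann, "case", "ctrl", stratify_fdr=True)
        for _, grp in dmps.groupby("element_class"):
            assert grp["p_fdr"].to_numpy() == pytest.approx(
                bh_adjust(grp["p"].to_numpy()), rel=1e-12
            )

    def test_non_resident_probes_excluded(self, rng):
        ann = make_annotation(["AluY", "", "L1PA3"])
        bm = make_beta(rng.random((3, 8)), ["case"] * 4 + ["ctrl"] * 4)
        dmps = call_dmps(bm, ann, "case", "ctrl")
        assert set(dmps["probe_id"]) == {"cg000000", "cg000002"}


class TestBetaMatrix:
    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            make_beta(np.array([[1.5, 0.2], [0.1, 0.3]]), ["a", "b"])

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            make_beta(np.array([[np.nan, 0.2], [0.1, 0.3]]), ["a", "b"])

    def test_roundtrip_files(self, tmp_path, rng):
        bm = make_beta(rng.random((3, 4)), ["a", "a", "b", "b"])
        beta_path, samples_path = tmp_path / "b.tsv", tmp_path / "s.csv"
        bm.values.to_csv(beta_path, sep="\t", index_label="probe_id")
        pd.DataFrame({"sample_id": bm.values.columns, "group": bm.groups.values}).to_csv(
            samples_path, index=False
        )
        loaded = BetaMatrix.from_files(beta_path, samples_path)
        assert np.allclose(loaded.values.to_numpy(), bm.values.to_numpy())
        assert loaded.samples_in("a") == bm.samples_in("a")
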