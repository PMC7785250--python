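import numpy as np
import pandas as pd
import pytest
from piconflict import (
    SimulationParams,
    compare_groups_ranksum,
    fold_changes,
    median_of_ratios_normalize,
    normalize_experiment,
    rank_across_knockdowns,
    simulate_counts,
    spearman,
)
from piconflict.types import CountMatrix


def matrix(data, genes=None):
    genes = genes or [f"g{i}" for i in range(len(next(iter(data.values()))))]
    return CountMatrix(counts=pd.DataFrame(data, index=genes))


class TestMedianOfRatios:
    def test_closed_form_two_by_two(self):
        m = matrix({"s1": [2, 8], "s2": [4, 16]})
        out = median_of_ratios_normalize(m)
        np.testing.assert_allclose(out.size_factors, [np.sqrt(0.5), np.sqrt(2.0)])
        pd.testing.assert_series_equal(
            out.counts["s1"], out.counts["s2"], check_names=False
        )

    def test_idempotence(self):
        m = matrix({"s1": [2, 8], "s2": [4, 16]})
        once = median_of_ratios_normalize(m)
        twice = median_of_ratios_normalize(CountMatrix(counts=once.counts))
        np.testing.assert_allclose(twice.size_factors, [1.0, 1.0])

    def test_zero_rows_excluded_from_reference(self):
        m = matrix({"s1": [2, 0, 8], "s2": [4, 7, 16]})
        out = median_of_ratios_normalize(m)
        np.testing.assert_allclose(out.size_factors, [np.sqrt(0.5), np.sqrt(2.0)])

    def test_no_all_positive_rows_errors(self):
        m = matrix({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError):
            median_of_ratios_normalize(m)

    def test_matches_pydeseq2_size_factors(self):
        """Independent cross-check against the DESeq2 reference implementation."""
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(0)
        counts = rng.poisson(rng.lognormal(3, 1, size=(60, 1)) * [1.0, 2.0, 0.5],
                             size=(60, 4 - 1))  # 60 genes x 3 samples
        m = matrix({f"s{j}": counts[:, j] for j in range(3)},
                   genes=[f"g{i}" for i in range(60)])
        out = median_of_ratios_normalize(m)
        _, ref_sf = pydeseq2_pp.deseq2_norm(m.counts.T.to_numpy())
        np.testing.assert_allclose(out.size_factors.to_numpy(), ref_sf, rtol=1e-8)

    def test_planted_library_size_recovered(self):
        params = SimulationParams(seed=5, n_genes=2000, n_knockdowns=2,
                                  library_size_factors=[1.0, 2.0, 1.0])
        sim = simulate_counts(params)
        _, kds = normalize_experiment(sim.control, sim.knockdowns)
        sf = np.concatenate([kd.size_factors.to_numpy() for kd in kds])
        assert sf[0] / sf[1] == pytest.approx(2.0, rel=0.10)


class TestFoldChanges:
    def control_and_kd(self, ctrl_vals, kd_vals):
        genes = [f"g{i}" for i in range(len(ctrl_vals))]
        return (
            matrix({"c": ctrl_vals}, genes),
            [matrix({"k": kd_vals}, genes)],
        )

    def test_pseudocount_formula(self):
        control, kds = self.control_and_kd([10], [20])
        fc = fold_changes(control, kds)
        assert fc.fc.iloc[0, 0] == pytest.approx(20.5 / 10.5)

    def test_equal_values_give_unity(self):
        control, kds = self.control_and_kd([7], [7])
        assert fold_changes(control, kds).fc.iloc[0, 0] == 1.0

    def test_zero_control_excluded(self):
        control, kds = self.control_and_kd([0, 5], [3, 10])
        fc = fold_changes(control, kds)
        assert fc.not_expressed == ["g0"]
        assert list(fc.fc.index) == ["g1"]

    def test_targeted_gene_masked(self):
        control, kds = self.control_and_kd([5, 5], [10, 10])
        fc = fold_changes(control, kds, targeted_genes=["g0"])
        assert np.isnan(fc.fc.loc["g0", "kd1"])

    def test_mismatched_gene_sets_error(self):
        control = matrix({"c": [1, 2]}, ["a", "b"])
        kd = matrix({"k": [1, 2]}, ["a", "c"])
        with pytest.raises(ValueError):
            fold_changes(control, [kd])


class TestRank:
    def table(self, fcs, genes):
        from piconflict.ranking import FoldChangeTable

        return FoldChangeTable(
            fc=pd.DataFrame(fcs, index=genes, columns=["e1", "e2"]),
            pseudocount=0.5,
            not_expressed=[],
        )

    def test_mixed_dominance(self):
        t = self.table([[2.0, 2.0], [3.0, 4.0], [3.0, 1.0]], ["focal", "a", "b"])
        res = rank_across_knockdowns(t, "focal")
        assert res.n_dominating == 1
        assert res.n_expressed == 3

    def test_focal_maximum_everywhere(self):
        t = self.table([[5.0, 5.0], [3.0, 4.0], [3.0, 1.0]], ["focal", "a", "b"])
        assert rank_across_knockdowns(t, "focal").n_dominating == 0

    def test_focal_not_counted_for_itself(self):
        t = self.table([[2.0, 2.0], [1.0, 1.0]], ["focal", "a"])
        assert rank_across_knockdowns(t, "focal").n_dominating == 0
        assert rank_across_knockdowns(t, "focal", include_focal=True).n_dominating == 1

    def test_invariant_under_per_experiment_scaling(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        fcs = rng.lognormal(0, 0.5, size=(50, 2))
        t1 = self.table(fcs, genes)
        t2 = self.table(fcs * np.array([3.0, 0.25]), genes)
        r1 = rank_across_knockdowns(t1, "g7")
        r2 = rank_across_knockdowns(t2, "g7")
        assert r1.n_dominating == r2.n_dominating

    def test_planted_responders_dominate_focal(self):
        responders = {f"g{i + 1:05d}": 4.0 for i in range(6)}  # g00001 .. g00006
        params = SimulationParams(seed=8, n_genes=3000, n_knockdowns=8,
                                  planted_fold_changes=responders)
        sim = simulate_counts(params)
        control, kds = normalize_experiment(sim.control, sim.knockdowns)
        fc = fold_changes(control, kds)
        res = rank_across_knockdowns(fc, "g00001")
        # only the other planted responders should plausibly dominate the focal
        assert res.n_dominating <= len(responders) + 2
        assert res.percentile < 0.01


class TestRankSum:
    def test_exact_extreme_ordering(self):
        u, p = compare_groups_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        _, p = compare_groups_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.5

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        _, p = compare_groups_ranksum(a, b)
        assert p < 1e-6

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups_ranksum([], [1.0])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2, 3, 5, 8]
        assert spearman(x, [2.0, 4, 9, 10, 30]) == pytest.approx(1.0)
        assert spearman(x, [30.0, 10, 9, 4, 2]) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman([1.0, 1, 1], [1.0, 2, 3]))

    def test_equals_correlation_of_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        from scipy.stats import rankdata

        assert spearman(x, y) == pytest.approx(
            spearman(rankdata(x), rankdata(y))
        )

    def test_planted_rank_correlation_recovered(self):
        rng = np.random.default_rng(4)
        n = 1000
        x = rng.normal(size=n)
        # Gaussian copula with correlation chosen to land near rho = 0.9
        y = 0.91 * x + np.sqrt(1 - 0.91**2) * rng.normal(size=n)
        assert 0.87 <= spearman(x, y) <= 0.93
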