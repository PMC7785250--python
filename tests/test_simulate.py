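import numpy as np
import pytest

from piconflict import (
    SimulationParams,
    make_conflict_locus,
    simulate_counts,
    simulate_degradome,
    simulate_genomic_coverage,
    simulate_small_rna,
    simulate_triplet,
)


class TestLocus:
    def test_default_plants_seventeen_sites(self, locus):
        assert len(locus.diagnostic_sites) == 17

    def test_zero_sites_gives_identical_segments(self):
        params = SimulationParams(seed=1, n_diagnostic_sites=0)
        truth = make_conflict_locus(params)
        g, t3 = truth.captured_interval_gene, truth.captured_interval_te3
        assert (
            truth.te_sequence.sequence[t3.start:t3.end]
            == truth.gene_sequence.sequence[g.start:g.end]
        )

    def test_mirrored_copies_identical(self, locus):
        t3, t5 = locus.captured_interval_te3, locus.captured_interval_te5
        te = locus.te_sequence.sequence
        assert te[t3.start:t3.end] == te[t5.start:t5.end]

    def test_sites_inside_captured_interval_in_both_frames(self, locus):
        for s in locus.diagnostic_sites:
            assert locus.captured_interval_gene.contains(s.gene_pos)
            assert locus.captured_interval_te3.contains(s.te_pos)
            te_base = locus.te_sequence.sequence[s.te_pos]
            gene_base = locus.gene_sequence.sequence[s.gene_pos]
            assert (te_base, gene_base) == (s.te_allele, s.gene_allele)

    def test_captured_intervals_equal_length(self, locus):
        assert (
            locus.captured_interval_gene.length
            == locus.captured_interval_te3.length
            == locus.captured_interval_te5.length
        )

    def test_infeasible_site_count_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(seed=0, captured_length=10, n_diagnostic_sites=17)

    def test_determinism(self):
        a = make_conflict_locus(SimulationParams(seed=7))
        b = make_conflict_locus(SimulationParams(seed=7))
        assert a == b


class TestSmallRna:
    def test_determinism(self, locus, default_params):
        a = simulate_small_rna(locus, default_params)
        b = simulate_small_rna(locus, default_params)
        assert a.reads == b.reads

    def test_lengths_and_bounds(self, locus, default_params):
        sim = simulate_small_rna(locus, default_params)
        lo, hi = default_params.pirna_length_range
        te_len = len(locus.te_sequence)
        for r in sim.reads:
            assert lo <= r.length <= hi
            assert 0 <= r.interval.start < r.interval.end <= te_len

    def test_all_pairs_library_structure(self, locus):
        params = SimulationParams(seed=2, n_reads=200, pingpong_pair_fraction=1.0,
                                  phased_fraction=0.0, background_fraction=0.0)
        sim = simulate_small_rna(locus, params)
        assert sim.n_pingpong_pairs == 100
        plus5 = {r.five_prime for r in sim.reads if r.strand == "+"}
        for r in sim.reads:
            if r.strand == "-":
                assert r.five_prime - 9 in plus5  # exact 10-nt 5':5' overlap partner

    def test_background_only_records_zero_pairs(self, locus):
        params = SimulationParams(seed=2, n_reads=100, pingpong_pair_fraction=0.0,
                                  phased_fraction=0.0, background_fraction=1.0)
        sim = simulate_small_rna(locus, params)
        assert sim.n_pingpong_pairs == 0 and sim.n_background_reads == 100

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(pingpong_pair_fraction=0.9, phased_fraction=0.9,
                             background_fraction=0.0)


class TestDegradome:
    def test_every_cleavage_position_covered(self, locus):
        params = SimulationParams(seed=3, n_decoy_degradome=0, n_background_pirnas=0)
        sim = simulate_degradome(locus, params)
        five_primes = {r.five_prime for r in sim.degradome_reads}
        assert five_primes == set(locus.cleavage_positions)
        assert len(five_primes) == 11

    def test_no_cleavage_sites_only_decoys(self):
        params = SimulationParams(seed=3, n_cleavage_sites=0, n_decoy_degradome=15)
        truth = make_conflict_locus(params)
        sim = simulate_degradome(truth, params)
        assert truth.cleavage_positions == []
        assert all(r.read_id.startswith("deg_decoy") for r in sim.degradome_reads)

    def test_determinism(self, locus, default_params):
        a = simulate_degradome(locus, default_params)
        b = simulate_degradome(locus, default_params)
        assert a.degradome_reads == b.degradome_reads
        assert a.pirna_reads == b.pirna_reads


class TestCoverage:
    def test_zero_copies(self, locus):
        sim = simulate_genomic_coverage(locus, SimulationParams(seed=1, n_te_copies=0))
        assert sim.track.values.sum() == 0 and sim.realized_truncation_fraction == 0

    def test_determinism(self, locus, default_params):
        a = simulate_genomic_coverage(locus, default_params)
        b = simulate_genomic_coverage(locus, default_params)
        np.testing.assert_array_equal(a.track.values, b.track.values)

    def test_track_length_matches_reference(self, locus, default_params):
        sim = simulate_genomic_coverage(locus, default_params)
        assert len(sim.track) == len(locus.te_sequence)

    def test_duplicated_segment_expectation(self, locus):
        """Both mirrored copies of the captured segment sit at the
        even-split expectation n*depth*(2 - f)/2."""
        params = SimulationParams(seed=6, n_te_copies=10, read_depth=100.0,
                                  truncation_fraction=0.5)
        sim = simulate_genomic_coverage(locus, params)
        expected = 10 * 100.0 * (2 - sim.realized_truncation_fraction) / 2
        for iv in (locus.captured_interval_te3, locus.captured_interval_te5):
            observed = sim.track.values[iv.start:iv.end].mean()
            assert observed == pytest.approx(expected, rel=0.03)


class TestCounts:
    def test_unit_multipliers_give_unit_median_fold_change(self):
        params = SimulationParams(seed=4, n_genes=3000, n_knockdowns=3)
        sim = simulate_counts(params)
        ctrl = sim.control.counts["control"].to_numpy().astype(float)
        kd = sim.knockdowns[0].counts.iloc[:, 0].to_numpy().astype(float)
        expressed = ctrl > 0
        median_fc = np.median((kd[expressed] + 0.5) / (ctrl[expressed] + 0.5))
        assert median_fc == pytest.approx(1.0, abs=0.05)

    def test_zero_multiplier_gives_all_zero_row(self):
        params = SimulationParams(seed=4, n_genes=500, n_knockdowns=2,
                                  planted_fold_changes={"g00010": 0.0})
        sim = simulate_counts(params)
        for kd in sim.knockdowns:
            assert kd.counts.loc["g00010"].sum() == 0

    def test_determinism(self):
        params = SimulationParams(seed=9, n_genes=400, n_knockdowns=2)
        a = simulate_counts(params)
        b = simulate_counts(params)
        assert a.control.counts.equals(b.control.counts)
        for ka, kb in zip(a.knockdowns, b.knockdowns):
            assert ka.counts.equals(kb.counts)


class TestTriplet:
    def test_zero_rates_identical_sequences(self):
        params = SimulationParams(seed=5, lineage_rates=(0.0, 0.0))
        sim = simulate_triplet(params)
        assert sim.m1 == sim.m2 == 0
        assert sim.ingroup1.sequence == sim.ingroup2.sequence == sim.outgroup.sequence

    def test_asymmetric_rates_order_counts(self):
        hits = 0
        for seed in range(20):
            sim = simulate_triplet(SimulationParams(seed=seed,
                                                    lineage_rates=(0.02, 0.002)))
            hits += sim.m1 > sim.m2
        assert hits >= 18

    def test_determinism(self):
        params = SimulationParams(seed=11)
        assert simulate_triplet(params) == simulate_triplet(params)
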