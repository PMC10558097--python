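import math

import numpy as np
import pytest

from strhaplo import (RepeatLocus, SimConfig, simulate_cohort,
                      simulate_decay_segments, simulate_optical_molecules,
                      simulate_read_evidence)
from strhaplo.loci import InvalidParameterError
from strhaplo.simulate import ConfigurationError


class TestDecaySegments:
    def test_mean_side_length_matches_exponential(self):
        # empirical one-side mean converges to 1/g (3-SE band)
        g, n = 1000.0, 100
        segs = simulate_decay_segments(g, n, 0.01, rng_seed=7)
        sides = np.array([s for seg in segs
                          for s in (seg.left_len, seg.right_len)])
        se = sides.std(ddof=1) / math.sqrt(len(sides))
        assert abs(sides.mean() - 1 / g) < 3 * se

    def test_tiny_window_censors_every_side(self):
        segs = simulate_decay_segments(2.0, 10, 1e-6, rng_seed=0)
        assert all(s.left_censored and s.right_censored for s in segs)
        assert all(s.left_len == s.right_len == 1e-6 for s in segs)

    def test_fixed_seed_is_deterministic(self):
        a = simulate_decay_segments(30, 20, 0.01, rng_seed=5)
        b = simulate_decay_segments(30, 20, 0.01, rng_seed=5)
        assert a == b

    @pytest.mark.parametrize("g,n", [(0, 5), (-1, 5), (10, 0)])
    def test_invalid_parameters_raise(self, g, n):
        with pytest.raises(InvalidParameterError):
            simulate_decay_segments(g, n, 0.01, rng_seed=0)


@pytest.fixture(scope="module")
def sim():
    return simulate_cohort(SimConfig(seed=11, n_controls=40, n_sites=120))


class TestCohort:

    def test_carrier_haplotype_copies_founder_inside_segment(self, sim):
        pos = sim.cohort.positions
        mid = (sim.config.locus.region_start
               + sim.config.locus.region_end) // 2
        for _, row in sim.truth[sim.truth["is_carrier"]].iterrows():
            inside = ((pos >= mid - row["seg_left_bp"])
                      & (pos <= mid + row["seg_right_bp"]))
            hap = sim.cohort.hap_matrix[:, row["expansion_hap"]]
            assert np.array_equal(hap[inside],
                                  sim.founder_haplotype[inside])

    def test_every_carrier_has_exactly_one_expanded_allele(self, sim):
        carriers = sim.truth[sim.truth["is_carrier"]]
        locus = sim.config.locus
        assert (carriers["allele_long"]
                >= locus.expansion_threshold).all()
        assert (carriers["allele_short"] <= locus.normal_max).all()

    def test_truth_segments_contain_locus(self, sim):
        carriers = sim.truth[sim.truth["is_carrier"]]
        assert (carriers["seg_left_bp"] >= 0).all()
        assert (carriers["seg_right_bp"] >= 0).all()

    def test_control_alleles_stay_in_normal_range(self, sim):
        controls = sim.truth[~sim.truth["is_carrier"]]
        alleles = np.concatenate([controls["allele_short"],
                                  controls["allele_long"]])
        assert alleles.min() >= 3 and alleles.max() <= 14

    def test_family_members_share_expansion_haplotype(self, sim):
        carriers = sim.truth[sim.truth["is_carrier"]]
        for _, fam in carriers.groupby("family"):
            haps = [sim.cohort.hap_matrix[:, c]
                    for c in fam["expansion_hap"]]
            for h in haps[1:]:
                assert np.array_equal(h, haps[0])
            assert fam["allele_long"].nunique() == 1

    def test_fixed_seed_reproduces_cohort(self):
        cfg = SimConfig(seed=3, n_controls=10, n_sites=50)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.cohort.hap_matrix, b.cohort.hap_matrix)
        assert np.array_equal(a.cohort.positions, b.cohort.positions)
        assert a.truth.equals(b.truth)

    def test_window_too_small_raises(self):
        locus = RepeatLocus()
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimConfig(seed=0, n_sites=1000,
                                      window_flank_bp=300,
                                      locus=locus, n_controls=2))

    def test_genotype_error_rate_flips_sites(self):
        base = SimConfig(seed=9, n_controls=30, n_sites=80)
        noisy = SimConfig(seed=9, n_controls=30, n_sites=80,
                          genotype_error_rate=0.2)
        a, b = simulate_cohort(base), simulate_cohort(noisy)
        frac = (a.cohort.hap_matrix != b.cohort.hap_matrix).mean()
        assert 0.1 < frac < 0.3


class TestReadEvidence:
    def test_short_alleles_give_only_spanning_reads(self):
        ev = simulate_read_evidence((9, 9), depth=12, read_len=150,
                                    rng_seed=1)
        assert set(ev.spanning_counts) == {9}
        assert ev.n_in_repeat_reads == 0

    def test_long_allele_gives_in_repeat_reads(self):
        ev = simulate_read_evidence((9, 1000), depth=15, read_len=150,
                                    rng_seed=2)
        assert set(ev.spanning_counts) == {9}
        assert ev.n_in_repeat_reads > 0

    def test_in_repeat_count_matches_poisson_expectation(self):
        # expected count 15 * (6000 - 150) / 150 = 585
        counts = [simulate_read_evidence((9, 1000), 15, 150,
                                         rng_seed=s).n_in_repeat_reads
                  for s in range(40)]
        assert abs(np.mean(counts) - 585) < 3 * math.sqrt(585 / 40)

    def test_preconditions(self):
        with pytest.raises(InvalidParameterError):
            simulate_read_evidence((9, 9), depth=0, read_len=150, rng_seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_read_evidence((9, 9), depth=10, read_len=8, rng_seed=0)


class TestOpticalMolecules:
    def test_zero_cv_gives_exact_deltas(self):
        mset = simulate_optical_molecules(2094, 50, 0.0, rng_seed=0)
        assert np.allclose(mset.deltas, 6 * 2094)

    def test_sample_mean_tracks_expected_size(self):
        mset = simulate_optical_molecules(2094, 200, 0.5, rng_seed=4)
        mean = 6 * 2094  # 12,564 bp
        se = mset.deltas.std(ddof=1) / math.sqrt(200)
        assert abs(mset.deltas.mean() - mean) < 3 * se

    def test_deltas_never_negative_and_deterministic(self):
        a = simulate_optical_molecules(100, 500, 2.0, rng_seed=8)
        b = simulate_optical_molecules(100, 500, 2.0, rng_seed=8)
        assert (a.deltas >= 0).all()
        assert np.array_equal(a.deltas, b.deltas)
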