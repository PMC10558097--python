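import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strhaplo import (RepeatLocus, SimConfig, control_block_sharing,
                      find_shared_block, ld_r2, pairwise_sharing,
                      select_carrier_haplotypes, simulate_cohort, tag_snps)
from strhaplo.loci import InvalidParameterError
from strhaplo.sharing import (InsufficientCarriersError, SharedBlockFinder,
                              UndefinedLDError)

from conftest import brute_force_block, make_block_fixture

LOCUS = RepeatLocus()


def random_instance(rng, n_haps=6, n_side=20, planted=False):
    """Random haplotypes on sites flanking the repeat; optionally plant a
    shared founder core across the locus gap."""
    left = np.sort(rng.choice(
        np.arange(2_400_000, LOCUS.region_start), n_side, replace=False))
    right = np.sort(rng.choice(
        np.arange(LOCUS.region_end + 1, 2_900_000), n_side, replace=False))
    positions = np.concatenate([left, right])
    haps = rng.integers(0, 2, size=(n_haps, len(positions)))
    if planted:
        core = rng.integers(0, 2, size=len(positions))
        a = rng.integers(0, n_side)            # core spans the gap
        b = rng.integers(n_side, len(positions))
        haps[:, a:b + 1] = core[a:b + 1]
    return haps, positions


class TestPairwiseSharing:
    def test_identical_haplotypes(self):
        haps = np.tile([0, 1, 1, 0], (3, 1))
        assert np.allclose(pairwise_sharing(haps), 1.0)

    def test_complementary_haplotypes(self):
        haps = np.array([[0, 1, 0, 1], [1, 0, 1, 0]])
        m = pairwise_sharing(haps)
        assert m[0, 1] == m[1, 0] == 0.0
        assert m[0, 0] == m[1, 1] == 1.0

    def test_partial_sharing_fraction(self):
        h1 = [0, 1, 1, 0]
        h2 = [0, 1, 1, 1]   # agrees at 3 of 4 sites
        h3 = [1, 0, 0, 1]
        m = pairwise_sharing(np.array([h1, h2, h3]))
        assert m[0, 1] == pytest.approx(0.75)
        assert np.allclose(m, m.T)

    def test_needs_two_haplotypes(self):
        with pytest.raises(InvalidParameterError):
            pairwise_sharing(np.array([[0, 1]]))


class TestFindSharedBlock:
    def test_reported_coordinates_and_length(self, block_fixture):
        haps, positions = block_fixture
        block = find_shared_block(haps, positions, LOCUS)
        assert block.window.start == 2_615_848
        assert block.window.end == 2_688_117
        assert block.length_bp == 72_269  # reported as 72.2 kb

    def test_single_haplotype_spans_all_sites(self):
        rng = np.random.default_rng(0)
        haps, positions = random_instance(rng, n_haps=1)
        block = find_shared_block(haps, positions, LOCUS)
        assert block.window.start == positions[0]
        assert block.window.end == positions[-1]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        haps, positions = random_instance(
            rng, n_haps=int(rng.integers(2, 7)),
            planted=bool(seed % 2))
        mm = int(rng.integers(0, 3))
        block = find_shared_block(haps, positions, LOCUS, max_mismatch=mm)
        best = brute_force_block(haps, positions, LOCUS, max_mismatch=mm)
        if best is None:
            assert block.length_bp == 0
        else:
            length, a, b = best
            assert block.length_bp == length
            assert (block.window.start, block.window.end) == (
                positions[a], positions[b])

    def test_length_non_increasing_in_haplotypes(self):
        rng = np.random.default_rng(42)
        haps, positions = random_instance(rng, n_haps=6, planted=True)
        lengths = [find_shared_block(haps[:k], positions, LOCUS).length_bp
                   for k in range(2, 7)]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_length_non_decreasing_in_mismatch_budget(self):
        rng = np.random.default_rng(43)
        haps, positions = random_instance(rng, n_haps=5, planted=True)
        lengths = [find_shared_block(haps, positions, LOCUS,
                                     max_mismatch=m).length_bp
                   for m in range(4)]
        assert all(a <= b for a, b in zip(lengths, lengths[1:]))

    def test_consensus_invariant_under_input_order(self):
        rng = np.random.default_rng(44)
        haps, positions = random_instance(rng, n_haps=6, planted=True)
        b1 = find_shared_block(haps, positions, LOCUS)
        b2 = find_shared_block(haps[::-1], positions, LOCUS)
        assert np.array_equal(b1.consensus, b2.consensus)
        assert b1.site_slice == b2.site_slice

    def test_locus_outside_site_range_rejected(self):
        positions = np.arange(10) + LOCUS.region_end + 100
        haps = np.zeros((2, 10), dtype=int)
        with pytest.raises(InvalidParameterError):
            find_shared_block(haps, positions, LOCUS)

    def test_estimator_wrapper_exposes_block(self, block_fixture):
        haps, positions = block_fixture
        finder = SharedBlockFinder(locus=LOCUS).fit(haps,
                                                    positions=positions)
        assert finder.block_.length_bp == 72_269
        assert finder.transform(haps).shape[1] == len(finder.block_.consensus)
        assert finder.get_params()["max_mismatch"] == 0


class TestControlSharing:
    def test_zero_controls(self, block_fixture):
        haps, positions = block_fixture
        block = find_shared_block(haps, positions, LOCUS)
        assert control_block_sharing(block, np.empty((0, len(positions)))) \
            == (0, 0.0)

    def test_matching_control(self, block_fixture):
        haps, positions = block_fixture
        block = find_shared_block(haps, positions, LOCUS)
        control = haps[:1].copy()
        assert control_block_sharing(block, control) == (1, 1.0)

    def test_fractional_sharing(self, block_fixture):
        haps, positions = block_fixture
        block = find_shared_block(haps, positions, LOCUS)
        a, b = block.site_slice
        controls = np.random.default_rng(1).integers(
            0, 2, size=(10, len(positions)))
        controls[:3, a:b] = block.consensus
        controls[3:, a] = 1 - block.consensus[0]
        n, frac = control_block_sharing(block, controls)
        assert (n, frac) == (3, 0.3)


class TestSelectCarrierHaplotypes:
    def test_recovers_truth_phases_on_simulated_cohort(self):
        sim = simulate_cohort(SimConfig(seed=21, n_controls=30, n_sites=150))
        cols, _ = select_carrier_haplotypes(sim.cohort, sim.config.locus)
        truth_cols = sim.truth.loc[sim.truth["is_carrier"],
                                   "expansion_hap"].tolist()
        assert cols == truth_cols

    def test_identical_phase_pair_selected(self):
        # two carriers whose first haplotypes are identical over the window
        import pandas as pd
        from strhaplo import PhasedCohort
        rng = np.random.default_rng(5)
        haps, positions = random_instance(rng, n_haps=4)
        haps[2] = haps[0]  # carrier2 phase0 == carrier1 phase0
        mat = haps.T.astype(np.int8)
        cohort = PhasedCohort(
            chrom="chr20", positions=positions,
            ref=["A"] * len(positions), alt=["G"] * len(positions),
            hap_matrix=mat,
            samples=pd.DataFrame({"sample": ["s1", "s2"],
                                  "family": ["f1", "f2"],
                                  "is_case": True, "is_carrier": True}))
        cols, _ = select_carrier_haplotypes(cohort, LOCUS)
        assert cols == [0, 2]

    def test_single_carrier_rejected(self):
        sim = simulate_cohort(SimConfig(
            seed=2, n_carrier_families=1, family_sizes=(1,),
            n_controls=5, n_sites=40))
        with pytest.raises(InsufficientCarriersError):
            select_carrier_haplotypes(sim.cohort, sim.config.locus)

    def test_block_covers_truth_segment_intersection(self):
        # at zero genotype error the detected block contains every site
        # inside the intersection of the true ancestral segments
        sim = simulate_cohort(SimConfig(seed=33, n_controls=20, n_sites=200))
        locus = sim.config.locus
        cols, haps = select_carrier_haplotypes(sim.cohort, locus)
        block = find_shared_block(haps, sim.cohort.positions, locus)
        carriers = sim.truth[sim.truth["is_carrier"]]
        mid = (locus.region_start + locus.region_end) // 2
        lo = mid - carriers["seg_left_bp"].min()
        hi = mid + carriers["seg_right_bp"].min()
        pos = sim.cohort.positions
        inside = pos[(pos >= lo) & (pos <= hi)]
        if len(inside):
            assert block.window.start <= inside[0]
            assert block.window.end >= inside[-1]
            # consensus equals the founder over the intersection
            a, _ = block.site_slice
            for p, f in zip(pos, sim.founder_haplotype):
                if lo <= p <= hi:
                    j = int(np.searchsorted(pos, p)) - a
                    assert block.consensus[j] == f


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 1, 0, 1])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_equilibrium_counts_give_zero(self):
        a = np.repeat([1, 1, 0, 0], 25)
        b = np.repeat([1, 0, 1, 0], 25)
        assert ld_r2(a, b) == pytest.approx(0.0)

    def test_direct_two_by_two_computation(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D = 0.15, r2 = 0.36
        a = np.repeat([1, 1, 0, 0], [40, 10, 10, 40])
        b = np.repeat([1, 0, 1, 0], [40, 10, 10, 40])
        assert ld_r2(a, b) == pytest.approx(0.36)

    def test_monomorphic_rejected(self):
        with pytest.raises(UndefinedLDError):
            ld_r2(np.ones(10), np.array([0, 1] * 5))

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=4, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_relabelling_invariance(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if a.mean() in (0, 1) or b.mean() in (0, 1):
            return
        r = ld_r2(a, b)
        assert ld_r2(b, a) == pytest.approx(r)
        assert ld_r2(1 - a, b) == pytest.approx(r)
        assert ld_r2(a, 1 - b) == pytest.approx(r)
        assert 0.0 <= r <= 1.0 + 1e-12


def tag_snps_reference(haps, window_sites, step_sites, r2_threshold):
    """Independent reimplementation of the sliding-window greedy rule."""
    n = haps.shape[1]
    removed = set()
    start = 0
    while start < n:
        window = [j for j in range(start, min(start + window_sites, n))
                  if j not in removed and 0 < haps[:, j].mean() < 1]
        for x in range(len(window)):
            for y in range(x + 1, len(window)):
                i, j = window[x], window[y]
                if i in removed or j in removed:
                    continue
                if ld_r2(haps[:, i], haps[:, j]) > r2_threshold:
                    removed.add(j)
        start += step_sites
    return [j for j in range(n) if j not in removed]


class TestTagSnps:
    def test_perfect_ld_pair_keeps_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=20)
        haps = np.column_stack([col, col])
        assert tag_snps(haps) == [0]

    def test_independent_sites_all_kept(self):
        # orthogonal design: each pair has r2 = 0
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert tag_snps(haps) == [0, 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(12, 20))
        w, s, t = int(rng.integers(3, 8)), int(rng.integers(1, 4)), 0.5
        assert tag_snps(haps, w, s, t) == tag_snps_reference(haps, w, s, t)
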