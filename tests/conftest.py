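import numpy as np
import pytest

from strhaplo import RepeatLocus


@pytest.fixture
def locus():
    return RepeatLocus()


def make_block_fixture(locus, n_haps=6, rng_seed=0):
    """Haplotypes identical across sites spanning chr20:2,615,848-2,688,117
    and disagreeing at the next site outward on each side.

    Returns (haps, positions): haplotype-major matrix and site positions.
    """
    rng = np.random.default_rng(rng_seed)
    inner = np.array([2_615_848, 2_625_000, 2_640_000, 2_650_000,
                      2_655_000, 2_670_000, 2_688_117])
    outer_left, outer_right = 2_600_000, 2_700_000
    positions = np.concatenate([[outer_left], inner, [outer_right]])
    core = rng.integers(0, 2, size=len(inner))
    haps = np.tile(core, (n_haps, 1))
    # outward sites: half the haplotypes carry the minority allele, so every
    # haplotype set breaks there (consensus tie resolves to 0; carriers of 1
    # mismatch)
    left_col = np.array([1] * (n_haps // 2) + [0] * (n_haps - n_haps // 2))
    right_col = 1 - left_col
    haps = np.column_stack([left_col, haps, right_col])
    assert positions[0] < locus.region_start < locus.region_end < positions[-1]
    return haps, positions


@pytest.fixture
def block_fixture(locus):
    return make_block_fixture(locus)


def brute_force_block(haps, positions, locus, max_mismatch=0):
    """Exhaustive-interval oracle for the maximal shared block.

    Enumerates every site interval spanning the locus gap, keeps those at
    which every haplotype matches the consensus with at most
    ``max_mismatch`` exceptions, and returns the (length, a, b) maximising
    (length_bp, a, b) lexicographically, or None if no interval qualifies.
    """
    haps = np.atleast_2d(np.asarray(haps))
    positions = np.asarray(positions)
    gap_l = int(np.searchsorted(positions, locus.region_start) - 1)
    gap_r = int(np.searchsorted(positions, locus.region_end, side="right"))
    cons = (haps.sum(axis=0) * 2 > haps.shape[0]).astype(int)
    best = None
    for a in range(gap_l + 1):
        for b in range(gap_r, len(positions)):
            mism = (haps[:, a:b + 1] != cons[a:b + 1]).sum(axis=1)
            if mism.max() <= max_mismatch:
                cand = (int(positions[b] - positions[a]), a, b)
                if best is None or cand > best:
                    best = cand
    return best
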