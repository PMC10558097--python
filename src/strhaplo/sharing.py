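"""Identity-by-state shared haplotype blocks around a repeat locus.

Given phased haplotypes in a window around the repeat, this module selects
each carrier's expansion-bearing phase, computes pairwise sharing, finds
the maximal contiguous shared block containing the inter-site gap where the
locus lies, quantifies how many control haplotypes also carry the block
consensus, and picks tagging SNPs by sliding-window LD (r-squared) pruning.

Sharing is deterministic identity by state: no recombination-map-aware
IBD model is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .loci import GenomicWindow, InvalidParameterError, RepeatLocus


class InsufficientCarriersError(ValueError):
    """Fewer than two carriers: no shared block is defined."""


class UndefinedLDError(ValueError):
    """LD is undefined at a monomorphic site."""


@dataclass
class SharedBlock:
    """A maximal carrier-shared interval around the repeat locus.

    ``length_bp`` follows the position-difference convention
    (end - start), matching how such blocks are reported in kb.
    """

    window: GenomicWindow | None
    length_bp: int
    member_ids: list[str]
    consensus: np.ndarray                 # alleles over block sites
    site_slice: tuple[int, int]           # half-open site-index range
    n_controls_matching: int = 0
    control_match_fraction: float = 0.0
    max_mismatch: int = 0


def _locus_gap(positions: np.ndarray, locus: RepeatLocus) -> tuple[int, int]:
    """Indices of the sites flanking the repeat tract (left, right)."""
    left = np.searchsorted(positions, locus.region_start) - 1
    right = np.searchsorted(positions, locus.region_end, side="right")
    if left < 0 or right >= len(positions):
        raise InvalidParameterError(
            "locus must have at least one site on each side")
    return int(left), int(right)


def _consensus(haps: np.ndarray) -> np.ndarray:
    # majority allele per site; ties -> allele 0 (order-invariant)
    return (haps.sum(axis=0) * 2 > haps.shape[0]).astype(np.int8)


def pairwise_sharing(haps: np.ndarray) -> np.ndarray:
    """Fraction of sites at which each haplotype pair agrees.

    ``haps`` is haplotype-major (n_haps, n_sites).  The diagonal is 1.
    """
    haps = np.asarray(haps)
    if haps.ndim != 2 or haps.shape[0] < 2:
        raise InvalidParameterError("need >= 2 haplotypes on one site set")
    n, m = haps.shape
    eq = (haps[:, None, :] == haps[None, :, :]).mean(axis=2)
    return eq


def find_shared_block(haps: np.ndarray, positions: np.ndarray,
                      locus: RepeatLocus, max_mismatch: int = 0,
                      member_ids: Sequence[str] | None = None) -> SharedBlock:
    """Maximal contiguous site interval containing the locus gap on which
    every haplotype matches the consensus with <= ``max_mismatch``
    exceptions.

    The block is the interval maximising ``pos[b] - pos[a]`` over all
    intervals ``[a, b]`` spanning the inter-site gap that holds the repeat;
    block coordinates are the first and last matching site positions.  If
    even the minimal gap-spanning interval violates the budget, a
    zero-length block abutting the locus is returned.
    """
    haps = np.atleast_2d(np.asarray(haps))
    positions = np.asarray(positions)
    if haps.shape[1] != len(positions):
        raise InvalidParameterError("haplotypes and positions disagree on sites")
    gap_l, gap_r = _locus_gap(positions, locus)
    cons = _consensus(haps)
    mism = (haps != cons[None, :]).astype(np.int64)
    csum = np.concatenate([np.zeros((haps.shape[0], 1), dtype=np.int64),
                           np.cumsum(mism, axis=1)], axis=1)
    ids = list(member_ids) if member_ids is not None else [
        f"hap{i}" for i in range(haps.shape[0])]

    def ok(a: int, b: int) -> bool:
        return bool(((csum[:, b + 1] - csum[:, a]) <= max_mismatch).all())

    best: tuple[int, int, int] | None = None  # (length_bp, a, b)
    n = len(positions)
    for a in range(gap_l, -1, -1):
        if not ok(a, gap_r):
            break
        lo, hi = gap_r, n - 1  # largest valid b: monotone, binary search
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if ok(a, mid):
                lo = mid
            else:
                hi = mid - 1
        length = int(positions[lo] - positions[a])
        if best is None or length > best[0]:
            best = (length, a, lo)

    if best is None:
        return SharedBlock(window=None, length_bp=0, member_ids=ids,
                           consensus=np.empty(0, dtype=np.int8),
                           site_slice=(gap_r, gap_r),
                           max_mismatch=max_mismatch)
    length, a, b = best
    return SharedBlock(
        window=GenomicWindow(locus.chrom, int(positions[a]),
                             int(positions[b])),
        length_bp=length, member_ids=ids,
        consensus=cons[a:b + 1].copy(), site_slice=(a, b + 1),
        max_mismatch=max_mismatch)


def control_block_sharing(block: SharedBlock,
                          control_haps: np.ndarray) -> tuple[int, float]:
    """Count control haplotypes matching the block consensus.

    A control shares the block when it matches the consensus at all block
    sites with at most the block's mismatch budget.  Control haplotypes
    must be given over the same full site set used to find the block.
    """
    control_haps = np.atleast_2d(np.asarray(control_haps))
    if control_haps.shape[0] == 0 or control_haps.size == 0:
        return 0, 0.0
    a, b = block.site_slice
    if b == a:
        return 0, 0.0
    sub = control_haps[:, a:b]
    mism = (sub != block.consensus[None, :]).sum(axis=1)
    n_match = int((mism <= block.max_mismatch).sum())
    return n_match, n_match / control_haps.shape[0]


class SharedBlockFinder(BaseEstimator):
    """Estimator wrapper: fit phased carrier haplotypes, expose the block.

    Parameters
    ----------
    locus : RepeatLocus
        Repeat definition whose flanking gap anchors the block.
    max_mismatch : int
        Per-haplotype mismatch budget against the block consensus.
    """

    def __init__(self, locus: RepeatLocus | None = None,
                 max_mismatch: int = 0):
        self.locus = locus
        self.max_mismatch = max_mismatch

    def fit(self, X: np.ndarray, y=None, *, positions: np.ndarray,
            member_ids: Sequence[str] | None = None) -> "SharedBlockFinder":
        locus = self.locus if self.locus is not None else RepeatLocus()
        self.block_ = find_shared_block(X, positions, locus,
                                        self.max_mismatch, member_ids)
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Restrict haplotypes to the fitted block's sites."""
        a, b = self.block_.site_slice
        return np.atleast_2d(np.asarray(X))[:, a:b]


def select_carrier_haplotypes(cohort, locus: RepeatLocus,
                              max_mismatch: int = 0,
                              exhaustive_limit: int = 12
                              ) -> tuple[list[int], np.ndarray]:
    """Choose each carrier's expansion-bearing phase.

    For up to ``exhaustive_limit`` carriers all 2^c phase assignments are
    scored by the shared-block length at the locus and the maximiser is
    returned (ties toward phase 0).  Beyond that a greedy scheme seeds with
    the best pair of phases from the first two carriers and adds each
    remaining carrier's better phase.

    Returns (haplotype column indices, haplotype-major allele matrix).
    """
    carriers = np.flatnonzero(cohort.samples["is_carrier"].to_numpy())
    if len(carriers) < 2:
        raise InsufficientCarriersError(
            f"need >= 2 carriers, got {len(carriers)}")
    positions = cohort.positions

    def cols_for(choice: Sequence[int]) -> list[int]:
        return [2 * int(s) + int(c) for s, c in zip(carriers, choice)]

    def score(cols: list[int]) -> int:
        haps = cohort.haplotypes(cols)
        return find_shared_block(haps, positions, locus,
                                 max_mismatch).length_bp

    c = len(carriers)
    if c <= exhaustive_limit:
        best_choice, best_len = None, -1
        for choice in itertools.product((0, 1), repeat=c):
            length = score(cols_for(choice))
            if length > best_len:
                best_choice, best_len = choice, length
        choice = list(best_choice)
    else:
        best_pair, best_len = (0, 0), -1
        for pair in itertools.product((0, 1), repeat=2):
            cols = [2 * int(carriers[0]) + pair[0],
                    2 * int(carriers[1]) + pair[1]]
            length = score(cols)
            if length > best_len:
                best_pair, best_len = pair, length
        choice = list(best_pair)
        for k in range(2, c):
            scored = []
            for ph in (0, 1):
                cols = cols_for(choice + [ph])[: k + 1]
                scored.append((score(cols), -ph))
            choice.append(-max(scored)[1])
    cols = cols_for(choice)
    return cols, cohort.haplotypes(cols)


def ld_r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Haplotype-count linkage disequilibrium r-squared for two sites.

    r2 = D^2 / (pA (1-pA) pB (1-pB)) with D = pAB - pA * pB, computed
    from phased binary allele vectors of equal length.
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("allele vectors must match in length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedLDError("monomorphic site: r2 undefined")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def tag_snps(haps: np.ndarray, window_sites: int = 50, step_sites: int = 5,
             r2_threshold: float = 0.5) -> list[int]:
    """Tagging-SNP selection by sliding-window greedy LD pruning.

    Within each window of ``window_sites`` consecutive site indices
    (advancing by ``step_sites``), the later site of any still-retained
    pair with r2 > ``r2_threshold`` is removed.  Monomorphic sites are
    never pruned (their LD is undefined).  Returns retained site indices
    in position order.
    """
    haps = np.atleast_2d(np.asarray(haps))
    n_sites = haps.shape[1]
    poly = [bool(0 < haps[:, j].mean() < 1) for j in range(n_sites)]
    keep = [True] * n_sites
    for start in range(0, n_sites, step_sites):
        idx = [j for j in range(start, min(start + window_sites, n_sites))
               if keep[j] and poly[j]]
        for i_pos, i in enumerate(idx):
            if not keep[i]:
                continue
            for j in idx[i_pos + 1:]:
                if keep[j] and ld_r2(haps[:, i], haps[:, j]) > r2_threshold:
                    keep[j] = False
    return [j for j in range(n_sites) if keep[j]]
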