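"""Synthetic cohorts with a founder repeat expansion.

The generator reproduces the statistical structure the downstream analysis
assumes: a single founder chromosome carrying the expansion, whose flanking
haplotype decays by recombination over ``g`` generations (independent
exponential genetic lengths on each side, i.e. a star genealogy); background
haplotypes drawn per-site from population allele frequencies (no background
LD); a non-expanded repeat-allele distribution spanning 3-14 units with mode
9; expanded alleles far above the pathogenic threshold; read evidence at the
locus; and somatically unstable optical-map molecule sizes.

Reproducibility: one root seed; every operation derives an independent
child stream via :class:`numpy.random.SeedSequence` spawning, so stages can
be re-run in isolation with identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import GenomicWindow, InvalidParameterError, RepeatLocus


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


def _triangular_normal_weights() -> dict[int, float]:
    # w(u) ∝ 7 - |u - 9| over 3..14: strict mode at 9 (a symmetric
    # triangle would tie 8 and 9).
    raw = {u: 7.0 - abs(u - 9) for u in range(3, 15)}
    total = sum(raw.values())
    return {u: w / total for u, w in raw.items()}


@dataclass(frozen=True)
class AncestralSegment:
    """Genetic extent (Morgans) of founder haplotype on one chromosome."""

    left_len: float
    right_len: float
    left_censored: bool = False
    right_censored: bool = False

    def __post_init__(self) -> None:
        if self.left_len < 0 or self.right_len < 0:
            raise InvalidParameterError("segment lengths must be >= 0")

    @property
    def sides(self) -> tuple[tuple[float, bool], tuple[float, bool]]:
        return (
            (self.left_len, self.left_censored),
            (self.right_len, self.right_censored),
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic founder-expansion cohort.

    Defaults follow the screened cohort: five carrier families (seven
    patients, family sizes 2,2,1,1,1), 7506 controls, an expansion roughly
    32 generations old, a ±1 Mb window around the NOP56 repeat, a linear
    1 cM/Mb genetic map, normal alleles 3-14 units with mode 9 and expanded
    alleles 650-2500 units.
    """

    seed: int = 0
    n_carrier_families: int = 5
    n_controls: int = 7506
    g_true: float = 31.7
    locus: RepeatLocus = field(default_factory=RepeatLocus)
    window_flank_bp: int = 1_000_000
    recomb_rate_cm_per_mb: float = 1.0
    n_sites: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    normal_allele_weights: Mapping[int, float] = field(
        default_factory=_triangular_normal_weights
    )
    expanded_allele_range: tuple[int, int] = (650, 2500)
    genotype_error_rate: float = 0.0
    family_sizes: tuple[int, ...] | None = (2, 2, 1, 1, 1)

    def __post_init__(self) -> None:
        if self.g_true < 1:
            raise InvalidParameterError("g_true must be >= 1")
        if self.n_sites < 2:
            raise InvalidParameterError("n_sites must be >= 2")
        if self.n_carrier_families < 0 or self.n_controls < 0:
            raise InvalidParameterError("counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie in (0, 0.5]")
        if not math.isclose(sum(self.normal_allele_weights.values()), 1.0,
                            rel_tol=1e-9):
            raise InvalidParameterError("normal allele weights must sum to 1")
        if self.expanded_allele_range[0] > self.expanded_allele_range[1]:
            raise InvalidParameterError("bad expanded_allele_range")
        if not 0 <= self.genotype_error_rate < 1:
            raise InvalidParameterError("genotype_error_rate in [0, 1)")
        if self.family_sizes is not None and (
            len(self.family_sizes) != self.n_carrier_families
            or any(s < 1 for s in self.family_sizes)
        ):
            raise InvalidParameterError(
                "family_sizes must list one positive size per carrier family"
            )

    @property
    def window(self) -> GenomicWindow:
        return self.locus.window(self.window_flank_bp)

    @property
    def sizes(self) -> tuple[int, ...]:
        if self.family_sizes is None:
            return (1,) * self.n_carrier_families
        return self.family_sizes


@dataclass
class PhasedCohort:
    """Phased biallelic sites over a cohort.

    ``hap_matrix`` is sites x haplotypes (two columns per sample, in
    sample order); ``samples`` carries per-sample metadata including
    carrier flags.
    """

    chrom: str
    positions: np.ndarray          # strictly increasing, 1-based
    ref: list[str]
    alt: list[str]
    hap_matrix: np.ndarray         # (n_sites, 2 * n_samples) of 0/1
    samples: pd.DataFrame          # columns: sample, family, is_case, is_carrier

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions) > 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if self.hap_matrix.shape != (len(self.positions),
                                     2 * len(self.samples)):
            raise InvalidParameterError("hap_matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def hap_columns(self, sample_index: int) -> tuple[int, int]:
        return 2 * sample_index, 2 * sample_index + 1

    def haplotypes(self, columns: Sequence[int]) -> np.ndarray:
        """Haplotype-major (n_haps, n_sites) view of selected columns."""
        return self.hap_matrix[:, list(columns)].T.copy()


@dataclass
class ReadEvidence:
    """Summarised short-read support for a repeat genotype."""

    spanning_counts: dict[int, int]
    n_in_repeat_reads: int
    read_len: int
    haploid_depth: float

    def __post_init__(self) -> None:
        if any(u < 1 or c < 0 for u, c in self.spanning_counts.items()):
            raise InvalidParameterError("bad spanning read counts")
        if self.n_in_repeat_reads < 0:
            raise InvalidParameterError("n_in_repeat_reads must be >= 0")


@dataclass
class OpticalMoleculeSet:
    """Optical-map molecule size deltas at the repeat locus.

    ``deltas`` are molecule sizes minus the reference inter-marker
    distance (bp), the quantity from which unit counts are derived.
    """

    deltas: np.ndarray
    reference_distance: int = 7990
    unit_len: int = 6

    @classmethod
    def from_raw_sizes(cls, sizes: Sequence[float],
                       reference_distance: int = 7990,
                       unit_len: int = 6) -> "OpticalMoleculeSet":
        """Build from raw molecule sizes (the subtract-reference dialect)."""
        return cls(np.asarray(sizes, dtype=float) - reference_distance,
                   reference_distance, unit_len)


@dataclass
class SimulatedCohort:
    cohort: PhasedCohort
    truth: pd.DataFrame            # per-sample truth table
    founder_haplotype: np.ndarray  # (n_sites,)
    allele_freqs: np.ndarray       # alt-allele frequencies per site
    config: SimConfig


def simulate_decay_segments(g: float, n_chrom: int,
                            window_genetic_half_length: float,
                            rng_seed: int) -> list[AncestralSegment]:
    """Draw per-chromosome ancestral segment extents after ``g`` generations.

    Each side's genetic length is exponential with rate ``g`` per Morgan
    (mean 1/g); draws beyond the window half-length are truncated there and
    flagged censored.  ``window_genetic_half_length`` may be ``math.inf``
    for an effectively unbounded window.
    """
    if g <= 0 or n_chrom <= 0:
        raise InvalidParameterError("g and n_chrom must be positive")
    if window_genetic_half_length <= 0:
        raise InvalidParameterError("window half-length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xDECA)))
    draws = rng.exponential(scale=1.0 / g, size=(n_chrom, 2))
    out = []
    bound = window_genetic_half_length
    for left, right in draws:
        lc, rc = left >= bound, right >= bound
        out.append(AncestralSegment(
            left_len=min(left, bound), right_len=min(right, bound),
            left_censored=bool(lc), right_censored=bool(rc)))
    return out


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    win, locus = cfg.window, cfg.locus
    candidates = np.concatenate([
        np.arange(win.start, locus.region_start),
        np.arange(locus.region_end + 1, win.end + 1),
    ])
    if len(candidates) < cfg.n_sites:
        raise ConfigurationError("window too small for n_sites")
    for _ in range(20):  # ensure >= 1 site on each side of the repeat
        pos = np.sort(rng.choice(candidates, size=cfg.n_sites, replace=False))
        if pos[0] < locus.region_start and pos[-1] > locus.region_end:
            return pos
    raise ConfigurationError("could not place sites on both sides of locus")


def _morgans_to_bp(m: float, rate_cm_per_mb: float) -> float:
    return m * 1e8 / rate_cm_per_mb


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a phased cohort carrying a founder repeat expansion.

    Carrier expansion-bearing haplotypes copy the founder haplotype inside
    their ancestral decay segment and are drawn from the population allele
    frequencies outside it; all other haplotypes are drawn from the
    frequencies throughout.  Carrier family members share the index
    carrier's expansion haplotype and segment.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_sites, rng_pop, rng_alleles, rng_err = (
        np.random.default_rng(s) for s in root.spawn(4))

    positions = _site_positions(cfg, rng_sites)
    n_sites = len(positions)
    freqs = rng_pop.uniform(*cfg.maf_range, size=n_sites)
    founder = (rng_pop.random(n_sites) < freqs).astype(np.int8)

    n_carriers = sum(cfg.sizes)
    n_samples = n_carriers + cfg.n_controls
    hap = (rng_pop.random((n_sites, 2 * n_samples))
           < freqs[:, None]).astype(np.int8)

    # decay segments: one per carrier family (shared within family)
    half_m = cfg.window_flank_bp * cfg.recomb_rate_cm_per_mb / 1e8
    fam_segments = simulate_decay_segments(
        cfg.g_true, max(cfg.n_carrier_families, 1), half_m,
        rng_seed=cfg.seed) if cfg.n_carrier_families else []

    normal_units = np.array(sorted(cfg.normal_allele_weights))
    normal_p = np.array([cfg.normal_allele_weights[u] for u in normal_units])

    rows = []
    locus_mid = (cfg.locus.region_start + cfg.locus.region_end) // 2
    sample_idx = 0
    for fam_idx in range(cfg.n_carrier_families):
        seg = fam_segments[fam_idx]
        left_bp = _morgans_to_bp(seg.left_len, cfg.recomb_rate_cm_per_mb)
        right_bp = _morgans_to_bp(seg.right_len, cfg.recomb_rate_cm_per_mb)
        lo = locus_mid - left_bp
        hi = locus_mid + right_bp
        inside = (positions >= lo) & (positions <= hi)
        exp_allele = int(rng_alleles.integers(cfg.expanded_allele_range[0],
                                              cfg.expanded_allele_range[1] + 1))
        index_col = 2 * sample_idx
        for member in range(cfg.sizes[fam_idx]):
            col = 2 * sample_idx  # expansion haplotype on first phase
            if member == 0:
                hap[inside, col] = founder[inside]
            else:
                # family members share the index carrier's expansion
                # haplotype in full
                hap[:, col] = hap[:, index_col]
            short = int(rng_alleles.choice(normal_units, p=normal_p))
            rows.append(dict(
                sample=f"F{fam_idx + 1}_P{member + 1}",
                family=f"F{fam_idx + 1}", is_case=True, is_carrier=True,
                allele_short=short, allele_long=exp_allele,
                expansion_hap=col,
                seg_left_bp=left_bp, seg_right_bp=right_bp,
                left_censored=seg.left_censored,
                right_censored=seg.right_censored))
            sample_idx += 1
    for c in range(cfg.n_controls):
        a, b = sorted(rng_alleles.choice(normal_units, size=2, p=normal_p))
        rows.append(dict(
            sample=f"C{c + 1}", family=f"CF{c + 1}", is_case=False,
            is_carrier=False, allele_short=int(a), allele_long=int(b),
            expansion_hap=-1, seg_left_bp=np.nan, seg_right_bp=np.nan,
            left_censored=False, right_censored=False))
        sample_idx += 1

    if cfg.genotype_error_rate > 0:
        flips = rng_err.random(hap.shape) < cfg.genotype_error_rate
        hap = np.where(flips, 1 - hap, hap).astype(np.int8)

    truth = pd.DataFrame(rows)
    samples = truth[["sample", "family", "is_case", "is_carrier"]].copy()
    cohort = PhasedCohort(
        chrom=cfg.locus.chrom, positions=positions,
        ref=["A"] * n_sites, alt=["G"] * n_sites,
        hap_matrix=hap, samples=samples)
    return SimulatedCohort(cohort=cohort, truth=truth,
                           founder_haplotype=founder,
                           allele_freqs=freqs, config=cfg)


def simulate_read_evidence(true_alleles: tuple[int, int], depth: float,
                           read_len: int, rng_seed: int,
                           unit_len: int = 6,
                           anchor_bp: int = 10) -> ReadEvidence:
    """Emit summarised read evidence for a repeat genotype.

    Alleles short enough for a read to span the tract plus two anchors
    yield spanning reads reporting the exact unit count, Poisson(depth)
    many; longer alleles yield in-repeat reads with expected count
    ``depth * (allele_bp - read_len) / read_len`` (floor 1).
    """
    if read_len < 2 * unit_len:
        raise InvalidParameterError("read_len must be >= 2 x unit length")
    if depth <= 0:
        raise InvalidParameterError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0x5EAD)))
    spanning: dict[int, int] = {}
    n_irr = 0
    for units in true_alleles:
        allele_bp = units * unit_len
        if allele_bp < read_len - 2 * anchor_bp:
            n = int(rng.poisson(depth))
            if n:
                spanning[units] = spanning.get(units, 0) + n
        else:
            expected = max(1.0, depth * (allele_bp - read_len) / read_len)
            n_irr += int(rng.poisson(expected))
    return ReadEvidence(spanning_counts=spanning, n_in_repeat_reads=n_irr,
                        read_len=read_len, haploid_depth=depth)


def simulate_optical_molecules(true_units: int, n_molecules: int,
                               mosaic_cv: float, rng_seed: int,
                               unit_len: int = 6) -> OpticalMoleculeSet:
    """Draw optical-map molecule deltas for a somatically unstable allele.

    Deltas are normal with mean ``unit_len * true_units`` and standard
    deviation ``mosaic_cv`` times the mean, truncated at zero.
    """
    if true_units <= 0:
        raise InvalidParameterError("true_units must be positive")
    if mosaic_cv < 0:
        raise InvalidParameterError("mosaic_cv must be >= 0")
    if n_molecules < 1:
        raise InvalidParameterError("n_molecules must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0x0971)))
    mean = float(unit_len * true_units)
    deltas = rng.normal(mean, mosaic_cv * mean, size=n_molecules)
    return OpticalMoleculeSet(deltas=np.maximum(deltas, 0.0))


def simulate_ancestry_coords(n_groups: int, n_samples: int, dim: int,
                             rng_seed: int, spread: float = 0.005,
                             scale: float = 1000.0):
    """Synthetic PC-space reference centroids and sample coordinates.

    Plumbing for end-to-end runs: centroids on a scaled simplex-like
    layout, samples scattered near a randomly chosen home centroid with
    isotropic noise of standard deviation ``spread``.
    Returns (labels, centroids, sample_coords, home_labels).
    """
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xA11C)))
    labels = [f"G{i + 1}" for i in range(n_groups)]
    centroids = rng.normal(0.0, 1.0, size=(n_groups, dim))
    home = rng.integers(0, n_groups, size=n_samples)
    coords = centroids[home] + rng.normal(0.0, spread, size=(n_samples, dim))
    return labels, centroids, coords, [labels[h] for h in home]
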