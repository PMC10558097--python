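"""Repeat-allele classification, read-evidence genotyping and cohort screening.

Alleles are classified from their unit count against the locus thresholds
(normal <= normal_max < intermediate < expansion_threshold <= expanded).
Repeat length is genotyped from summarised read evidence: spanning reads
give exact unit counts which are split into at most two clusters by exact
one-dimensional two-means; in-repeat reads (reads lying wholly inside the
tract) give only a lower bound on the long allele, estimated from their
count, the read length and the haploid depth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .loci import InvalidParameterError, RepeatLocus
from .simulate import ReadEvidence

NORMAL = "normal"
INTERMEDIATE = "intermediate"
EXPANDED = "expanded"


class NoEvidenceError(ValueError):
    """No spanning or in-repeat reads were supplied."""


@dataclass(frozen=True)
class RepeatGenotype:
    sample: str
    short_allele: int
    long_allele: int
    long_is_lower_bound: bool
    classification: str

    def __post_init__(self) -> None:
        if self.short_allele > self.long_allele:
            raise InvalidParameterError("short_allele must be <= long_allele")


@dataclass(frozen=True)
class ScreenSummary:
    n_samples: int
    n_carriers: int
    n_carrier_families: int
    n_families: int
    carrier_fraction_families: float
    allele_histogram: dict[int, int]
    modal_allele: int | None


def classify_allele(units: int, locus: RepeatLocus) -> str:
    """Classify a repeat allele as normal, intermediate or expanded."""
    if units < 1:
        raise InvalidParameterError(f"allele unit count must be >= 1, got {units}")
    if units <= locus.normal_max:
        return NORMAL
    if units >= locus.expansion_threshold:
        return EXPANDED
    return INTERMEDIATE


def _two_means_split(values: np.ndarray, weights: np.ndarray) -> int:
    """Exact weighted 1-D two-means: index of first element of the upper
    cluster in the sorted value array (0 = single cluster).

    Ties in within-cluster sum of squares are broken toward the larger
    lower cluster, so a value equidistant between the two cluster means
    joins the lower cluster.
    """
    n = len(values)
    if n == 1:
        return 0
    best_sse, best_split = math.inf, 0
    w_total = weights.sum()
    mean_all = float((values * weights).sum() / w_total)
    sse_all = float((weights * (values - mean_all) ** 2).sum())
    best_sse, best_split = sse_all, 0
    for split in range(1, n):  # ascending + <= : ties favour larger lower cluster
        lo_v, lo_w = values[:split], weights[:split]
        hi_v, hi_w = values[split:], weights[split:]
        m_lo = float((lo_v * lo_w).sum() / lo_w.sum())
        m_hi = float((hi_v * hi_w).sum() / hi_w.sum())
        sse = float((lo_w * (lo_v - m_lo) ** 2).sum()
                    + (hi_w * (hi_v - m_hi) ** 2).sum())
        if sse <= best_sse:
            best_sse, best_split = sse, split
    return best_split


def _cluster_mode(values: np.ndarray, weights: np.ndarray) -> int:
    best = max(zip(weights, -values))  # max weight, ties -> smaller value
    return int(-best[1])


def genotype_from_reads(ev: ReadEvidence, locus: RepeatLocus,
                        sample: str = "sample") -> RepeatGenotype:
    """Genotype repeat length from summarised read evidence.

    Spanning unit counts are split into at most two clusters (exact 1-D
    two-means, weighted by read multiplicity); each cluster's allele is its
    modal count.  If in-repeat reads are present the long allele becomes
    the larger of the cluster estimate and
    ``ceil(n_irr * read_len / (unit_len * depth)) + read_len / unit_len``,
    flagged as a lower bound.
    """
    spanning = {u: c for u, c in ev.spanning_counts.items() if c > 0}
    if not spanning and ev.n_in_repeat_reads == 0:
        raise NoEvidenceError("no spanning or in-repeat reads")

    short = long_ = None
    if spanning:
        values = np.array(sorted(spanning), dtype=float)
        weights = np.array([spanning[int(v)] for v in values], dtype=float)
        split = _two_means_split(values, weights)
        if split == 0:
            a = _cluster_mode(values, weights)
            short = long_ = a
        else:
            short = _cluster_mode(values[:split], weights[:split])
            long_ = _cluster_mode(values[split:], weights[split:])

    lower_bound = False
    if ev.n_in_repeat_reads > 0:
        irr_est = (math.ceil(ev.n_in_repeat_reads * ev.read_len
                             / (locus.unit_len * ev.haploid_depth))
                   + ev.read_len // locus.unit_len)
        long_ = max(long_ if long_ is not None else 0, irr_est)
        if short is None:
            short = long_  # only the long allele is observed
        lower_bound = True

    return RepeatGenotype(
        sample=sample, short_allele=int(short), long_allele=int(long_),
        long_is_lower_bound=lower_bound,
        classification=classify_allele(int(long_), locus))


def screen_cohort(genotypes: Sequence[RepeatGenotype],
                  family_of: Mapping[str, str] | Callable[[str], str]
                  ) -> ScreenSummary:
    """Screen a genotyped cohort for expansion carriers.

    Counts carrier samples and families, builds the allele histogram over
    all 2n alleles and reports the modal allele (ties broken toward the
    smaller allele).  Totals are invariant under input order.
    """
    lookup = family_of if callable(family_of) else family_of.__getitem__
    seen: set[str] = set()
    families: set[str] = set()
    carrier_families: set[str] = set()
    n_carriers = 0
    hist: Counter[int] = Counter()
    for gt in genotypes:
        if gt.sample in seen:
            raise InvalidParameterError(f"duplicate sample id {gt.sample!r}")
        seen.add(gt.sample)
        fam = lookup(gt.sample)
        families.add(fam)
        hist[gt.short_allele] += 1
        hist[gt.long_allele] += 1
        if gt.classification == EXPANDED:
            n_carriers += 1
            carrier_families.add(fam)
    modal = min(hist, key=lambda u: (-hist[u], u)) if hist else None
    n_fam = len(families)
    return ScreenSummary(
        n_samples=len(seen), n_carriers=n_carriers,
        n_carrier_families=len(carrier_families), n_families=n_fam,
        carrier_fraction_families=(len(carrier_families) / n_fam
                                   if n_fam else 0.0),
        allele_histogram=dict(sorted(hist.items())), modal_allele=modal)


def mean_depth(per_position_depths: Iterable[float],
               region: RepeatLocus | None = None) -> float:
    """Arithmetic mean read depth over the repeat region."""
    depths = np.asarray(list(per_position_depths), dtype=float)
    if depths.size == 0:
        raise InvalidParameterError("empty depth list")
    return float(depths.mean())
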