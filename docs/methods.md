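# Methods

## Screening model

A repeat allele is classified purely from its unit count against two
locus thresholds: `normal_max` (default 14) and `expansion_threshold`
(default 30). The expansion boundary is inclusive (`u ≥ 30` is
expanded); whether exactly-30 alleles belong to the pathogenic band is
genuinely ambiguous in the clinical literature for this locus, so the
boundary is a configuration field rather than a constant. Counts of
15–29 are labelled *intermediate* and never counted as carriers.

Read-evidence genotyping assumes evidence has already been summarised
into (a) a multiset of exact unit counts from spanning reads and (b) a
count of in-repeat reads (IRR), i.e. reads mapping wholly inside the
tract. Spanning counts are split by exact weighted one-dimensional
two-means over the sorted distinct counts (every split point is scored;
ties in within-cluster sum of squares are resolved so that a count
equidistant between the cluster means joins the lower cluster). Each
cluster's allele is its modal count, ties toward the smaller count. When
IRR are present the long allele becomes
`max(cluster estimate, ⌈n_irr·L/(u·d)⌉ + L/u)` with read length `L`,
unit length `u` and haploid depth `d`, and is flagged a lower bound; the
additive `L/u` term accounts for the read-length worth of repeat a
spanning-capable allele would already contain. This inverts the
simulator's IRR expectation `d·(allele_bp − L)/L` exactly in the mean,
so simulated long alleles are recovered to within Poisson noise. If
only IRR are observed, the short allele is reported equal to the long
estimate (both flagged through the lower-bound field) — with no spanning
reads nothing constrains the second allele.

Cohort screening counts expanded samples and families, builds the
histogram over all `2n` alleles and reports the modal allele (ties to the
smaller count). All totals are input-order invariant.

## Shared-block detection

Carrier expansion phases are unknown a priori. For ≤ 12 carriers every
one of the `2^c` phase assignments is scored by the resulting shared-block
length and the maximiser is kept (ties resolve to phase 0); beyond 12 a
greedy scheme seeds with the best pair from the first two carriers and
adds each carrier's better phase. On error-free simulated cohorts the
exhaustive search recovers the true expansion phases.

The block itself is defined over the cohort's site positions: among all
contiguous site intervals that span the inter-site gap containing the
repeat tract, take the one maximising `pos[b] − pos[a]` subject to every
haplotype matching the per-site consensus (majority allele, ties to REF)
with at most `max_mismatch` exceptions per haplotype (default 0 — with
phased, QC-filtered input no error tolerance is assumed). The search is
O(sites · log sites · haplotypes) using per-haplotype mismatch prefix
sums and the monotonicity of the budget in interval growth; tests check
it against a brute-force enumeration of all gap-spanning intervals. If
no interval satisfies the budget (possible on adversarial input) a
zero-length block abutting the repeat is returned rather than an error.
Block length uses the position-difference convention `end − start`,
which is how such blocks are conventionally quoted in kb.

Control sharing re-applies the same match rule to control haplotypes
over the block sites. LD r² uses the phased haplotype-count formula
`D²/(p_A(1−p_A)p_B(1−p_B))`; tag-SNP pruning is a single left-to-right
pass of the sliding-window greedy rule (window 50 sites, step 5,
removing the later member of any pair with r² > 0.5 — the defaults of
the standard pruning tools). Monomorphic sites have undefined r² and
are never pruned.

## Founder-age model

Assumptions: a star genealogy (each carrier chromosome descends
independently from the founder), a linear genetic map (default 1 cM/Mb;
no published map is assumed for the region), and recombination as the
only process eroding the shared haplotype. Under these assumptions each
side's shared genetic length is Exponential with rate g per Morgan. The
window truncates observation: a side reaching the window edge is
censored at the half-length and contributes its bound to the total
length S but not to the uncensored count k (standard censored-exponential
likelihood; the numeric maximiser of that likelihood agrees with the
closed form k/S to 6 significant digits in tests). The point estimate
uses the (k−1)/S bias correction — the MLE k/S is biased upward because
E[1/S] = rate/(k−1) for a Gamma(k) sum. The CI divides Gamma(shape k,
rate 1) quantiles by S; under the model this interval is exact, and
Monte-Carlo coverage at nominal 95% is confirmed within binomial error
in two regimes (young founder / few chromosomes, old founder / many).
With five carrier chromosomes (k = 10) the bound ratio
Q(0.975)/Q(0.025) ≈ 3.56 is data-independent.

Correlated genealogies, mutation-based dating and population-growth
corrections are out of scope; with handfuls of carrier families the
star-genealogy interval is already the dominant uncertainty.

In the pipeline, per-family physical extents are measured from the
repeat edge to the outermost consecutive site at which the family's
expansion haplotype matches the carrier consensus; a run reaching the
window edge is recorded at the full flank and therefore censored. One
haplotype per family enters the estimate (families share one founder
chromosome).

## Ancestry assignment

A nearest-centroid rule in a 16-dimensional principal-component space.
The squared Euclidean distance to each reference centroid is mapped to
an approximate F_ST by a linear scale supplied with the reference set
(the conversion is pluggable; only its monotonicity and the decision
rule matter here). Assignment requires the minimal F_ST to be *strictly*
below 0.002 — the boundary case is left unassigned, recording the
ambiguity of a rule stated both as "< 0.002 assigns" and "> 0.002 does
not". Argmin ties break lexicographically by group label. The rule is
invariant under rigid rotations applied jointly to samples and
centroids, and lowering the threshold can only unassign.

## Optical sizing

Unit counts are `⌊delta / unit_len⌋` where delta is molecule size minus
the reference inter-marker distance (default 7990 bp for the assayed
region). Floor rounding is deliberate: a partial repeat unit is not a
full unit. Negative deltas are clipped to zero with a warning. The
delta dialect is primary (the plotted axis in optical-map reports is the
already-subtracted difference); raw molecule sizes are accepted through
a constructor that subtracts the reference distance. Somatic
instability is summarised as max/median of the deltas.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: one
founder haplotype; per-site alt-allele frequencies uniform in
[0.05, 0.5]; background haplotypes drawn per-site independently (no
background LD — block detection is IBS-based and does not require it);
carrier expansion haplotypes copying the founder inside an ancestral
segment drawn from the decay model and background elsewhere; family
members sharing the index carrier's expansion haplotype in full.
Non-expanded repeat alleles are drawn from a triangular distribution
over 3–14 units with weights ∝ 7 − |u − 9|, giving a strict mode at 9
(a symmetric triangle would tie 8 and 9); expanded alleles are uniform
over 650–2500 units. Default cohort shape: five carrier families with
sizes (2, 2, 1, 1, 1) — seven carriers — and 7506 controls, a founder
age of 31.7 generations, a ±1 Mb window and 400 sites.

Read evidence and optical molecules are generated per the genotyping and
sizing models above (Poisson read counts; normal molecule deltas with
standard deviation `cv × mean`, truncated at zero). One root seed feeds
per-operation child streams (`numpy.random.SeedSequence`), so any stage
re-run in isolation reproduces its output and a fixed seed makes the
whole pipeline byte-identical.

What the generator does *not* emulate — background LD, realistic read
sequences, genotyping error structure beyond i.i.d. flips, demographic
history beyond the single founder event — bounds what passing tests
show: they validate the inference machinery under its own model, not its
robustness to real-data artefacts.

## Problem sizes in the test suite

Unit and property tests run cohorts of tens of samples over 50–200
sites, which already exercise every code path including censoring;
coverage simulations use 400–500 replicates (binomial error ±1% at
n = 500 against a ±3% acceptance band); oracle comparisons use 200
random instances of ≤ 6 haplotypes × 40 sites. The full suite runs in a
few seconds on one CPU.
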