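# strhaplo

Repeat-expansion screening and founder-haplotype analysis around a short
tandem repeat locus, with a synthetic-cohort generator for end-to-end
validation.

The package targets the analysis pattern used for intronic repeat
expansions such as the GGCCTG hexanucleotide in *NOP56*
(chr20:2,652,733–2,652,775, GRCh38), whose expansion causes
spinocerebellar ataxia type 36: screen a sequenced cohort for expanded
alleles, show that carriers share a haplotype around the repeat (a founder
effect), date the founder event, and size the expansion with orthogonal
optical-map data. It is written for statistical geneticists who have
phased genotypes around a repeat locus plus per-sample repeat-genotype
evidence, and who want the downstream inference reproducible and tested.

## What it computes

**Screening.** An allele with `u` repeat units is *normal* if
`u ≤ 14`, *expanded* if `u ≥ 30`, *intermediate* otherwise (both bounds
configurable on `RepeatLocus`). Repeat length is genotyped from
summarised read evidence: spanning reads give exact unit counts, split
into ≤ 2 clusters by exact 1-D two-means; in-repeat reads (reads wholly
inside the tract) yield a lower bound
`⌈n_irr · L / (6 · d)⌉ + L/6` on the long allele, with read length `L`
and haploid depth `d`.

**Shared block.** For the carriers' expansion-bearing haplotypes (phase
chosen to maximise the locus-spanning shared run), the shared block is
the maximal contiguous site interval containing the inter-site gap at the
repeat on which every haplotype matches the consensus (with an optional
per-haplotype mismatch budget). Block length is `end − start` in bp.
Control haplotypes matching the consensus quantify how permissive the
background haplotype is. Tagging SNPs come from sliding-window greedy
r² pruning (50 sites / step 5 / r² > 0.5).

**Founder age.** Each carrier chromosome's shared segment extends left
and right of the repeat by independent Exponential(g) genetic lengths
(Morgans), where g is the age in generations. With `k` uncensored sides
and total length `S` (censored sides contribute their window bound to `S`
but not to `k`), the estimator is

```
ĝ = (k − 1) / S        (bias-corrected; MLE is k/S)
CI = [ Q_Γ(α/2; k) / S ,  Q_Γ(1−α/2; k) / S ]      (shape k, rate 1)
```

**Ancestry.** A thresholded nearest-centroid classifier in a 16-dim PC
space: squared Euclidean distance to each reference-group centroid is
converted to an approximate F_ST by a linear scale, and a sample is
assigned to the nearest group only when F_ST < 0.002 (strict), otherwise
left unassigned.

**Optical sizing.** Repeat units per molecule are
`⌊(molecule size − reference distance) / 6⌋`; the spread across molecules
(max/median ratio) summarises somatic instability.

## Worked example

```python
from strhaplo import AncestralSegment, estimate_age

S = 9 / 31.7  # total shared genetic length, Morgans, over 10 sides
segs = [AncestralSegment(S / 10, S / 10) for _ in range(5)]
est = estimate_age(segs, alpha=0.05)
print(f"g_hat = {est.g_hat:.1f}, 95% CI = ({est.ci_low:.1f}, {est.ci_high:.0f})")
```

prints

```
g_hat = 31.7, 95% CI = (16.9, 60)
```

i.e. five carrier chromosomes whose shared-segment sides total
S ≈ 0.284 Morgans date the founder expansion to roughly 32 generations
ago, with a 95% interval of about 17–60 generations.

A full synthetic run from the shell:

```bash
strhaplo run-all --out-dir out --seed 7
cat out/run_report.json
```

simulates a cohort (five carrier families on one founder haplotype,
7506 controls), genotypes and screens it, finds the carrier-shared block,
dates the founder event, summarises optical molecules and assigns
ancestry; `run_report.json` carries the seed, a config digest and the
headline numbers (carrier families, block coordinates and length, ĝ with
CI). Reruns with the same config and seed are byte-identical.

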