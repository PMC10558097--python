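"""Readers and writers for the pipeline's file formats.

Phased genotypes travel as plain-text VCFv4.2 with GT-only FORMAT and "|"
phase separators; tables (repeat genotypes, read evidence, optical
molecules, reference centroids) are TSV with documented headers.  Reading
VCF goes through cyvcf2; records that are multi-allelic, non-SNV, missing
or unphased in any requested sample are dropped and counted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .loci import InvalidParameterError
from .simulate import OpticalMoleculeSet, PhasedCohort, ReadEvidence

log = logging.getLogger("strhaplo")


def write_phased_vcf(path, cohort: PhasedCohort) -> None:
    """Write a cohort as minimal VCFv4.2 (GT-only, phased)."""
    path = Path(path)
    n = cohort.n_samples
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cohort.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples["sample"]) + "\n")
        mat = cohort.hap_matrix
        for i, pos in enumerate(cohort.positions):
            gts = "\t".join(
                f"{mat[i, 2 * s]}|{mat[i, 2 * s + 1]}" for s in range(n))
            fh.write(f"{cohort.chrom}\t{pos}\t.\t{cohort.ref[i]}\t"
                     f"{cohort.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path, samples: pd.DataFrame | None = None) -> PhasedCohort:
    """Read a phased VCF into a PhasedCohort.

    ``samples`` optionally supplies metadata (sample, family, is_case,
    is_carrier); missing metadata defaults to one family per sample and no
    carriers.  Sites dropped for being multi-allelic, non-SNV, missing or
    unphased are counted in the log.
    """
    path = str(path)
    vcf = VCF(path)
    names = list(vcf.samples)
    positions, ref, alt, rows = [], [], [], []
    n_dropped = 0
    for var in vcf:
        if (len(var.ALT) != 1 or len(var.REF) != 1
                or len(var.ALT[0]) != 1):
            n_dropped += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        if any(g[0] < 0 or g[1] < 0 or not g[2] for g in gts):
            n_dropped += 1
            continue
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append([a for g in gts for a in (g[0], g[1])])
    vcf.close()
    if n_dropped:
        log.info("read_phased_vcf: dropped %d site(s) "
                 "(multi-allelic/missing/unphased)", n_dropped)
    if not positions:
        raise InvalidParameterError(f"no usable phased sites in {path}")
    if samples is None:
        samples = pd.DataFrame({
            "sample": names, "family": names,
            "is_case": False, "is_carrier": False})
    return PhasedCohort(
        chrom=VCF(path).seqnames[0] if VCF(path).seqnames else "chr?",
        positions=np.asarray(positions),
        ref=ref, alt=alt,
        hap_matrix=np.asarray(rows, dtype=np.int8),
        samples=samples.reset_index(drop=True))


# ---------------------------------------------------------------- tables

GENOTYPE_COLS = ["sample", "family", "short_allele", "long_allele",
                 "long_is_lower_bound", "classification"]


def write_genotype_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENOTYPE_COLS[:4]) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"genotype table lacks columns {missing}")
    return df


def encode_spanning(counts: dict[int, int]) -> str:
    return ";".join(f"{u}:{c}" for u, c in sorted(counts.items())) or "."


def decode_spanning(text: str) -> dict[int, int]:
    if not text or text == ".":
        return {}
    return {int(u): int(c) for u, c in
            (tok.split(":") for tok in text.split(";"))}


def write_evidence_table(path, evidence: dict[str, ReadEvidence]) -> None:
    rows = [dict(sample=s, spanning=encode_spanning(ev.spanning_counts),
                 n_in_repeat=ev.n_in_repeat_reads, read_len=ev.read_len,
                 haploid_depth=ev.haploid_depth)
            for s, ev in evidence.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_evidence_table(path) -> dict[str, ReadEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"spanning": str})
    return {row["sample"]: ReadEvidence(
                spanning_counts=decode_spanning(row["spanning"]),
                n_in_repeat_reads=int(row["n_in_repeat"]),
                read_len=int(row["read_len"]),
                haploid_depth=float(row["haploid_depth"]))
            for _, row in df.iterrows()}


def write_molecule_table(path, mset: OpticalMoleculeSet) -> None:
    pd.DataFrame({"delta_bp": np.asarray(mset.deltas)}).to_csv(
        path, sep="\t", index=False)


def read_molecule_table(path, reference_distance: int = 7990,
                        unit_len: int = 6,
                        raw_sizes: bool = False) -> OpticalMoleculeSet:
    """Read molecule deltas; with ``raw_sizes`` the column holds raw
    molecule sizes and the reference distance is subtracted on read."""
    df = pd.read_csv(path, sep="\t")
    col = df.columns[0]
    vals = df[col].to_numpy(dtype=float)
    if raw_sizes:
        return OpticalMoleculeSet.from_raw_sizes(vals, reference_distance,
                                                 unit_len)
    return OpticalMoleculeSet(vals, reference_distance, unit_len)


def read_centroid_table(path) -> tuple[list[str], np.ndarray]:
    """Centroid TSV: first column group label, rest coordinates."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:].to_numpy(float)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
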