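"""Pipeline orchestration: simulate → genotype → share → age → optical → ancestry.

Each stage reads and writes plain-text artifacts (VCF/TSV/JSON) in the
output directory and contributes headline numbers to a machine-readable
run report (``run_report.json``).  Runs are deterministic: the report
contains the seed and a digest of the resolved configuration, and a rerun
with the same (config, seed) produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age import FounderAgeEstimator, segments_from_block
from .ancestry import AncestryClassifier
from .genotyping import (RepeatGenotype, classify_allele, genotype_from_reads,
                         screen_cohort)
from .loci import InvalidParameterError, RepeatLocus
from .optical import summarize_molecules
from .sharing import (SharedBlock, control_block_sharing, find_shared_block,
                      pairwise_sharing, select_carrier_haplotypes, tag_snps)
from .simulate import (SimConfig, simulate_ancestry_coords, simulate_cohort,
                       simulate_optical_molecules, simulate_read_evidence)
from . import vcfio

log = logging.getLogger("strhaplo")

REPORT_NAME = "run_report.json"


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run.

    File inputs override simulation: when ``vcf`` / ``genotype_table`` /
    ``evidence_table`` / ``molecule_table`` paths are given those stages
    consume them instead of simulated artifacts.
    """

    out_dir: str = "strhaplo_out"
    seed: int = 0
    # locus & window
    chrom: str = "chr20"
    region_start: int = 2_652_733
    region_end: int = 2_652_775
    unit: str = "GGCCTG"
    expansion_threshold: int = 30
    normal_max: int = 14
    window_flank_bp: int = 1_000_000
    recomb_rate_cm_per_mb: float = 1.0
    # simulation
    simulate: bool = True
    n_carrier_families: int = 5
    family_sizes: tuple[int, ...] | None = (2, 2, 1, 1, 1)
    n_controls: int = 7506
    g_true: float = 31.7
    n_sites: int = 400
    genotype_error_rate: float = 0.0
    read_len: int = 150
    haploid_depth: float = 15.0
    n_molecules: int = 200
    mosaic_cv: float = 0.5
    # thresholds
    max_mismatch: int = 0
    alpha: float = 0.05
    fst_threshold: float = 0.002
    fst_scale: float = 1.0
    r2_threshold: float = 0.5
    tag_window_sites: int = 50
    tag_step_sites: int = 5
    # optional file inputs
    vcf: str | None = None
    genotype_table: str | None = None
    evidence_table: str | None = None
    molecule_table: str | None = None
    centroid_table: str | None = None
    coords_table: str | None = None
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "genotype", "share", "age",
                               "optical", "ancestry")

    @property
    def locus(self) -> RepeatLocus:
        return RepeatLocus(chrom=self.chrom, region_start=self.region_start,
                           region_end=self.region_end, unit=self.unit,
                           expansion_threshold=self.expansion_threshold,
                           normal_max=self.normal_max)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=self.seed, n_carrier_families=self.n_carrier_families,
            n_controls=self.n_controls, g_true=self.g_true,
            locus=self.locus, window_flank_bp=self.window_flank_bp,
            recomb_rate_cm_per_mb=self.recomb_rate_cm_per_mb,
            n_sites=self.n_sites,
            genotype_error_rate=self.genotype_error_rate,
            family_sizes=(tuple(self.family_sizes)
                          if self.family_sizes is not None else None))

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {unknown}")
        if "family_sizes" in data and data["family_sizes"] is not None:
            data["family_sizes"] = tuple(data["family_sizes"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def digest(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _genotype_row(gt: RepeatGenotype, family: str) -> dict:
    return dict(sample=gt.sample, family=family,
                short_allele=gt.short_allele, long_allele=gt.long_allele,
                long_is_lower_bound=gt.long_is_lower_bound,
                classification=gt.classification)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the run report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    locus = cfg.locus
    report: dict = {
        "version": __version__, "seed": cfg.seed,
        "config_digest": cfg.digest(), "stages_run": [],
    }
    sim = None
    cohort = None
    geno_df = None

    def stage(name: str) -> bool:
        return name in cfg.stages

    try:
        if stage("simulate") and cfg.simulate and cfg.vcf is None:
            sim = simulate_cohort(cfg.sim_config())
            cohort = sim.cohort
            vcfio.write_phased_vcf(out / "cohort.vcf", cohort)
            sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            evidence = {
                row["sample"]: simulate_read_evidence(
                    (row["allele_short"], row["allele_long"]),
                    depth=cfg.haploid_depth, read_len=cfg.read_len,
                    rng_seed=cfg.seed * 100_003 + i,
                    unit_len=locus.unit_len)
                for i, row in sim.truth.iterrows()}
            vcfio.write_evidence_table(out / "evidence.tsv", evidence)
            carriers = sim.truth[sim.truth["is_carrier"]]
            if len(carriers):
                mset = simulate_optical_molecules(
                    int(carriers.iloc[0]["allele_long"]),
                    n_molecules=cfg.n_molecules, mosaic_cv=cfg.mosaic_cv,
                    rng_seed=cfg.seed, unit_len=locus.unit_len)
                vcfio.write_molecule_table(out / "molecules.tsv", mset)
            report["stages_run"].append("simulate")
            report["n_samples_simulated"] = int(len(sim.truth))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"simulate: {exc}") from exc

    try:
        if stage("genotype"):
            if cfg.genotype_table is not None:
                geno_df = vcfio.read_genotype_table(cfg.genotype_table)
                if "classification" not in geno_df.columns:
                    geno_df["classification"] = [
                        classify_allele(int(u), locus)
                        for u in geno_df["long_allele"]]
                if "long_is_lower_bound" not in geno_df.columns:
                    geno_df["long_is_lower_bound"] = False
                genotypes = [RepeatGenotype(
                    sample=str(r["sample"]),
                    short_allele=int(r["short_allele"]),
                    long_allele=int(r["long_allele"]),
                    long_is_lower_bound=bool(r["long_is_lower_bound"]),
                    classification=str(r["classification"]))
                    for _, r in geno_df.iterrows()]
                fam = dict(zip(geno_df["sample"].astype(str),
                               geno_df["family"].astype(str)))
            else:
                ev_path = (cfg.evidence_table if cfg.evidence_table
                           else out / "evidence.tsv")
                evidence = vcfio.read_evidence_table(ev_path)
                fam_src = (dict(zip(sim.truth["sample"],
                                    sim.truth["family"]))
                           if sim is not None else {s: s for s in evidence})
                genotypes = [genotype_from_reads(ev, locus, sample=s)
                             for s, ev in evidence.items()]
                fam = fam_src
                geno_df = pd.DataFrame(
                    [_genotype_row(g, fam[g.sample]) for g in genotypes])
                if sim is not None:
                    geno_df["is_case"] = geno_df["sample"].map(
                        dict(zip(sim.truth["sample"], sim.truth["is_case"])))
            vcfio.write_genotype_table(out / "genotypes.tsv", geno_df)
            summary = screen_cohort(genotypes, fam)
            pd.DataFrame(
                {"units": list(summary.allele_histogram),
                 "count": list(summary.allele_histogram.values())}
            ).to_csv(out / "allele_histogram.tsv", sep="\t", index=False)
            vcfio.write_json(out / "screen_summary.json", dict(
                n_samples=summary.n_samples,
                n_carriers=summary.n_carriers,
                n_carrier_families=summary.n_carrier_families,
                n_families=summary.n_families,
                carrier_fraction_families=summary.carrier_fraction_families,
                modal_allele=summary.modal_allele))
            report["stages_run"].append("genotype")
            report["n_screened"] = summary.n_samples
            report["n_carriers"] = summary.n_carriers
            report["n_carrier_families"] = summary.n_carrier_families
            report["carrier_fraction_families"] = (
                summary.carrier_fraction_families)
            report["modal_allele"] = summary.modal_allele
            if "is_case" in geno_df.columns:
                n_cases = int(geno_df["is_case"].sum())
                report["n_cases"] = n_cases
                report["n_controls"] = summary.n_samples - n_cases
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        _write_report(out, report)
        raise StageError(f"genotype: {exc}") from exc

    block: SharedBlock | None = None
    sel_cols = None
    try:
        if stage("share"):
            if cohort is None:
                vcf_path = cfg.vcf if cfg.vcf else out / "cohort.vcf"
                meta = None
                if geno_df is not None:
                    meta = pd.DataFrame({
                        "sample": geno_df["sample"].astype(str),
                        "family": geno_df["family"].astype(str),
                        "is_case": True,
                        "is_carrier": geno_df["classification"] == "expanded",
                    })
                cohort = vcfio.read_phased_vcf(vcf_path, samples=meta)
            elif geno_df is not None:
                carrier_map = dict(zip(
                    geno_df["sample"].astype(str),
                    geno_df["classification"] == "expanded"))
                cohort.samples["is_carrier"] = [
                    bool(carrier_map.get(s, False))
                    for s in cohort.samples["sample"]]
            sel_cols, sel_haps = select_carrier_haplotypes(
                cohort, locus, cfg.max_mismatch)
            carrier_idx = np.flatnonzero(
                cohort.samples["is_carrier"].to_numpy())
            member_ids = [
                f"{cohort.samples['sample'].iloc[i]}/h{c % 2}"
                for i, c in zip(carrier_idx, sel_cols)]
            block = find_shared_block(sel_haps, cohort.positions, locus,
                                      cfg.max_mismatch, member_ids)
            control_cols = [c for s in np.flatnonzero(
                ~cohort.samples["is_carrier"].to_numpy())
                for c in (2 * s, 2 * s + 1)]
            n_match, frac = control_block_sharing(
                block, cohort.haplotypes(control_cols)) \
                if control_cols else (0, 0.0)
            block.n_controls_matching, block.control_match_fraction = (
                n_match, frac)
            share = pairwise_sharing(sel_haps)
            pd.DataFrame(share, index=member_ids, columns=member_ids).to_csv(
                out / "sharing_matrix.tsv", sep="\t")
            a, b = block.site_slice
            retained = tag_snps(sel_haps[:, a:b], cfg.tag_window_sites,
                                cfg.tag_step_sites, cfg.r2_threshold) \
                if b > a else []
            pd.DataFrame({"position": cohort.positions[a:b][retained]}
                         ).to_csv(out / "tag_snps.tsv", sep="\t",
                                  index=False)
            vcfio.write_json(out / "shared_block.json", dict(
                chrom=locus.chrom,
                start=(block.window.start if block.window else None),
                end=(block.window.end if block.window else None),
                length_bp=block.length_bp,
                members=block.member_ids,
                consensus="".join(str(x) for x in block.consensus),
                n_controls_matching=block.n_controls_matching,
                control_match_fraction=block.control_match_fraction))
            report["stages_run"].append("share")
            report["block_start"] = (block.window.start if block.window
                                     else None)
            report["block_end"] = block.window.end if block.window else None
            report["block_length_bp"] = block.length_bp
            report["n_controls_matching_block"] = block.n_controls_matching
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        _write_report(out, report)
        raise StageError(f"share: {exc}") from exc

    try:
        if stage("age") and cohort is not None and sel_cols is not None:
            extents = _family_extents(cohort, sel_cols, locus,
                                      cfg.window_flank_bp)
            segs = segments_from_block(
                extents, cfg.recomb_rate_cm_per_mb, cfg.window_flank_bp)
            est = FounderAgeEstimator(alpha=cfg.alpha).fit(segs).estimate_
            vcfio.write_json(out / "age_estimate.json", dict(
                g_hat=est.g_hat, ci_low=est.ci_low, ci_high=est.ci_high,
                alpha=est.alpha, n_chrom=est.n_chrom,
                n_observed_sides=est.n_observed_sides,
                total_length_morgans=est.total_length))
            report["stages_run"].append("age")
            report["g_hat"] = est.g_hat
            report["g_ci"] = [est.ci_low, est.ci_high]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        _write_report(out, report)
        raise StageError(f"age: {exc}") from exc

    try:
        if stage("optical"):
            mol_path = (cfg.molecule_table if cfg.molecule_table
                        else out / "molecules.tsv")
            if Path(mol_path).exists():
                mset = vcfio.read_molecule_table(mol_path,
                                                 unit_len=locus.unit_len)
                osum = summarize_molecules(mset)
                vcfio.write_json(out / "optical_summary.json", dict(
                    n_molecules=osum.n_molecules,
                    mean_delta=osum.mean_delta,
                    median_delta=osum.median_delta,
                    min_delta=osum.min_delta, max_delta=osum.max_delta,
                    instability_ratio=osum.instability_ratio))
                report["stages_run"].append("optical")
                report["optical_mean_delta"] = osum.mean_delta
                report["optical_median_delta"] = osum.median_delta
    except Exception as exc:  # noqa: BLE001
        _write_report(out, report)
        raise StageError(f"optical: {exc}") from exc

    try:
        if stage("ancestry"):
            if cfg.centroid_table and cfg.coords_table:
                labels, centroids = vcfio.read_centroid_table(
                    cfg.centroid_table)
                coords_df = pd.read_csv(cfg.coords_table, sep="\t")
                sample_ids = coords_df.iloc[:, 0].astype(str).tolist()
                coords = coords_df.iloc[:, 1:].to_numpy(float)
            else:
                labels, centroids, coords, _ = simulate_ancestry_coords(
                    n_groups=21, n_samples=(len(cohort.samples)
                                            if cohort is not None else 10),
                    dim=16, rng_seed=cfg.seed)
                sample_ids = (list(cohort.samples["sample"])
                              if cohort is not None
                              else [f"S{i}" for i in range(len(coords))])
            clf = AncestryClassifier(threshold=cfg.fst_threshold,
                                     scale=cfg.fst_scale)
            clf.fit(centroids, labels)
            fst = clf.predict_fst(coords)
            best = fst.argmin(axis=1)
            pd.DataFrame({
                "sample": sample_ids,
                "best_group": clf.classes_[best],
                "fst": fst[np.arange(len(best)), best],
                "assigned": clf.predict(coords),
            }).to_csv(out / "ancestry.tsv", sep="\t", index=False)
            report["stages_run"].append("ancestry")
            report["n_unassigned"] = int(
                (clf.predict(coords) == "unassigned").sum())
    except Exception as exc:  # noqa: BLE001
        _write_report(out, report)
        raise StageError(f"ancestry: {exc}") from exc

    _write_report(out, report)
    return report


def _family_extents(cohort, sel_cols, locus,
                    flank_bp: int) -> list[tuple[float, float]]:
    """Physical shared extents of each carrier family's expansion haplotype.

    Uses one haplotype per family (founders are unrelated); the extent on
    each side runs from the repeat edge to the outermost consecutive site
    matching the carrier consensus.  A run reaching the end of the window
    is reported at the full window flank, which the downstream conversion
    flags as censored.
    """
    from .sharing import _consensus, _locus_gap

    carrier_idx = np.flatnonzero(cohort.samples["is_carrier"].to_numpy())
    fams = cohort.samples["family"].iloc[carrier_idx].to_numpy()
    _, first_of_family = np.unique(fams, return_index=True)
    haps = cohort.haplotypes(sel_cols)
    cons = _consensus(haps)
    gap_l, gap_r = _locus_gap(cohort.positions, locus)
    extents = []
    n = len(cohort.positions)
    for fi in sorted(first_of_family):
        hap = haps[fi]
        j = gap_l
        while j >= 0 and hap[j] == cons[j]:
            j -= 1
        if j < 0:
            left = float(flank_bp)  # run reaches the window edge
        elif j + 1 <= gap_l:
            left = float(locus.region_start - cohort.positions[j + 1])
        else:
            left = 0.0
        k = gap_r
        while k < n and hap[k] == cons[k]:
            k += 1
        if k >= n:
            right = float(flank_bp)
        elif k - 1 >= gap_r:
            right = float(cohort.positions[k - 1] - locus.region_end)
        else:
            right = 0.0
        extents.append((min(max(left, 0.0), flank_bp),
                        min(max(right, 0.0), flank_bp)))
    return extents


def _write_report(out: Path, report: dict) -> None:
    vcfio.write_json(out / REPORT_NAME, report)
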