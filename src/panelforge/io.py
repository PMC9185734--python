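"""File formats, run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    QUALITY_TIERS,
)

logger = logging.getLogger("panelforge")

__all__ = ["VcfImport", "read_vcf", "RunConfig", "run_pipeline"]


# ---------------------------------------------------------------------------
# VCF import
# ---------------------------------------------------------------------------

@dataclass
class VcfImport:
    genotypes: GenotypeMatrix
    frequencies: AlleleFrequencyTable
    n_skipped: int


def read_vcf(path: str | Path) -> VcfImport:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    Multi-allelic and indel records are skipped (the count is logged and
    returned).  Dosage counts the ALT allele; frequencies are computed from
    called genotypes only, with missing './.' honored.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from None
    samples = list(vcf.samples)
    dosages, locus_ids, alleles = [], [], []
    n_skipped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    lut = np.array([0, 1, MISSING, 2], dtype=np.int16)
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            n_skipped += 1
            continue
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        alleles.append({"allele1": rec.REF, "allele2": rec.ALT[0]})
        dosages.append(lut[rec.gt_types])
    if not locus_ids:
        raise ValueError(f"no usable records in {path}")
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    dosage = np.stack(dosages, axis=1)
    allele_df = pd.DataFrame(alleles, index=pd.Index(locus_ids, name="locus_id"))
    gm = GenotypeMatrix(dosage, samples, locus_ids, allele_df)
    return VcfImport(genotypes=gm, frequencies=gm.allele_frequencies(),
                     n_skipped=n_skipped)


def stratified_frequencies(gm: GenotypeMatrix, strata: pd.Series) -> AlleleFrequencyTable:
    """Allele frequencies overall plus one column per stratum (e.g. per sex)."""
    base = gm.allele_frequencies().table[["p_allele2"]].copy()
    strata = strata.loc[gm.sample_ids]
    for value in sorted(strata.dropna().unique()):
        sub = gm.subset_samples([s for s, v in strata.items() if v == value])
        base[str(value)] = sub.allele_frequencies().table["p_allele2"]
    return AlleleFrequencyTable(base)


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters for a fully synthetic end-to-end run.

    Every random stage derives its seed from ``seed``; re-running an
    identical config reproduces identical outputs byte-for-byte.
    """

    seed: int = 1
    n_loci: int = 40
    maf_bin: str = "high"
    n_samples: int = 12
    tier: str = "tissue"
    read_length: int = 75
    min_depth: int = 10
    max_missing_sample: float = 0.5
    max_missing_locus: float = 0.5
    match_tolerance: float = 0.02
    min_overlap: int = 20
    identity_threshold: float = 0.007

    def validate(self) -> None:
        if self.n_loci < 1 or self.n_samples < 1:
            raise ValueError("n_loci and n_samples must be >= 1")
        if self.tier not in QUALITY_TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; valid: {sorted(QUALITY_TIERS)}")
        if self.min_overlap > self.n_loci:
            raise ValueError("min_overlap cannot exceed n_loci")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Chain simulate -> design -> genotype -> qc -> forensics on synthetic data.

    Writes all stage outputs plus a provenance manifest (config, seeds,
    package version, output checksums) into ``outdir`` and returns the path.
    """
    from . import design, forensics, qc, synthetic
    from .genotyper import call_genotypes, count_alleles, reports_to_matrix

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(("freqs", "genotypes", "panel", "reads"), ss.spawn(4))}

    logger.info("pipeline: simulating %d %s-MAF loci", config.n_loci, config.maf_bin)
    freqs = synthetic.draw_frequency_spectrum(config.n_loci, config.maf_bin, seeds["freqs"])
    freqs.to_tsv(outdir / "frequencies.tsv")

    truth = synthetic.simulate_population_genotypes(freqs, config.n_samples,
                                                    seeds["genotypes"])
    truth.to_tsv(outdir / "true_genotypes.tsv")

    panel = synthetic.synthetic_panel(freqs.locus_ids, seeds["panel"])
    panel.to_tsv(outdir / "panel.tsv")

    tier = QUALITY_TIERS[config.tier]
    sim = synthetic.simulate_amplicon_reads(panel, truth, tier, seeds["reads"],
                                            read_length=config.read_length)
    fastq_dir = outdir / "reads"
    sim.write_fastq(fastq_dir)

    logger.info("pipeline: genotyping %d samples", config.n_samples)
    reports = [call_genotypes(count_alleles(sim.reads[s], panel, sample_id=s),
                              min_depth=config.min_depth)
               for s in truth.sample_ids]
    called = reports_to_matrix(reports, panel)
    called.to_tsv(outdir / "called_genotypes.tsv")

    filtered, dropped_samples = qc.filter_samples(called, config.max_missing_sample)
    filtered, dropped_loci = qc.filter_loci(filtered, config.max_missing_locus)
    filtered.to_tsv(outdir / "filtered_genotypes.tsv")
    success = qc.genotyping_success(filtered)

    curve = design.identity_power_curve(freqs, config.identity_threshold)
    curve.curve.to_csv(outdir / "identity_power.tsv", sep="\t", index=False)

    clusters = forensics.cluster_individuals(filtered, config.match_tolerance,
                                             config.min_overlap)
    individuals, _ = forensics.mark_recapture_summary(clusters)
    individuals.to_csv(outdir / "individuals.tsv", sep="\t", index=False)

    kin = forensics.loiselle_kinship(filtered)
    kin.to_tsv(outdir / "kinship.tsv")

    config.to_yaml(outdir / "config.yaml")
    outputs = sorted(p for p in outdir.glob("*.tsv"))
    manifest = {
        "panelforge_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "dropped_samples": dropped_samples,
        "dropped_loci": dropped_loci,
        "genotyping_success": {k: float(v) for k, v in success.items()},
        "min_panel_size_p_id": curve.min_n_id,
        "min_panel_size_p_idsib": curve.min_n_idsib,
        "n_unique_individuals": clusters.n_unique,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
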