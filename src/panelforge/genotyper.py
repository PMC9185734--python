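"""Amplicon-read genotyping and panel-health diagnostics.

The caller follows the exact-substring convention of multiplexed-amplicon
genotypers: a read belongs to a locus iff it contains that locus's forward
primer, and supports an allele iff it also contains the corresponding
allele probe.  Genotypes come from the allele-count ratio
``count_a1 / max(count_a2, 0.1)``: homozygous when the ratio is extreme
(>= 10 one way, <= 0.1 the other), heterozygous inside a central band
(default [0.2, 5]), missing when the depth gate fails or the ratio falls in
the ambiguous gaps.

Panel health is assessed two ways: per-primer read shares (overrepresented
primers hog sequencing effort) and a primer-interaction scan that counts
reads carrying two or more panel primers (in either orientation) but no
allele probe — the signature of primer dimers and PCR artifacts.  These
diagnostics flag loci; dropping them is a panel-curation decision left to
the user.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import MISSING, AmpliconPanel, GenotypeMatrix, revcomp

__all__ = [
    "read_fastq",
    "GenotypeCallReport",
    "PanelHealthReport",
    "count_alleles",
    "call_genotypes",
    "merge_technical_runs",
    "primer_overrepresentation",
    "primer_interaction_scan",
    "reports_to_matrix",
]

CALL_CODES = {"hom1": 0, "het": 1, "hom2": 2, "missing": MISSING}

#: Ratio-caller defaults (configurable in :func:`call_genotypes`).
DEFAULT_MIN_DEPTH = 10
DEFAULT_HOM_RATIO = 10.0
DEFAULT_HET_BAND = (0.2, 5.0)
RATIO_FLOOR = 0.1  # denominator floor: count_a2 == 0 gives ratio 10 * count_a1


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a (optionally gzipped) 4-line FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from None


def _as_sequences(reads) -> list[str]:
    if isinstance(reads, (str, Path)):
        return read_fastq(reads)
    return list(reads)


@dataclass
class GenotypeCallReport:
    """Per-locus allele counts (and, once called, genotypes) for one sample.

    ``per_locus`` columns: count_a1, count_a2, depth (reads matching the
    primer and either probe), primer_reads (reads matching the primer at
    all), ratio, call.  ``on_target_fraction`` is the share of reads
    containing a primer together with one of that locus's probes.
    """

    sample_id: str
    per_locus: pd.DataFrame
    total_reads: int
    on_target_fraction: float
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.per_locus.to_csv(path, sep="\t")


@dataclass
class PanelHealthReport:
    primer_fractions: pd.Series
    flagged_primers: list[str]
    pair_fractions: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)
    artifact_fraction: float = 0.0
    total_reads: int = 0


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------

def count_alleles(reads, panel: AmpliconPanel,
                  sample_id: str = "sample") -> GenotypeCallReport:
    """Count allele-probe matches per locus for one sample's read set.

    ``reads`` may be a FASTQ path or an iterable of sequences.  A read is
    assigned to every locus whose forward primer it contains; allele counts
    require the respective probe as well.  Reads matching a primer but no
    probe contribute to ``primer_reads`` only.
    """
    seqs = _as_sequences(reads)
    ids = panel.locus_ids
    count_a1 = np.zeros(len(ids), dtype=np.int64)
    count_a2 = np.zeros(len(ids), dtype=np.int64)
    primer_reads = np.zeros(len(ids), dtype=np.int64)
    primers = [panel.primer(l) for l in ids]
    probes = [panel.probes(l) for l in ids]

    n_on_target = 0
    for seq in seqs:
        on_target = False
        for j, primer in enumerate(primers):
            if primer in seq:
                primer_reads[j] += 1
                p1, p2 = probes[j]
                if p1 in seq:
                    count_a1[j] += 1
                    on_target = True
                elif p2 in seq:
                    count_a2[j] += 1
                    on_target = True
        if on_target:
            n_on_target += 1

    per_locus = pd.DataFrame({
        "count_a1": count_a1, "count_a2": count_a2,
        "depth": count_a1 + count_a2, "primer_reads": primer_reads,
    }, index=pd.Index(ids, name="locus_id"))
    on_frac = n_on_target / len(seqs) if seqs else 0.0
    return GenotypeCallReport(sample_id=sample_id, per_locus=per_locus,
                              total_reads=len(seqs), on_target_fraction=on_frac)


# ---------------------------------------------------------------------------
# Ratio-based genotype calling
# ---------------------------------------------------------------------------

def call_genotypes(report: GenotypeCallReport,
                   min_depth: int = DEFAULT_MIN_DEPTH,
                   hom_ratio: float = DEFAULT_HOM_RATIO,
                   het_band: tuple[float, float] = DEFAULT_HET_BAND) -> GenotypeCallReport:
    """Apply the allele-ratio caller to a counts report (returns a new report).

    ratio = count_a1 / max(count_a2, 0.1); hom1 if ratio >= hom_ratio,
    hom2 if ratio <= 1/hom_ratio, het inside ``het_band``, otherwise (or
    when depth < min_depth) missing.
    """
    df = report.per_locus.copy()
    a1 = df["count_a1"].to_numpy(dtype=float)
    a2 = df["count_a2"].to_numpy(dtype=float)
    ratio = a1 / np.maximum(a2, RATIO_FLOOR)
    depth = a1 + a2

    call = np.full(len(df), "missing", dtype=object)
    lo, hi = het_band
    call[ratio >= hom_ratio] = "hom1"
    call[ratio <= 1.0 / hom_ratio] = "hom2"
    call[(ratio >= lo) & (ratio <= hi)] = "het"
    call[depth < min_depth] = "missing"

    df["ratio"] = ratio
    df["call"] = call
    params = dict(report.params, min_depth=min_depth, hom_ratio=hom_ratio,
                  het_band=het_band, ratio_floor=RATIO_FLOOR)
    return GenotypeCallReport(sample_id=report.sample_id, per_locus=df,
                              total_reads=report.total_reads,
                              on_target_fraction=report.on_target_fraction,
                              params=params)


def merge_technical_runs(report1: GenotypeCallReport,
                         report2: GenotypeCallReport) -> GenotypeCallReport:
    """Pool two technical runs of the same sample by summing counts locus-wise.

    Counts are combined *before* calling, so loci undercovered in each run
    alone can still reach the depth gate.  Calls present on the inputs are
    dropped; re-call the merged report.
    """
    if report1.sample_id != report2.sample_id:
        raise ValueError("cannot merge runs from different samples")
    if list(report1.per_locus.index) != list(report2.per_locus.index):
        raise ValueError("cannot merge runs genotyped against different panels")
    cols = ["count_a1", "count_a2", "primer_reads"]
    merged = report1.per_locus[cols] + report2.per_locus[cols]
    merged["depth"] = merged["count_a1"] + merged["count_a2"]
    merged = merged[["count_a1", "count_a2", "depth", "primer_reads"]]
    total = report1.total_reads + report2.total_reads
    on = (report1.on_target_fraction * report1.total_reads +
          report2.on_target_fraction * report2.total_reads)
    return GenotypeCallReport(sample_id=report1.sample_id, per_locus=merged,
                              total_reads=total,
                              on_target_fraction=on / total if total else 0.0)


def reports_to_matrix(reports: Sequence[GenotypeCallReport],
                      panel: AmpliconPanel) -> GenotypeMatrix:
    """Stack called reports into a GenotypeMatrix (dosage counts allele 2)."""
    sample_ids = [r.sample_id for r in reports]
    dosage = np.full((len(reports), panel.n_loci), MISSING, dtype=np.int16)
    for i, rep in enumerate(reports):
        if "call" not in rep.per_locus.columns:
            raise ValueError(f"report for {rep.sample_id!r} has no calls; run call_genotypes")
        calls = rep.per_locus.loc[panel.locus_ids, "call"]
        dosage[i, :] = [CALL_CODES[c] for c in calls]
    # allele labels: central SNP base of each probe where they differ
    labels = []
    for locus in panel.locus_ids:
        p1, p2 = panel.probes(locus)
        pos = next((k for k, (x, y) in enumerate(zip(p1, p2)) if x != y), 0)
        labels.append({"allele1": p1[pos], "allele2": p2[pos]})
    alleles = pd.DataFrame(labels, index=pd.Index(panel.locus_ids, name="locus_id"))
    return GenotypeMatrix(dosage, sample_ids, panel.locus_ids, alleles)


# ---------------------------------------------------------------------------
# Panel-health diagnostics
# ---------------------------------------------------------------------------

def primer_overrepresentation(reads, panel: AmpliconPanel,
                              flag_threshold: float | None = None) -> PanelHealthReport:
    """Per-primer share of a pooled read set; flag primers hogging reads.

    Default flag threshold is 10x the panel-uniform share 1/n_loci.
    """
    seqs = _as_sequences(reads)
    if not seqs:
        raise ValueError("need at least one read")
    if flag_threshold is None:
        flag_threshold = 10.0 / panel.n_loci
    counts = {l: 0 for l in panel.locus_ids}
    for seq in seqs:
        for locus in panel.locus_ids:
            if panel.primer(locus) in seq:
                counts[locus] += 1
    fractions = pd.Series(counts, name="primer_fraction", dtype=float) / len(seqs)
    flagged = sorted(fractions.index[fractions > flag_threshold])
    return PanelHealthReport(primer_fractions=fractions, flagged_primers=flagged,
                             total_reads=len(seqs))


def primer_interaction_scan(reads, panel: AmpliconPanel,
                            flag_fraction: float = 0.01) -> PanelHealthReport:
    """Detect primer-dimer / PCR-artifact reads in a pooled read set.

    An artifact read contains >= 2 distinct panel primers (forward or
    reverse-complement orientation) and no allele probe; legitimate
    amplicons always carry a probe.  Per unordered primer pair, the report
    gives the fraction of total reads attributed to that pair.
    """
    seqs = _as_sequences(reads)
    if not seqs:
        raise ValueError("need at least one read")
    ids = panel.locus_ids
    motifs = {l: (panel.primer(l), revcomp(panel.primer(l))) for l in ids}
    probe_list = [p for l in ids for p in panel.probes(l)]

    primer_counts = {l: 0 for l in ids}
    pair_counts: dict[tuple[str, str], int] = {}
    n_artifact = 0
    for seq in seqs:
        hits = [l for l, (fwd, rc) in motifs.items() if fwd in seq or rc in seq]
        for l in hits:
            primer_counts[l] += 1
        if len(hits) >= 2 and not any(p in seq for p in probe_list):
            n_artifact += 1
            for pair in combinations(sorted(hits), 2):
                pair_counts[pair] = pair_counts.get(pair, 0) + 1

    n = len(seqs)
    pair_rows = [{"primer_a": a, "primer_b": b, "fraction": c / n}
                 for (a, b), c in sorted(pair_counts.items())]
    pair_fractions = pd.DataFrame(pair_rows, columns=["primer_a", "primer_b", "fraction"])
    flagged = [(r.primer_a, r.primer_b) for r in pair_fractions.itertuples()
               if r.fraction > flag_fraction]
    fractions = pd.Series(primer_counts, name="primer_fraction", dtype=float) / n
    return PanelHealthReport(primer_fractions=fractions, flagged_primers=[],
                             pair_fractions=pair_fractions, flagged_pairs=flagged,
                             artifact_fraction=n_artifact / n, total_reads=n)
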