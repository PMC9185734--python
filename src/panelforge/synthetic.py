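"""Synthetic inputs for the panel pipeline.

Everything downstream (design, genotyping, QC, forensics) can be exercised
from the generators in this module: minor-allele-frequency spectra, Hardy-
Weinberg population genotypes, pedigreed dyads with category-specific IBD
sharing, sex-differentiated loci, and amplicon read sets with configurable
depth, on-target fraction, locus dropout and substitution noise.

All randomness flows through explicit integer seeds; re-running a generator
with the same arguments reproduces its output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MAF_BINS,
    MISSING,
    PROPORTIONAL,
    AlleleFrequencyTable,
    AmpliconPanel,
    GenotypeMatrix,
    RELATIONSHIPS,
    RelationshipCategory,
    SampleQualityTier,
)

__all__ = [
    "draw_frequency_spectrum",
    "simulate_population_genotypes",
    "simulate_dyad",
    "simulate_dyads",
    "simulate_sex_loci",
    "synthetic_panel",
    "simulate_amplicon_reads",
    "ReadSimulation",
]


# ---------------------------------------------------------------------------
# Allele-frequency spectra
# ---------------------------------------------------------------------------

def draw_frequency_spectrum(n_loci: int, bin_name: str, seed: int,
                            proportional_weights: tuple[float, float, float] | None = None,
                            prefix: str = "locus") -> AlleleFrequencyTable:
    """Draw per-locus minor-allele frequencies uniformly within a MAF bin.

    ``bin_name`` is one of ``low`` (0.00-0.10), ``moderate`` (0.20-0.30),
    ``high`` (0.40-0.49) or ``proportional``, which mixes the three ranges
    with ``proportional_weights`` (default equal thirds).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    if bin_name == PROPORTIONAL:
        w = np.asarray(proportional_weights if proportional_weights is not None
                       else (1 / 3, 1 / 3, 1 / 3), dtype=float)
        if w.shape != (3,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("proportional_weights must be 3 non-negative numbers")
        w = w / w.sum()
        bins = list(MAF_BINS.values())
        which = rng.choice(3, size=n_loci, p=w)
        lo = np.array([bins[i].lo for i in which])
        hi = np.array([bins[i].hi for i in which])
        p = rng.uniform(lo, hi)
    elif bin_name in MAF_BINS:
        b = MAF_BINS[bin_name]
        p = rng.uniform(b.lo, b.hi, size=n_loci)
    else:
        valid = sorted(MAF_BINS) + [PROPORTIONAL]
        raise ValueError(f"unknown MAF bin {bin_name!r}; valid bins: {valid}")
    ids = [f"{prefix}{i + 1:05d}" for i in range(n_loci)]
    return AlleleFrequencyTable.from_minor(ids, p)


# ---------------------------------------------------------------------------
# Population genotypes under Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def simulate_population_genotypes(freqs: AlleleFrequencyTable, n_samples: int,
                                  seed: int, prefix: str = "S") -> GenotypeMatrix:
    """Draw unrelated diploid genotypes: dosage ~ Binomial(2, p) per locus."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p = freqs.p_allele2
    dosage = rng.binomial(2, p, size=(n_samples, freqs.n_loci)).astype(np.int16)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(dosage, ids, freqs.locus_ids)


# ---------------------------------------------------------------------------
# Dyad simulation
# ---------------------------------------------------------------------------

def _resolve_category(category: str | RelationshipCategory) -> RelationshipCategory:
    if isinstance(category, RelationshipCategory):
        return category
    try:
        return RELATIONSHIPS[category]
    except KeyError:
        raise ValueError(
            f"unknown relationship {category!r}; valid: {sorted(RELATIONSHIPS)}") from None


def simulate_dyads(freqs: AlleleFrequencyTable, category: str | RelationshipCategory,
                   n_dyads: int, seed: int, return_ibd: bool = False):
    """Simulate genotype dosages for ``n_dyads`` pairs with a given relationship.

    Individual 1 is a Hardy-Weinberg draw.  At each locus the pair shares
    k ~ ibd_distribution alleles identical-by-descent: shared alleles are
    copied from individual 1 (a random one of its two alleles when k=1, both
    when k=2) and the remainder of individual 2's alleles are fresh
    population draws.  Loci are independent (unlinked markers).

    Returns ``(dosage1, dosage2)`` arrays of shape (n_dyads, n_loci), plus
    the true IBD-state array when ``return_ibd`` is set.
    """
    cat = _resolve_category(category)
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    rng = np.random.default_rng(seed)
    p = freqs.p_allele2
    L = freqs.n_loci
    shape = (n_dyads, L)

    a = rng.random(shape + (2,)) < p[None, :, None]          # individual 1 alleles
    b = rng.random(shape + (2,)) < p[None, :, None]          # fresh draws for ind. 2
    k = rng.choice(3, size=shape, p=np.asarray(cat.ibd_distribution))
    pick = rng.integers(0, 2, size=shape)                    # which allele of ind. 1 is shared

    shared = np.take_along_axis(a, pick[..., None], axis=2)[..., 0]
    other = np.take_along_axis(a, (1 - pick)[..., None], axis=2)[..., 0]
    b0 = np.where(k >= 1, shared, b[..., 0])
    b1 = np.where(k == 2, other, b[..., 1])

    dosage1 = a.sum(axis=2).astype(np.int16)
    dosage2 = (b0.astype(np.int16) + b1.astype(np.int16))
    if return_ibd:
        return dosage1, dosage2, k
    return dosage1, dosage2


def simulate_dyad(freqs: AlleleFrequencyTable, category: str | RelationshipCategory,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-dyad convenience wrapper: two dosage vectors of length n_loci."""
    d1, d2 = simulate_dyads(freqs, category, 1, seed)
    return d1[0], d2[0]


# ---------------------------------------------------------------------------
# Sex-differentiated loci
# ---------------------------------------------------------------------------

def simulate_sex_loci(n_loci: int, differential: float, n_males: int,
                      n_females: int, seed: int):
    """Plant loci whose allele-2 frequency differs between the sexes.

    Construction: the female frequency f is uniform on [0, 1-differential]
    and the male frequency is f + differential, so the per-sex gap is exactly
    ``differential`` by construction.  ``differential=1.0`` yields fixed
    differences (gametolog-like markers: females 0/0, males 1/1 throughout).
    Genotypes are drawn Hardy-Weinberg within sex.

    Returns ``(GenotypeMatrix with sex metadata, sex label Series,
    AlleleFrequencyTable with realized 'male'/'female' stratum columns)``.
    """
    if not (0.0 < differential <= 1.0):
        raise ValueError("differential must lie in (0, 1]")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if n_males < 1 or n_females < 1:
        raise ValueError("need at least one individual of each sex")
    rng = np.random.default_rng(seed)
    f_female = rng.uniform(0.0, 1.0 - differential, size=n_loci)
    f_male = np.clip(f_female + differential, 0.0, 1.0)

    dos_f = rng.binomial(2, f_female, size=(n_females, n_loci))
    dos_m = rng.binomial(2, f_male, size=(n_males, n_loci))
    dosage = np.vstack([dos_f, dos_m]).astype(np.int16)

    sample_ids = [f"F{i + 1:04d}" for i in range(n_females)] + \
                 [f"M{i + 1:04d}" for i in range(n_males)]
    sex = pd.Series(["female"] * n_females + ["male"] * n_males,
                    index=sample_ids, name="sex")
    locus_ids = [f"sexlocus{i + 1:03d}" for i in range(n_loci)]
    metadata = sex.to_frame()
    gm = GenotypeMatrix(dosage, sample_ids, locus_ids, metadata=metadata)

    realized_f = dos_f.mean(axis=0) / 2.0
    realized_m = dos_m.mean(axis=0) / 2.0
    pooled = dosage.mean(axis=0) / 2.0
    freqs = AlleleFrequencyTable(pd.DataFrame(
        {"p_allele2": pooled, "male": realized_m, "female": realized_f},
        index=pd.Index(locus_ids, name="locus_id")))
    return gm, sex, freqs


# ---------------------------------------------------------------------------
# Synthetic amplicon panel
# ---------------------------------------------------------------------------

def synthetic_panel(locus_ids, seed: int, primer_length: tuple[int, int] = (15, 17),
                    probe_flank: int = 7) -> AmpliconPanel:
    """Construct a random panel: one forward primer and two allele probes per locus.

    Probes share flanking context and differ only at the central SNP base,
    mirroring real allele-specific probes.  Random primers of 15-17 bases are
    effectively unique at any realistic panel size.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows = []
    seen: set[str] = set()
    for locus in locus_ids:
        while True:
            plen = int(rng.integers(primer_length[0], primer_length[1] + 1))
            primer = "".join(rng.choice(bases, size=plen))
            if primer not in seen:
                seen.add(primer)
                break
        flank5 = "".join(rng.choice(bases, size=probe_flank))
        flank3 = "".join(rng.choice(bases, size=probe_flank))
        a1, a2 = rng.choice(bases, size=2, replace=False)
        rows.append({"locus_id": locus, "fwd_primer": primer,
                     "probe_allele1": flank5 + a1 + flank3,
                     "probe_allele2": flank5 + a2 + flank3})
    return AmpliconPanel(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimulation:
    """Simulated per-sample read sets plus the emission ledger.

    ``reads`` maps sample_id -> list of read sequences.  ``ledger`` records,
    per sample x locus, how many reads were emitted for each allele *before*
    sequencing errors were applied — the ground truth that a genotyper's
    allele counts can be checked against when ``error_rate == 0``.
    """

    reads: dict[str, list[str]]
    ledger: pd.DataFrame
    read_length: int
    tier: SampleQualityTier

    def write_fastq(self, outdir: str | Path) -> dict[str, Path]:
        """Write one 4-line-record FASTQ per sample (dummy 'I' qualities)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, seqs in self.reads.items():
            path = outdir / f"{sample}.fastq"
            with open(path, "w") as fh:
                for i, seq in enumerate(seqs):
                    fh.write(f"@{sample}_read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[sample] = path
        return paths


def _apply_errors(seqs: list[str], error_rate: float, length: int,
                  rng: np.random.Generator) -> list[str]:
    # vectorized per-base substitution over equal-length reads
    if not seqs or error_rate <= 0:
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length).copy()
    hit = rng.random(arr.shape) < error_rate
    n_hit = int(hit.sum())
    if n_hit:
        # replace with a uniformly random *different* base
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        cur = arr[hit]
        offset = rng.integers(1, 4, size=n_hit)
        idx = np.searchsorted(bases, cur)
        arr[hit] = bases[(idx + offset) % 4]
    return ["".join(map(chr, row)) for row in arr]


def simulate_amplicon_reads(panel: AmpliconPanel, genotypes: GenotypeMatrix,
                            tier: SampleQualityTier, seed: int,
                            read_length: int = 75,
                            allele2_bias: float = 0.5) -> ReadSimulation:
    """Simulate single-end amplicon reads for every sample in ``genotypes``.

    Per locus, depth ~ NegativeBinomial(mean=tier.mean_depth, size=
    tier.depth_dispersion), zeroed with probability ``tier.dropout_prob``.
    Each on-target read is forward primer + allele probe + random filler to
    ``read_length``; heterozygotes emit allele 2 with probability
    ``allele2_bias``.  Per-base substitutions occur at ``tier.error_rate``,
    and enough uniformly random off-target reads are appended to make the
    on-target share equal ``tier.on_target_fraction`` in expectation.
    """
    missing_in_panel = [l for l in genotypes.locus_ids if l not in set(panel.locus_ids)]
    if missing_in_panel:
        raise ValueError(f"loci absent from panel: {missing_in_panel[:5]}")
    min_len = max(len(panel.primer(l)) + len(panel.probes(l)[0])
                  for l in genotypes.locus_ids)
    if read_length < min_len:
        raise ValueError(f"read_length {read_length} shorter than primer+probe ({min_len})")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    nb_n = tier.depth_dispersion
    nb_p = nb_n / (nb_n + tier.mean_depth)

    reads: dict[str, list[str]] = {}
    ledger_rows = []
    for i, sample in enumerate(genotypes.sample_ids):
        sample_reads: list[str] = []
        for j, locus in enumerate(genotypes.locus_ids):
            g = int(genotypes.dosage[i, j])
            depth = 0
            if g != MISSING and rng.random() >= tier.dropout_prob:
                depth = int(rng.negative_binomial(nb_n, nb_p))
            if depth > 0:
                p2 = {0: 0.0, 1: allele2_bias, 2: 1.0}[g]
                n2 = int(rng.binomial(depth, p2))
            else:
                n2 = 0
            n1 = depth - n2
            primer = panel.primer(locus)
            probe1, probe2 = panel.probes(locus)
            for probe, count in ((probe1, n1), (probe2, n2)):
                if count == 0:
                    continue
                fill_len = read_length - len(primer) - len(probe)
                fillers = rng.choice(bases, size=(count, fill_len)) if fill_len else None
                for r in range(count):
                    filler = "".join(fillers[r]) if fillers is not None else ""
                    sample_reads.append(primer + probe + filler)
            ledger_rows.append({"sample_id": sample, "locus_id": locus,
                                "count_a1": n1, "count_a2": n2, "depth": depth})
        n_on = len(sample_reads)
        n_off = int(round(n_on * (1.0 - tier.on_target_fraction) / tier.on_target_fraction))
        sample_reads = _apply_errors(sample_reads, tier.error_rate, read_length, rng)
        if n_off:
            off = rng.choice(bases, size=(n_off, read_length))
            sample_reads.extend("".join(row) for row in off)
        reads[sample] = sample_reads
    ledger = pd.DataFrame(ledger_rows)
    return ReadSimulation(reads=reads, ledger=ledger, read_length=read_length, tier=tier)
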