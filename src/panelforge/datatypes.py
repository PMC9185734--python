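"""Core data containers shared across panel design, genotyping, QC and forensics.

The common currency of the pipeline is a dosage-coded genotype matrix
(samples x loci, values 0/1/2 counting copies of the focal allele, -1 for
missing) together with a per-locus allele-frequency table.  Both carry
string identifiers and round-trip losslessly through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

VALID_DOSAGES = frozenset({-1, 0, 1, 2})


# ---------------------------------------------------------------------------
# Minor-allele-frequency bins used in the marker-informativeness sensitivity
# analysis.  "proportional" mixes the three ranges with configurable weights.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAFBin:
    """A named minor-allele-frequency range, e.g. high = [0.40, 0.49]."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 0.5):
            raise ValueError(f"MAF bin bounds must satisfy 0 <= lo <= hi <= 0.5, got {self}")


MAF_BINS: dict[str, MAFBin] = {
    "low": MAFBin("low", 0.00, 0.10),
    "moderate": MAFBin("moderate", 0.20, 0.30),
    "high": MAFBin("high", 0.40, 0.49),
}

#: Name of the composite bin mixing the three ranges above.
PROPORTIONAL = "proportional"


# ---------------------------------------------------------------------------
# Relationship categories for dyad simulation.  The IBD distribution gives
# the probability that a pair shares 0/1/2 alleles identical-by-descent at a
# single autosomal locus; the kinship coefficient is the expected probability
# that two randomly drawn alleles (one per individual) are IBD.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelationshipCategory:
    code: str
    ibd_distribution: tuple[float, float, float]
    expected_kinship: float

    def __post_init__(self) -> None:
        if abs(sum(self.ibd_distribution) - 1.0) > 1e-12:
            raise ValueError(f"IBD distribution must sum to 1: {self}")


RELATIONSHIPS: dict[str, RelationshipCategory] = {
    "PO": RelationshipCategory("PO", (0.0, 1.0, 0.0), 0.25),
    "FS": RelationshipCategory("FS", (0.25, 0.5, 0.25), 0.25),
    "HS": RelationshipCategory("HS", (0.5, 0.5, 0.0), 0.125),
    "FC": RelationshipCategory("FC", (0.75, 0.25, 0.0), 0.0625),
    "UR": RelationshipCategory("UR", (1.0, 0.0, 0.0), 0.0),
}

#: Categories ordered least related -> most related; classification ties are
#: broken toward the earlier (less related) category.
RELATEDNESS_ORDER: tuple[str, ...] = ("UR", "FC", "HS", "FS", "PO")


# ---------------------------------------------------------------------------
# Sample-quality tiers for amplicon read simulation.  The four tiers emulate
# the tissue > hair > colon feces > field feces quality gradient typical of
# noninvasive sampling: decreasing depth and on-target fraction, increasing
# locus dropout and substitution noise.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleQualityTier:
    name: str
    on_target_fraction: float
    mean_depth: float
    dropout_prob: float
    error_rate: float
    depth_dispersion: float = 5.0  # negative-binomial size parameter

    def __post_init__(self) -> None:
        for attr in ("on_target_fraction", "dropout_prob", "error_rate"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.on_target_fraction == 0:
            raise ValueError("on_target_fraction must be > 0 to emit any target reads")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


QUALITY_TIERS: dict[str, SampleQualityTier] = {
    "tissue": SampleQualityTier("tissue", 0.90, 149.0, 0.03, 0.002),
    "hair": SampleQualityTier("hair", 0.60, 177.0, 0.05, 0.003),
    "colon_feces": SampleQualityTier("colon_feces", 0.50, 119.0, 0.10, 0.004),
    "field_feces": SampleQualityTier("field_feces", 0.45, 96.0, 0.14, 0.005),
}


# ---------------------------------------------------------------------------
# Allele-frequency table
# ---------------------------------------------------------------------------

class AlleleFrequencyTable:
    """Per-locus biallelic allele frequencies, optionally stratified.

    The focal allele ("allele 2", the allele counted by genotype dosage)
    has frequency ``p_allele2``; ``p_minor``/``p_major`` are the folded
    frequencies.  Extra strata (e.g. ``male``/``female``) are stored as
    additional columns holding the within-stratum frequency of allele 2.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "p_allele2" not in table.columns:
            if "p_minor" not in table.columns:
                raise ValueError("frequency table needs a p_allele2 or p_minor column")
            table["p_allele2"] = table["p_minor"].astype(float)
        table["p_allele2"] = table["p_allele2"].astype(float)
        if ((table["p_allele2"] < 0) | (table["p_allele2"] > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        table["p_minor"] = np.minimum(table["p_allele2"], 1.0 - table["p_allele2"])
        table["p_major"] = 1.0 - table["p_minor"]
        if table.index.name != "locus_id":
            if "locus_id" in table.columns:
                table = table.set_index("locus_id")
            else:
                raise ValueError("frequency table needs locus_id as index or column")
        if table.index.duplicated().any():
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate locus_id: {dup!r}")
        self.table = table

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_minor(cls, locus_ids: Sequence[str], p_minor: Iterable[float],
                   **strata: Iterable[float]) -> "AlleleFrequencyTable":
        """Build a table where the focal allele is the minor allele."""
        df = pd.DataFrame({"p_allele2": np.asarray(list(p_minor), dtype=float)},
                          index=pd.Index(locus_ids, name="locus_id"))
        for name, vals in strata.items():
            df[name] = np.asarray(list(vals), dtype=float)
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        return cls(pd.read_csv(path, sep="\t").set_index("locus_id"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    # -- accessors ----------------------------------------------------------

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def p_minor(self) -> np.ndarray:
        return self.table["p_minor"].to_numpy()

    @property
    def p_allele2(self) -> np.ndarray:
        return self.table["p_allele2"].to_numpy()

    @property
    def strata(self) -> list[str]:
        reserved = {"p_allele2", "p_minor", "p_major"}
        return [c for c in self.table.columns if c not in reserved]

    def stratum(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"stratum {name!r} not present; have {self.strata}")
        return self.table[name].to_numpy(dtype=float)

    def subset(self, locus_ids: Sequence[str]) -> "AlleleFrequencyTable":
        return AlleleFrequencyTable(self.table.loc[list(locus_ids)])

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"AlleleFrequencyTable({self.n_loci} loci, strata={self.strata})"


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Samples x loci diploid genotypes coded as allele-2 dosage.

    ``dosage[i, j]`` counts copies of allele 2 carried by sample ``i`` at
    locus ``j`` (0, 1, 2) or is -1 for a missing call.  ``alleles`` maps each
    locus to its two allele labels (defaults to A/G); ``metadata`` is an
    optional per-sample frame (sample_type, method, individual_id, sex,
    coordinates, ...) indexed by sample_id.
    """

    def __init__(self, dosage: np.ndarray, sample_ids: Sequence[str],
                 locus_ids: Sequence[str], alleles: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None):
        dosage = np.asarray(dosage)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x loci)")
        dosage = dosage.astype(np.int16)
        if not set(np.unique(dosage)) <= VALID_DOSAGES:
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        n_s, n_l = dosage.shape
        sample_ids = [str(s) for s in sample_ids]
        locus_ids = [str(l) for l in locus_ids]
        if len(sample_ids) != n_s or len(locus_ids) != n_l:
            raise ValueError("identifier lengths do not match dosage shape")
        if len(set(sample_ids)) != n_s:
            raise ValueError("sample_ids must be unique")
        if len(set(locus_ids)) != n_l:
            raise ValueError("locus_ids must be unique")
        if alleles is None:
            alleles = pd.DataFrame({"allele1": "A", "allele2": "G"},
                                   index=pd.Index(locus_ids, name="locus_id"))
        else:
            alleles = alleles.loc[locus_ids, ["allele1", "allele2"]].copy()
        if metadata is not None:
            metadata = metadata.loc[sample_ids].copy()
        self.dosage = dosage
        self.sample_ids = sample_ids
        self.locus_ids = locus_ids
        self.alleles = alleles
        self.metadata = metadata

    # -- shape and missingness ---------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def missing_by_sample(self) -> pd.Series:
        frac = (self.dosage == MISSING).mean(axis=1)
        return pd.Series(frac, index=self.sample_ids, name="missing_fraction")

    def missing_by_locus(self) -> pd.Series:
        frac = (self.dosage == MISSING).mean(axis=0)
        return pd.Series(frac, index=self.locus_ids, name="missing_fraction")

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(self.dosage[idx, :], list(keep), self.locus_ids,
                              self.alleles, self.metadata)

    def subset_loci(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in keep]
        return GenotypeMatrix(self.dosage[:, idx], self.sample_ids, list(keep),
                              self.alleles.loc[list(keep)], self.metadata)

    # -- derived quantities -------------------------------------------------

    def allele_frequencies(self) -> AlleleFrequencyTable:
        """Allele-2 frequency among called genotypes at each locus.

        Loci with no calls at all get frequency NaN.
        """
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p2 = np.nanmean(d, axis=0) / 2.0
        df = pd.DataFrame({"p_allele2": p2},
                          index=pd.Index(self.locus_ids, name="locus_id"))
        df["n_called"] = (self.dosage != MISSING).sum(axis=0)
        return AlleleFrequencyTable(df)

    def call_strings(self) -> pd.DataFrame:
        """Genotypes as 'A/G'-style strings (loci rows, samples columns)."""
        a1 = self.alleles["allele1"].to_numpy()
        a2 = self.alleles["allele2"].to_numpy()
        out = np.empty((self.n_loci, self.n_samples), dtype=object)
        d = self.dosage.T  # loci x samples
        for j in range(self.n_loci):
            lut = {0: f"{a1[j]}/{a1[j]}", 1: f"{a1[j]}/{a2[j]}",
                   2: f"{a2[j]}/{a2[j]}", MISSING: "NA"}
            out[j, :] = [lut[int(v)] for v in d[j]]
        return pd.DataFrame(out, index=pd.Index(self.locus_ids, name="locus_id"),
                            columns=self.sample_ids)

    # -- TSV round-trip -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write loci-as-rows TSV: allele labels, then one call column per sample."""
        df = self.call_strings()
        df.insert(0, "allele1", self.alleles["allele1"].to_numpy())
        df.insert(1, "allele2", self.alleles["allele2"].to_numpy())
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 metadata: pd.DataFrame | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str,
                         keep_default_na=False).set_index("locus_id")
        alleles = df[["allele1", "allele2"]]
        calls = df.drop(columns=["allele1", "allele2"])
        sample_ids = list(calls.columns)
        a1 = alleles["allele1"].to_numpy()
        a2 = alleles["allele2"].to_numpy()
        dosage = np.full((len(sample_ids), len(df)), MISSING, dtype=np.int16)
        for j in range(len(df)):
            lut = {f"{a1[j]}/{a1[j]}": 0, f"{a1[j]}/{a2[j]}": 1,
                   f"{a2[j]}/{a1[j]}": 1, f"{a2[j]}/{a2[j]}": 2, "NA": MISSING}
            col = calls.iloc[j].to_numpy()
            try:
                dosage[:, j] = [lut[c] for c in col]
            except KeyError as exc:
                raise ValueError(
                    f"unparseable call {exc.args[0]!r} at locus {df.index[j]!r}") from None
        return cls(dosage, sample_ids, list(df.index), alleles, metadata)

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


# ---------------------------------------------------------------------------
# Amplicon panel
# ---------------------------------------------------------------------------

_DNA = frozenset("ACGT")


class AmpliconPanel:
    """Per-locus forward primer plus the two allele-specific probes.

    Probes are stored in read orientation; genotyping searches them as exact
    substrings.  Primers are 15-17 bases by convention but any non-empty
    ACGT string is accepted.
    """

    COLUMNS = ("fwd_primer", "probe_allele1", "probe_allele2")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "locus_id":
            if "locus_id" in table.columns:
                table = table.set_index("locus_id")
            else:
                raise ValueError("panel table needs locus_id as index or column")
        missing_cols = [c for c in self.COLUMNS if c not in table.columns]
        if missing_cols:
            raise ValueError(f"panel table missing columns: {missing_cols}")
        if len(table) == 0:
            raise ValueError("empty panel")
        if table.index.duplicated().any():
            raise ValueError("panel locus_ids must be unique")
        for col in self.COLUMNS:
            for locus, seq in table[col].items():
                if not isinstance(seq, str) or not seq or not set(seq) <= _DNA:
                    raise ValueError(
                        f"{col} for locus {locus!r} must be a non-empty uppercase ACGT string")
        same = table["probe_allele1"] == table["probe_allele2"]
        if same.any():
            raise ValueError(
                f"probe pair identical at locus {table.index[same][0]!r}")
        self.table = table[list(self.COLUMNS)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AmpliconPanel":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_loci(self) -> int:
        return len(self.table)

    def primer(self, locus_id: str) -> str:
        return self.table.at[locus_id, "fwd_primer"]

    def probes(self, locus_id: str) -> tuple[str, str]:
        row = self.table.loc[locus_id]
        return row["probe_allele1"], row["probe_allele2"]

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"AmpliconPanel({self.n_loci} loci)"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
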