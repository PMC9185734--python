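"""Genotype quality control: missingness filters, success rates, concordance.

The filtering convention follows standard noninvasive-genetics practice:
first drop samples with more than the allowed missing-data fraction, then
drop loci the same way (sample filter first, so a few failed samples do not
take whole loci down with them).  The ">" is strict — a sample at exactly
the cutoff is retained.

Discordance between paired genotypes (replicates, tissue vs noninvasive,
or across genotyping methods) only considers loci called in *both* members
of a pair; genotypes are compared as unordered allele pairs, so het vs hom
is discordant even when an allele is shared.  The headline rate pools
counts across pairs (total discordant / total comparable); per-pair rates
are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "filter_samples",
    "filter_loci",
    "genotyping_success",
    "ConcordanceReport",
    "discordance",
    "cross_method_concordance",
]


def filter_samples(gm: GenotypeMatrix, max_missing: float = 0.5):
    """Drop samples whose missing fraction exceeds ``max_missing`` (strict >).

    Returns ``(filtered GenotypeMatrix, list of removed sample_ids)`` with
    input order preserved.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    miss = gm.missing_by_sample()
    keep = [s for s in gm.sample_ids if miss[s] <= max_missing]
    removed = [s for s in gm.sample_ids if miss[s] > max_missing]
    return gm.subset_samples(keep), removed


def filter_loci(gm: GenotypeMatrix, max_missing: float = 0.5):
    """Drop loci whose missing fraction exceeds ``max_missing`` (strict >)."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    miss = gm.missing_by_locus()
    keep = [l for l in gm.locus_ids if miss[l] <= max_missing]
    removed = [l for l in gm.locus_ids if miss[l] > max_missing]
    return gm.subset_loci(keep), removed


def genotyping_success(gm: GenotypeMatrix, strata: pd.Series | None = None) -> pd.Series:
    """Mean per-sample call rate (1 - missing fraction), optionally by stratum.

    ``strata`` maps sample_id -> group label (e.g. sample type).  Groups
    with no samples are simply absent from the result.  Values are
    proportions in [0, 1].
    """
    if gm.n_samples < 1:
        raise ValueError("need at least one sample")
    success = 1.0 - gm.missing_by_sample()
    success.name = "genotyping_success"
    if strata is None:
        return pd.Series({"overall": success.mean()}, name="genotyping_success")
    strata = strata.loc[gm.sample_ids]
    return success.groupby(strata).mean().rename("genotyping_success")


@dataclass
class ConcordanceReport:
    n_pairs: int
    n_comparable_calls: int
    n_discordant: int
    discordance: float
    per_pair: pd.DataFrame
    excluded_pairs: list[tuple[str, str]]
    label: str = ""


def _pairwise_discordance(d_a: np.ndarray, d_b: np.ndarray,
                          pairs: list[tuple[str, str]],
                          ids_a: list[str], ids_b: list[str],
                          label: str) -> ConcordanceReport:
    ia = {s: k for k, s in enumerate(ids_a)}
    ib = {s: k for k, s in enumerate(ids_b)}
    rows, excluded = [], []
    tot_comp = tot_disc = 0
    for a, b in pairs:
        if a not in ia or b not in ib:
            raise ValueError(f"pair ({a!r}, {b!r}) not found in genotype matrix")
        va, vb = d_a[ia[a]], d_b[ib[b]]
        both = (va != MISSING) & (vb != MISSING)
        n_comp = int(both.sum())
        if n_comp == 0:
            excluded.append((a, b))
            continue
        n_disc = int((va[both] != vb[both]).sum())
        tot_comp += n_comp
        tot_disc += n_disc
        rows.append({"sample_a": a, "sample_b": b, "n_comparable": n_comp,
                     "n_discordant": n_disc, "discordance": n_disc / n_comp})
    per_pair = pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_comparable",
                                           "n_discordant", "discordance"])
    rate = tot_disc / tot_comp if tot_comp else np.nan
    return ConcordanceReport(n_pairs=len(rows), n_comparable_calls=tot_comp,
                             n_discordant=tot_disc, discordance=rate,
                             per_pair=per_pair, excluded_pairs=excluded, label=label)


def discordance(gm: GenotypeMatrix, pairing: list[tuple[str, str]],
                label: str = "") -> ConcordanceReport:
    """Genotyping discordance over paired samples within one matrix.

    Comparable cells are loci called in both members; discordant cells are
    those where the (unordered) genotypes differ.  Pairs with zero
    comparable loci are excluded and listed on the report.
    """
    return _pairwise_discordance(gm.dosage, gm.dosage, pairing,
                                 gm.sample_ids, gm.sample_ids, label)


def cross_method_concordance(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix,
                             pairing: list[tuple[str, str]] | None = None,
                             shared_loci: list[str] | None = None,
                             label: str = "cross-method") -> ConcordanceReport:
    """Discordance between two matrices (e.g. amplicon panel vs RADseq).

    Restricted to ``shared_loci`` (default: the locus intersection, which
    must be non-empty).  ``pairing`` defaults to samples with identical ids
    in both matrices.
    """
    if shared_loci is None:
        shared_loci = [l for l in gm_a.locus_ids if l in set(gm_b.locus_ids)]
    if not shared_loci:
        raise ValueError("matrices share no loci")
    sub_a = gm_a.subset_loci(shared_loci)
    sub_b = gm_b.subset_loci(shared_loci)
    if pairing is None:
        common = [s for s in gm_a.sample_ids if s in set(gm_b.sample_ids)]
        if not common:
            raise ValueError("no shared samples and no explicit pairing given")
        pairing = [(s, s) for s in common]
    return _pairwise_discordance(sub_a.dosage, sub_b.dosage, pairing,
                                 sub_a.sample_ids, sub_b.sample_ids, label)
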