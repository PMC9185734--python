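"""Marker-informativeness analysis for SNP panel design.

Quantifies what a candidate set of biallelic SNPs can deliver for three
applications:

* individual identification — cumulative probability of identity for
  unrelated individuals (P_ID) and for full siblings (P_IDsib), with the
  minimum panel size needed to push each below a threshold (conventionally
  the reciprocal of the sample size);
* kinship classification — simulated dyads of known relationship scored
  with the Loiselle kinship estimator and assigned by maximum likelihood,
  yielding per-category assignment accuracy and a misclassification matrix;
* sex identification — screening loci whose allele frequencies differ
  between the sexes by at least a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AlleleFrequencyTable,
    RELATEDNESS_ORDER,
    RELATIONSHIPS,
)
from .synthetic import draw_frequency_spectrum, simulate_dyads
from .forensics import loiselle_pairs

__all__ = [
    "p_id_locus",
    "p_idsib_locus",
    "IdentityPowerCurve",
    "identity_power_curve",
    "DyadSimulationResult",
    "kinship_assignment_accuracy",
    "kinship_sensitivity_analysis",
    "screen_sex_markers",
]


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------

def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequency must lie in [0, 1]")
    return p

def p_id_locus(p):
    """Per-locus probability of identity for two unrelated individuals.

    For a biallelic locus with allele frequencies p, q under HWE:
    P_ID = p^4 + q^4 + (2pq)^2 — the chance two independent genotypes match.
    Accepts scalars or arrays.
    """
    p = _check_p(p)
    q = 1.0 - p
    return p ** 4 + q ** 4 + (2 * p * q) ** 2


def p_idsib_locus(p):
    """Per-locus probability of identity for full siblings.

    P_IDsib = 0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4 with S2 = sum p_i^2 and
    S4 = sum p_i^4.  Always >= P_ID; equals 1 for a monomorphic locus.
    """
    p = _check_p(p)
    q = 1.0 - p
    s2 = p ** 2 + q ** 2
    s4 = p ** 4 + q ** 4
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


@dataclass
class IdentityPowerCurve:
    """Cumulative identity power over increasing panel sizes.

    ``curve`` has one row per panel size n with columns ``p_id_cum`` and
    ``p_idsib_cum`` (products of the n most informative per-locus values);
    ``min_n_id``/``min_n_idsib`` are the smallest n at which the cumulative
    value drops strictly below ``threshold`` (None if never reached).
    """

    curve: pd.DataFrame
    threshold: float
    min_n_id: int | None
    min_n_idsib: int | None


def identity_power_curve(freqs: AlleleFrequencyTable, threshold: float,
                         order: str = "informativeness") -> IdentityPowerCurve:
    """Cumulative P_ID / P_IDsib and the minimum panel sizes meeting ``threshold``.

    Loci are ranked most-informative first (ascending per-locus P_ID) unless
    ``order='input'``.  Accumulation is done in log space; with ~hundreds of
    loci the products underflow double precision otherwise.
    """
    if freqs.n_loci < 1:
        raise ValueError("need at least one locus")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    pid = p_id_locus(freqs.p_minor)
    psib = p_idsib_locus(freqs.p_minor)
    if order == "informativeness":
        rank = np.argsort(pid, kind="stable")
    elif order == "input":
        rank = np.arange(len(pid))
    else:
        raise ValueError("order must be 'informativeness' or 'input'")
    pid, psib = pid[rank], psib[rank]
    locus_order = [freqs.locus_ids[i] for i in rank]

    with np.errstate(divide="ignore"):
        cum_id = np.exp(np.cumsum(np.log(pid)))
        cum_sib = np.exp(np.cumsum(np.log(psib)))
    curve = pd.DataFrame({"n": np.arange(1, len(pid) + 1), "locus_id": locus_order,
                          "p_id_cum": cum_id, "p_idsib_cum": cum_sib})

    def first_below(vals: np.ndarray) -> int | None:
        hit = np.nonzero(vals < threshold)[0]
        return int(hit[0]) + 1 if hit.size else None

    return IdentityPowerCurve(curve, threshold, first_below(cum_id), first_below(cum_sib))


# ---------------------------------------------------------------------------
# Kinship assignment accuracy via dyad simulation
# ---------------------------------------------------------------------------

@dataclass
class DyadSimulationResult:
    """Relationship-labelled kinship estimates and their classification.

    ``estimates`` maps category code -> per-dyad Loiselle kinship estimates;
    ``confusion`` is the row-normalized 5x5 misclassification matrix (rows =
    true category, columns = assigned); ``accuracy`` is its diagonal.
    """

    estimates: dict[str, np.ndarray]
    confusion: pd.DataFrame
    accuracy: pd.Series
    training_params: pd.DataFrame


def _polymorphic_count(freqs: AlleleFrequencyTable) -> int:
    p = freqs.p_allele2
    return int(((p > 0) & (p < 1)).sum())


def kinship_assignment_accuracy(freqs: AlleleFrequencyTable,
                                n_dyads_per_category: int, seed: int,
                                n_training_dyads: int | None = None,
                                categories=RELATEDNESS_ORDER) -> DyadSimulationResult:
    """Simulate dyads per relationship category and classify them.

    For each category, ``n_dyads_per_category`` dyads are simulated, their
    kinship estimated with the Loiselle estimator against the panel's
    (true) allele frequencies, and each dyad assigned by maximum likelihood
    under per-category normal approximations whose mean and variance are fit
    on an independent training simulation of the same size (training seed =
    seed + 1).  Ties go to the less related category.
    """
    if n_dyads_per_category < 100:
        raise ValueError("n_dyads_per_category must be >= 100")
    if _polymorphic_count(freqs) < 2:
        raise ValueError("need at least 2 polymorphic loci")
    p = freqs.p_allele2
    cat_index = {c: i for i, c in enumerate(categories)}

    def batch(cat: str, base_seed: int, n: int) -> np.ndarray:
        sub = np.random.SeedSequence([base_seed, cat_index[cat]])
        d1, d2 = simulate_dyads(freqs, cat, n, seed=int(sub.generate_state(1)[0] % (2 ** 31)))
        return loiselle_pairs(d1, d2, p)

    # training pass: fit a normal per category
    params = {}
    n_train = n_training_dyads or n_dyads_per_category
    for cat in categories:
        est = batch(cat, seed + 1, n_train)
        params[cat] = (float(est.mean()), float(est.std(ddof=1)))
    training_params = pd.DataFrame(params, index=["mean", "sd"]).T

    # test pass: classify by max normal likelihood, least-related-first ties
    estimates = {}
    counts = pd.DataFrame(0.0, index=list(categories), columns=list(categories))
    means = training_params["mean"].to_numpy()
    sds = np.maximum(training_params["sd"].to_numpy(), 1e-9)
    for cat in categories:
        est = batch(cat, seed, n_dyads_per_category)
        estimates[cat] = est
        loglik = stats.norm.logpdf(est[:, None], loc=means[None, :], scale=sds[None, :])
        assigned = np.argmax(loglik, axis=1)  # first max -> least related wins ties
        for idx, n in zip(*np.unique(assigned, return_counts=True)):
            counts.loc[cat, categories[idx]] += n
    confusion = counts.div(counts.sum(axis=1), axis=0)
    accuracy = pd.Series(np.diag(confusion), index=confusion.index, name="accuracy")
    return DyadSimulationResult(estimates, confusion, accuracy, training_params)


def kinship_sensitivity_analysis(sizes=(50, 100, 200, 400),
                                 bins=("low", "moderate", "high"),
                                 n_dyads_per_category: int = 10_000,
                                 replicates: int = 4,
                                 seed: int = 0) -> pd.DataFrame:
    """Assignment accuracy across panel sizes and MAF bins.

    For each (bin, size) cell, ``replicates`` independent frequency panels
    are drawn and their per-category accuracies averaged — mirroring a
    sensitivity analysis over random SNP subsets.  Returns a tidy frame with
    columns bin, n_loci, category, accuracy.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for b in bins:
        for n in sizes:
            acc = None
            for rep in range(replicates):
                child = ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 2)
                freqs = draw_frequency_spectrum(n, b, seed=int(child))
                res = kinship_assignment_accuracy(
                    freqs, n_dyads_per_category, seed=int(child) + 1)
                acc = res.accuracy if acc is None else acc + res.accuracy
            acc = acc / replicates
            for cat, a in acc.items():
                rows.append({"bin": b, "n_loci": n, "category": cat, "accuracy": a})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sex-marker screening
# ---------------------------------------------------------------------------

def screen_sex_markers(freqs: AlleleFrequencyTable, cutoff: float = 0.20,
                       strata: tuple[str, str] = ("male", "female")) -> pd.DataFrame:
    """Flag loci whose between-sex allele-frequency differential meets ``cutoff``.

    Returns a frame with per-locus male/female frequencies, the absolute
    differential, and a ``selected`` flag (differential >= cutoff).
    """
    for s in strata:
        if s not in freqs.table.columns:
            raise ValueError(f"frequency table lacks stratum {s!r}")
    male = freqs.table[strata[0]].astype(float)
    female = freqs.table[strata[1]].astype(float)
    bad = male.isna() | female.isna()
    if bad.any():
        raise ValueError(f"locus {male.index[bad][0]!r} is missing a stratum frequency")
    diff = (male - female).abs()
    return pd.DataFrame({
        strata[0]: male, strata[1]: female,
        "differential": diff, "selected": diff >= cutoff,
    })
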