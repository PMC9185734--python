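"""Forensic applications of a validated SNP panel.

Given called genotypes from noninvasive samples, this module answers the
field questions: how many distinct individuals were sampled (genetic
mark-recapture via multilocus genotype matching), how are they related
(pairwise Loiselle kinship), and what sex are they (supervised naive-Bayes
classification at sex-associated loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import MISSING, AlleleFrequencyTable, GenotypeMatrix

__all__ = [
    "loiselle_pairs",
    "loiselle_kinship",
    "KinshipMatrix",
    "cluster_individuals",
    "ClusterResult",
    "SexModel",
    "fit_sex_model",
    "assign_sex",
    "mark_recapture_summary",
]


# ---------------------------------------------------------------------------
# Loiselle kinship estimator
# ---------------------------------------------------------------------------
#
# For a biallelic locus with reference allele-2 frequency p, write an
# individual's allelic state as x = dosage / 2 (0, 1/2, 1).  The pairwise
# kinship estimate is
#
#     F_ij = sum_l 2 (x_il - p_l)(x_jl - p_l) + bias_l
#            -----------------------------------------
#                     sum_l 2 p_l (1 - p_l)
#
# summed over loci called in both individuals (the factor 2 covers the two
# alleles of a biallelic locus, whose deviation products are equal).  When
# the reference frequencies are estimated from the analyzed samples
# themselves, the small-sample bias term 2 p(1-p) / (2 n_l - 1) is added per
# locus (n_l = individuals called at locus l, so 2 n_l gene copies); it
# cancels the negative covariance induced by centering on the sample's own
# frequency estimate.  With externally supplied (e.g. population or true
# simulation) frequencies the term is zero.
# E[F_ij] equals the kinship coefficient: 0.25 for parent-offspring and
# full siblings, 0.125 for half siblings, 0.0625 for first cousins, 0 for
# unrelated pairs.


def loiselle_pairs(dosage1: np.ndarray, dosage2: np.ndarray,
                   p: np.ndarray) -> np.ndarray:
    """Vectorized Loiselle kinship for paired dosage arrays.

    ``dosage1``/``dosage2`` have shape (n_pairs, n_loci) with -1 for
    missing; ``p`` gives the reference allele-2 frequency per locus.
    Monomorphic loci contribute nothing.  Returns one estimate per pair
    (NaN where a pair shares no informative called loci).
    """
    d1 = np.asarray(dosage1, dtype=float)
    d2 = np.asarray(dosage2, dtype=float)
    ok = (d1 != MISSING) & (d2 != MISSING) & (p > 0) & (p < 1)
    x1 = d1 / 2.0 - p
    x2 = d2 / 2.0 - p
    num = np.where(ok, 2.0 * x1 * x2, 0.0).sum(axis=1)
    den = np.where(ok, 2.0 * p * (1.0 - p), 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship estimates; the diagonal is not reported."""

    estimates: pd.DataFrame
    reference: AlleleFrequencyTable
    n_shared_loci: pd.DataFrame

    def pair(self, a: str, b: str) -> float:
        return float(self.estimates.at[a, b])

    def to_tsv(self, path) -> None:
        self.estimates.to_csv(path, sep="\t")


def loiselle_kinship(gm: GenotypeMatrix,
                     freqs: AlleleFrequencyTable | None = None) -> KinshipMatrix:
    """All-pairs Loiselle kinship for a genotype matrix.

    Reference frequencies default to those computed from ``gm`` itself (the
    usual convention of population-genetics software), in which case the
    per-locus small-sample bias correction is applied; pass external
    ``freqs`` to use fixed reference frequencies instead.
    """
    internal = freqs is None
    if internal:
        freqs = gm.allele_frequencies()
    else:
        missing = [l for l in gm.locus_ids if l not in set(freqs.locus_ids)]
        if missing:
            raise ValueError(f"reference frequencies missing for loci: {missing[:5]}")
        freqs = freqs.subset(gm.locus_ids)
    p = freqs.p_allele2
    called = gm.dosage != MISSING
    with np.errstate(invalid="ignore"):
        informative = (p > 0) & (p < 1) & ~np.isnan(p)
    p = np.nan_to_num(p)  # NaN frequencies only occur at uninformative loci

    if internal:
        n_called = called.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            bias = np.where(n_called > 1,
                            2.0 * p * (1.0 - p) / (2.0 * n_called - 1.0), 0.0)
    else:
        bias = np.zeros_like(p)

    x = gm.dosage / 2.0 - p  # deviations; missing/uninformative cells zeroed below
    x = np.where(called & informative, x, 0.0)
    w = np.where(informative, 1.0, 0.0)
    m = called.astype(float) * w  # sample x locus usable indicator

    # numerator: sum over loci usable in both pair members of 2*x_i*x_j + bias
    num = 2.0 * (x * w) @ x.T + (m * bias * w) @ m.T
    den = (m * (2.0 * p * (1.0 - p)) * w) @ m.T
    shared = (m @ m.T).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = num / den
    est[den == 0] = np.nan
    np.fill_diagonal(est, np.nan)  # self-kinship not reported
    ids = gm.sample_ids
    return KinshipMatrix(
        estimates=pd.DataFrame(est, index=ids, columns=ids),
        reference=freqs,
        n_shared_loci=pd.DataFrame(shared, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# Unique-genotype clustering (genetic mark-recapture)
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Pairwise match decisions and the resulting individual clusters."""

    decisions: pd.DataFrame
    clusters: list[list[str]]
    n_unique: int
    match_tolerance: float
    min_overlap: int
    p_id: float
    p_idsib: float


def cluster_individuals(gm: GenotypeMatrix, match_tolerance: float = 0.02,
                        min_overlap: int = 50,
                        linkage: str = "single") -> ClusterResult:
    """Collapse samples into unique multilocus genotypes.

    Two samples match (decision ``same_individual``) when they share at
    least ``min_overlap`` called loci and disagree at a fraction of them no
    greater than ``match_tolerance``; pairs with insufficient overlap are
    ``undetermined``.  Matching samples are merged by single-linkage
    (default) or complete-linkage over the match graph; the cluster count is
    the unique-genotype (minimum census) estimate.  The empirical
    cumulative P_ID / P_IDsib of the locus set is reported for context.
    """
    if gm.n_samples < 1:
        raise ValueError("need at least one sample")
    if min_overlap > gm.n_loci:
        raise ValueError(f"min_overlap {min_overlap} exceeds locus count {gm.n_loci}")
    from .design import p_id_locus, p_idsib_locus  # late import: avoid cycle

    d = gm.dosage
    called = d != MISSING
    n = gm.n_samples
    rows = []
    same = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            n_comp = int(both.sum())
            n_mm = int((d[i, both] != d[j, both]).sum())
            rate = n_mm / n_comp if n_comp else np.nan
            if n_comp < min_overlap:
                decision = "undetermined"
            elif rate <= match_tolerance:
                decision = "same_individual"
                same[i, j] = same[j, i] = True
            else:
                decision = "different"
            rows.append({"sample_a": gm.sample_ids[i], "sample_b": gm.sample_ids[j],
                         "n_compared": n_comp, "n_mismatches": n_mm,
                         "mismatch_rate": rate, "decision": decision})
    decisions = pd.DataFrame(rows)

    if linkage == "single":
        n_comp_graph, labels = connected_components(csr_matrix(same), directed=False)
    elif linkage == "complete":
        labels = _complete_linkage(same)
        n_comp_graph = labels.max() + 1
    else:
        raise ValueError("linkage must be 'single' or 'complete'")
    clusters = [[] for _ in range(n_comp_graph)]
    for s, lab in zip(gm.sample_ids, labels):
        clusters[lab].append(s)
    clusters = [sorted(c) for c in clusters]

    p = gm.allele_frequencies().p_minor
    p = p[~np.isnan(p)]
    p_id = float(np.prod(p_id_locus(p))) if p.size else 1.0
    p_idsib = float(np.prod(p_idsib_locus(p))) if p.size else 1.0
    return ClusterResult(decisions=decisions, clusters=clusters,
                         n_unique=len(clusters), match_tolerance=match_tolerance,
                         min_overlap=min_overlap, p_id=p_id, p_idsib=p_idsib)


def _complete_linkage(same: np.ndarray) -> np.ndarray:
    # greedy complete-linkage: every member of a cluster must match every other
    n = same.shape[0]
    labels = np.full(n, -1, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = nxt
        for j in range(i + 1, n):
            if labels[j] < 0 and all(same[j, k] for k in np.nonzero(labels == nxt)[0]):
                labels[j] = nxt
        nxt += 1
    return labels


# ---------------------------------------------------------------------------
# Sex assignment (supervised naive Bayes over genotype classes)
# ---------------------------------------------------------------------------

@dataclass
class SexModel:
    """Per-locus genotype-class frequencies for each sex, pseudocounted.

    ``class_probs[sex]`` is a (n_loci x 3) frame of P(genotype class | sex)
    estimated from known-sex training individuals with a pseudocount of 0.5
    per class, so unseen classes keep non-zero likelihood.
    """

    class_probs: dict[str, pd.DataFrame]
    locus_ids: list[str]
    pseudocount: float = 0.5


def fit_sex_model(training: GenotypeMatrix, sex: pd.Series,
                  pseudocount: float = 0.5) -> SexModel:
    """Estimate per-sex genotype-class frequencies at the panel's sex loci."""
    sex = sex.loc[training.sample_ids]
    present = set(sex.unique())
    if not {"male", "female"} <= present:
        raise ValueError(f"training set must contain both sexes, got {sorted(present)}")
    probs = {}
    for s in ("female", "male"):
        sub = training.dosage[(sex == s).to_numpy(), :]
        rows = []
        for j in range(training.n_loci):
            col = sub[:, j]
            col = col[col != MISSING]
            counts = np.array([(col == g).sum() for g in (0, 1, 2)], dtype=float)
            rows.append((counts + pseudocount) / (counts.sum() + 3 * pseudocount))
        probs[s] = pd.DataFrame(rows, index=pd.Index(training.locus_ids, name="locus_id"),
                                columns=[0, 1, 2])
    return SexModel(class_probs=probs, locus_ids=list(training.locus_ids),
                    pseudocount=pseudocount)


def assign_sex(gm: GenotypeMatrix, model: SexModel,
               posterior_cutoff: float = 0.9) -> pd.DataFrame:
    """Assign sex per sample from its called sex-locus genotypes.

    Equal priors; posterior over {male, female} is the product of per-locus
    class likelihoods over called loci.  A sample is called when the
    winning posterior reaches ``posterior_cutoff``; samples with no called
    sex locus are ``unassigned``.
    """
    loci = [l for l in model.locus_ids if l in set(gm.locus_ids)]
    if not loci:
        raise ValueError("genotype matrix shares no loci with the sex model")
    sub = gm.subset_loci(loci)
    logp = {s: np.log(model.class_probs[s].loc[loci].to_numpy()) for s in ("female", "male")}
    rows = []
    for i, sample in enumerate(sub.sample_ids):
        d = sub.dosage[i]
        called = d != MISSING
        n_inf = int(called.sum())
        if n_inf == 0:
            rows.append({"sample_id": sample, "p_male": np.nan,
                         "call": "unassigned", "n_informative_loci": 0})
            continue
        ll = {}
        for s in ("female", "male"):
            ll[s] = np.log(0.5) + logp[s][called, d[called]].sum()
        shift = max(ll.values())
        pf, pm = np.exp(ll["female"] - shift), np.exp(ll["male"] - shift)
        p_male = pm / (pm + pf)
        if p_male >= posterior_cutoff:
            call = "male"
        elif (1.0 - p_male) >= posterior_cutoff:
            call = "female"
        else:
            call = "unassigned"
        rows.append({"sample_id": sample, "p_male": p_male, "call": call,
                     "n_informative_loci": n_inf})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Mark-recapture summary
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6_371_000.0


def _haversine_m(lat1, lon1, lat2, lon2) -> float:
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(h)))


def mark_recapture_summary(clusters: ClusterResult | list[list[str]],
                           coordinates: pd.DataFrame | None = None,
                           mode: str = "euclidean") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual capture counts and between-capture distances.

    ``coordinates`` (optional) is indexed by sample with columns ``x``/``y``
    (mode='euclidean', metres) or ``lat``/``lon`` (mode='haversine').
    Returns ``(individuals, distances)``; distances is empty when no
    coordinates are supplied.
    """
    members = clusters.clusters if isinstance(clusters, ClusterResult) else clusters
    ind_rows = []
    dist_rows = []
    for k, samples in enumerate(members):
        ind_id = f"IND{k + 1:03d}"
        ind_rows.append({"individual_id": ind_id, "n_captures": len(samples),
                         "samples": ",".join(samples)})
        if coordinates is None or len(samples) < 2:
            continue
        for a_i in range(len(samples)):
            for b_i in range(a_i + 1, len(samples)):
                a, b = samples[a_i], samples[b_i]
                if a not in coordinates.index or b not in coordinates.index:
                    continue
                ca, cb = coordinates.loc[a], coordinates.loc[b]
                if mode == "euclidean":
                    dist = float(np.hypot(ca["x"] - cb["x"], ca["y"] - cb["y"]))
                elif mode == "haversine":
                    dist = _haversine_m(ca["lat"], ca["lon"], cb["lat"], cb["lon"])
                else:
                    raise ValueError("mode must be 'euclidean' or 'haversine'")
                dist_rows.append({"individual_id": ind_id, "sample_a": a,
                                  "sample_b": b, "distance_m": dist})
    individuals = pd.DataFrame(ind_rows)
    distances = pd.DataFrame(dist_rows, columns=["individual_id", "sample_a",
                                                 "sample_b", "distance_m"])
    return individuals, distances
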