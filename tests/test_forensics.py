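"""Kinship estimation, unique-genotype clustering, sexing, mark-recapture."""

import numpy as np
import pandas as pd
import pytest

from panelforge.datatypes import MISSING, RELATIONSHIPS, AlleleFrequencyTable, GenotypeMatrix
from panelforge.forensics import (
    assign_sex,
    cluster_individuals,
    fit_sex_model,
    loiselle_kinship,
    loiselle_pairs,
    mark_recapture_summary,
)
from panelforge.synthetic import (
    draw_frequency_spectrum,
    simulate_dyads,
    simulate_population_genotypes,
    simulate_sex_loci,
)


def _uniform_freqs(p, n):
    return AlleleFrequencyTable.from_minor([f"l{i}" for i in range(n)], [p] * n)


# ---------------------------------------------------------------------------
# Loiselle kinship
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cat", ["PO", "FS", "HS", "FC", "UR"])
def test_dyad_kinship_recovers_expected_coefficient(cat):
    freqs = _uniform_freqs(0.3, 500)
    d1, d2 = simulate_dyads(freqs, cat, 300, seed=31)
    est = loiselle_pairs(d1, d2, freqs.p_allele2)
    expected = RELATIONSHIPS[cat].expected_kinship
    se = est.std(ddof=1) / np.sqrt(est.size)
    assert abs(est.mean() - expected) <= 3 * se


def test_kinship_matrix_symmetric_with_unreported_diagonal():
    freqs = draw_frequency_spectrum(100, "high", seed=32)
    gm = simulate_population_genotypes(freqs, 12, seed=33)
    kin = loiselle_kinship(gm)
    est = kin.estimates.to_numpy()
    assert np.isnan(np.diag(est)).all()
    off = ~np.eye(len(est), dtype=bool)
    np.testing.assert_allclose(est[off], est.T[off], atol=1e-12)


def test_unrelated_population_kinship_centers_on_zero():
    freqs = draw_frequency_spectrum(400, "high", seed=34)
    gm = simulate_population_genotypes(freqs, 40, seed=35)
    kin = loiselle_kinship(gm)  # internal frequencies, bias-corrected
    vals = kin.estimates.to_numpy()
    vals = vals[~np.isnan(vals)]
    assert abs(vals.mean()) < 0.01


def test_pair_without_shared_loci_flagged_absent():
    dosage = np.array([[0, 1, MISSING, MISSING],
                       [MISSING, MISSING, 1, 2]], dtype=np.int16)
    gm = GenotypeMatrix(dosage, ["a", "b"], [f"l{i}" for i in range(4)])
    freqs = _uniform_freqs(0.4, 4)
    kin = loiselle_kinship(gm, freqs)
    assert np.isnan(kin.pair("a", "b"))
    assert kin.n_shared_loci.at["a", "b"] == 0


def test_external_frequencies_must_cover_all_loci():
    gm = GenotypeMatrix(np.zeros((2, 2), dtype=np.int16), ["a", "b"], ["x", "y"])
    with pytest.raises(ValueError, match="missing"):
        loiselle_kinship(gm, _uniform_freqs(0.3, 1))


# ---------------------------------------------------------------------------
# Unique-genotype clustering
# ---------------------------------------------------------------------------

def test_identical_samples_form_one_cluster():
    freqs = draw_frequency_spectrum(200, "high", seed=36)
    gm = simulate_population_genotypes(freqs, 1, seed=37)
    dup = GenotypeMatrix(np.vstack([gm.dosage, gm.dosage]), ["a", "b"],
                         gm.locus_ids)
    res = cluster_individuals(dup, match_tolerance=0.02, min_overlap=50)
    assert res.n_unique == 1 and res.clusters == [["a", "b"]]


def test_zero_tolerance_splits_on_single_discordance():
    freqs = draw_frequency_spectrum(100, "high", seed=38)
    gm = simulate_population_genotypes(freqs, 1, seed=39)
    other = gm.dosage.copy()
    other[0, 0] = (other[0, 0] + 1) % 3
    dup = GenotypeMatrix(np.vstack([gm.dosage, other]), ["a", "b"], gm.locus_ids)
    assert cluster_individuals(dup, 0.0, 50).n_unique == 2
    assert cluster_individuals(dup, 0.02, 50).n_unique == 1


def test_cluster_count_invariant_to_sample_order():
    freqs = draw_frequency_spectrum(150, "high", seed=40)
    gm = simulate_population_genotypes(freqs, 10, seed=41)
    res = cluster_individuals(gm, 0.02, 50)
    rev = gm.subset_samples(list(reversed(gm.sample_ids)))
    res_rev = cluster_individuals(rev, 0.02, 50)
    assert res.n_unique == res_rev.n_unique
    assert sorted(map(tuple, res.clusters)) == sorted(map(tuple, res_rev.clusters))


def test_unique_count_monotone_in_tolerance():
    rng = np.random.default_rng(42)
    freqs = draw_frequency_spectrum(200, "high", seed=43)
    base = simulate_population_genotypes(freqs, 6, seed=44)
    # three noisy copies of each individual
    rows, ids = [], []
    for rep in range(3):
        noisy = base.dosage.copy()
        flip = rng.random(noisy.shape) < 0.01
        noisy[flip] = (noisy[flip] + 1) % 3
        rows.append(noisy)
        ids += [f"i{k}_rep{rep}" for k in range(6)]
    gm = GenotypeMatrix(np.vstack(rows), ids, freqs.locus_ids)
    counts = [cluster_individuals(gm, tol, 50).n_unique
              for tol in (0.0, 0.01, 0.02, 0.05, 0.2)]
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] <= 6


def test_field_sample_reenactment_recovers_true_individual_count():
    """33 degraded fecal samples drawn from 20 individuals collapse back to
    20 unique genotypes under the default matching rule."""
    rng = np.random.default_rng(7)
    freqs = draw_frequency_spectrum(200, "high", seed=45)
    inds = simulate_population_genotypes(freqs, 20, seed=46)
    owners = list(range(20)) + list(rng.integers(0, 20, 13))
    dosage = inds.dosage[owners].copy()
    drop = rng.random(dosage.shape) < 0.14          # field-feces dropout scale
    dosage[drop] = MISSING
    flip = (rng.random(dosage.shape) < 0.0025) & ~drop  # ~0.5% pair discordance
    dosage[flip] = (dosage[flip] + 1) % 3
    gm = GenotypeMatrix(dosage, [f"fec{i:02d}" for i in range(33)], freqs.locus_ids)
    res = cluster_individuals(gm, match_tolerance=0.02, min_overlap=50)
    assert res.n_unique == 20


def test_min_overlap_validation_and_undetermined():
    gm = GenotypeMatrix(np.zeros((2, 10), dtype=np.int16), ["a", "b"],
                        [f"l{i}" for i in range(10)])
    with pytest.raises(ValueError, match="min_overlap"):
        cluster_individuals(gm, 0.02, min_overlap=11)
    sparse = gm.dosage.copy()
    sparse[0, 5:] = MISSING
    sparse[1, :5] = MISSING
    gm2 = GenotypeMatrix(sparse, ["a", "b"], gm.locus_ids)
    res = cluster_individuals(gm2, 0.02, min_overlap=3)
    assert res.decisions.iloc[0]["decision"] == "undetermined"
    assert res.n_unique == 2


# ---------------------------------------------------------------------------
# Sex assignment
# ---------------------------------------------------------------------------

def _split_cohort(gm, sex, n_train_per_sex):
    females = [s for s in gm.sample_ids if sex[s] == "female"]
    males = [s for s in gm.sample_ids if sex[s] == "male"]
    train = females[:n_train_per_sex] + males[:n_train_per_sex]
    test = [s for s in gm.sample_ids if s not in set(train)]
    return train, test


def test_fixed_difference_loci_give_certain_calls():
    gm, sex, _ = simulate_sex_loci(7, differential=1.0, n_males=20, n_females=20, seed=47)
    train, test = _split_cohort(gm, sex, 10)
    model = fit_sex_model(gm.subset_samples(train), sex)
    res = assign_sex(gm.subset_samples(test), model, posterior_cutoff=0.9)
    assert (res["call"] == sex.loc[test]).all()
    certainty = np.maximum(res["p_male"], 1 - res["p_male"])
    assert (certainty > 0.99).all()


def test_sex_assignment_perfect_across_seeds_at_fixed_difference():
    for seed in range(20):
        gm, sex, _ = simulate_sex_loci(7, 1.0, n_males=15, n_females=15, seed=seed)
        train, test = _split_cohort(gm, sex, 7)
        model = fit_sex_model(gm.subset_samples(train), sex)
        res = assign_sex(gm.subset_samples(test), model, 0.9)
        assert (res["call"] == sex.loc[test]).all()


def test_sample_missing_all_sex_loci_is_unassigned():
    gm, sex, _ = simulate_sex_loci(7, 1.0, n_males=10, n_females=10, seed=48)
    dosage = gm.dosage.copy()
    dosage[0, :] = MISSING
    gm2 = GenotypeMatrix(dosage, gm.sample_ids, gm.locus_ids)
    model = fit_sex_model(gm, sex)
    res = assign_sex(gm2, model, 0.9)
    assert res.iloc[0]["call"] == "unassigned"
    assert res.iloc[0]["n_informative_loci"] == 0


def test_field_cohort_sex_tally_reenactment():
    """A 9-female / 11-male cohort at 7 near-diagnostic loci is sexed
    perfectly, reproducing the tally by construction."""
    gm, sex, _ = simulate_sex_loci(7, differential=0.9, n_males=11 + 20,
                                   n_females=9 + 20, seed=49)
    train, test = _split_cohort(gm, sex, 20)
    assert len(test) == 20
    model = fit_sex_model(gm.subset_samples(train), sex)
    res = assign_sex(gm.subset_samples(test), model, 0.9)
    assert (res["call"] == sex.loc[test]).all()
    assert res["call"].value_counts().to_dict() == {"male": 11, "female": 9}


def test_training_set_must_contain_both_sexes():
    gm, sex, _ = simulate_sex_loci(5, 1.0, n_males=5, n_females=5, seed=50)
    males = [s for s in gm.sample_ids if sex[s] == "male"]
    with pytest.raises(ValueError, match="both sexes"):
        fit_sex_model(gm.subset_samples(males), sex)


# ---------------------------------------------------------------------------
# Mark-recapture summary
# ---------------------------------------------------------------------------

def test_singleton_cluster_has_one_capture_no_distances():
    individuals, distances = mark_recapture_summary([["a"]])
    assert individuals.iloc[0]["n_captures"] == 1
    assert distances.empty


def test_identical_coordinates_give_zero_distance():
    coords = pd.DataFrame({"x": [10.0, 10.0], "y": [5.0, 5.0]}, index=["a", "b"])
    _, distances = mark_recapture_summary([["a", "b"]], coords)
    assert distances.iloc[0]["distance_m"] == 0.0


def test_euclidean_distance_three_four_five():
    coords = pd.DataFrame({"x": [0.0, 300.0], "y": [0.0, 400.0]}, index=["a", "b"])
    _, distances = mark_recapture_summary([["a", "b"]], coords)
    assert distances.iloc[0]["distance_m"] == pytest.approx(500.0)


def test_haversine_mode_scales_with_latitude_offset():
    # 0.01 degrees of latitude is ~1111.9 m on the reference sphere
    coords = pd.DataFrame({"lat": [52.0, 52.01], "lon": [-131.0, -131.0]},
                          index=["a", "b"])
    _, distances = mark_recapture_summary([["a", "b"]], coords, mode="haversine")
    assert distances.iloc[0]["distance_m"] == pytest.approx(1111.95, rel=0.01)


def test_missing_coordinates_omit_distances():
    coords = pd.DataFrame({"x": [0.0], "y": [0.0]}, index=["a"])
    individuals, distances = mark_recapture_summary([["a", "b"]], coords)
    assert individuals.iloc[0]["n_captures"] == 2
    assert distances.empty
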