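"""Allele counting, ratio calling, technical-run merging, panel health."""

import numpy as np
import pandas as pd
import pytest

from panelforge.datatypes import AmpliconPanel, revcomp
from panelforge.genotyper import (
    GenotypeCallReport,
    call_genotypes,
    count_alleles,
    merge_technical_runs,
    primer_interaction_scan,
    primer_overrepresentation,
    read_fastq,
    reports_to_matrix,
)


def _toy_panel():
    return AmpliconPanel(pd.DataFrame([
        {"locus_id": "L1", "fwd_primer": "ACGTACGTACGTAAA",
         "probe_allele1": "TTTTATTTT", "probe_allele2": "TTTTGTTTT"},
        {"locus_id": "L2", "fwd_primer": "GGGTTTCCCAAAGGG",
         "probe_allele1": "CCCCACCCC", "probe_allele2": "CCCCTCCCC"},
    ]))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def test_read_with_primer_and_probe_counts_one_allele():
    panel = _toy_panel()
    reads = ["ACGTACGTACGTAAA" + "TTTTATTTT" + "GG"]
    rep = count_alleles(reads, panel)
    assert rep.per_locus.at["L1", "count_a1"] == 1
    assert rep.per_locus.at["L1", "count_a2"] == 0
    assert rep.per_locus.at["L2", "count_a1"] == 0
    assert rep.on_target_fraction == 1.0


def test_empty_read_set_counts_zero():
    rep = count_alleles([], _toy_panel())
    assert (rep.per_locus[["count_a1", "count_a2"]] == 0).all().all()
    assert rep.on_target_fraction == 0.0 and rep.total_reads == 0


def test_primer_without_probe_counts_depth_diagnostics_only():
    panel = _toy_panel()
    rep = count_alleles(["ACGTACGTACGTAAA" + "GGGGGGGGG"], panel)
    assert rep.per_locus.at["L1", "primer_reads"] == 1
    assert rep.per_locus.at["L1", "depth"] == 0
    assert rep.on_target_fraction == 0.0


def test_counts_match_simulator_ledger_exactly(clean_sim):
    _, truth, panel, sim = clean_sim
    ledger = sim.ledger.set_index(["sample_id", "locus_id"])
    for sample in truth.sample_ids[:3]:
        rep = count_alleles(sim.reads[sample], panel, sample_id=sample)
        for locus in panel.locus_ids:
            assert rep.per_locus.at[locus, "count_a1"] == ledger.at[(sample, locus), "count_a1"]
            assert rep.per_locus.at[locus, "count_a2"] == ledger.at[(sample, locus), "count_a2"]


def test_counts_invariant_to_read_order(clean_sim):
    _, truth, panel, sim = clean_sim
    sample = truth.sample_ids[0]
    rep = count_alleles(sim.reads[sample], panel)
    shuffled = list(sim.reads[sample])
    np.random.default_rng(1).shuffle(shuffled)
    rep2 = count_alleles(shuffled, panel)
    pd.testing.assert_frame_equal(rep.per_locus, rep2.per_locus)


def test_count_conservation(clean_sim):
    _, truth, panel, sim = clean_sim
    rep = count_alleles(sim.reads[truth.sample_ids[0]], panel)
    assert (rep.per_locus["depth"] <= rep.per_locus["primer_reads"]).all()


def _naive_scan(reads, panel):
    """Scan-all-substring-positions oracle, independent of `in`-based matching."""
    counts = {l: [0, 0] for l in panel.locus_ids}
    for seq in reads:
        for locus in panel.locus_ids:
            primer = panel.primer(locus)
            found = any(seq[i:i + len(primer)] == primer
                        for i in range(len(seq) - len(primer) + 1))
            if not found:
                continue
            for k, probe in enumerate(panel.probes(locus)):
                if any(seq[i:i + len(probe)] == probe
                       for i in range(len(seq) - len(probe) + 1)):
                    counts[locus][k] += 1
                    break
    return counts


def test_matching_agrees_with_naive_substring_oracle(clean_sim):
    _, truth, panel, sim = clean_sim
    reads = sim.reads[truth.sample_ids[0]][:1000]
    rep = count_alleles(reads, panel)
    oracle = _naive_scan(reads, panel)
    for locus in panel.locus_ids:
        assert rep.per_locus.at[locus, "count_a1"] == oracle[locus][0]
        assert rep.per_locus.at[locus, "count_a2"] == oracle[locus][1]


def test_malformed_fastq_rejected(tmp_path):
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\nplus-line-missing\n")
    with pytest.raises(ValueError, match="malformed FASTQ"):
        read_fastq(bad)


# ---------------------------------------------------------------------------
# Ratio calling
# ---------------------------------------------------------------------------

def _counts_report(a1, a2):
    df = pd.DataFrame({"count_a1": [a1], "count_a2": [a2],
                       "depth": [a1 + a2], "primer_reads": [a1 + a2]},
                      index=pd.Index(["L1"], name="locus_id"))
    return GenotypeCallReport("s", df, a1 + a2, 1.0)


@pytest.mark.parametrize("a1,a2,expected", [
    (100, 2, "hom1"),     # ratio 50 >= 10
    (2, 100, "hom2"),     # ratio 0.02 <= 0.1
    (40, 38, "het"),      # ratio ~1.05 in [0.2, 5]
    (5, 4, "missing"),    # depth 9 below the gate
    (30, 0, "hom1"),      # floored denominator: ratio 300
    (80, 10, "missing"),  # ratio 8: ambiguous gap between het band and hom
])
def test_ratio_caller_thresholds(a1, a2, expected):
    called = call_genotypes(_counts_report(a1, a2), min_depth=10)
    assert called.per_locus.at["L1", "call"] == expected


def test_caller_parameters_are_logged():
    called = call_genotypes(_counts_report(50, 50), min_depth=5, hom_ratio=20)
    assert called.params["min_depth"] == 5
    assert called.params["hom_ratio"] == 20
    assert called.params["ratio_floor"] == 0.1


# ---------------------------------------------------------------------------
# Technical-run merging
# ---------------------------------------------------------------------------

def test_merge_with_empty_run_is_identity():
    rep = _counts_report(12, 3)
    empty = _counts_report(0, 0)
    empty.total_reads = 0
    merged = merge_technical_runs(rep, empty)
    pd.testing.assert_frame_equal(merged.per_locus, rep.per_locus)


def test_merge_is_commutative():
    a, b = _counts_report(5, 7), _counts_report(2, 1)
    m1 = merge_technical_runs(a, b).per_locus
    m2 = merge_technical_runs(b, a).per_locus
    pd.testing.assert_frame_equal(m1, m2)


def test_merge_rescues_undercovered_locus():
    r1, r2 = _counts_report(3, 3), _counts_report(3, 3)
    assert call_genotypes(r1, min_depth=10).per_locus.at["L1", "call"] == "missing"
    merged = merge_technical_runs(r1, r2)
    assert call_genotypes(merged, min_depth=10).per_locus.at["L1", "call"] == "het"


def test_merge_rejects_mismatched_inputs():
    other = _counts_report(1, 1)
    other.sample_id = "other"
    with pytest.raises(ValueError, match="different samples"):
        merge_technical_runs(_counts_report(1, 1), other)
    diff_panel = _counts_report(1, 1)
    diff_panel.per_locus = diff_panel.per_locus.rename(index={"L1": "LX"})
    with pytest.raises(ValueError, match="different panels"):
        merge_technical_runs(_counts_report(1, 1), diff_panel)


# ---------------------------------------------------------------------------
# Round trip: noiseless reads -> true genotypes
# ---------------------------------------------------------------------------

def test_noiseless_round_trip_recovers_all_genotypes(clean_sim):
    _, truth, panel, sim = clean_sim
    reports = [call_genotypes(count_alleles(sim.reads[s], panel, sample_id=s))
               for s in truth.sample_ids]
    called = reports_to_matrix(reports, panel)
    assert (called.dosage == truth.dosage).all()


# ---------------------------------------------------------------------------
# Panel health
# ---------------------------------------------------------------------------

def test_uniform_panel_has_no_overrepresented_primers(clean_sim):
    _, truth, panel, sim = clean_sim
    pooled = [r for s in truth.sample_ids for r in sim.reads[s]]
    health = primer_overrepresentation(pooled, panel)
    assert health.flagged_primers == []
    assert health.primer_fractions.between(0, 1).all()


def test_hogging_primer_is_flagged():
    panel = _toy_panel()
    # L1 takes half the reads in a panel whose uniform share would be 1/2;
    # use an explicit threshold representing a 100-locus panel's 10x rule
    reads = ["ACGTACGTACGTAAATTTTATTTT"] * 50 + ["T" * 24] * 50
    health = primer_overrepresentation(reads, panel, flag_threshold=10 / 100)
    assert health.flagged_primers == ["L1"]


def test_no_primer_matches_yields_zero_fractions():
    health = primer_overrepresentation(["T" * 30] * 5, _toy_panel())
    assert (health.primer_fractions == 0).all()


def test_primer_dimer_reads_reported_at_exact_fraction():
    panel = _toy_panel()
    dimer = panel.primer("L1") + revcomp(panel.primer("L2"))
    clean = panel.primer("L1") + "TTTTATTTT"
    reads = [dimer] * 5 + [clean] * 95
    health = primer_interaction_scan(reads, panel)
    assert health.artifact_fraction == pytest.approx(0.05)
    pair = health.pair_fractions.iloc[0]
    assert {pair["primer_a"], pair["primer_b"]} == {"L1", "L2"}
    assert pair["fraction"] == pytest.approx(0.05)
    assert health.flagged_pairs == [("L1", "L2")]


def test_clean_simulation_has_no_artifacts(clean_sim):
    _, truth, panel, sim = clean_sim
    health = primer_interaction_scan(sim.reads[truth.sample_ids[0]], panel)
    assert health.artifact_fraction == 0.0


def test_legitimate_amplicon_never_counted_as_artifact():
    panel = _toy_panel()
    # contains both primers but also a probe -> real amplicon, not a dimer
    read = panel.primer("L1") + panel.primer("L2") + "TTTTATTTT"
    health = primer_interaction_scan([read], panel)
    assert health.artifact_fraction == 0.0
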