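"""Authenticity screens: homopolymer filter, damage profile, overlap MAF,
replicate concordance."""

import json
import math

import numpy as np
import pytest
from scipy import stats as sps

from ancientmt import (
    VariantCall,
    apply_variants,
    call_consensus,
    compare_replicates,
    damage_profile,
    filter_homopolymer_indels,
    flag_damage_ambiguous,
    generate_reference,
    mutate_haplotype,
    overlap_site_spectra,
    pairwise_diff,
    pileup,
    simulate_reads,
)
from ancientmt.consensus import AlignedRead, ColumnCounts
from ancientmt.reference import ReferenceGenome
from ancientmt.simulate import SimTruth
from ancientmt.variants import left_normalize
from conftest import (
    ledger_mismatch_expectation,
    plant_clean_indel,
    run_chain,
    simulate_chain,
)


def make_ref(seq: str) -> ReferenceGenome:
    return ReferenceGenome(id="toy", sequence=seq)


# ------------------------------------------------------- homopolymer filter

def test_deletion_at_end_of_long_run_is_removed():
    ref = make_ref("CGT" + "A" * 6 + "CGTCGTCG")
    v = VariantCall(position=9, ref_allele="A", alt_allele="-")  # last A of run
    kept, removed = filter_homopolymer_indels([v], ref, run_threshold=5)
    assert removed == [v] and kept == []


def test_deletion_in_run_of_exactly_five_is_kept():
    ref = make_ref("CGT" + "A" * 5 + "CGTCGTCGT")
    v = VariantCall(position=8, ref_allele="A", alt_allele="-")
    kept, removed = filter_homopolymer_indels([v], ref, run_threshold=5)
    assert kept == [v] and removed == []


def test_insertion_next_to_short_c_run_is_kept():
    # mirrors the retained "+C" insertion next to a C-run of length <= 5
    ref = make_ref("ATG" + "C" * 4 + "ATGATGATG")
    v = VariantCall(position=7, ref_allele="-", alt_allele="C")
    kept, removed = filter_homopolymer_indels([v], ref, run_threshold=5)
    assert kept == [v] and removed == []


def test_substitutions_are_never_removed():
    ref = make_ref("CG" + "A" * 10 + "CGTCGTCG")
    subs = [VariantCall(position=p, ref_allele="A", alt_allele="G")
            for p in range(3, 13)]
    kept, removed = filter_homopolymer_indels(subs, ref, run_threshold=5)
    assert kept == subs and removed == []


def test_out_of_range_variant_is_an_error():
    ref = make_ref("ACGTACGTACGT")
    with pytest.raises(ValueError):
        filter_homopolymer_indels(
            [VariantCall(position=99, ref_allele="A", alt_allele="-")], ref)


def test_filter_removes_simulated_artifacts_and_keeps_true_indel():
    """At moderate depth, consensus-level homopolymer artifacts are
    removed while the planted true indel survives; artifacts escaping the
    run->5 rule can only sit at runs of 5 or shorter (which the rule
    keeps by definition)."""
    n_artifacts = n_removed = n_true_kept = 0
    for seed in range(10):
        ref = generate_reference(1500, homopolymer_boost=6, seed=seed)
        panel_kwargs = dict(n_amplicons=12, n_sets=4, seed=seed)
        from ancientmt import design_panel

        panel = design_panel(ref, **panel_kwargs)
        true_indel, truth_seq = plant_clean_indel(ref)
        truth = SimTruth(
            truth_sequence=truth_seq, planted_variants=[true_indel],
            damage_rate=0.0, seq_error_rate=0.0,
            homopolymer_indel_base_rate=0.12,
            depth_log_median=math.log(20), depth_log_sigma=0.3,
            seed=seed + 500,
        )
        reads, _ = simulate_reads(panel, truth)
        _, _, _, cons = run_chain(reads, ref, panel)
        diffs = pairwise_diff(ref.sequence, cons.sequence)
        tnorm = left_normalize(true_indel, ref.sequence)
        tkey = (tnorm.position, tnorm.ref_allele, tnorm.alt_allele)
        indels = [v for v in diffs.variants if v.kind != "substitution"]
        artifacts = [v for v in indels
                     if (v.position, v.ref_allele, v.alt_allele) != tkey]
        kept, removed = filter_homopolymer_indels(diffs.variants, ref, 5)
        n_artifacts += len(artifacts)
        n_removed += sum((v.position, v.ref_allele, v.alt_allele) != tkey
                        for v in removed)
        n_true_kept += any((v.position, v.ref_allele, v.alt_allele) == tkey
                           for v in kept)
        for v in kept:  # anything kept besides the true indel sits at a short run
            key = (v.position, v.ref_allele, v.alt_allele)
            if v.kind != "substitution" and key != tkey:
                allele = v.alt_allele if v.kind == "insertion" else v.ref_allele
                s = ref.sequence
                p = v.position - 1
                run = 1
                q = p - 1
                while q >= 0 and s[q] == allele[0]:
                    run += 1
                    q -= 1
                q = p + 1
                while q < len(s) and s[q] == allele[0]:
                    run += 1
                    q += 1
                assert run <= 5
    assert n_true_kept == 10
    assert n_artifacts >= 5  # the error model does create artifacts
    assert n_removed >= 0.9 * n_artifacts


# ----------------------------------------------------------- damage profile

def test_clean_pileup_has_no_mismatches(clean_chain):
    dp = damage_profile(clean_chain["counts"], clean_chain["consensus"],
                        n_bootstrap=0)
    assert dp.type1_count == 0 and dp.type2_count == 0
    assert dp.ratio is None


def test_constructed_counts_give_printed_style_ratio():
    counts = ColumnCounts(2)
    for i in range(300):
        counts.add(AlignedRead(f"c{i}", "amp001", start=1, bases="CA"))
    for i in range(158):  # type II: consensus C read as T
        counts.add(AlignedRead(f"t{i}", "amp001", start=1, bases="TA"))
    for i in range(100):  # type I: consensus A read as G
        counts.add(AlignedRead(f"g{i}", "amp001", start=2, bases="G"))
    cons = call_consensus(counts)
    dp = damage_profile(counts, cons, n_bootstrap=200, seed=1)
    assert (dp.type2_count, dp.type1_count) == (158, 100)
    assert dp.ratio == pytest.approx(1.58)
    lo, hi = dp.ratio_ci
    assert lo < 1.58 < hi


@pytest.mark.parametrize("depth_median", [10, 30, 90])
def test_damage_ratio_tracks_ledger_truth_at_three_depths(depth_median):
    ref, panel, truth, reads, ledger = simulate_chain(
        length=3000, n_amplicons=24, seed=40 + depth_median,
        depth_log_median=math.log(depth_median), depth_log_sigma=0.3,
        damage_rate=0.03, seq_error_rate=0.002,
    )
    _, _, counts, cons = run_chain(reads, ref, panel)
    dp = damage_profile(counts, cons, n_bootstrap=0)
    exp1, exp2 = ledger_mismatch_expectation(ledger)
    assert dp.ratio is not None and dp.ratio > 1
    # counted events agree with the ledger within 3 SE (plus a small
    # allowance for consensus miscalls at the lowest depth)
    tol2 = 3 * math.sqrt(exp2) + 0.01 * exp2 + 5
    tol1 = 3 * math.sqrt(max(exp1, 1)) + 0.01 * exp1 + 5
    assert abs(dp.type2_count - exp2) <= tol2
    assert abs(dp.type1_count - exp1) <= tol1


def test_empty_counts_rejected():
    with pytest.raises(ValueError):
        damage_profile(ColumnCounts(5), None)


# ------------------------------------------------------ damage-flag triage

def test_weakly_supported_damage_substitutions_are_flagged():
    flagged = flag_damage_ambiguous([
        VariantCall(100, "C", "T", support=0.54),
        VariantCall(200, "C", "T", support=0.58),
        VariantCall(300, "C", "T", support=1.00),
        VariantCall(400, "A", "C", support=0.55),
        VariantCall(500, "G", "A", support=0.60),
    ], support_threshold=0.75)
    assert [v.position for v in flagged] == [100, 200, 500]


def test_flag_threshold_must_exceed_half():
    with pytest.raises(ValueError):
        flag_damage_ambiguous([], support_threshold=0.4)


# ------------------------------------------------------- overlap spectra

def _contamination_run(contamination, seed):
    ref = generate_reference(3000, seed=seed)
    from ancientmt import design_panel

    panel = design_panel(ref, n_amplicons=24, n_sets=4, seed=seed)
    truth_seq, planted = mutate_haplotype(ref, 3, 0, seed=seed)
    contaminant, cvars = mutate_haplotype(ref, 30, 0, seed=seed + 70)
    truth = SimTruth(
        truth_sequence=truth_seq, planted_variants=planted,
        damage_rate=0.0, seq_error_rate=0.002, homopolymer_indel_base_rate=0.0,
        contamination_fraction=contamination, contaminant_sequence=contaminant,
        depth_log_median=math.log(40), depth_log_sigma=0.3, seed=seed + 7,
    )
    reads, ledger = simulate_reads(panel, truth)
    _, _, counts, cons = run_chain(reads, ref, panel)
    modern = {f"m{k}": mutate_haplotype(ref, 16, 0, seed=seed + 200 + k)[0]
              for k in range(8)}
    modern["lineage_of_contaminant"] = contaminant
    report = overlap_site_spectra(counts, panel, modern, maf_threshold=0.02)
    return ref, panel, cvars, report


def test_no_contamination_null_flags_almost_nothing():
    _, _, _, report = _contamination_run(0.0, seed=31)
    assert report.n_polymorphic_flagged <= 2
    # flag rates at monomorphic vs polymorphic sites are indistinguishable
    mono_high = sum(report.site_maf[p] > 0.02 for p, c in report.site_class.items()
                    if c == "monomorphic")
    table = [
        [report.n_polymorphic_flagged,
         report.n_polymorphic - report.n_polymorphic_flagged],
        [mono_high, report.n_monomorphic - mono_high],
    ]
    assert sps.fisher_exact(table)[1] > 0.01


def test_ten_percent_contamination_shows_up_at_informative_sites():
    ref, panel, cvars, report = _contamination_run(0.10, seed=31)
    informative = ({v.position for v in cvars}
                   & {int(p) for p in panel.overlap_sites(ref.length)})
    mafs = [report.site_maf[p] for p in informative if p in report.site_maf]
    assert len(mafs) >= 5
    assert np.mean(mafs) == pytest.approx(0.10, abs=0.04)
    flagged_informative = sum(m > 0.02 for m in mafs)
    assert flagged_informative >= 0.8 * len(mafs)


def test_report_summary_mirrors_published_phrasing():
    _, _, _, report = _contamination_run(0.0, seed=32)
    import re

    assert re.fullmatch(
        r"\d+ out of \d+ polymorphic sites with rare allele > 2% \(max .*%\)",
        report.summary(),
    )


def test_modern_panel_length_mismatch_rejected(clean_chain):
    with pytest.raises(ValueError):
        overlap_site_spectra(clean_chain["counts"], clean_chain["panel"],
                             {"bad": "ACGT"}, 0.02)


# --------------------------------------------------- replicate concordance

def test_identical_replicates_are_fully_concordant(clean_chain):
    cons = clean_chain["consensus"]
    rep = compare_replicates(cons, cons)
    assert rep.concordance == 1.0 and rep.n_mismatch == 0


def test_planted_discordance_is_located():
    ref, panel, truth, reads, _ = simulate_chain(seed=3)
    _, _, _, cons_a = run_chain(reads, ref, panel)
    import copy

    cons_b = copy.deepcopy(cons_a)
    p = 700
    cons_b.calls[p - 1] = "A" if cons_b.calls[p - 1] != "A" else "G"
    rep = compare_replicates(cons_a, cons_b)
    assert [m[0] for m in rep.mismatches] == [p]


def test_independent_simulations_agree_at_called_sites():
    ref, panel, truth, reads, _ = simulate_chain(
        seed=4, damage_rate=0.02, depth_log_median=math.log(25),
    )
    _, _, _, cons_a = run_chain(reads, ref, panel)
    truth_b = SimTruth(
        truth_sequence=truth.truth_sequence,
        planted_variants=truth.planted_variants,
        damage_rate=0.02, seq_error_rate=0.0, homopolymer_indel_base_rate=0.0,
        depth_log_median=math.log(25), depth_log_sigma=0.3, seed=4242,
    )
    reads_b, _ = simulate_reads(panel, truth_b)
    _, _, _, cons_b = run_chain(reads_b, ref, panel)
    rep = compare_replicates(cons_a, cons_b)
    assert rep.concordance == 1.0


def test_disjoint_frames_rejected(clean_chain):
    cons = clean_chain["consensus"]
    import copy

    other = copy.deepcopy(cons)
    other.calls = other.calls[:-10]
    with pytest.raises(ValueError):
        compare_replicates(cons, other)
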