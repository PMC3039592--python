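"""End-to-end driver: simulate -> consensus -> authenticate -> compare -> QC/date.

Each stage logs read conservation and writes its artifacts; the whole run
is summarized in one JSON report. The same seed and config produce a
byte-identical report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import authenticate as auth
from . import compare as cmp
from . import consensus as cns
from . import io as amtio
from . import qcdate
from .config import CALIBRATIONS, RunConfig
from .panel import AmpliconPanel, design_panel
from .qcdate import CalibratedRates, DatedSample
from .reference import generate_reference
from .simulate import (
    SimTruth,
    mutate_haplotype,
    simulate_modern_panel,
    simulate_reads,
)

log = logging.getLogger("ancientmt")

#: Canonical preservation inputs used when a run supplies no measured
#: values: a dilution series on the published curve shape, replicate Cts
#: around ~5000 copies, and low D/L ratios typical of a well-preserved bone.
DEFAULT_QPCR_POINTS = [(10.0**k, 45.34 - 3.391 * k) for k in range(1, 6)]
DEFAULT_QPCR_REPLICATE_COPIES = [4200.0, 5100.0, 6100.0]
DEFAULT_DL = {"aspartic_acid": 0.05, "alanine": 0.03, "glutamine": 0.04}
DEFAULT_DATES = [("R1333", 11300.0, 150.0), ("Ly3415", 11600.0, 130.0)]


def attach_support(variants, consensus: cns.ConsensusResult) -> None:
    for v in variants:
        if v.kind == "substitution" and 1 <= v.position <= len(consensus.calls):
            s = consensus.per_site_support[v.position - 1]
            v.support = None if np.isnan(s) else float(s)


def consensus_stage(reads, ref, panel: AmpliconPanel, config: RunConfig):
    assigned = cns.assign_reads(reads, panel, config.primer_mismatches)
    masked = cns.mask_reads(assigned, panel)
    counts = cns.pileup(masked, ref, panel, min_identity=config.min_identity)
    result = cns.call_consensus(counts, min_depth=config.min_depth)
    result.low_coverage_amplicons = cns.flag_low_coverage(
        counts, panel, config.low_coverage_threshold
    )
    rep = assigned.assignment_report
    log.info(
        "consensus: %d reads = %d assigned + %d unassigned + %d ambiguous; %d excluded in pileup",
        rep["total"], rep["assigned"], rep["unassigned"],
        rep["dropped_ambiguous"], counts.n_excluded,
    )
    return assigned, counts, result


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    # ---- simulate ----------------------------------------------------
    ref = generate_reference(config.genome_length, seed=config.seed)
    panel_obj = design_panel(
        ref,
        insert_range=(config.insert_min, config.insert_max),
        min_overlap=config.min_overlap,
        n_amplicons=config.n_amplicons,
        n_sets=config.n_sets,
        seed=config.seed,
    )
    truth_seq, planted = mutate_haplotype(
        ref, config.n_substitutions, config.n_indels, seed=config.seed
    )
    contaminant = ""
    if config.contamination_fraction > 0:
        contaminant, _ = mutate_haplotype(
            ref, max(1, config.genome_length // 100), 0, seed=config.seed + 101
        )
    truth = SimTruth(
        truth_sequence=truth_seq,
        planted_variants=planted,
        damage_rate=config.damage_rate,
        seq_error_rate=config.seq_error_rate,
        homopolymer_indel_base_rate=config.homopolymer_indel_base_rate,
        contamination_fraction=config.contamination_fraction,
        contaminant_sequence=contaminant,
        depth_log_median=config.depth_log_median,
        depth_log_sigma=config.depth_log_sigma,
        seed=config.seed,
    )
    reads, ledger = simulate_reads(panel_obj, truth)
    n_endo = int((ledger["source"] == "endogenous").sum())
    report["stages"]["simulate"] = {
        "n_reads": len(reads),
        "n_endogenous": n_endo,
        "n_contaminant": len(reads) - n_endo,
        "n_amplicons": len(panel_obj),
        "genome_length": ref.length,
        "planted_variants": len(planted),
    }
    log.info("simulate: %d reads over %d amplicons", len(reads), len(panel_obj))
    amtio.write_fasta({ref.id: ref.sequence, "truth": truth_seq}, out / "reference.fasta")
    amtio.write_panel_tsv(panel_obj, out / "panel.tsv")
    ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)
    if config.write_reads:
        amtio.write_fastq(reads, out / "reads.fastq")

    # ---- consensus ---------------------------------------------------
    assigned, counts, consensus = consensus_stage(reads, ref, panel_obj, config)
    depth = counts.depth
    report["stages"]["consensus"] = {
        "assignment": {k: v for k, v in assigned.assignment_report.items()
                       if k != "dropped"},
        "mean_depth": consensus.mean_depth,
        "median_depth": consensus.median_depth,
        "mean_support": consensus.mean_support,
        "n_ambiguous_positions": len(consensus.ambiguous_positions),
        "n_low_coverage_amplicons": len(consensus.low_coverage_amplicons),
        "consensus_length": len(consensus.sequence),
        "n_uncovered_positions": int((depth == 0).sum()),
    }
    amtio.write_fasta({"consensus": consensus.sequence}, out / "consensus.fasta")
    amtio.write_persite_tsv(counts, consensus, out / "per_site.tsv")

    # ---- authenticate ------------------------------------------------
    diffs = cmp.pairwise_diff(ref.sequence, consensus.sequence,
                              seq_a_id=ref.id, seq_b_id="consensus")
    attach_support(diffs.variants, consensus)
    kept, removed = auth.filter_homopolymer_indels(diffs.variants, ref,
                                                   config.run_threshold)
    damage = auth.damage_profile(counts, consensus, seed=config.seed)
    flagged = auth.flag_damage_ambiguous(kept, config.support_threshold)
    modern_panel = simulate_modern_panel(
        ref, n_genomes=config.modern_panel_size,
        mean_substitutions=config.modern_panel_substitutions,
        seed=config.seed + 200,
    )
    spectra_panel = dict(modern_panel)
    if contaminant:
        spectra_panel["contaminant"] = contaminant
    overlap = auth.overlap_site_spectra(counts, panel_obj, spectra_panel,
                                        config.maf_threshold)
    concordance = None
    if config.replicate_amplicons > 0:
        sub = AmpliconPanel(
            reference_id=panel_obj.reference_id,
            amplicons=panel_obj.amplicons[: config.replicate_amplicons],
        )
        truth_rep = SimTruth(
            truth_sequence=truth.truth_sequence,
            planted_variants=truth.planted_variants,
            damage_rate=truth.damage_rate,
            seq_error_rate=truth.seq_error_rate,
            homopolymer_indel_base_rate=truth.homopolymer_indel_base_rate,
            contamination_fraction=truth.contamination_fraction,
            contaminant_sequence=truth.contaminant_sequence,
            depth_log_median=truth.depth_log_median,
            depth_log_sigma=truth.depth_log_sigma,
            seed=truth.seed + 1,
        )
        rep_reads, _ = simulate_reads(sub, truth_rep)
        _, rep_counts, rep_consensus = consensus_stage(rep_reads, ref, sub, config)
        intervals = [(a.insert_start, min(a.insert_end, ref.length)) for a in sub]
        concordance = auth.compare_replicates(consensus, rep_consensus, intervals)
    report["stages"]["authenticate"] = {
        "variants_vs_reference": len(diffs.variants),
        "homopolymer_artifacts_removed": len(removed),
        "variants_kept": len(kept),
        "damage": damage.summary(),
        "damage_flagged_positions": [v.position for v in flagged],
        "overlap_screen": {
            "n_overlap_sites": overlap.n_overlap_sites,
            "n_polymorphic": overlap.n_polymorphic,
            "n_polymorphic_flagged": overlap.n_polymorphic_flagged,
            "max_observed_maf": overlap.max_observed_maf,
            "summary": overlap.summary(),
        },
        "replicate_concordance": (
            None if concordance is None else {
                "compared": concordance.n_compared,
                "mismatches": concordance.n_mismatch,
                "concordance": concordance.concordance,
            }
        ),
    }
    # ---- compare -----------------------------------------------------
    kept_diffs = cmp.DiffSet(seq_a_id=ref.id, seq_b_id="consensus",
                             variants=kept, compared_length=diffs.compared_length)
    classes = cmp.classify_variants(kept_diffs)
    partition = cmp.partition_by_region(kept_diffs, ref)
    amtio.write_vcf(kept, ref, out / "variants.vcf")
    distances = cmp.panel_distance_summary(consensus.sequence, modern_panel,
                                           within_panel=True)
    truth_check = cmp.pairwise_diff(truth.truth_sequence, consensus.sequence,
                                    seq_a_id="truth", seq_b_id="consensus")
    report["stages"]["compare"] = {
        "classification": classes,
        "region_partition": partition,
        "panel_distances": {
            "mean": distances.mean, "min": distances.min, "max": distances.max,
            "within_mean": distances.within_mean,
            "within_min": distances.within_min, "within_max": distances.within_max,
            "formatted": distances.format(),
        },
        "percent_distance_vs_reference": kept_diffs.percent_distance,
        "consensus_vs_truth_differences": len(truth_check.variants),
    }

    # ---- qc / dating -------------------------------------------------
    curve = qcdate.fit_standard_curve(DEFAULT_QPCR_POINTS)
    rep_cts = [curve.y_intercept + curve.slope * np.log10(c)
               for c in DEFAULT_QPCR_REPLICATE_COPIES]
    copies, copies_sd = qcdate.quantify_replicates(rep_cts, curve)
    preservation = qcdate.racemization_check(DEFAULT_DL)
    preservation.copies_per_reaction = copies
    preservation.copies_sd = copies_sd
    dates = [DatedSample(label, age, sd) for label, age, sd in DEFAULT_DATES]
    mean_date = qcdate.average_dates(dates)
    cal_time, cal_rate = CALIBRATIONS[config.calibration]
    base = CalibratedRates(calibration_time=cal_time, rate=cal_rate)
    rates = {
        name: qcdate.calibrate_rate(base, t).rate
        for name, (t, _) in sorted(CALIBRATIONS.items())
    }
    rho = qcdate.rho_tmrca(
        {k: v for k, v in modern_panel.items()},
        ref.sequence,
        base,
    )
    # nucleotide diversity of the modern panel -> effective size
    seqs = list(modern_panel.values())
    pair_d = [
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i in range(len(seqs)) for j in range(i + 1, len(seqs))
    ]
    theta = (np.mean(pair_d) / ref.length) if pair_d else 0.0
    ne = qcdate.theta_to_ne(float(theta), base, config.generation_time) if theta > 0 else None
    report["stages"]["qc_dating"] = {
        "standard_curve": {
            "slope": curve.slope, "y_intercept": curve.y_intercept,
            "r_squared": curve.r_squared, "efficiency": curve.efficiency,
        },
        "copies_per_reaction": copies,
        "copies_sd": copies_sd,
        "preservation_pass": preservation.overall_pass,
        "racemization": preservation.acid_pass,
        "caveat": preservation.caveat,
        "mean_age_bp": mean_date.age,
        "mean_age_sd": mean_date.sd,
        "calibrated_rates": rates,
        "rho": {"rho": rho.rho, "age": rho.age,
                "lower": rho.age_lower, "upper": rho.age_upper},
        "theta_per_site": float(theta),
        "effective_size": ne,
    }
    report["qc_verdict"] = "pass" if preservation.overall_pass else "fail"
    amtio.write_json_report(report, out / "report.json")
    return report
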