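"""Authenticate the consensus: damage typing, homopolymer filtering,
overlap-site contamination screen, replicate concordance.

Recomputes the pileup from the stored reads, then runs the three
authenticity analyses and a 16-amplicon replication experiment with an
independent simulated sequencing run of the same truth.
"""

from pathlib import Path

from ancientmt import RunConfig, SimTruth, simulate_modern_panel, simulate_reads
from ancientmt import authenticate as auth
from ancientmt import compare as cmp
from ancientmt import io as amtio
from ancientmt.panel import AmpliconPanel
from ancientmt.pipeline import attach_support, consensus_stage
from ancientmt.reference import ReferenceGenome

SIM_DIR = Path("scratch/analysis")
RES_DIR = Path("results")


def main() -> None:
    cfg = RunConfig.from_yaml(SIM_DIR / "config.yaml")
    fasta = amtio.read_fasta(SIM_DIR / "reference.fasta")
    ref = ReferenceGenome(id="simref", sequence=fasta["simref"])
    panel = amtio.read_panel_tsv(SIM_DIR / "panel.tsv")
    reads = amtio.read_fastq(SIM_DIR / "reads.fastq")
    _, counts, cons = consensus_stage(reads, ref, panel, cfg)

    diffs = cmp.pairwise_diff(ref.sequence, cons.sequence)
    attach_support(diffs.variants, cons)
    kept, removed = auth.filter_homopolymer_indels(diffs.variants, ref,
                                                   cfg.run_threshold)
    damage = auth.damage_profile(counts, cons, seed=cfg.seed)
    flagged = auth.flag_damage_ambiguous(kept, cfg.support_threshold)

    modern = simulate_modern_panel(ref, n_genomes=cfg.modern_panel_size,
                                   mean_substitutions=cfg.modern_panel_substitutions,
                                   seed=cfg.seed + 200)
    overlap = auth.overlap_site_spectra(counts, panel, modern,
                                        cfg.maf_threshold)

    # replicate 16 amplicons in an independent simulated run
    truth_seq = fasta["truth"]
    planted = amtio.read_vcf(SIM_DIR / "truth_variants.vcf")
    sub = AmpliconPanel(reference_id=panel.reference_id,
                        amplicons=panel.amplicons[:cfg.replicate_amplicons])
    rep_truth = SimTruth(truth_sequence=truth_seq, planted_variants=planted,
                         seed=cfg.seed + 1)
    rep_reads, _ = simulate_reads(sub, rep_truth)
    _, _, rep_cons = consensus_stage(rep_reads, ref, sub, cfg)
    intervals = [(a.insert_start, min(a.insert_end, ref.length)) for a in sub]
    concord = auth.compare_replicates(cons, rep_cons, intervals)

    report = {
        "variants_vs_reference": len(diffs.variants),
        "homopolymer_artifacts_removed": len(removed),
        "variants_kept": len(kept),
        "damage": damage.summary(),
        "damage_flagged_positions": [v.position for v in flagged],
        "overlap_screen": overlap.summary(),
        "overlap_sites": overlap.n_overlap_sites,
        "replicate_concordance": concord.concordance,
        "replicate_mismatches": concord.mismatches,
    }
    amtio.write_json_report(report, RES_DIR / "03_authentication.json")
    ratio = damage.ratio
    print(f"typeII/typeI = {ratio if ratio is None else round(ratio, 2)} "
          f"(CI {damage.ratio_ci}); {overlap.summary()}; "
          f"replicate concordance {concord.concordance:.4f}")


if __name__ == "__main__":
    main()
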