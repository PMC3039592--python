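"""Call the majority-rule consensus from the simulated read set.

Reads the artifacts of 01_simulate_reads.py, assigns reads by their
primer termini, masks primers, aligns inserts to amplicon windows, and
calls the most frequent base per position. Reports coverage statistics
and the amplicons that would be re-pooled (< 10 reads).
"""

from pathlib import Path

from ancientmt import RunConfig
from ancientmt import io as amtio
from ancientmt.pipeline import consensus_stage
from ancientmt.reference import ReferenceGenome

SIM_DIR = Path("scratch/analysis")
RES_DIR = Path("results")


def main() -> None:
    cfg = RunConfig.from_yaml(SIM_DIR / "config.yaml")
    fasta = amtio.read_fasta(SIM_DIR / "reference.fasta")
    ref = ReferenceGenome(id="simref", sequence=fasta["simref"])
    panel = amtio.read_panel_tsv(SIM_DIR / "panel.tsv")
    reads = amtio.read_fastq(SIM_DIR / "reads.fastq")

    assigned, counts, cons = consensus_stage(reads, ref, panel, cfg)
    amtio.write_fasta({"consensus": cons.sequence}, SIM_DIR / "consensus.fasta")
    amtio.write_persite_tsv(counts, cons, SIM_DIR / "per_site.tsv")

    truth = fasta["truth"]
    summary = {
        "mapped_fraction": assigned.assignment_report["mapped_fraction"],
        "mean_depth": round(cons.mean_depth, 1),
        "median_depth": cons.median_depth,
        "mean_support": round(cons.mean_support, 4),
        "consensus_length": len(cons.sequence),
        "consensus_equals_truth": cons.sequence == truth,
        "ambiguous_positions": cons.ambiguous_positions,
        "low_coverage_amplicons_for_repool": cons.low_coverage_amplicons,
    }
    amtio.write_json_report(summary, RES_DIR / "02_consensus_summary.json")
    print(f"consensus {len(cons.sequence)} bp; equals truth: "
          f"{summary['consensus_equals_truth']}; mean support "
          f"{cons.mean_support:.3f}; {len(cons.low_coverage_amplicons)} "
          f"amplicons below the re-pool threshold")


if __name__ == "__main__":
    main()
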