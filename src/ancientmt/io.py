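"""File formats: FASTA/FASTQ, panel TSV, minimal VCF, TSV/JSON reports.

On-disk interval coordinates are 0-based half-open (BED convention);
everything in memory is 1-based inclusive. The conversion happens here
and only here. JSON output is deterministic: keys sorted, floats rounded
to 10 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ColumnCounts, ConsensusResult, Read, ReadSet
from .panel import Amplicon, AmpliconPanel
from .reference import ReferenceGenome
from .variants import VariantCall

PANEL_COLUMNS = ["chrom", "start0", "end", "amplicon_id", "set_label",
                 "fwd_primer", "rev_primer"]


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> ReadSet:
    reads = [Read(read_id=rec.id, sequence=str(rec.seq).upper())
             for rec in SeqIO.parse(str(path), "fastq")]
    return ReadSet(reads=reads)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------- panel TSV

def write_panel_tsv(panel: AmpliconPanel, path: str | Path) -> None:
    """BED-like TSV; for origin-wrapping amplicons ``end`` runs past the
    reference length (circular extension) so the record stays one line."""
    rows = [
        {
            "chrom": panel.reference_id,
            "start0": a.start - 1,
            "end": a.end,
            "amplicon_id": a.amplicon_id,
            "set_label": a.set_label,
            "fwd_primer": a.fwd_primer,
            "rev_primer": a.rev_primer,
        }
        for a in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> AmpliconPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel TSV missing columns: {sorted(missing)}")
    amplicons = []
    for i, row in enumerate(df.itertuples(index=False)):
        start = int(row.start0) + 1
        end = int(row.end)
        fwd, rev = str(row.fwd_primer), str(row.rev_primer)
        if end - start + 1 <= len(fwd) + len(rev):
            raise ValueError(f"line {i + 2}: amplicon shorter than its primers")
        amplicons.append(Amplicon(
            amplicon_id=str(row.amplicon_id),
            set_label=str(row.set_label),
            fwd_primer=fwd,
            rev_primer=rev,
            start=start,
            end=end,
            insert_start=start + len(fwd),
            insert_end=end - len(rev),
        ))
    chrom = str(df["chrom"].iloc[0]) if len(df) else ""
    return AmpliconPanel(reference_id=chrom, amplicons=amplicons)


# ---------------------------------------------------------------- minimal VCF

def write_vcf(
    variants: Sequence[VariantCall],
    ref: ReferenceGenome,
    path: str | Path,
) -> None:
    """Minimal VCFv4.2: indels anchored on the previous reference base."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.id},length={ref.length}>",
        '##INFO=<ID=KIND,Number=1,Type=String,Description="substitution/insertion/deletion">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="transition/transversion/indel">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="functional region class">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Float,Description="fraction of reads with the call">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in sorted(variants, key=lambda v: v.position):
        if v.kind == "substitution":
            pos, vr, va = v.position, v.ref_allele, v.alt_allele
        elif v.kind == "insertion":
            if v.position < 1:
                raise ValueError("cannot encode an insertion before position 1 in VCF")
            anchor = ref.sequence[v.position - 1]
            pos, vr, va = v.position, anchor, anchor + v.alt_allele
        else:
            if v.position < 2:
                raise ValueError("cannot encode a deletion at position 1 in VCF")
            anchor = ref.sequence[v.position - 2]
            pos, vr, va = v.position - 1, anchor + v.ref_allele, anchor
        info = [f"KIND={v.kind}", f"CLASS={v.classification}"]
        if v.region_class:
            info.append(f"REGION={v.region_class}")
        if v.support is not None:
            info.append(f"SUPPORT={v.support:.4f}")
        lines.append(f"{ref.id}\t{pos}\t.\t{vr}\t{va}\t.\t.\t{';'.join(info)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Parse a minimal VCF back into calls (anchor bases stripped)."""
    variants: list[VariantCall] = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"malformed VCF record at line {n}")
        pos, vr, va, info_s = int(fields[1]), fields[3], fields[4], fields[7]
        info = dict(kv.split("=", 1) for kv in info_s.split(";") if "=" in kv)
        region = info.get("REGION")
        support = float(info["SUPPORT"]) if "SUPPORT" in info else None
        if len(vr) == 1 and len(va) == 1:
            v = VariantCall(position=pos, ref_allele=vr, alt_allele=va,
                            region_class=region, support=support)
        elif len(va) > len(vr) == 1 and va[0] == vr:
            v = VariantCall(position=pos, ref_allele="-", alt_allele=va[1:],
                            region_class=region, support=support)
        elif len(vr) > len(va) == 1 and vr[0] == va:
            v = VariantCall(position=pos + 1, ref_allele=vr[1:], alt_allele="-",
                            region_class=region, support=support)
        else:
            raise ValueError(f"unsupported allele encoding at line {n}: {vr}>{va}")
        variants.append(v)
    return variants


# ---------------------------------------------------------------- tables/JSON

def write_persite_tsv(counts: ColumnCounts, consensus: ConsensusResult,
                      path: str | Path) -> None:
    depth = counts.depth
    df = pd.DataFrame({
        "pos": np.arange(1, counts.ref_length + 1),
        "depth": depth,
        "A": counts.counts[:, 0],
        "C": counts.counts[:, 1],
        "G": counts.counts[:, 2],
        "T": counts.counts[:, 3],
        "del": counts.counts[:, 4],
        "call": consensus.calls,
        "support": np.round(consensus.per_site_support, 4),
    })
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if f != f or f in (float("inf"), float("-inf")):
            return None
        return float(f"{f:.10g}")
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_tsv_pairs(path: str | Path, col_a: str, col_b: str) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    for col in (col_a, col_b):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return list(zip(df[col_a].astype(float), df[col_b].astype(float)))
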