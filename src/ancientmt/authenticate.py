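"""Authenticity analyses for an ancient amplicon consensus.

Four screens, in the order a sceptical reviewer would apply them:

1. homopolymer indel filtering — pyrosequencing miscounts run lengths, so
   indels touching long homopolymers are treated as platform artifacts;
2. damage-type profiling — genuine ancient templates show an excess of
   type II (C->T / G->A) over type I (A->G / T->C) mismatches among
   reads, the signature of cytosine deamination;
3. overlap-site contamination screening — at sites covered by two
   amplicons, contamination with modern DNA inflates minor-allele
   frequencies specifically at sites polymorphic in the modern panel;
4. replicate concordance — independently generated consensuses must
   agree at every confidently called site.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .consensus import ColumnCounts, ConsensusResult
from .panel import AmpliconPanel
from .reference import ReferenceGenome, homopolymer_runs
from .variants import VariantCall

TYPE1 = (("A", "G"), ("T", "C"))  # consensus base read as...
TYPE2 = (("C", "T"), ("G", "A"))


def filter_homopolymer_indels(
    variants: Sequence[VariantCall],
    ref: ReferenceGenome,
    run_threshold: int = 5,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split variants into (kept, removed_as_artifact).

    An indel is removed iff its inserted/deleted base equals the base of a
    maximal reference homopolymer run of length strictly greater than
    ``run_threshold`` that the indel lies in or immediately flanks.
    Substitutions are never removed.
    """
    runs_by_base: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for s, e, b in homopolymer_runs(ref.sequence):
        if e - s + 1 > run_threshold:
            runs_by_base[b].append((s, e))
    kept: list[VariantCall] = []
    removed: list[VariantCall] = []
    for v in variants:
        if not 0 <= v.position <= ref.length:
            raise ValueError(f"variant position {v.position} outside reference")
        if v.kind == "substitution":
            kept.append(v)
            continue
        allele = v.alt_allele if v.kind == "insertion" else v.ref_allele
        bases = set(allele)
        if len(bases) != 1:
            kept.append(v)  # mixed-base indel: not a run-length miscount
            continue
        base = bases.pop()
        if v.kind == "insertion":
            lo, hi = v.position, v.position + 1
        else:
            lo, hi = v.position, v.position + len(v.ref_allele) - 1
        artifact = any(
            s <= hi + 1 and e >= lo - 1
            for s, e in runs_by_base.get(base, [])
        )
        (removed if artifact else kept).append(v)
    return kept, removed


@dataclass
class DamageProfile:
    matrix: dict[tuple[str, str], int]  # (consensus base, read base) -> count
    type1_count: int
    type2_count: int
    ratio: Optional[float]
    ratio_ci: Optional[tuple[float, float]] = None
    n_read_bases: int = 0

    def summary(self) -> dict:
        return {
            "type1_count": self.type1_count,
            "type2_count": self.type2_count,
            "ratio_type2_type1": self.ratio,
            "ratio_ci95": list(self.ratio_ci) if self.ratio_ci else None,
            "matrix": {f"{a}>{b}": c for (a, b), c in sorted(self.matrix.items())},
        }


def damage_profile(
    counts: ColumnCounts,
    consensus: ConsensusResult,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DamageProfile:
    """Directional mismatch matrix of read bases against the consensus.

    Misincorporation is a read-level deviation from the endogenous
    sequence, so typing is against the consensus, not the mapping
    reference. The type II / type I ratio gets a read-level bootstrap
    interval (the read, not the base, is the resampling unit because
    damage events on one template molecule are not independent).
    """
    if not counts.aligned_reads:
        raise ValueError("empty pileup")
    calls = consensus.calls
    per_read: list[Counter] = []
    matrix: Counter = Counter()
    n_read_bases = 0
    for ar in counts.aligned_reads:
        local: Counter = Counter()
        for pos, ch in counts.positions_of(ar):
            c = calls[pos - 1]
            if c not in "ACGT" or ch not in "ACGT":
                continue
            n_read_bases += 1
            if ch != c:
                local[(c, ch)] += 1
        per_read.append(local)
        matrix.update(local)
    t1 = sum(matrix.get(p, 0) for p in TYPE1)
    t2 = sum(matrix.get(p, 0) for p in TYPE2)
    ratio = (t2 / t1) if t1 > 0 else None
    ci = None
    if ratio is not None and n_bootstrap > 0:
        rng = np.random.default_rng([seed, 0xB007])
        n = len(per_read)
        t1_arr = np.array([sum(c.get(p, 0) for p in TYPE1) for c in per_read])
        t2_arr = np.array([sum(c.get(p, 0) for p in TYPE2) for c in per_read])
        ratios = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            b1 = int(t1_arr[idx].sum())
            if b1 > 0:
                ratios.append(t2_arr[idx].sum() / b1)
        if ratios:
            ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    return DamageProfile(
        matrix=dict(matrix),
        type1_count=t1,
        type2_count=t2,
        ratio=ratio,
        ratio_ci=ci,
        n_read_bases=n_read_bases,
    )


def flag_damage_ambiguous(
    variants: Sequence[VariantCall],
    support_threshold: float = 0.75,
) -> list[VariantCall]:
    """Damage-type consensus substitutions with weak read support.

    A consensus-vs-reference C->T or G->A substitution carried by fewer
    than ``support_threshold`` of the reads is a candidate deamination
    artifact: it is flagged for independent replication (never
    auto-reverted, since a genuine variant can also sit on a damaged
    template).
    """
    if not 0.5 < support_threshold <= 1.0:
        raise ValueError("support_threshold must be in (0.5, 1]")
    flagged = []
    for v in variants:
        if v.kind != "substitution" or v.support is None:
            continue
        if (v.ref_allele, v.alt_allele) in TYPE2 and v.support < support_threshold:
            flagged.append(v)
    return flagged


@dataclass
class OverlapSpectrumReport:
    n_overlap_sites: int
    n_polymorphic: int
    n_monomorphic: int
    n_polymorphic_flagged: int
    max_observed_maf: float
    maf_threshold: float
    site_maf: dict[int, float] = field(default_factory=dict)
    site_class: dict[int, str] = field(default_factory=dict)
    histogram_polymorphic: list[int] = field(default_factory=list)
    histogram_monomorphic: list[int] = field(default_factory=list)
    histogram_bins: list[float] = field(default_factory=list)
    stratified_maf: dict[int, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.n_polymorphic_flagged} out of {self.n_polymorphic} polymorphic "
            f"sites with rare allele > {self.maf_threshold:.0%} "
            f"(max {self.max_observed_maf:.1%})"
        )


def _site_maf(row: np.ndarray) -> float:
    acgt = np.sort(row[:4])[::-1]
    total = acgt.sum()
    return float(acgt[1] / total) if total > 0 else 0.0


def overlap_site_spectra(
    counts: ColumnCounts,
    panel: AmpliconPanel,
    modern_panel: dict[str, str],
    maf_threshold: float = 0.02,
) -> OverlapSpectrumReport:
    """Minor-allele spectra at amplicon-overlap sites.

    Sites are classed monomorphic/polymorphic from the modern genome
    panel (aligned to reference coordinates). Under contamination the
    polymorphic class picks up excess minor-allele frequency; without it
    the two spectra match the sequencing-error null.
    """
    L = counts.ref_length
    for name, seq in modern_panel.items():
        if len(seq) != L:
            raise ValueError(f"modern panel sequence {name} length {len(seq)} != reference {L}")
    sites = panel.overlap_sites(L)
    maf: dict[int, float] = {}
    site_class: dict[int, str] = {}
    seqs = list(modern_panel.values())
    for p in sites:
        row = counts.counts[p - 1]
        if row[:4].sum() == 0:
            continue
        maf[int(p)] = _site_maf(row)
        alleles = {s[p - 1] for s in seqs if s[p - 1] in "ACGT"}
        site_class[int(p)] = "polymorphic" if len(alleles) >= 2 else "monomorphic"
    # per-amplicon stratified MAF at overlap sites, for diagnostics
    per_site_amp: dict[int, dict[str, Counter]] = defaultdict(lambda: defaultdict(Counter))
    overlap_set = set(maf)
    for ar in counts.aligned_reads:
        for pos, ch in counts.positions_of(ar):
            if pos in overlap_set and ch in "ACGT":
                per_site_amp[pos][ar.amplicon_id][ch] += 1
    stratified: dict[int, dict[str, float]] = {}
    for p, by_amp in per_site_amp.items():
        stratified[p] = {}
        for amp_id, cnt in by_amp.items():
            row = np.zeros(5, dtype=np.int64)
            for b, c in cnt.items():
                row["ACGT".index(b)] = c
            stratified[p][amp_id] = _site_maf(row)
    poly = [p for p, c in site_class.items() if c == "polymorphic"]
    mono = [p for p, c in site_class.items() if c == "monomorphic"]
    flagged = [p for p in poly if maf[p] > maf_threshold]
    bins = list(np.linspace(0, 0.5, 26))
    hist_poly = list(np.histogram([maf[p] for p in poly], bins=bins)[0].astype(int))
    hist_mono = list(np.histogram([maf[p] for p in mono], bins=bins)[0].astype(int))
    return OverlapSpectrumReport(
        n_overlap_sites=len(maf),
        n_polymorphic=len(poly),
        n_monomorphic=len(mono),
        n_polymorphic_flagged=len(flagged),
        max_observed_maf=max((maf[p] for p in poly), default=0.0),
        maf_threshold=maf_threshold,
        site_maf=maf,
        site_class=site_class,
        histogram_polymorphic=hist_poly,
        histogram_monomorphic=hist_mono,
        histogram_bins=bins,
        stratified_maf=stratified,
    )


@dataclass
class ConcordanceReport:
    intervals: list[dict]
    n_compared: int
    n_mismatch: int
    mismatches: list[tuple[int, str, str]]

    @property
    def concordance(self) -> float:
        return 1.0 - self.n_mismatch / self.n_compared if self.n_compared else float("nan")


def compare_replicates(
    consensus_a: ConsensusResult,
    consensus_b: ConsensusResult,
    regions: Optional[Sequence[tuple[int, int]]] = None,
) -> ConcordanceReport:
    """Per-interval concordance of two consensuses in the same frame.

    Positions where either replicate called N are not compared (they are
    uninformative, not discordant).
    """
    a, b = consensus_a.calls, consensus_b.calls
    if len(a) != len(b):
        raise ValueError("consensuses are in disjoint coordinate frames")
    if regions is None:
        regions = [(1, len(a))]
    intervals = []
    mismatches: list[tuple[int, str, str]] = []
    total = 0
    for start, end in regions:
        if not (1 <= start <= end <= len(a)):
            raise ValueError(f"interval ({start}, {end}) outside frame")
        n_cmp = n_bad = 0
        for p in range(start, end + 1):
            ca, cb = a[p - 1], b[p - 1]
            if ca == "N" or cb == "N":
                continue
            n_cmp += 1
            if ca != cb:
                n_bad += 1
                mismatches.append((p, ca, cb))
        intervals.append({"start": start, "end": end,
                          "compared": n_cmp, "mismatches": n_bad})
        total += n_cmp
    return ConcordanceReport(
        intervals=intervals,
        n_compared=total,
        n_mismatch=len(mismatches),
        mismatches=mismatches,
    )
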