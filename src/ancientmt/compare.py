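"""Pairwise genome comparison and variant bookkeeping.

Distances are substitution counts by default (indels reported separately),
sites with N in either sequence are excluded pairwise, and indels are
left-normalized so the same physical edit always gets one canonical
coordinate — the conventions under which a mutation table like
"position / ref / alt / region" is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import global_alignment_columns
from .reference import ReferenceGenome
from .variants import VariantCall, apply_variants, left_normalize

__all__ = [
    "DiffSet",
    "pairwise_diff",
    "classify_variants",
    "partition_by_region",
    "panel_distance_summary",
    "PanelDistanceSummary",
    "apply_variants",
]


@dataclass
class DiffSet:
    seq_a_id: str
    seq_b_id: str
    variants: list[VariantCall] = field(default_factory=list)
    compared_length: int = 0

    @property
    def n_substitutions(self) -> int:
        return sum(v.kind == "substitution" for v in self.variants)

    @property
    def n_indels(self) -> int:
        return sum(v.kind != "substitution" for v in self.variants)

    @property
    def percent_distance(self) -> float:
        """Substitutions / compared length x 100 (indels not counted)."""
        if self.compared_length == 0:
            return 0.0
        return self.n_substitutions / self.compared_length * 100.0


def _diff_from_columns(col_a: str, col_b: str, seq_a: str) -> list[VariantCall]:
    variants: list[VariantCall] = []
    a_pos = 0  # last consumed 1-based position of seq_a
    i = 0
    n = len(col_a)
    while i < n:
        ca, cb = col_a[i], col_b[i]
        if ca != "-" and cb != "-":
            a_pos += 1
            if ca != cb and ca in "ACGT" and cb in "ACGT":
                variants.append(VariantCall(position=a_pos, ref_allele=ca, alt_allele=cb))
            i += 1
        elif cb == "-":  # run of deletion relative to seq_a
            j = i
            while j < n and col_b[j] == "-" and col_a[j] != "-":
                j += 1
            deleted = col_a[i:j]
            variants.append(
                left_normalize(
                    VariantCall(position=a_pos + 1, ref_allele=deleted, alt_allele="-"),
                    seq_a,
                )
            )
            a_pos += len(deleted)
            i = j
        else:  # ca == '-': insertion relative to seq_a
            j = i
            while j < n and col_a[j] == "-" and col_b[j] != "-":
                j += 1
            inserted = col_b[i:j]
            variants.append(
                left_normalize(
                    VariantCall(position=a_pos, ref_allele="-", alt_allele=inserted),
                    seq_a,
                )
            )
            i = j
    variants.sort(key=lambda v: (v.position, v.kind))
    return variants


def pairwise_diff(
    seq_a: str,
    seq_b: str,
    aligned: bool = False,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
) -> DiffSet:
    """Enumerate the differences between two sequences, in a-coordinates.

    With ``aligned=True`` the inputs are gapped columns of an existing
    alignment; otherwise a global alignment (unit mismatch, gap open 2,
    extend 1) is computed first. Columns with N on either side are
    excluded from both the variant list and the compared length.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty input sequence")
    if aligned:
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned inputs must have equal column counts")
        col_a, col_b = seq_a, seq_b
    elif seq_a == seq_b:
        col_a, col_b = seq_a, seq_b
    elif len(seq_a) == len(seq_b) and _columnar_ok(seq_a, seq_b):
        col_a, col_b = seq_a, seq_b  # isolated substitutions only: columns as-is
    else:
        col_a, col_b = global_alignment_columns(seq_a, seq_b)
    ungapped_a = col_a.replace("-", "")
    variants = _diff_from_columns(col_a, col_b, ungapped_a)
    len_a = sum(c in "ACGT" for c in col_a)
    len_b = sum(c in "ACGT" for c in col_b)
    return DiffSet(
        seq_a_id=seq_a_id,
        seq_b_id=seq_b_id,
        variants=variants,
        compared_length=min(len_a, len_b),
    )


def _columnar_ok(a: str, b: str, max_mismatch_run: int = 5,
                 min_identity: float = 0.9) -> bool:
    """Equal-length pair safe to walk column-by-column?

    A frameshift (compensating indel pair) shows up as a dense stretch of
    mismatches — long consecutive runs, or many mismatches crowded into a
    short window; isolated substitutions never do. Only the latter may
    skip the global alignment.
    """
    positions = []
    run = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            positions.append(i)
            run += 1
            if run > max_mismatch_run:
                return False
        else:
            run = 0
    for k in range(len(positions) - 7):
        if positions[k + 7] - positions[k] <= 40:  # 8 mismatches within 40 bp
            return False
    return 1.0 - len(positions) / len(a) >= min_identity


def classify_variants(diffs: DiffSet) -> dict[str, int]:
    out = {"transitions": 0, "transversions": 0, "indels": 0}
    for v in diffs.variants:
        c = v.classification
        out["transitions" if c == "transition" else
            "transversions" if c == "transversion" else "indels"] += 1
    return out


def partition_by_region(diffs: DiffSet, ref: ReferenceGenome) -> dict[str, dict]:
    """Distribute variants over {control_region, rRNA+tRNA, protein}.

    Percentages are count / total x 100 to two decimals; unannotated
    positions land in "other" and are reported, not silently dropped.
    """
    combine = {"control_region": "control_region", "rRNA": "rRNA_tRNA",
               "tRNA": "rRNA_tRNA", "protein": "protein", None: "other"}
    tally: dict[str, int] = {"control_region": 0, "rRNA_tRNA": 0, "protein": 0, "other": 0}
    for v in diffs.variants:
        cls = combine[ref.region_at(v.position)]
        v.region_class = cls
        tally[cls] += 1
    total = sum(tally.values())
    return {
        cls: {"count": n, "percent": round(n / total * 100.0, 2) if total else 0.0}
        for cls, n in tally.items()
    }


@dataclass
class PanelDistanceSummary:
    per_genome: dict[str, int]
    mean: float
    min: int
    max: int
    within_mean: Optional[float] = None
    within_min: Optional[int] = None
    within_max: Optional[int] = None

    def format(self) -> str:
        s = f"{self.mean:.1f} sites (range: {self.min} - {self.max})"
        if self.within_mean is not None:
            s += (f"; within panel {self.within_mean:.1f} sites "
                  f"(range: {self.within_min} - {self.within_max})")
        return s


def panel_distance_summary(
    query: str,
    panel: dict[str, str],
    include_indels: bool = False,
    within_panel: bool = False,
) -> PanelDistanceSummary:
    """Substitution-count distances from ``query`` to every panel genome."""
    if not panel:
        raise ValueError("empty genome panel")

    def dist(a: str, b: str) -> int:
        d = pairwise_diff(a, b)
        return d.n_substitutions + (d.n_indels if include_indels else 0)

    per_genome = {name: dist(query, seq) for name, seq in panel.items()}
    values = list(per_genome.values())
    wmean = wmin = wmax = None
    if within_panel and len(panel) >= 2:
        names = list(panel)
        pair_d = [
            dist(panel[names[i]], panel[names[j]])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        wmean = sum(pair_d) / len(pair_d)
        wmin, wmax = min(pair_d), max(pair_d)
    return PanelDistanceSummary(
        per_genome=per_genome,
        mean=sum(values) / len(values),
        min=min(values),
        max=max(values),
        within_mean=wmean,
        within_min=wmin,
        within_max=wmax,
    )
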