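"""Overlapping multiplex-PCR amplicon panels tiling a circular mitogenome.

A panel is a set of primer pairs whose inserts tile the whole circle with a
guaranteed minimum overlap between neighbours. Overlapping amplicons must
sit in different multiplex sets (labelled A, B, C, ...) so that short
overlap products cannot form within one reaction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceGenome, revcomp


@dataclass
class Amplicon:
    amplicon_id: str
    set_label: str
    fwd_primer: str
    rev_primer: str  # as synthesized: reverse complement of the reference 3' end
    start: int  # 1-based, primers included; end may exceed L when wrapping
    end: int
    insert_start: int
    insert_end: int

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start + 1

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AmpliconPanel:
    reference_id: str
    amplicons: list[Amplicon] = field(default_factory=list)

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_id(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def insert_coverage(self, ref_length: int) -> np.ndarray:
        """Number of amplicon inserts covering each reference position."""
        cov = np.zeros(ref_length, dtype=np.int32)
        for a in self.amplicons:
            for p in range(a.insert_start, a.insert_end + 1):
                cov[(p - 1) % ref_length] += 1
        return cov

    def overlap_sites(self, ref_length: int) -> np.ndarray:
        """1-based positions covered by >= 2 amplicon inserts."""
        return np.nonzero(self.insert_coverage(ref_length) >= 2)[0] + 1


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], length: int) -> bool:
    pa = {(p - 1) % length for p in range(a[0], a[1] + 1)}
    for p in range(b[0], b[1] + 1):
        if (p - 1) % length in pa:
            return True
    return False


def design_panel(
    ref: ReferenceGenome,
    insert_range: tuple[int, int] = (155, 230),
    min_overlap: int = 30,
    n_amplicons: int = 130,
    n_sets: int = 4,
    primer_length_range: tuple[int, int] = (18, 25),
    seed: int = 0,
) -> AmpliconPanel:
    """Tile the circle with ``n_amplicons`` overlapping inserts.

    Insert start points are spread evenly; each insert is drawn long enough
    to reach ``min_overlap`` bases into its successor, within
    ``insert_range``. Primers flank the insert and are exact reference
    substrings (the reverse primer reverse-complemented). Set labels are
    assigned greedily (round-robin preference) so that no two overlapping
    amplicons share a set; infeasible requests raise ``ValueError``.
    """
    lo, hi = insert_range
    L = ref.length
    if n_amplicons < 1:
        raise ValueError("need at least one amplicon")
    mean_insert = (lo + hi) / 2
    if n_amplicons * (mean_insert - min_overlap) < L:
        raise ValueError(
            f"infeasible tiling: {n_amplicons} x ({mean_insert} - {min_overlap}) < {L}"
        )
    rng = np.random.default_rng([seed, 0xA3B])
    starts = [int(np.floor(i * L / n_amplicons)) + 1 for i in range(n_amplicons)]
    amplicons: list[Amplicon] = []
    for i, s in enumerate(starts):
        nxt = starts[i + 1] if i + 1 < n_amplicons else L + starts[0]
        need = (nxt - s) + min_overlap  # reach min_overlap into the successor
        if need > hi:
            raise ValueError(
                f"infeasible tiling: insert of {need} bp needed at position {s}, max {hi}"
            )
        ins_len = int(rng.integers(max(lo, need), hi + 1))
        e = s + ins_len - 1
        flen = int(rng.integers(primer_length_range[0], primer_length_range[1] + 1))
        rlen = int(rng.integers(primer_length_range[0], primer_length_range[1] + 1))
        fwd = ref.fetch(s - flen, s - 1)
        rev = revcomp(ref.fetch(e + 1, e + rlen))
        amplicons.append(
            Amplicon(
                amplicon_id=f"amp{i + 1:03d}",
                set_label="",
                fwd_primer=fwd,
                rev_primer=rev,
                start=s - flen,
                end=e + rlen,
                insert_start=s,
                insert_end=e,
            )
        )
    _assign_sets(amplicons, n_sets, L)
    return AmpliconPanel(reference_id=ref.id, amplicons=amplicons)


def _assign_sets(amplicons: list[Amplicon], n_sets: int, length: int) -> None:
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    labels = list(string.ascii_uppercase[:n_sets])
    n = len(amplicons)
    overlaps: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _circ_overlap(amplicons[i].interval(), amplicons[j].interval(), length):
                overlaps[i].add(j)
                overlaps[j].add(i)
    if n_sets == 1 and any(overlaps):
        raise ValueError("overlapping amplicons cannot share the single requested set")
    assignment: list[str] = [""] * n
    # round-robin-preferring depth-first colouring: the preference keeps
    # neighbouring amplicons cycling A,B,C,D; backtracking handles wrap
    # conflicts when the amplicon count is not a multiple of n_sets
    i = 0
    choice_idx = [0] * n
    steps = 0
    while 0 <= i < n:
        steps += 1
        if steps > 200 * n:
            raise ValueError(
                f"cannot tile the panel with {n_sets} sets without a same-set "
                "overlap; increase n_sets"
            )
        placed = False
        for k in range(choice_idx[i], n_sets):
            cand = labels[(i + k) % n_sets]
            if all(assignment[j] != cand for j in overlaps[i]):
                assignment[i] = cand
                choice_idx[i] = k + 1
                placed = True
                break
        if placed:
            i += 1
        else:
            assignment[i] = ""
            choice_idx[i] = 0
            i -= 1
    if i < 0:
        raise ValueError(
            f"cannot tile the panel with {n_sets} sets without a same-set "
            "overlap; increase n_sets"
        )
    for amp, label in zip(amplicons, assignment):
        amp.set_label = label
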