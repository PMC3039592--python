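"""Read assignment, primer masking, pileup and majority-rule consensus.

The calling model is deliberately simple, matching how small amplicon
resequencing studies assemble a mitogenome: each read is identified by the
PCR primer at its terminus, the primers are masked, the insert is aligned
to its amplicon's reference window, and the most frequent base at every
reference position becomes the consensus. Ties and under-covered positions
are emitted as N rather than resolved with ambiguity codes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .align import project_onto_window
from .panel import Amplicon, AmpliconPanel
from .reference import ReferenceGenome, revcomp

BASE_ORDER = "ACGT-"
BASE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class Read:
    read_id: str
    sequence: str
    assigned_amplicon: Optional[str] = None
    strand: Optional[str] = None  # '+' or '-'
    masked: bool = False


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    assignment_report: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class AlignedRead:
    read_id: str
    amplicon_id: str
    start: int  # 1-based ref position of the first window column
    bases: str  # one char per window column: ACGTN or '-' (deletion)
    insertions: list[tuple[int, str]] = field(default_factory=list)  # (after_ref_pos, seq)


class ColumnCounts:
    """Per-reference-position base/indel counts plus the aligned reads.

    Keeping the (compact) aligned reads allows read-level resampling for
    the damage-ratio bootstrap and per-amplicon stratified statistics.
    """

    def __init__(self, ref_length: int):
        self.ref_length = ref_length
        self.counts = np.zeros((ref_length, 5), dtype=np.int64)
        self.insertions: dict[int, Counter] = defaultdict(Counter)
        self.aligned_reads: list[AlignedRead] = []
        self.n_excluded = 0

    def add(self, ar: AlignedRead) -> None:
        L = self.ref_length
        for k, ch in enumerate(ar.bases):
            idx = BASE_IDX.get(ch)
            if idx is None:  # N or other: not counted
                continue
            self.counts[(ar.start - 1 + k) % L, idx] += 1
        for after, seq in ar.insertions:
            self.insertions[(after - 1) % L + 1][seq] += 1
        self.aligned_reads.append(ar)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def positions_of(self, ar: AlignedRead) -> Iterable[tuple[int, str]]:
        L = self.ref_length
        for k, ch in enumerate(ar.bases):
            yield (ar.start - 1 + k) % L + 1, ch


@dataclass
class ConsensusResult:
    sequence: str
    calls: np.ndarray  # per-ref-position call: ACGT, '-' (deleted) or N
    per_site_support: np.ndarray  # fraction of reads carrying the call (nan if none)
    mean_depth: float
    median_depth: float
    mean_support: float
    ambiguous_positions: list[int] = field(default_factory=list)
    called_insertions: dict[int, str] = field(default_factory=dict)
    low_coverage_amplicons: list[str] = field(default_factory=list)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def check_primer_distinguishability(panel: AmpliconPanel, max_mismatches: int) -> None:
    primers = []
    for a in panel:
        primers.append((a.fwd_primer, a.amplicon_id, "+"))
        primers.append((a.rev_primer, a.amplicon_id, "-"))
    for i in range(len(primers)):
        for j in range(i + 1, len(primers)):
            p, q = primers[i][0], primers[j][0]
            n = min(len(p), len(q))
            if _hamming(p[:n], q[:n]) <= 2 * max_mismatches:
                raise ValueError(
                    f"primers of {primers[i][1]}{primers[i][2]} and "
                    f"{primers[j][1]}{primers[j][2]} are not distinguishable "
                    f"at {max_mismatches} mismatches"
                )


def assign_reads(
    reads: ReadSet,
    panel: AmpliconPanel,
    max_primer_mismatches: int = 1,
) -> ReadSet:
    """Assign each read to the amplicon whose primer starts it.

    A read beginning with a forward primer is a '+' strand read; one
    beginning with a (synthesized) reverse primer is '-'. Ambiguous reads
    (two primers match) are dropped; non-matching reads stay unassigned
    and are excluded downstream. The mapped fraction is reported in
    ``assignment_report``.
    """
    check_primer_distinguishability(panel, max_primer_mismatches)
    exact: dict[str, tuple[str, str]] = {}
    by_length: dict[int, list[tuple[str, str, str]]] = defaultdict(list)
    for a in panel:
        exact[a.fwd_primer] = (a.amplicon_id, "+")
        exact[a.rev_primer] = (a.amplicon_id, "-")
        by_length[len(a.fwd_primer)].append((a.fwd_primer, a.amplicon_id, "+"))
        by_length[len(a.rev_primer)].append((a.rev_primer, a.amplicon_id, "-"))
    lengths = sorted(by_length)
    out: list[Read] = []
    n_assigned = n_unassigned = n_ambiguous = 0
    dropped: list[tuple[str, str]] = []
    for r in reads:
        hits: list[tuple[str, str]] = []
        for l in lengths:
            hit = exact.get(r.sequence[:l])
            if hit is not None:
                hits.append(hit)
        if not hits and max_primer_mismatches > 0:
            for l in lengths:
                prefix = r.sequence[:l]
                for primer, amp_id, strand in by_length[l]:
                    if len(prefix) == l and _hamming(prefix, primer) <= max_primer_mismatches:
                        hits.append((amp_id, strand))
        uniq = set(hits)
        if len(uniq) == 1:
            amp_id, strand = uniq.pop()
            out.append(replace(r, assigned_amplicon=amp_id, strand=strand))
            n_assigned += 1
        elif len(uniq) == 0:
            out.append(replace(r, assigned_amplicon=None, strand=None))
            n_unassigned += 1
        else:
            dropped.append((r.read_id, "ambiguous primer match"))
            n_ambiguous += 1
    total = len(reads)
    report = {
        "total": total,
        "assigned": n_assigned,
        "unassigned": n_unassigned,
        "dropped_ambiguous": n_ambiguous,
        "mapped_fraction": n_assigned / total if total else 0.0,
        "dropped": dropped,
    }
    return ReadSet(reads=out, assignment_report=report)


def mask_primers(read: Read, amplicon: Amplicon) -> Read:
    """Strip the primer-length prefix and suffix from an assigned read."""
    if read.assigned_amplicon is None or read.strand is None:
        raise ValueError(f"read {read.read_id} is not assigned")
    flen, rlen = len(amplicon.fwd_primer), len(amplicon.rev_primer)
    lead, trail = (flen, rlen) if read.strand == "+" else (rlen, flen)
    if len(read.sequence) <= lead + trail:
        raise ValueError(f"read {read.read_id} shorter than its primers")
    return replace(read, sequence=read.sequence[lead : len(read.sequence) - trail], masked=True)


def mask_reads(reads: ReadSet, panel: AmpliconPanel) -> ReadSet:
    """Mask every assigned read; too-short reads are dropped with a reason."""
    amps = {a.amplicon_id: a for a in panel}
    out, dropped = [], []
    for r in reads:
        if r.assigned_amplicon is None:
            continue
        try:
            out.append(mask_primers(r, amps[r.assigned_amplicon]))
        except ValueError as exc:
            dropped.append((r.read_id, str(exc)))
    report = dict(reads.assignment_report)
    report["dropped_too_short"] = dropped
    return ReadSet(reads=out, assignment_report=report)


def pileup(
    reads: ReadSet,
    ref: ReferenceGenome,
    panel: AmpliconPanel,
    min_identity: float = 0.7,
) -> ColumnCounts:
    """Align masked inserts to their amplicon windows and accumulate counts.

    Reverse-strand reads are reverse-complemented into reference
    orientation before counting. Reads aligning below ``min_identity`` are
    excluded as exogenous and tallied in ``n_excluded``.
    """
    amps = {a.amplicon_id: a for a in panel}
    counts = ColumnCounts(ref.length)
    for r in reads:
        if r.assigned_amplicon is None or not r.masked:
            continue
        amp = amps[r.assigned_amplicon]
        window = ref.fetch(amp.insert_start, amp.insert_end)
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        proj = project_onto_window(seq, window)
        if proj.identity < min_identity:
            counts.n_excluded += 1
            continue
        counts.add(
            AlignedRead(
                read_id=r.read_id,
                amplicon_id=amp.amplicon_id,
                start=ref.normalize(amp.insert_start),
                bases="".join(proj.bases),
                insertions=[
                    (ref.normalize(amp.insert_start + off - 1), seq_ins)
                    for off, seq_ins in proj.insertions
                    if off > 0  # an insertion before the window has no anchor
                ],
            )
        )
    return counts


def call_consensus(
    counts: ColumnCounts,
    min_depth: int = 1,
    tie_policy: str = "N",
) -> ConsensusResult:
    """Majority-rule consensus over the pileup.

    At each position with depth >= ``min_depth`` the most frequent symbol
    among {A, C, G, T, deletion} is called; a winning deletion suppresses
    the position; an insertion is emitted when its count exceeds half the
    local depth. Exact ties and under-covered positions are called N (the
    only supported ``tie_policy``).
    """
    if tie_policy != "N":
        raise ValueError("only tie_policy='N' is supported")
    L = counts.ref_length
    depth = counts.depth
    if L == 0 or int(depth.sum()) == 0:
        raise ValueError("empty pileup: no aligned bases")
    calls = np.full(L, "N", dtype="<U1")
    support = np.full(L, np.nan)
    ambiguous: list[int] = []
    top_ins: dict[int, str] = {}
    for pos, cnt in counts.insertions.items():
        seq_ins, c = cnt.most_common(1)[0]
        if depth[pos - 1] > 0 and c > depth[pos - 1] / 2:
            top_ins[pos] = seq_ins
    pieces: list[str] = []
    for p in range(L):
        d = int(depth[p])
        if d >= min_depth and d > 0:
            row = counts.counts[p]
            best = int(row.max())
            winners = [BASE_ORDER[i] for i in range(5) if row[i] == best]
            if len(winners) > 1:
                calls[p] = "N"
                ambiguous.append(p + 1)
            else:
                calls[p] = winners[0]
                support[p] = best / d
        if calls[p] != "-":
            pieces.append(calls[p])
        if (p + 1) in top_ins:
            pieces.append(top_ins[p + 1])
    covered = support[~np.isnan(support)]
    return ConsensusResult(
        sequence="".join(pieces),
        calls=calls,
        per_site_support=support,
        mean_depth=float(depth.mean()),
        median_depth=float(np.median(depth)),
        mean_support=float(covered.mean()) if covered.size else float("nan"),
        ambiguous_positions=ambiguous,
        called_insertions=top_ins,
    )


def flag_low_coverage(
    counts: ColumnCounts,
    panel: AmpliconPanel,
    threshold: int = 10,
) -> list[str]:
    """Amplicons with strictly fewer than ``threshold`` aligned reads.

    These are the candidates for a re-pool and a second sequencing round.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    per_amp = Counter(ar.amplicon_id for ar in counts.aligned_reads)
    return [a.amplicon_id for a in panel if per_amp.get(a.amplicon_id, 0) < threshold]
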