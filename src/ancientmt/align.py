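"""Global alignment of amplicon inserts against their reference window.

Because every read is pre-assigned to an amplicon, mapping reduces to a
global alignment of the masked insert against a known ~200 bp reference
window (unit mismatch cost, affine gaps: open 2, extend 1). Reads that are
substitution-only are projected without dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


@dataclass
class Projection:
    """A query projected onto reference-window coordinates."""

    bases: list[str]  # one char per window position: ACGTN or '-' (deleted)
    insertions: list[tuple[int, str]]  # (0-based window pos the insert follows, seq)
    n_match: int = 0
    identity: float = 0.0
    gapped: bool = field(default=False)


def project_onto_window(query: str, window: str, fast_identity: float = 0.9) -> Projection:
    """Project ``query`` onto ``window`` positions.

    Equal-length pairs at >= ``fast_identity`` ungapped identity skip the
    DP: an indel pair would have to explain several compensating
    mismatches to beat the ungapped alignment at these costs.
    """
    if len(query) == len(window):
        mismatches = sum(a != b for a, b in zip(query, window))
        ident = 1.0 - mismatches / len(window) if window else 0.0
        if ident >= fast_identity:
            return Projection(
                bases=list(query),
                insertions=[],
                n_match=len(window) - mismatches,
                identity=ident,
            )
    aln = _aligner.align(window, query)[0]
    bases = ["-"] * len(window)
    insertions: list[tuple[int, str]] = []
    n_match = 0
    t_blocks, q_blocks = aln.aligned
    prev_t_end = 0
    prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q_end:  # unaligned query bases -> insertion after prev_t_end
            insertions.append((prev_t_end, query[prev_q_end:qs]))
        for t, q in zip(range(ts, te), range(qs, qe)):
            bases[t] = query[q]
            if query[q] == window[t]:
                n_match += 1
        prev_t_end, prev_q_end = te, qe
    if prev_q_end < len(query):
        insertions.append((prev_t_end, query[prev_q_end:]))
    identity = n_match / max(len(query), len(window)) if window else 0.0
    return Projection(bases=bases, insertions=insertions, n_match=n_match,
                      identity=identity, gapped=True)


def global_alignment_columns(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Aligned strings (with '-') for two sequences, same cost model."""
    aln = _aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])
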