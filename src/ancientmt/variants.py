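"""Variant calls against a reference coordinate frame.

Conventions
-----------
Positions are 1-based on the reference. A substitution replaces the single
base at ``position``. An insertion places ``alt_allele`` *after* ``position``
(``ref_allele`` is ``"-"``); position 0 means a prepended insertion. A
deletion removes ``ref_allele`` starting at ``position`` (``alt_allele`` is
``"-"``). This matches the single-coordinate notation used for
mitochondrial mutation tables (e.g. "587 +C").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

TRANSITIONS = {frozenset("AG"), frozenset("CT")}
BASES = "ACGT"


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """Transition (A<->G, C<->T) or transversion (everything else)."""
    pair = frozenset((ref_allele, alt_allele))
    if len(pair) != 2 or not pair <= set(BASES):
        raise ValueError(f"not a substitution: {ref_allele}>{alt_allele}")
    return "transition" if pair in TRANSITIONS else "transversion"


@dataclass
class VariantCall:
    position: int
    ref_allele: str
    alt_allele: str
    kind: str = field(default="")  # substitution | insertion | deletion
    region_class: Optional[str] = None
    support: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.kind:
            if self.ref_allele == "-":
                self.kind = "insertion"
            elif self.alt_allele == "-":
                self.kind = "deletion"
            else:
                self.kind = "substitution"
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution alleles must differ")

    @property
    def classification(self) -> str:
        if self.kind != "substitution":
            return "indel"
        return classify_substitution(self.ref_allele, self.alt_allele)

    def length_change(self) -> int:
        if self.kind == "insertion":
            return len(self.alt_allele)
        if self.kind == "deletion":
            return -len(self.ref_allele)
        return 0

    def span(self) -> tuple[int, int]:
        """Reference interval occupied by the variant (inclusive).

        An insertion after p occupies the empty interval (p, p+1), encoded
        as (p+1, p) so that overlap checks against real bases work.
        """
        if self.kind == "insertion":
            return (self.position + 1, self.position)
        return (self.position, self.position + len(self.ref_allele) - 1)


def apply_variants(ref: str, variants: Iterable[VariantCall]) -> str:
    """Apply sorted, non-overlapping variants to ``ref``.

    Raises ``ValueError`` on unsorted, overlapping or out-of-range variants.
    Returned length is len(ref) + sum of insertion lengths - deletions.
    """
    out: list[str] = []
    cursor = 1  # next unconsumed 1-based ref position
    last_end = 0
    for v in sorted(variants, key=lambda v: (v.position, v.kind != "insertion")):
        start, end = v.span()
        if v.kind == "insertion":
            if v.position < 0 or v.position > len(ref):
                raise ValueError(f"insertion anchor {v.position} out of range")
            if v.position < last_end:
                raise ValueError(f"overlapping variant at {v.position}")
            out.append(ref[cursor - 1 : v.position])
            out.append(v.alt_allele)
            cursor = v.position + 1
            last_end = max(last_end, v.position)
            continue
        if start < 1 or end > len(ref):
            raise ValueError(f"variant at {v.position} out of range")
        if start <= last_end:
            raise ValueError(f"overlapping variant at {v.position}")
        out.append(ref[cursor - 1 : start - 1])
        if v.kind == "substitution":
            if ref[start - 1] != v.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {v.position}: "
                    f"expected {v.ref_allele}, found {ref[start - 1]}"
                )
            out.append(v.alt_allele)
        else:  # deletion
            if ref[start - 1 : end] != v.ref_allele:
                raise ValueError(f"ref allele mismatch at {v.position}")
        cursor = end + 1
        last_end = end
    out.append(ref[cursor - 1 :])
    return "".join(out)


def left_normalize(variant: VariantCall, ref: str) -> VariantCall:
    """Shift an indel to its leftmost equivalent placement.

    Within a homopolymer (or short tandem) context the same edit can be
    written at several coordinates; comparison tables report one canonical
    coordinate, so indels are rotated left while the base preceding the
    event equals the last base of the indel allele.
    """
    if variant.kind == "substitution":
        return variant
    allele = variant.alt_allele if variant.kind == "insertion" else variant.ref_allele
    pos = variant.position
    if variant.kind == "insertion":
        # inserted after pos; can move to pos-1 if ref[pos] == allele[-1]
        while pos >= 1 and ref[pos - 1] == allele[-1]:
            allele = allele[-1] + allele[:-1]
            pos -= 1
        return replace(variant, position=pos, alt_allele=allele)
    while pos > 1 and ref[pos - 2] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        pos -= 1
        if ref[pos - 1 : pos - 1 + len(allele)] != allele:
            # rotation no longer matches the reference; undo and stop
            pos += 1
            allele = allele[1:] + allele[0]
            break
    return replace(variant, position=pos, ref_allele=allele)
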