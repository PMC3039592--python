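"""Circular mitochondrial reference genomes with functional-region annotation.

The reference provides the coordinate frame (1-based, inclusive, circular)
for amplicon panels, pileups and variant tables. Region classes follow the
standard mitogenome partition: the non-coding control region, rRNA and tRNA
genes, and protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_CLASSES = ("control_region", "rRNA", "tRNA", "protein")

#: Default class composition, mirroring a taurine mitogenome: ~11.4 kb of
#: protein genes, ~2.5 kb rRNA, ~1.5 kb of tRNAs and a ~0.9 kb control
#: region on a 16.3 kb circle.
DEFAULT_REGION_FRACTIONS = {
    "protein": 0.695,
    "rRNA": 0.155,
    "tRNA": 0.092,
    "control_region": 0.056,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Region:
    region_class: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class ReferenceGenome:
    id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def normalize(self, pos: int) -> int:
        """Map any integer onto the circle as a 1-based position."""
        return (pos - 1) % self.length + 1

    def fetch(self, start: int, end: int) -> str:
        """Circular slice, 1-based inclusive; end may run past the origin."""
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        span = end - start + 1
        if span > 2 * self.length:
            raise ValueError("slice longer than twice the genome")
        doubled = self.sequence * 2
        s0 = (start - 1) % self.length
        return doubled[s0 : s0 + span]

    def region_at(self, pos: int) -> str | None:
        pos = self.normalize(pos)
        for r in self.regions:
            if r.start <= pos <= r.end:
                return r.region_class
        return None

    def region_lookup(self) -> np.ndarray:
        """Per-position class index array (-1 = unannotated)."""
        arr = np.full(self.length, -1, dtype=np.int8)
        idx = {c: i for i, c in enumerate(REGION_CLASSES)}
        for r in self.regions:
            arr[r.start - 1 : r.end] = idx[r.region_class]
        return arr


def homopolymer_runs(seq: str, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases as (start, end, base), 1-based."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append((i + 1, j + 1, seq[i]))
        i = j + 1
    return runs


def _layout_regions(length: int, fractions: dict[str, float]) -> list[Region]:
    # Block counts echo real mitogenome architecture: one control region,
    # two rRNAs, 22 tRNAs interleaved between 13 protein genes.
    n_blocks = {"control_region": 1, "rRNA": 2, "tRNA": 22, "protein": 13}
    blocks: list[tuple[str, int]] = []
    for cls in REGION_CLASSES:
        frac = fractions.get(cls, 0.0)
        total = int(round(frac * length))
        if total <= 0:
            continue
        k = min(n_blocks[cls], total)
        sizes = [total // k] * k
        for i in range(total - sum(sizes)):
            sizes[i] += 1
        blocks.append((cls, sizes))  # type: ignore[arg-type]
    # Interleave: control region first, then rRNAs each followed by a tRNA,
    # then proteins alternating with the remaining tRNAs.
    queues = dict(blocks)
    order: list[tuple[str, int]] = []

    def take(cls: str) -> bool:
        q = queues.get(cls)
        if q:
            order.append((cls, q.pop(0)))
            return True
        return False

    take("control_region")
    for _ in range(2):
        take("rRNA")
        take("tRNA")
    while queues.get("protein") or queues.get("tRNA"):
        if not take("protein") and not take("tRNA"):
            break
        take("tRNA")
    regions = []
    pos = 1
    for cls, size in order:
        regions.append(Region(cls, pos, pos + size - 1))
        pos += size
    if regions and regions[-1].end > length:
        last = regions[-1]
        regions[-1] = Region(last.region_class, last.start, length)
        regions = [r for r in regions if r.start <= length]
    return regions


def generate_reference(
    length: int = 16338,
    region_fractions: dict[str, float] | None = None,
    homopolymer_boost: float = 1.0,
    seed: int = 0,
    genome_id: str = "simref",
) -> ReferenceGenome:
    """Random annotated circular genome.

    ``homopolymer_boost`` is the expected number of planted runs of >=6
    identical bases per kb (0 disables planting); pyrosequencing error
    simulation needs such runs to act on.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    fractions = dict(DEFAULT_REGION_FRACTIONS if region_fractions is None else region_fractions)
    bad = set(fractions) - set(REGION_CLASSES)
    if bad:
        raise ValueError(f"unknown region classes: {sorted(bad)}")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("region fractions sum above 1")
    if homopolymer_boost < 0:
        raise ValueError("homopolymer_boost must be >= 0")
    rng = np.random.default_rng([seed, 0x5E0])
    seq = rng.choice(list("ACGT"), size=length)
    if homopolymer_boost > 0:
        n_runs = rng.poisson(homopolymer_boost * length / 1000.0)
        for _ in range(n_runs):
            run_len = 6 + rng.poisson(1.2)
            start = int(rng.integers(0, length))
            base = str(rng.choice(list("ACGT")))
            for k in range(run_len):
                seq[(start + k) % length] = base
    return ReferenceGenome(
        id=genome_id,
        sequence="".join(seq),
        regions=_layout_regions(length, fractions),
    )
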