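"""Synthetic ancient-DNA amplicon read sets with a complete truth ledger.

The generator emulates the phenomena that make ancient amplicon
pyrosequencing data hard: wildly irregular per-amplicon read depth
(lognormal, mean >> median), strand-symmetric cytosine-deamination damage
(C->T on the read strand, seen as G->A on reverse-strand reads),
homopolymer-length-dependent indel errors, uniform base-call errors, and a
tunable fraction of reads drawn from a modern contaminant haplotype.
Every perturbation of every read is recorded in a ledger so downstream
stages can be tested against exact truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import Read, ReadSet
from .panel import AmpliconPanel
from .reference import ReferenceGenome, homopolymer_runs, revcomp
from .variants import VariantCall, apply_variants

#: Lognormal depth defaults: median e^mu = 93 reads/amplicon and
#: mean e^(mu + sigma^2/2) = 463 give sigma = sqrt(2 ln(463/93)) ~= 1.79.
DEPTH_LOG_MEDIAN = math.log(93.0)
DEPTH_LOG_SIGMA = math.sqrt(2.0 * math.log(463.0 / 93.0))


@dataclass
class SimTruth:
    """Truth state for one simulation.

    Default rates describe a plausibly preserved ancient sample sequenced
    on an early pyrosequencing platform: a ~1% aggregate per-base call
    error, an aggregate deamination rate of 0.4% per eligible base on the
    damaged strand (enough to give the characteristic excess of type II
    over type I mismatches, ~1.6x: only the strand carrying the pyrimidine
    shows each event, so the expected ratio is 1 + (3/2) x damage/error),
    and homopolymer indel errors growing linearly with run length.
    """

    truth_sequence: str
    planted_variants: list[VariantCall] = field(default_factory=list)
    damage_rate: float = 0.004
    seq_error_rate: float = 0.01
    homopolymer_indel_base_rate: float = 0.03
    contamination_fraction: float = 0.0
    contaminant_sequence: str = ""
    depth_log_median: float = DEPTH_LOG_MEDIAN
    depth_log_sigma: float = DEPTH_LOG_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("damage_rate", "seq_error_rate", "homopolymer_indel_base_rate",
                     "contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def reference_length(self) -> int:
        return len(self.truth_sequence) - sum(v.length_change() for v in self.planted_variants)


def mutate_haplotype(
    ref: ReferenceGenome,
    n_substitutions: int,
    n_indels: int,
    seed: int = 0,
) -> tuple[str, list[VariantCall]]:
    """Plant random substitutions and single-base indels on the reference.

    The returned variant list exactly reconciles the reference with the
    returned sequence (``apply_variants`` round-trips). Edit positions are
    kept >= 2 bp apart so the calls never overlap.
    """
    if n_substitutions < 0 or n_indels < 0:
        raise ValueError("variant counts must be >= 0")
    total = n_substitutions + n_indels
    if total > ref.length // 100:
        raise ValueError(f"{total} edits exceed the cap of length/100 = {ref.length // 100}")
    rng = np.random.default_rng([seed, 0x11A9])
    positions: list[int] = []
    attempts = 0
    while len(positions) < total:
        p = int(rng.integers(2, ref.length))  # avoid position 1 and L for simplicity
        if all(abs(p - q) >= 2 for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 1000 * max(total, 1):
            raise RuntimeError("could not place variants with spacing")
    variants: list[VariantCall] = []
    for i, p in enumerate(positions):
        ref_base = ref.sequence[p - 1]
        if i < n_substitutions:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(VariantCall(position=p, ref_allele=ref_base, alt_allele=alt))
        elif rng.random() < 0.5:
            ins = str(rng.choice(list("ACGT")))
            variants.append(VariantCall(position=p, ref_allele="-", alt_allele=ins))
        else:
            variants.append(VariantCall(position=p, ref_allele=ref_base, alt_allele="-"))
    variants.sort(key=lambda v: v.position)
    return apply_variants(ref.sequence, variants), variants


def simulate_modern_panel(
    ref: ReferenceGenome,
    n_genomes: int = 10,
    mean_substitutions: float = 8.0,
    seed: int = 0,
) -> dict[str, str]:
    """Panel of modern haplotypes diverged from the reference.

    Each genome carries a Poisson-distributed number of substitutions
    (no indels), so pairwise distances within the panel scatter around
    2 x ``mean_substitutions`` the way real mitogenome panels do.
    """
    rng = np.random.default_rng([seed, 0x90DE])
    panel: dict[str, str] = {}
    for k in range(n_genomes):
        n_subs = min(int(rng.poisson(mean_substitutions)), ref.length // 100)
        seq, _ = mutate_haplotype(ref, n_subs, 0, seed=int(rng.integers(2**31)))
        panel[f"modern{k:02d}"] = seq
    return panel


def draw_amplicon_read_count(
    rng: np.random.Generator,
    depth_log_median: float = DEPTH_LOG_MEDIAN,
    depth_log_sigma: float = DEPTH_LOG_SIGMA,
) -> int:
    """One lognormal per-amplicon read count, rounded up.

    The heavy right tail is the point: re-sequenced pools inflate the mean
    far above the median (defaults give mean/median ~= 5).
    """
    return int(math.ceil(math.exp(rng.normal(depth_log_median, depth_log_sigma))))


def truth_coordinate_map(ref_length: int, variants: list[VariantCall]) -> np.ndarray:
    """tpos[p] = 1-based index of reference base p in the truth sequence (0 if deleted)."""
    ins_after: dict[int, int] = {}
    deleted: set[int] = set()
    for v in variants:
        if v.kind == "insertion":
            ins_after[v.position] = ins_after.get(v.position, 0) + len(v.alt_allele)
        elif v.kind == "deletion":
            deleted.update(range(v.position, v.position + len(v.ref_allele)))
    tpos = np.zeros(ref_length + 1, dtype=np.int64)
    t = ins_after.get(0, 0)
    for p in range(1, ref_length + 1):
        if p in deleted:
            tpos[p] = 0
        else:
            t += 1
            tpos[p] = t
        t += ins_after.get(p, 0)
    return tpos


def _segment(
    seq: str,
    tpos: np.ndarray,
    rpos: np.ndarray,
    start: int,
    end: int,
    ref_length: int,
) -> tuple[str, list[int]]:
    """Truth bases corresponding to circular reference span [start, end]."""
    parts: list[tuple[int, int]] = []
    start = (start - 1) % ref_length + 1
    span = end - start  # end given in unwrapped coords relative to start
    end = start + span
    if end <= ref_length:
        parts = [(start, end)]
    else:
        parts = [(start, ref_length), (1, end - ref_length)]
    out: list[str] = []
    refpos: list[int] = []
    for s, e in parts:
        block = tpos[s : e + 1]
        nz = block[block > 0]
        if nz.size == 0:
            continue
        t1, t2 = int(nz[0]), int(nz[-1])
        out.append(seq[t1 - 1 : t2])
        refpos.extend(int(rpos[t]) for t in range(t1, t2 + 1))
    return "".join(out), refpos


def _inverse_map(tpos: np.ndarray, truth_len: int) -> np.ndarray:
    rpos = np.zeros(truth_len + 1, dtype=np.int64)
    for p in range(1, len(tpos)):
        if tpos[p] > 0:
            rpos[tpos[p]] = p
    return rpos


def simulate_reads(
    panel: AmpliconPanel,
    truth: SimTruth,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate a full sequencing run over the panel.

    Returns the read set (reads in physical orientation, primers at the
    termini) and a ledger with one row per read: source, strand, and every
    perturbation (damage, base-call error, homopolymer indel) as JSON.
    Damage is applied only to endogenous reads; call errors and
    homopolymer miscounts affect contaminant reads too.
    """
    if len(panel) == 0:
        raise ValueError("empty amplicon panel")
    L = truth.reference_length
    tpos = truth_coordinate_map(L, truth.planted_variants)
    rpos = _inverse_map(tpos, len(truth.truth_sequence))
    contaminating = truth.contamination_fraction > 0
    if contaminating:
        longest = max(a.span for a in panel)
        if len(truth.contaminant_sequence) < longest:
            raise ValueError("contaminant sequence shorter than the longest amplicon span")
    reads: list[Read] = []
    ledger_rows: list[dict] = []
    for i, amp in enumerate(panel):
        rng = np.random.default_rng([truth.seed, 0xF00D, i])
        n_reads = draw_amplicon_read_count(rng, truth.depth_log_median,
                                           truth.depth_log_sigma)
        endo_seq, endo_refpos = _segment(truth.truth_sequence, tpos, rpos,
                                         amp.insert_start, amp.insert_end, L)
        templates = {"endogenous": (endo_seq, endo_refpos)}
        if contaminating:
            cl = len(truth.contaminant_sequence)
            doubled = truth.contaminant_sequence * 2
            s0 = (amp.insert_start - 1) % cl
            cont_seq = doubled[s0 : s0 + (amp.insert_end - amp.insert_start + 1)]
            cont_refpos = [(amp.insert_start + k - 1) % L + 1 for k in range(len(cont_seq))]
            templates["contaminant"] = (cont_seq, cont_refpos)
        # Per-template precomputation: eligible damage sites and runs.
        # The indel direction at each homopolymer is drawn once per
        # amplicon context, not per read: run-length miscounts are a
        # systematic property of the flow signal for that context, which
        # is what lets long-run artifacts reach a consensus majority.
        prep = {}
        for src, (seg, refs) in templates.items():
            prep[src] = {
                "seg": seg,
                "refs": refs,
                "C": np.array([k for k, ch in enumerate(seg) if ch == "C"], dtype=np.int64),
                "G": np.array([k for k, ch in enumerate(seg) if ch == "G"], dtype=np.int64),
                "runs": [
                    (s - 1, e - 1, b,
                     min(truth.homopolymer_indel_base_rate * (e - s - 1), 0.5),
                     "ins" if rng.random() < 0.5 else "del")
                    for s, e, b in homopolymer_runs(seg)
                    if e - s + 1 >= 3
                ],
            }
        for j in range(n_reads):
            src = ("contaminant"
                   if contaminating and rng.random() < truth.contamination_fraction
                   else "endogenous")
            t = prep[src]
            seq = list(t["seg"])
            refs = t["refs"]
            events: list[dict] = []
            strand = "+" if rng.random() < 0.5 else "-"
            if src == "endogenous" and truth.damage_rate > 0:
                sites = t["C"] if strand == "+" else t["G"]
                if sites.size:
                    hit = sites[rng.random(sites.size) < truth.damage_rate]
                    to = "T" if strand == "+" else "A"
                    for k in hit:
                        events.append({"type": "damage", "ref_pos": refs[k],
                                       "from": seq[k], "to": to})
                        seq[k] = to
            if truth.seq_error_rate > 0:
                mask = rng.random(len(seq)) < truth.seq_error_rate
                for k in np.nonzero(mask)[0]:
                    alt = str(rng.choice([b for b in "ACGT" if b != seq[k]]))
                    events.append({"type": "error", "ref_pos": refs[k],
                                   "from": seq[k], "to": alt})
                    seq[k] = alt
            if truth.homopolymer_indel_base_rate > 0 and t["runs"]:
                for s0, e0, base, prob, direction in reversed(t["runs"]):
                    if rng.random() < prob:
                        if direction == "ins":
                            seq.insert(e0 + 1, base)
                            events.append({"type": "hp_ins", "ref_pos": refs[e0],
                                           "base": base})
                        else:
                            del seq[e0]
                            events.append({"type": "hp_del", "ref_pos": refs[e0],
                                           "base": base})
            read_seq = amp.fwd_primer + "".join(seq) + revcomp(amp.rev_primer)
            if strand == "-":
                read_seq = revcomp(read_seq)
            read_id = f"r_{amp.amplicon_id}_{j:05d}"
            reads.append(Read(read_id=read_id, sequence=read_seq))
            ledger_rows.append({
                "read_id": read_id,
                "amplicon_id": amp.amplicon_id,
                "source": src,
                "strand": strand,
                "n_damage": sum(e["type"] == "damage" for e in events),
                "n_error": sum(e["type"] == "error" for e in events),
                "n_hp_indel": sum(e["type"].startswith("hp_") for e in events),
                "perturbations": json.dumps(events),
            })
    ledger = pd.DataFrame(ledger_rows, columns=[
        "read_id", "amplicon_id", "source", "strand",
        "n_damage", "n_error", "n_hp_indel", "perturbations",
    ])
    return ReadSet(reads=reads), ledger
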