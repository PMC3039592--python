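"""Shared fixtures: small simulated chains every stage can reuse."""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings

from ancientmt import (
    SimTruth,
    VariantCall,
    apply_variants,
    assign_reads,
    call_consensus,
    design_panel,
    generate_reference,
    mutate_haplotype,
    pileup,
    simulate_reads,
)
from ancientmt.consensus import mask_reads
from ancientmt.reference import homopolymer_runs

settings.register_profile(
    "unit",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")

#: The eight differences of the studied aurochs genome against the bovine
#: reference frame: position, reference allele, observed allele.
TABLE1_EDITS = [
    (587, "-", "C"),     # insertion, 12S rRNA
    (2536, "C", "A"),    # 16S rRNA
    (9682, "G", "C"),    # COX3
    (12738, "C", "T"),   # ND5
    (12744, "C", "T"),   # ND5
    (13310, "A", "C"),   # ND5
    (14159, "A", "G"),   # ND6
    (15384, "G", "A"),   # CYTB
]


def table1_variants() -> list[VariantCall]:
    return [VariantCall(position=p, ref_allele=r, alt_allele=a)
            for p, r, a in TABLE1_EDITS]


def reference_with_table1_context(seed: int = 17):
    """A 16,338 bp synthetic genome carrying the published reference
    alleles at the eight comparison positions (the positions and alleles
    are inputs; the rest of the sequence is synthetic)."""
    ref = generate_reference(16338, seed=seed)
    seq = list(ref.sequence)
    for pos, ref_allele, _alt in TABLE1_EDITS:
        if ref_allele != "-":
            seq[pos - 1] = ref_allele
    # keep the 587 insertion non-shiftable so its coordinate is canonical
    for p in (587, 588):
        if seq[p - 1] == "C":
            seq[p - 1] = "A"
    ref.sequence = "".join(seq)
    return ref


def run_chain(reads, ref, panel, max_primer_mismatches=1, min_depth=1):
    """assign -> mask -> pileup -> consensus, returning all intermediates."""
    assigned = assign_reads(reads, panel, max_primer_mismatches)
    masked = mask_reads(assigned, panel)
    counts = pileup(masked, ref, panel)
    cons = call_consensus(counts, min_depth=min_depth)
    return assigned, masked, counts, cons


def simulate_chain(
    length=2000,
    n_amplicons=16,
    seed=5,
    n_substitutions=5,
    n_indels=1,
    depth_log_median=math.log(20),
    depth_log_sigma=0.3,
    homopolymer_boost=1.0,
    **truth_kwargs,
):
    """Reference + panel + truth + simulated reads with all noise off by
    default; noise rates are opted into via ``truth_kwargs``."""
    ref = generate_reference(length, homopolymer_boost=homopolymer_boost, seed=seed)
    panel = design_panel(ref, n_amplicons=n_amplicons, n_sets=4, seed=seed)
    truth_seq, planted = mutate_haplotype(ref, n_substitutions, n_indels, seed=seed)
    defaults = dict(damage_rate=0.0, seq_error_rate=0.0,
                    homopolymer_indel_base_rate=0.0)
    defaults.update(truth_kwargs)
    truth = SimTruth(
        truth_sequence=truth_seq,
        planted_variants=planted,
        depth_log_median=depth_log_median,
        depth_log_sigma=depth_log_sigma,
        seed=seed + 1000,
        **defaults,
    )
    reads, ledger = simulate_reads(panel, truth)
    return ref, panel, truth, reads, ledger


def plant_clean_indel(ref, lo=200, hi=None):
    """A single-base deletion at a position not touching any homopolymer
    run of length >= 3 (a 'true' indel the artifact filter must keep)."""
    hi = hi or ref.length - 200
    runs = [(s, e) for s, e, _ in homopolymer_runs(ref.sequence)
            if e - s + 1 >= 3]
    for p in range(lo, hi):
        s = ref.sequence
        if (s[p - 1] != s[p] and s[p - 1] != s[p - 2]
                and all(not (rs - 2 <= p <= re + 2) for rs, re in runs)):
            v = VariantCall(position=p, ref_allele=s[p - 1], alt_allele="-")
            return v, apply_variants(s, [v])
    raise AssertionError("no clean indel position found")


def ledger_mismatch_expectation(ledger):
    """Exact expected type I / type II mismatch counts from the ledger.

    Each read's perturbation chain is collapsed per position (template
    base -> final base) and the net change classified directionally.
    """
    import json as _json

    type1 = type2 = 0
    for perturb in ledger["perturbations"]:
        final: dict[int, list] = {}
        for ev in _json.loads(perturb):
            if ev["type"] not in ("damage", "error"):
                continue
            key = ev["ref_pos"]
            if key in final:
                final[key][1] = ev["to"]
            else:
                final[key] = [ev["from"], ev["to"]]
        for frm, to in final.values():
            if (frm, to) in (("C", "T"), ("G", "A")):
                type2 += 1
            elif (frm, to) in (("A", "G"), ("T", "C")):
                type1 += 1
    return type1, type2


@pytest.fixture(scope="session")
def clean_chain():
    """Noise-free end-to-end chain on a 2 kb genome (session-cached)."""
    ref, panel, truth, reads, ledger = simulate_chain()
    assigned, masked, counts, cons = run_chain(reads, ref, panel)
    return {
        "ref": ref, "panel": panel, "truth": truth, "reads": reads,
        "ledger": ledger, "assigned": assigned, "masked": masked,
        "counts": counts, "consensus": cons,
    }
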