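"""Read assignment, masking, pileup and majority-rule calling."""

import math

import numpy as np
import pytest

from ancientmt import (
    Read,
    ReadSet,
    assign_reads,
    call_consensus,
    flag_low_coverage,
    generate_reference,
    mask_primers,
    pileup,
    revcomp,
)
from ancientmt.consensus import AlignedRead, ColumnCounts, mask_reads
from ancientmt.panel import Amplicon, AmpliconPanel
from conftest import run_chain, simulate_chain


def make_counts(column_reads, length=3, pos=2):
    """ColumnCounts with the given read bases piled on one position."""
    counts = ColumnCounts(length)
    for i, base in enumerate(column_reads):
        counts.add(AlignedRead(read_id=f"r{i}", amplicon_id="amp001",
                               start=pos, bases=base))
    return counts


# ---------------------------------------------------------------- assignment

def test_exact_forward_primer_assigns_plus_strand(clean_chain):
    panel = clean_chain["panel"]
    ref = clean_chain["ref"]
    amp = panel.amplicons[6]
    seq = ref.fetch(amp.start, amp.end)
    rs = assign_reads(ReadSet(reads=[Read("q1", seq)]), panel, 1)
    assert rs.reads[0].assigned_amplicon == amp.amplicon_id
    assert rs.reads[0].strand == "+"
    rs2 = assign_reads(ReadSet(reads=[Read("q2", revcomp(seq))]), panel, 1)
    assert rs2.reads[0].assigned_amplicon == amp.amplicon_id
    assert rs2.reads[0].strand == "-"


def test_primer_mismatch_threshold_is_a_boundary(clean_chain):
    panel = clean_chain["panel"]
    ref = clean_chain["ref"]
    amp = panel.amplicons[2]
    seq = ref.fetch(amp.start, amp.end)
    one = "T" if seq[0] != "T" else "G"
    two = "T" if seq[3] != "T" else "G"
    read_1mm = one + seq[1:]
    read_2mm = one + seq[1:3] + two + seq[4:]
    rs = assign_reads(ReadSet(reads=[Read("m1", read_1mm), Read("m2", read_2mm)]),
                      panel, max_primer_mismatches=1)
    by_id = {r.read_id: r for r in rs.reads}
    assert by_id["m1"].assigned_amplicon == amp.amplicon_id
    assert by_id["m2"].assigned_amplicon is None


def test_scrambled_decoys_lower_mapped_fraction_and_match_ledger(clean_chain):
    reads = clean_chain["reads"]
    panel = clean_chain["panel"]
    ledger = clean_chain["ledger"].set_index("read_id")
    rng = np.random.default_rng(77)
    decoyed, decoy_ids = [], set()
    for i, r in enumerate(reads):
        if i % 10 == 0:  # 10% decoys with scrambled termini
            decoy = "".join(rng.choice(list("ACGT"), size=30)) + r.sequence[30:]
            decoyed.append(Read(r.read_id, decoy))
            decoy_ids.add(r.read_id)
        else:
            decoyed.append(Read(r.read_id, r.sequence))
    rs = assign_reads(ReadSet(reads=decoyed), panel, 1)
    rep = rs.assignment_report
    assert rep["total"] == len(reads)
    assert (rep["assigned"] + rep["unassigned"] + rep["dropped_ambiguous"]
            == rep["total"])
    assert rep["mapped_fraction"] == pytest.approx(0.9, abs=0.02)
    for r in rs.reads:
        if r.assigned_amplicon is not None:
            assert r.read_id not in decoy_ids
            assert r.assigned_amplicon == ledger.loc[r.read_id, "amplicon_id"]


# ------------------------------------------------------------------ masking

def _toy_amplicon(flen=20, rlen=22):
    return Amplicon(amplicon_id="toy", set_label="A",
                    fwd_primer="AC" * (flen // 2), rev_primer="GT" * (rlen // 2),
                    start=1, end=flen + 158 + rlen,
                    insert_start=flen + 1, insert_end=flen + 158)


def test_masking_strips_both_primer_lengths():
    amp = _toy_amplicon()
    read = Read("r", "A" * 200, assigned_amplicon="toy", strand="+")
    assert len(mask_primers(read, amp).sequence) == 158


def test_primer_only_read_is_an_error():
    amp = _toy_amplicon()
    read = Read("r", "A" * 42, assigned_amplicon="toy", strand="+")
    with pytest.raises(ValueError):
        mask_primers(read, amp)


def test_masked_reads_equal_simulated_inserts(clean_chain):
    truth = clean_chain["truth"]
    doubled = truth.truth_sequence * 2
    for r in clean_chain["masked"].reads[:200]:
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        assert seq in doubled


# ------------------------------------------------------------------- pileup

def test_single_clean_read_counts_one_per_position(clean_chain):
    ref = clean_chain["ref"]
    panel = clean_chain["panel"]
    amp = panel.amplicons[0]
    window = ref.fetch(amp.insert_start, amp.insert_end)
    rs = ReadSet(reads=[Read("one", window, assigned_amplicon=amp.amplicon_id,
                             strand="+", masked=True)])
    counts = pileup(rs, ref, panel)
    depth = counts.depth
    assert depth.sum() == len(window)
    for k, base in enumerate(window):
        p = (amp.insert_start - 1 + k) % ref.length
        assert counts.counts[p, "ACGT-".index(base)] == 1


def test_single_mismatch_lands_on_the_right_column(clean_chain):
    ref = clean_chain["ref"]
    panel = clean_chain["panel"]
    amp = panel.amplicons[0]
    window = ref.fetch(amp.insert_start, amp.insert_end)
    k = window.index("C")
    p = (amp.insert_start - 1 + k) % ref.length
    read = window[:k] + "T" + window[k + 1:]
    counts = pileup(ReadSet(reads=[Read("mm", read, assigned_amplicon=amp.amplicon_id,
                                        strand="+", masked=True)]), ref, panel)
    assert counts.counts[p, "ACGT-".index("T")] == 1
    assert counts.counts[p, "ACGT-".index("C")] == 0


def test_low_identity_read_is_excluded(clean_chain):
    ref = clean_chain["ref"]
    panel = clean_chain["panel"]
    amp = panel.amplicons[0]
    rng = np.random.default_rng(3)
    junk = "".join(rng.choice(list("ACGT"), size=amp.insert_length))
    counts = pileup(ReadSet(reads=[Read("junk", junk,
                                        assigned_amplicon=amp.amplicon_id,
                                        strand="+", masked=True)]), ref, panel)
    assert counts.n_excluded == 1
    assert len(counts.aligned_reads) == 0


# ------------------------------------------------------------------ calling

def test_majority_base_with_support():
    counts = make_counts(["A"] * 6 + ["G"] * 4)
    cons = call_consensus(counts)
    assert cons.calls[1] == "A"
    assert cons.per_site_support[1] == pytest.approx(0.6)


def test_exact_tie_is_called_n_and_flagged():
    counts = make_counts(["A"] * 5 + ["G"] * 5)
    cons = call_consensus(counts)
    assert cons.calls[1] == "N"
    assert cons.ambiguous_positions == [2]


def test_below_min_depth_is_called_n():
    counts = make_counts(["A"] * 3)
    cons = call_consensus(counts, min_depth=5)
    assert cons.calls[1] == "N"


def test_majority_deletion_suppresses_position():
    counts = make_counts(["A"] * 2 + ["-"] * 5, length=3)
    # give the flanking columns a base so the sequence is well formed
    counts.add(AlignedRead("f", "amp001", start=1, bases="C"))
    counts.add(AlignedRead("g", "amp001", start=3, bases="G"))
    cons = call_consensus(counts)
    assert cons.calls[1] == "-"
    assert cons.sequence == "CG"


def test_majority_insertion_is_emitted():
    counts = ColumnCounts(3)
    for i in range(4):
        ins = [(2, "T")] if i < 3 else []
        counts.add(AlignedRead(f"r{i}", "amp001", start=1, bases="ACG",
                               insertions=ins))
    cons = call_consensus(counts)
    assert cons.called_insertions == {2: "T"}
    assert cons.sequence == "ACTG"


def test_empty_pileup_is_an_error():
    with pytest.raises(ValueError):
        call_consensus(ColumnCounts(10))


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_noise_free_chain_reproduces_truth(seed):
    ref, panel, truth, reads, _ = simulate_chain(seed=seed)
    _, _, _, cons = run_chain(reads, ref, panel)
    assert cons.sequence == truth.truth_sequence


def test_mean_support_non_increasing_in_error_rate():
    supports = []
    for err in [0.0, 0.005, 0.02]:
        ref, panel, truth, reads, _ = simulate_chain(seed=6, seq_error_rate=err)
        _, _, _, cons = run_chain(reads, ref, panel)
        supports.append(cons.mean_support)
    assert supports[0] >= supports[1] >= supports[2]


def test_depth_statistics_are_per_reference_position(clean_chain):
    counts = clean_chain["counts"]
    cons = clean_chain["consensus"]
    depth = counts.depth
    assert cons.mean_depth == pytest.approx(depth.mean())
    assert cons.median_depth == pytest.approx(np.median(depth))


# ------------------------------------------------------------- low coverage

def test_low_coverage_boundary_is_strict():
    panel = AmpliconPanel(reference_id="r", amplicons=[
        _toy_amplicon(), Amplicon("toy2", "B", "AC" * 10, "GT" * 11,
                                  1, 200, 21, 178),
    ])
    counts = ColumnCounts(300)
    for i in range(9):
        counts.add(AlignedRead(f"a{i}", "toy", start=21, bases="A"))
    for i in range(10):
        counts.add(AlignedRead(f"b{i}", "toy2", start=21, bases="A"))
    assert flag_low_coverage(counts, panel, threshold=10) == ["toy"]


def test_empty_amplicon_is_flagged(clean_chain):
    panel = clean_chain["panel"]
    counts = ColumnCounts(clean_chain["ref"].length)
    flagged = flag_low_coverage(counts, panel, threshold=10)
    assert flagged == [a.amplicon_id for a in panel]


def test_depleted_amplicon_is_exactly_the_flagged_one(clean_chain):
    ref, panel = clean_chain["ref"], clean_chain["panel"]
    target = panel.amplicons[4].amplicon_id
    ledger = clean_chain["ledger"]
    keep_ids = set()
    kept_of_target = 0
    for row in ledger.itertuples(index=False):
        if row.amplicon_id == target:
            if kept_of_target < 3:
                keep_ids.add(row.read_id)
                kept_of_target += 1
        else:
            keep_ids.add(row.read_id)
    reads = ReadSet(reads=[r for r in clean_chain["reads"] if r.read_id in keep_ids])
    _, _, counts, _ = run_chain(reads, ref, panel)
    assert flag_low_coverage(counts, panel, threshold=10) == [target]
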