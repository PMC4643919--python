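"""Outgroup polarization of substitutions and indels, repeat context."""

import itertools
from collections import Counter

import pytest

import plastomics as pm
from plastomics.spectrum import (
    classify_context,
    substitution_class,
)
from conftest import make_alignment

INGROUP = ["t1", "t2", "t3", "t4"]
OUT = "out"


def _aln_from_cols(cols):
    """Build a 5-row alignment from a list of (t1,t2,t3,t4,out) columns."""
    taxa = INGROUP + [OUT]
    seqs = {t: "".join(col[i] for col in cols) for i, t in enumerate(taxa)}
    return make_alignment(**seqs)


# -- substitution polarization ---------------------------------------------


def _brute_polarize_column(col):
    """Independent rule-by-definition polarizer for one 5-taxon column.

    Returns (ancestral, derived, carriers) or the skip reason.
    """
    ing, out = col[:4], col[4]
    if any(c not in "ACGT" for c in col):
        return "gap_or_n"
    states = sorted(set(ing))
    if len(states) == 1:
        return "ingroup_invariant"
    if len(states) > 2:
        return "ingroup_multiallelic"
    if out not in states:
        return "outgroup_mismatch"
    derived = states[0] if states[1] == out else states[1]
    carriers = tuple(t for t, c in zip(INGROUP, ing) if c == derived)
    return (out, derived, carriers)


def test_polarize_trivial_columns():
    aln = _aln_from_cols([("A", "A", "A", "A", "A"), ("A", "A", "A", "C", "A")])
    res = pm.polarize_substitutions(aln, INGROUP, OUT)
    assert len(res.events) == 1
    ev = res.events[0]
    assert (ev.column, ev.ancestral, ev.derived, ev.carriers) == (1, "A", "C", ("t4",))
    assert res.skipped["ingroup_invariant"] == 1


def test_polarize_exhaustive_all_ungapped_patterns():
    """Every 4^5 ungapped 5-taxon column agrees with an independent
    brute-force application of the polarization rule."""
    cols = list(itertools.product("ACGT", repeat=5))
    aln = _aln_from_cols(cols)
    res = pm.polarize_substitutions(aln, INGROUP, OUT)
    by_col = {e.column: e for e in res.events}
    n_expected_events = 0
    expected_skips = Counter()
    for i, col in enumerate(cols):
        expected = _brute_polarize_column(col)
        if isinstance(expected, str):
            expected_skips[expected] += 1
            assert i not in by_col
        else:
            n_expected_events += 1
            ev = by_col[i]
            assert (ev.ancestral, ev.derived, ev.carriers) == expected
    assert len(res.events) == n_expected_events
    for reason, n in expected_skips.items():
        assert res.skipped[reason] == n


def test_outgroup_missing_raises():
    aln = make_alignment(t1="A", t2="A", t3="A", t4="A")
    with pytest.raises(ValueError, match="outgroup"):
        pm.polarize_substitutions(aln, INGROUP[:3], "nope")


def test_substitution_class_partition():
    assert substitution_class("A", "G") == "transition"
    assert substitution_class("C", "T") == "transition"
    assert substitution_class("A", "C") == "transversion"
    assert substitution_class("G", "C") == "transversion"


# -- spectrum summary -------------------------------------------------------


def test_empty_event_list_gives_zeros():
    s = pm.substitution_spectrum([])
    assert s.n_substitutions == 0
    assert s.ts_tv_ratio is None
    assert all(v == 0 for v in s.direction_counts.values())


def test_directed_counts_collapse_to_undirected():
    events = [
        pm.SubstitutionEvent(0, "A", "C", ("t1",)),
        pm.SubstitutionEvent(1, "C", "A", ("t1",)),
        pm.SubstitutionEvent(2, "A", "G", ("t2",)),
    ]
    s = pm.substitution_spectrum(events)
    assert sum(s.direction_counts.values()) == 3
    assert s.direction_counts["A>C"] + s.direction_counts["C>A"] == 2
    assert s.n_transitions == 1 and s.n_transversions == 2


def test_zero_transversions_ratio_undefined():
    events = [pm.SubstitutionEvent(0, "A", "G", ("t1",))]
    s = pm.substitution_spectrum(events)
    assert s.ts_tv_ratio is None


# -- indel calling ----------------------------------------------------------


def test_no_gaps_no_events():
    aln = _aln_from_cols([("A",) * 5] * 10)
    res = pm.call_and_polarize_indels(aln, INGROUP, OUT)
    assert res.events == []


def test_single_taxon_gap_run_is_deletion():
    aln = make_alignment(
        t1="ACGTACGTAC",
        t2="ACG---GTAC",
        t3="ACGTACGTAC",
        t4="ACGTACGTAC",
        out="ACGTACGTAC",
    )
    res = pm.call_and_polarize_indels(aln, INGROUP, OUT)
    assert len(res.events) == 1
    ev = res.events[0]
    assert ev.polarity == "deletion"
    assert ev.carriers == ("t2",)
    assert ev.columns == (3, 6)
    assert ev.seq == "TAC"


def test_outgroup_and_others_gapped_is_insertion():
    aln = make_alignment(
        t1="ACGTTTACGT",
        t2="ACG---ACGT",
        t3="ACG---ACGT",
        t4="ACG---ACGT",
        out="ACG---ACGT",
    )
    res = pm.call_and_polarize_indels(aln, INGROUP, OUT)
    assert len(res.events) == 1
    ev = res.events[0]
    assert ev.polarity == "insertion"
    assert ev.carriers == ("t1",)
    assert ev.seq == "TTT"


def _brute_indel_pattern(gapped):
    """Expected polarity/carriers for a clean single-run pattern with the
    given gapped subset of (t1..t4, out)."""
    gapped = frozenset(gapped)
    ing = frozenset(INGROUP)
    if OUT not in gapped:
        if gapped == ing:
            return "not_variable_in_ingroup"
        return ("deletion", tuple(t for t in INGROUP if t in gapped))
    carriers = tuple(t for t in INGROUP if t not in gapped)
    if not carriers:
        return "all_gap_pattern"
    if len(carriers) == 4:
        return "not_variable_in_ingroup"
    return ("insertion", carriers)


def test_indel_polarization_exhaustive_single_run_patterns():
    """Every nonempty gapped subset of the 5 taxa, as one clean 3-column
    run, polarizes as the brute-force rule predicts."""
    taxa = INGROUP + [OUT]
    for r in range(1, 6):
        for gapped in itertools.combinations(taxa, r):
            seqs = {
                t: ("ACGT" + ("---" if t in gapped else "TTT") + "ACGT")
                for t in taxa
            }
            if r == 5:
                continue  # all-gap columns cannot occur in a 5-taxon alignment
            aln = make_alignment(**seqs)
            res = pm.call_and_polarize_indels(aln, INGROUP, OUT)
            expected = _brute_indel_pattern(gapped)
            if isinstance(expected, str):
                assert res.events == []
                assert res.excluded[expected] == 1
            else:
                assert len(res.events) == 1
                ev = res.events[0]
                assert (ev.polarity, ev.carriers) == expected


def test_staggered_runs_are_unpolarizable():
    seqs = dict(
        t1="ACGT----ACGT",
        t2="ACGT--TTACGT",
        t3="ACGTTTTTACGT",
        t4="ACGTTTTTACGT",
        out="ACGTTTTTACGT",
    )
    aln = make_alignment(**seqs)
    res = pm.call_and_polarize_indels(aln, INGROUP, OUT)
    # t1 is partially gapped over t2's run and vice versa: both patterns
    # have staggered boundaries, so neither is polarizable
    assert res.events == []
    assert res.excluded["unpolarizable"] == 2


def test_simulator_truth_indels_recovered(small_truth):
    """Indels logged on ingroup branches are called with matching polarity,
    length and carriers from the true alignment (one-IR view)."""
    from plastomics.simulate import single_ir_columns

    keep = single_ir_columns(small_truth)
    aln = pm.AlignmentMatrix(
        list(small_truth.alignment.taxa), small_truth.alignment.matrix[:, keep]
    )
    ingroup = ["TiliaA", "TiliaB", "TiliaC", "TiliaD"]
    res = pm.call_and_polarize_indels(aln, ingroup, "Outgroup")
    called = Counter((e.polarity, len(e.seq)) for e in res.events)

    ingroup_branches = {"TiliaA", "TiliaB", "TiliaC", "TiliaD", "node2", "node5"}
    truth = Counter(
        (d.polarity, len(d.seq))
        for d in small_truth.indels
        if d.branch in ingroup_branches
    )
    n_called = sum(called.values())
    n_truth = sum(truth.values())
    # staggered overlaps can drop a few events; large disagreement = bug
    assert n_truth > 0
    assert abs(n_called - n_truth) <= max(2, 0.1 * n_truth)
    overlap = sum(min(called[k], truth[k]) for k in truth)
    assert overlap >= 0.85 * n_truth


# -- context classification -------------------------------------------------


@pytest.mark.parametrize(
    "seq,left,right,expected",
    [
        ("A", "CCAA", "ACGT", "homopolymer"),  # A inside AAAA run
        ("A", "CCCC", "CGTT", "none"),
        ("ATG", "CATG", "CCGT", "tandem_repeat"),  # equals upstream flank
        ("ATG", "CCCC", "ATGT", "tandem_repeat"),  # equals downstream flank
        ("ATG", "CCCC", "CGTT", "none"),
        # multi-base event: tandem fails, homopolymer run 2+3 = 5 ≥ 4
        ("TTT", "GCTT", "CGAA", "homopolymer"),
    ],
)
def test_classify_context_cases(seq, left, right, expected):
    assert classify_context(seq, left, right) == expected


def test_homopolymer_needs_minimum_run():
    # inserted A with only 2 further A's in the neighborhood: run 3 < 4
    assert classify_context("A", "CA", "AC") == "none"
    assert classify_context("A", "CAA", "AC") == "homopolymer"


def test_classify_from_alignment_insertion(small_truth):
    """Simulator slip-seeded indels are overwhelmingly classified as
    repeat-associated; the planted fraction is 52/58."""
    from plastomics.simulate import single_ir_columns

    keep = single_ir_columns(small_truth)
    aln = pm.AlignmentMatrix(
        list(small_truth.alignment.taxa), small_truth.alignment.matrix[:, keep]
    )
    ingroup = ["TiliaA", "TiliaB", "TiliaC", "TiliaD"]
    res = pm.call_and_polarize_indels(aln, ingroup, "Outgroup")
    events = [pm.classify_indel_context(e, aln) for e in res.events]
    n = len(events)
    n_rep = sum(1 for e in events if e.context in ("homopolymer", "tandem_repeat"))
    assert n >= 15
    assert n_rep / n > 0.6  # strong repeat association, small-sample slack


# -- length spectrum --------------------------------------------------------


def test_indel_length_spectrum_arithmetic():
    events = [
        pm.IndelEvent((0, 1), "insertion", ("t1",), "A"),
        pm.IndelEvent((5, 6), "insertion", ("t2",), "C"),
        pm.IndelEvent((9, 12), "insertion", ("t1",), "ACG"),
    ]
    spec = pm.indel_length_spectrum(events)
    assert spec.fraction_1bp_insertions == pytest.approx(2 / 3)
    assert spec.max_insertion == 3
    assert spec.max_deletion == 0
    assert spec.fraction_1bp_deletions is None


def test_empty_spectrum():
    spec = pm.indel_length_spectrum([])
    assert spec.max_insertion == 0 and spec.fraction_1bp_insertions is None
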