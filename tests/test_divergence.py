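"""p-distance, region variability, sliding identity, informative sites."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import plastomics as pm
from plastomics.divergence import UndefinedDistanceError
from conftest import make_alignment


def test_p_distance_trivial_cases():
    aln = make_alignment(a="AAAA", b="AAAA", c="AAAT")
    assert pm.p_distance(aln, "a", "b") == 0.0
    assert pm.p_distance(aln, "a", "c") == 0.25


def test_p_distance_pairwise_deletion():
    aln = make_alignment(a="A-CGN", b="AACGT")
    # columns 0, 2, 3 comparable; all match
    assert pm.p_distance(aln, "a", "b") == 0.0


def test_p_distance_undefined_without_comparable_columns():
    aln = make_alignment(a="A--N", b="-AN-")
    with pytest.raises(UndefinedDistanceError):
        pm.p_distance(aln, "a", "b")


@given(
    st.lists(
        st.tuples(
            st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-")
        ),
        min_size=1,
        max_size=60,
    )
)
def test_p_distance_symmetry_and_bounds(cols):
    rows = ["".join(c[i] for c in cols) for i in range(3)]
    if any(set(r) == {"-"} for r in rows):
        return
    aln = make_alignment(a=rows[0], b=rows[1], c=rows[2])
    try:
        d_ab = pm.p_distance(aln, "a", "b")
        d_ba = pm.p_distance(aln, "b", "a")
    except UndefinedDistanceError:
        return
    assert d_ab == d_ba
    assert 0.0 <= d_ab <= 1.0


def test_overall_divergence_two_taxa_collapses():
    aln = make_alignment(a="AAAA", b="AAAT")
    s = pm.overall_divergence(aln)
    assert s.mean == s.min == s.max == 0.25


def test_simulated_quartet_mean_within_monte_carlo_error(small_truth):
    """Mean pairwise p-distance of the ingroup quartet estimates the summed
    branch-length expectation within 3 Monte-Carlo SE."""
    cfg = small_truth.config
    aln = small_truth.alignment
    ingroup = ["TiliaA", "TiliaB", "TiliaC", "TiliaD"]
    s = pm.overall_divergence(aln, ingroup)
    # expected pairwise distances from the default tree branch lengths
    bl = {"A": 0.0005, "B": 0.0004, "C": 0.0004, "D": 0.0005, "ab": 0.0003, "cd": 0.0002}
    expected = np.mean(
        [
            bl["A"] + bl["B"],
            bl["A"] + bl["ab"] + bl["cd"] + bl["C"],
            bl["A"] + bl["ab"] + bl["cd"] + bl["D"],
            bl["B"] + bl["ab"] + bl["cd"] + bl["C"],
            bl["B"] + bl["ab"] + bl["cd"] + bl["D"],
            bl["C"] + bl["D"],
        ]
    )
    n = small_truth.leaf_records["TiliaA"].length
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(s.mean - expected) < 3 * se + 1e-9


# -- region variability -----------------------------------------------------


def test_region_identical_across_taxa_is_zero():
    aln = make_alignment(a="ACGT" * 60, b="ACGT" * 60)
    regs = [pm.RegionAnnotationOnAlignment("igs1", "IGS", (0, 240))]
    rec = pm.region_variability(aln, regs)[0]
    assert rec.percent_variable == 0.0


def test_region_variability_hand_enumeration():
    """300-column region: 6 substitution sites + one 3-column gap run in a
    single taxon = 7 variable characters → 100×7/300 ≈ 2.33%."""
    a = list("A" * 300)
    b = list("A" * 300)
    for i in range(6):
        b[10 + 7 * i] = "C"
    for i in range(100, 103):
        b[i] = "-"
    aln = make_alignment(a="".join(a), b="".join(b))
    regs = [pm.RegionAnnotationOnAlignment("r", "IGS", (0, 300))]
    rec = pm.region_variability(aln, regs)[0]
    assert rec.n_substitution_sites == 6
    assert rec.n_indel_events == 1
    assert rec.percent_variable == pytest.approx(100 * 7 / 300)


def test_shared_gap_run_is_one_event_distinct_runs_are_two():
    a = "AAAAAAA" + "A" * 294
    b = "AA---AA" + "A" * 294
    c = "AA---AA" + "A" * 294
    d = "A----AA" + "A" * 294
    aln = make_alignment(a=a, b=b, c=c, d=d)
    regs = [pm.RegionAnnotationOnAlignment("r", "IGS", (0, 301))]
    rec = pm.region_variability(aln, regs)[0]
    # b+c share one run; d has a different-boundary run: two events
    assert rec.n_indel_events == 2


def test_variability_additive_over_disjoint_regions():
    rng = np.random.default_rng(2)
    n = 600
    rows = {}
    for t in "abcd":
        row = rng.choice(list("ACGT"), size=n)
        mask = rng.random(n) < 0.01
        row[mask] = "-"
        rows[t] = "".join(row)
    aln = make_alignment(**rows)
    whole = pm.region_variability(
        aln, [pm.RegionAnnotationOnAlignment("w", "IGS", (0, 600))], min_aligned_length=10
    )[0]
    halves = pm.region_variability(
        aln,
        [
            pm.RegionAnnotationOnAlignment("h1", "IGS", (0, 300)),
            pm.RegionAnnotationOnAlignment("h2", "IGS", (300, 600)),
        ],
        min_aligned_length=10,
    )
    total_parts = sum(r.n_substitution_sites + r.n_indel_events for r in halves)
    assert whole.n_substitution_sites + whole.n_indel_events == total_parts


def test_overlapping_regions_rejected():
    aln = make_alignment(a="A" * 500, b="A" * 500)
    regs = [
        pm.RegionAnnotationOnAlignment("r1", "IGS", (0, 300)),
        pm.RegionAnnotationOnAlignment("r2", "IGS", (250, 500)),
    ]
    with pytest.raises(ValueError, match="overlap"):
        pm.region_variability(aln, regs)


def test_short_regions_filtered_by_aligned_length():
    aln = make_alignment(a="A" * 500, b="A" * 500)
    regs = [
        pm.RegionAnnotationOnAlignment("short", "IGS", (0, 150)),
        pm.RegionAnnotationOnAlignment("long", "IGS", (150, 500)),
    ]
    recs = pm.region_variability(aln, regs)
    assert [r.name for r in recs] == ["long"]


# -- sliding identity -------------------------------------------------------


def test_identical_pair_all_windows_100():
    aln = make_alignment(ref="ACGT" * 100, other="ACGT" * 100)
    prof = pm.sliding_identity(aln, "ref", window=100, step=25)
    assert np.all(prof["other"] == 100.0)


def test_planted_mismatch_block_drops_window_identity():
    ref = "A" * 400
    other = "A" * 100 + "C" * 10 + "A" * 290
    aln = make_alignment(ref=ref, other=other)
    prof = pm.sliding_identity(aln, "ref", window=100, step=100)
    assert prof["other"][1] == 90.0
    assert prof["other"][0] == 100.0


def test_profile_mean_tracks_p_distance(small_truth):
    aln = small_truth.alignment.subset(["TiliaA", "TiliaB"])
    prof = pm.sliding_identity(aln, "TiliaA", window=200, step=200)
    p = pm.p_distance(aln, "TiliaA", "TiliaB")
    assert np.nanmean(prof["TiliaB"]) == pytest.approx(100 * (1 - p), abs=0.1)


def test_oversized_window_warns_and_truncates():
    aln = make_alignment(a="ACGTACGT", b="ACGTACGT")
    with pytest.warns(UserWarning, match="window"):
        prof = pm.sliding_identity(aln, "a", window=100, step=1)
    assert prof["b"].shape == (1,)


# -- informative sites ------------------------------------------------------


def _brute_force_informative(cols):
    n = 0
    for col in cols:
        bases = [c for c in col if c in "ACGT"]
        counts = {b: bases.count(b) for b in set(bases)}
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def test_informative_sites_definition_cases():
    aln = make_alignment(a="AA", b="AA", c="TA", d="TT")
    # column 0: A,A,T,T informative; column 1: A,A,A,T not
    assert pm.count_informative_sites(aln) == 1


def test_all_identical_alignment_has_none():
    aln = make_alignment(a="ACGT", b="ACGT", c="ACGT", d="ACGT")
    assert pm.count_informative_sites(aln) == 0


def test_informative_sites_exhaustive_against_brute_force():
    """All 4-taxon columns over {A,C,T,-}, three at a time, agree with an
    independent pattern-enumeration count."""
    symbols = "ACT-"
    patterns = list(itertools.product(symbols, repeat=4))
    # drop columns that would make a row all-gap across the 3-col alignment
    trip = [p for p in patterns if set(p) != {"-"}]
    cols = trip[:]
    rows = ["".join(c[i] for c in cols) for i in range(4)]
    if any(set(r) == {"-"} for r in rows):
        pytest.skip("degenerate arrangement")
    aln = make_alignment(t1=rows[0], t2=rows[1], t3=rows[2], t4=rows[3])
    assert pm.count_informative_sites(aln) == _brute_force_informative(cols)


def test_informative_sites_requires_four_taxa():
    aln = make_alignment(a="ACGT", b="ACGT", c="ACGT")
    with pytest.raises(ValueError, match="4 taxa"):
        pm.count_informative_sites(aln)
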