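"""Quadripartite structure: inverted-repeat detection, region labelling,
SSC orientation, and junction gene overlaps.

A typical plastome is a circle partitioned into a large single-copy region
(LSC), a small single-copy region (SSC) and two inverted repeats (IRa/IRb)
that are exact reverse complements of each other. Detection here is by
exact-match maximal repeats: the two IR copies of one assembled genome are
identical, so a mismatch-tolerant search is unnecessary. All coordinates are
0-based half-open on the circle; intervals are reported as (start, end) with
``end`` possibly numerically smaller than ``start`` when a region wraps the
origin (use the stored lengths, which are unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from .io import GenomeFeature, PlastomeRecord, revcomp

__all__ = [
    "QuadripartiteStructure",
    "JunctionEntry",
    "JunctionReport",
    "NoQuadripartiteStructure",
    "detect_inverted_repeats",
    "canonicalize_orientation",
    "junction_report",
    "OrientationResult",
]

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


class NoQuadripartiteStructure(ValueError):
    """No reverse-complement repeat pair of the required size exists."""

    def __init__(self, msg: str, longest_found: int = 0):
        super().__init__(msg)
        self.longest_found = longest_found


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/SSC/IRa/IRb intervals on the circular genome.

    Junction naming: JLB is the LSC/IRb boundary, JSB the IRb/SSC boundary,
    JSA the SSC/IRa boundary and JLA the IRa/LSC boundary; IRb is the IR
    copy immediately downstream of the LSC.
    """

    genome_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    def _ilen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return (e - s) % self.genome_length or (
            self.genome_length if e == s else 0
        )

    @property
    def lsc_length(self) -> int:
        return self._ilen(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._ilen(self.ssc)

    @property
    def ir_length(self) -> int:
        return self._ilen(self.ira)

    @property
    def junctions(self) -> dict[str, int]:
        """Junction positions: the first base of the downstream region."""
        return {
            "JLB": self.irb[0],
            "JSB": self.ssc[0],
            "JSA": self.ira[0],
            "JLA": self.lsc[0],
        }

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(self, name)
            if (pos - s) % self.genome_length < self._ilen((s, e)):
                return name.upper() if name.startswith("ir") else name.upper()
        raise AssertionError("position not covered by any region")


def _maximal_rc_matches(seq: str, min_len: int, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches between the circular sequence and its reverse
    complement, as (a, b, m): S[a:a+m] (circular) == revcomp(S[b:b+m]).
    """
    L = len(seq)
    s2 = seq + seq
    r = revcomp(seq)
    r2 = r + r

    kmer_pos: dict[str, list[int]] = {}
    for j in range(2 * L - k + 1):
        kmer_pos.setdefault(r2[j : j + k], []).append(j)

    hits: list[tuple[int, int, int]] = []
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> seen i-intervals
    for i in range(L):
        positions = kmer_pos.get(s2[i : i + k])
        if not positions:
            continue
        for j in positions:
            d = i - j
            if any(lo <= i < hi for lo, hi in covered.get(d, ())):
                continue
            # extend the seed to a maximal match along this diagonal
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and s2[lo_i - 1] == r2[lo_j - 1]:
                lo_i -= 1
                lo_j -= 1
            hi_i, hi_j = i + k, j + k
            while (
                hi_i < 2 * L
                and hi_j < 2 * L
                and hi_i - lo_i < L
                and s2[hi_i] == r2[hi_j]
            ):
                hi_i += 1
                hi_j += 1
            covered.setdefault(d, []).append((lo_i, hi_i))
            m = hi_i - lo_i
            if m < min_len:
                continue
            a = lo_i % L
            b = (L - (lo_j % L) - m) % L
            hits.append((a, b, m))
    return hits


def _disjoint_on_circle(a: int, b: int, m: int, L: int) -> bool:
    """Do circular intervals [a,a+m) and [b,b+m) not overlap?"""
    if 2 * m > L:
        return False
    gap_ab = (b - (a + m)) % L
    gap_ba = (a - (b + m)) % L
    return gap_ab + gap_ba == L - 2 * m


def detect_inverted_repeats(
    record: PlastomeRecord, min_ir_length: int = 1000, seed_k: int | None = None
) -> QuadripartiteStructure:
    """Find the inverted repeat and partition the genome into four regions.

    Returns the longest pair of disjoint, exactly reverse-complementary
    repeats of at least ``min_ir_length`` bases, labelling the longer
    single-copy region LSC and the shorter SSC. Works across the sequence
    origin. Ties on repeat length are broken by maximizing the shorter
    single-copy region, then by coordinates, so the result is deterministic.
    """
    L = record.length
    if L <= 4 * min_ir_length:
        raise ValueError(
            f"sequence length {L} too short for min_ir_length={min_ir_length}"
        )
    k = seed_k if seed_k is not None else max(12, min(31, min_ir_length // 2))
    hits = _maximal_rc_matches(record.sequence, min_ir_length, k)

    candidates = []
    seen = set()
    longest_any = 0
    for a, b, m in hits:
        longest_any = max(longest_any, m)
        if not _disjoint_on_circle(a, b, m, L):
            continue
        key = (min(a, b), max(a, b), m)
        if key in seen:
            continue
        seen.add(key)
        gap_ab = (b - (a + m)) % L  # single-copy region following copy at a
        gap_ba = (a - (b + m)) % L
        candidates.append((m, min(gap_ab, gap_ba), a, b, gap_ab, gap_ba))

    if not candidates:
        raise NoQuadripartiteStructure(
            f"no disjoint reverse-complement repeat pair ≥ {min_ir_length} bp "
            f"(longest repeat found: {longest_any} bp)",
            longest_found=longest_any,
        )

    m, _, a, b, gap_ab, gap_ba = max(
        candidates, key=lambda c: (c[0], c[1], -c[2], -c[3])
    )

    # LSC is the longer single-copy gap; IRb is the copy downstream of LSC.
    if gap_ba >= gap_ab:
        # LSC runs from b+m to a; copy at a is IRb; SSC = gap_ab; copy at b is IRa
        lsc = ((b + m) % L, a)
        irb = (a, (a + m) % L)
        ssc = ((a + m) % L, b)
        ira = (b, (b + m) % L)
    else:
        lsc = ((a + m) % L, b)
        irb = (b, (b + m) % L)
        ssc = ((b + m) % L, a)
        ira = (a, (a + m) % L)
    return QuadripartiteStructure(L, lsc=lsc, irb=irb, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------


@dataclass
class OrientationResult:
    record: PlastomeRecord
    flipped: bool
    forward_distance: int
    reverse_distance: int


def canonicalize_orientation(
    record: PlastomeRecord,
    structure: QuadripartiteStructure,
    reference: PlastomeRecord,
    reference_structure: QuadripartiteStructure,
) -> OrientationResult:
    """Flip the SSC segment if its reverse complement matches the reference
    SSC better than the forward orientation.

    The SSC of a plastome exists as two equimolar isomers; assemblies pick
    one arbitrarily. Flipping changes no gene order — features inside the
    SSC have their coordinates reflected and strands inverted. Alignment
    distances are computed with edlib (global edit distance).
    """
    if reference_structure is None:
        raise ValueError("reference record lacks a quadripartite structure")
    ssc = record.subsequence(*structure.ssc)
    ref_ssc = reference.subsequence(*reference_structure.ssc)
    fwd = edlib.align(ssc, ref_ssc, mode="NW", task="distance")["editDistance"]
    rev = edlib.align(revcomp(ssc), ref_ssc, mode="NW", task="distance")["editDistance"]
    if rev >= fwd:
        return OrientationResult(record, False, fwd, rev)

    # rebuild the sequence with the SSC segment reverse-complemented
    L = record.length
    s, e = structure.ssc
    slen = structure.ssc_length
    rot = record.rotated(s)  # SSC now occupies [0, slen)
    new_seq = revcomp(rot.sequence[:slen]) + rot.sequence[slen:]

    def reflect(iv):
        a, b = iv
        return (slen - b, slen - a)

    feats = []
    for f in rot.features:
        if f.end <= slen:  # wholly inside the SSC: reflect and flip strand
            exons = tuple(sorted(reflect(iv) for iv in f.exons))
            feats.append(replace(f, exons=exons, strand=-f.strand))
        else:
            feats.append(f)
    flipped_rec = PlastomeRecord(record.id, new_seq, record.circular, feats).rotated(
        (-s) % L
    )
    return OrientationResult(flipped_rec, True, fwd, rev)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionEntry:
    junction: str
    gene: str | None  # gene spanning the junction, if any
    overlap_into_ir: int  # bases of that gene inside the IR (0 if none)
    nearest_gene: str | None = None  # for 0-overlap junctions
    nearest_distance: int | None = None


@dataclass(frozen=True)
class JunctionReport:
    entries: dict[str, JunctionEntry]

    def __getitem__(self, junction: str) -> JunctionEntry:
        return self.entries[junction]


def _extent_contains(f: GenomeFeature, pos: int) -> bool:
    """Does the linear extent (first exon start to last exon end) cover pos?"""
    return f.start <= pos < f.end


def _circular_intersection(a_s: int, a_len: int, b_s: int, b_len: int, L: int) -> int:
    """Length of the intersection of circular intervals [a_s,a_s+a_len) and
    [b_s,b_s+b_len)."""
    total = 0
    off = (b_s - a_s) % L
    for o in (off, off - L):
        total += max(0, min(a_len, o + b_len) - max(0, o))
    return total


def junction_report(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> JunctionReport:
    """For each of the four junctions, report the gene crossing it and how
    many of its bases extend into the IR; junctions crossed by no gene
    report the nearest flanking gene and its distance instead.
    """
    L = record.length
    ir_for_junction = {
        "JLB": structure.irb,
        "JSB": structure.irb,
        "JSA": structure.ira,
        "JLA": structure.ira,
    }
    entries = {}
    for name, pos in structure.junctions.items():
        if not record.features:
            entries[name] = JunctionEntry(name, None, 0)
            continue
        spanning = None
        before = (pos - 1) % L
        for f in record.features:
            if _extent_contains(f, before) and _extent_contains(f, pos):
                spanning = f
                break
        if spanning is not None:
            ir_s, _ = ir_for_junction[name]
            overlap = _circular_intersection(
                spanning.start,
                spanning.end - spanning.start,
                ir_s,
                structure.ir_length,
                L,
            )
            entries[name] = JunctionEntry(name, spanning.name, overlap)
        else:
            # nearest flanking gene: smallest circular distance from the
            # junction point to any feature boundary
            best, bdist = None, None
            for f in record.features:
                for bpos in (f.start, f.end):
                    d = min((bpos - pos) % L, (pos - bpos) % L)
                    if bdist is None or d < bdist:
                        best, bdist = f, d
            entries[name] = JunctionEntry(
                name, None, 0, nearest_gene=best.name if best else None,
                nearest_distance=bdist,
            )
    return JunctionReport(entries)
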