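"""Genome-size decomposition between two annotated plastomes.

The genome is partitioned into genes (exon unions), introns and intergenic
spacers (IGS) on a single-IR representation (LSC + IRb + SSC, dropping the
IRa copy so duplicated genes are counted once). Matched elements between
two genomes then attribute the whole-genome size difference to individual
loci, and a pairwise indel list attributes it to individual large indels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io import PlastomeRecord
from .quadripartite import QuadripartiteStructure
from .spectrum import IndelEvent

__all__ = [
    "PartitionElement",
    "RegionPartition",
    "RegionSizes",
    "SizeComparison",
    "LargeIndelSummary",
    "partition_genome",
    "compare_partitions",
    "size_deltas",
    "large_indel_accounting",
]


@dataclass(frozen=True)
class PartitionElement:
    name: str
    klass: str  # gene | intron | IGS
    interval: tuple[int, int]  # on the linearized LSC+IRb+SSC representation

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class RegionSizes:
    """Printed-table genome metrics: total and per-region lengths in bp."""

    total: int
    lsc: int
    ssc: int
    ir: int


@dataclass
class RegionPartition:
    genome_id: str
    elements: list[PartitionElement]
    represented_length: int  # LSC + one IR + SSC
    region_sizes: RegionSizes

    def by_name(self) -> dict[str, PartitionElement]:
        return {e.name: e for e in self.elements}

    def total_length(self) -> int:
        return sum(e.length for e in self.elements)


def partition_genome(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> RegionPartition:
    """Tile the LSC + IRb + SSC representation into genes, introns and IGS.

    Gene elements are exon unions per feature; introns are the gaps between
    consecutive exons of one feature; IGS are the maximal intervals covered
    by no gene extent, named after their flanking genes. Where two gene
    extents overlap, the overlap is assigned to the earlier-starting gene
    and the later element starts where the earlier ends, preserving an
    exact tiling so that length deltas stay additive.
    """
    L = record.length
    # rotate so the representation LSC+IRb+SSC starts at 0
    rot = record.rotated(structure.lsc[0])
    rep_len = structure.lsc_length + structure.ir_length + structure.ssc_length
    ira_start = rep_len  # IRa occupies [rep_len, L) after rotation

    feats = [f for f in rot.features if f.start < ira_start and not f.is_duplicate]
    if not feats:
        warnings.warn(f"record {record.id}: no annotation; single-IGS partition")
        sizes = RegionSizes(L, structure.lsc_length, structure.ssc_length, structure.ir_length)
        return RegionPartition(
            record.id,
            [PartitionElement("whole_genome", "IGS", (0, rep_len))],
            rep_len,
            sizes,
        )
    feats.sort(key=lambda f: (f.start, f.end))

    elements: list[PartitionElement] = []
    cursor = 0
    prev_name = None
    intron_counts: dict[str, int] = {}
    for f in feats:
        start = max(f.start, cursor)
        end = min(f.end, ira_start)
        if end <= start:
            continue  # fully swallowed by an earlier overlapping gene
        if start > cursor:
            left = prev_name if prev_name else "origin"
            elements.append(
                PartitionElement(f"{left}-{f.name}", "IGS", (cursor, start))
            )
        # exons and introns inside the (possibly truncated) extent
        exon_ivs = sorted(
            (max(s, start), min(e, end)) for s, e in f.exons if min(e, end) > max(s, start)
        )
        if not exon_ivs:
            exon_ivs = [(start, end)]
        pos = start
        n_intr = 0
        for i, (xs, xe) in enumerate(exon_ivs):
            if xs > pos:
                n_intr += 1
                intron_counts[f.name] = intron_counts.get(f.name, 0) + 1
                idx = intron_counts[f.name]
                elements.append(
                    PartitionElement(f"{f.name}_intron{idx}", "intron", (pos, xs))
                )
            pos = xe
        # one gene element per feature covering its exon bases; interval is
        # the extent minus introns — record exons as separate slices but a
        # single named element keeps cross-genome matching simple, so we
        # emit one element per exon slice sharing the name
        for i, (xs, xe) in enumerate(exon_ivs):
            suffix = "" if len(exon_ivs) == 1 else f"_exon{i + 1}"
            elements.append(
                PartitionElement(f"{f.name}{suffix}", "gene", (xs, xe))
            )
        cursor = max(cursor, end)
        prev_name = f.name
    if cursor < ira_start:
        elements.append(
            PartitionElement(f"{prev_name}-origin", "IGS", (cursor, ira_start))
        )
    elements.sort(key=lambda e: e.interval)
    sizes = RegionSizes(
        L, structure.lsc_length, structure.ssc_length, structure.ir_length
    )
    return RegionPartition(record.id, elements, rep_len, sizes)


# ---------------------------------------------------------------------------


def _igs_key(name: str) -> frozenset:
    return frozenset(name.split("-"))


@dataclass
class MatchedElement:
    name: str
    klass: str
    length_a: int
    length_b: int

    @property
    def delta(self) -> int:
        return self.length_a - self.length_b


@dataclass
class SizeComparison:
    genome_a: str
    genome_b: str
    matched: list[MatchedElement]
    unmatched_a: list[PartitionElement]
    unmatched_b: list[PartitionElement]
    whole_genome_delta: int
    region_deltas: dict[str, int]
    large_threshold: int

    @property
    def totals_per_klass(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.matched:
            out[m.klass] = out.get(m.klass, 0) + m.delta
        return out

    @property
    def larger_in_a(self) -> int:
        return sum(1 for m in self.matched if m.delta > 0)

    @property
    def larger_in_b(self) -> int:
        return sum(1 for m in self.matched if m.delta < 0)

    @property
    def equal(self) -> int:
        return sum(1 for m in self.matched if m.delta == 0)

    @property
    def large_elements(self) -> list[MatchedElement]:
        return [m for m in self.matched if abs(m.delta) >= self.large_threshold]


def size_deltas(a: RegionSizes, b: RegionSizes) -> dict[str, int]:
    """Whole-genome and per-region length differences (a minus b), in bp."""
    return {
        "total": a.total - b.total,
        "lsc": a.lsc - b.lsc,
        "ssc": a.ssc - b.ssc,
        "ir": a.ir - b.ir,
    }


def compare_partitions(
    a: RegionPartition, b: RegionPartition, large_threshold: int = 100
) -> SizeComparison:
    """Match elements by name across two partitions and report length deltas.

    Genes and introns match on exact name; IGS match on the unordered pair
    of flanking gene names, so a local strand flip does not break matching.
    Elements without a partner are listed separately — rearranged
    neighborhoods yield unmatched elements rather than forced matches.
    """
    def keyed(p: RegionPartition) -> dict:
        out = {}
        for e in p.elements:
            key = (e.klass, _igs_key(e.name)) if e.klass == "IGS" else (e.klass, e.name)
            out.setdefault(key, []).append(e)
        return out

    ka, kb = keyed(a), keyed(b)
    matched, unmatched_a, unmatched_b = [], [], []
    for key, elems_a in ka.items():
        elems_b = kb.get(key)
        if elems_b is None or len(elems_a) != 1 or len(elems_b) != 1:
            unmatched_a.extend(elems_a)
            if elems_b:
                unmatched_b.extend(elems_b)
            continue
        ea, eb = elems_a[0], elems_b[0]
        matched.append(MatchedElement(ea.name, ea.klass, ea.length, eb.length))
    for key, elems_b in kb.items():
        if key not in ka:
            unmatched_b.extend(elems_b)

    return SizeComparison(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        matched=matched,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        whole_genome_delta=a.region_sizes.total - b.region_sizes.total,
        region_deltas=size_deltas(a.region_sizes, b.region_sizes),
        large_threshold=large_threshold,
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LargeIndelSummary:
    n_large: int
    summed_length: int  # signed toward the focal genome
    fraction_of_delta: float | None


def large_indel_accounting(
    events: list[IndelEvent],
    total_delta: int,
    focal_taxon: str,
    min_len: int = 100,
) -> LargeIndelSummary:
    """How much of a pairwise size difference do large indels explain?

    ``events`` is a polarized indel list from a two-taxon (+outgroup)
    alignment; ``focal_taxon`` is the genome whose size excess
    ``total_delta`` (focal minus other) is being decomposed. Insertions
    carried by the focal taxon and deletions carried by the other count
    positive; the reverse count negative. The fraction is the signed sum
    over ``total_delta`` (undefined when the delta is 0).
    """
    signed = 0
    n = 0
    for e in events:
        if e.length < min_len:
            continue
        n += 1
        carried_by_focal = focal_taxon in e.carriers
        if e.polarity == "insertion":
            signed += e.length if carried_by_focal else -e.length
        else:
            signed += -e.length if carried_by_focal else e.length
    frac = None if total_delta == 0 else signed / total_delta
    return LargeIndelSummary(n_large=n, summed_length=signed, fraction_of_delta=frac)
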