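"""Sequence-divergence statistics on multiple alignments.

Implements uncorrected p-distance with pairwise deletion, per-region
percent variability of noncoding loci, sliding-window percent identity,
and parsimony-informative site counting. Divergence among congeneric
plastomes is typically tiny (p ~ 1e-3), so everything here is exact
counting — no model correction is applied or needed at these depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import GAP, AlignmentMatrix

__all__ = [
    "read_region_table",
    "RegionAnnotationOnAlignment",
    "VariabilityRecord",
    "DivergenceSummary",
    "p_distance",
    "overall_divergence",
    "region_variability",
    "sliding_identity",
    "count_informative_sites",
    "gap_runs",
]

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no gap-free comparable column."""


def _is_base(arr: np.ndarray) -> np.ndarray:
    return (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))


def p_distance(aln: AlignmentMatrix, taxon_a: str, taxon_b: str) -> float:
    """Uncorrected p-distance between two alignment rows.

    Only columns where both taxa carry a base in {A,C,G,T} are compared
    (pairwise deletion); gaps and N are skipped.
    """
    a = aln.row_array(taxon_a)
    b = aln.row_array(taxon_b)
    comparable = _is_base(a) & _is_base(b)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {taxon_a!r} and {taxon_b!r}"
        )
    mism = int((a[comparable] != b[comparable]).sum())
    return mism / n


@dataclass(frozen=True)
class DivergenceSummary:
    mean: float
    min: float
    max: float
    pairwise: dict[tuple[str, str], float]


def overall_divergence(
    aln: AlignmentMatrix, taxa: list[str] | None = None
) -> DivergenceSummary:
    """Mean/min/max pairwise p-distance over all unordered pairs of taxa."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    pairwise = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            pairwise[(a, b)] = p_distance(aln, a, b)
    vals = list(pairwise.values())
    return DivergenceSummary(
        mean=float(np.mean(vals)), min=min(vals), max=max(vals), pairwise=pairwise
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionAnnotationOnAlignment:
    """A locus mapped onto alignment columns (half-open column interval)."""

    name: str
    klass: str  # gene | intron | IGS
    columns: tuple[int, int]

    @property
    def aligned_length(self) -> int:
        return self.columns[1] - self.columns[0]


@dataclass(frozen=True)
class VariabilityRecord:
    name: str
    klass: str
    aligned_length: int
    n_substitution_sites: int
    n_indel_events: int

    @property
    def percent_variable(self) -> float:
        return 100.0 * (self.n_substitution_sites + self.n_indel_events) / self.aligned_length


def read_region_table(path) -> list[RegionAnnotationOnAlignment]:
    """Read a region TSV (name, klass, col_start, col_end; 1-based inclusive
    columns) into alignment-space region annotations."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            name, klass, cs, ce = parts[:4]
            out.append(
                RegionAnnotationOnAlignment(name, klass, (int(cs) - 1, int(ce)))
            )
    return out


def gap_runs(aln: AlignmentMatrix, taxa: list[str] | None = None) -> dict[tuple[int, int], frozenset[str]]:
    """Maximal gap runs per taxon, grouped by (start, end) column interval.

    Returns a mapping interval → set of taxa whose row is gapped over
    exactly that maximal interval. Two overlapping runs with different
    boundaries are distinct keys.
    """
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    runs: dict[tuple[int, int], set[str]] = {}
    for t in taxa:
        r = aln.row_array(t)
        isgap = (r == GAP).astype(np.int8)
        if not isgap.any():
            continue
        d = np.diff(isgap)
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if isgap[0]:
            starts.insert(0, 0)
        if isgap[-1]:
            ends.append(len(r))
        for s, e in zip(starts, ends):
            runs.setdefault((int(s), int(e)), set()).add(t)
    return {iv: frozenset(ts) for iv, ts in runs.items()}


def _substitution_site_mask(mat: np.ndarray) -> np.ndarray:
    """Columns with ≥2 distinct bases among rows, ignoring gaps and N."""
    ncol = mat.shape[1]
    present = np.zeros((4, ncol), dtype=bool)
    for i, code in enumerate(_BASE_CODES):
        present[i] = (mat == code).any(axis=0)
    return present.sum(axis=0) >= 2


def region_variability(
    aln: AlignmentMatrix,
    regions: list[RegionAnnotationOnAlignment],
    taxa: list[str] | None = None,
    min_aligned_length: int = 200,
) -> list[VariabilityRecord]:
    """Percent variable characters per noncoding region.

    For each region longer than ``min_aligned_length`` aligned columns:
    substitution sites are columns with at least two distinct bases among
    the taxa (gap/N ignored columnwise); indel events are maximal gap runs,
    counted once per distinct (start, end) interval regardless of how many
    taxa share the run, with a run attributed to the region containing its
    first column. Percent variable = 100 × (sites + events) / aligned length.
    """
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    order = sorted(regions, key=lambda r: r.columns)
    for r1, r2 in zip(order, order[1:]):
        if r1.columns[1] > r2.columns[0]:
            raise ValueError(f"regions {r1.name} and {r2.name} overlap on the alignment")

    sub = aln.subset(taxa)
    site_mask = _substitution_site_mask(sub.matrix)
    all_runs = gap_runs(aln, taxa)

    out = []
    for reg in regions:
        if reg.aligned_length <= min_aligned_length:
            continue
        s, e = reg.columns
        n_sites = int(site_mask[s:e].sum())
        n_events = sum(1 for (rs, _re) in all_runs if s <= rs < e)
        out.append(
            VariabilityRecord(
                name=reg.name,
                klass=reg.klass,
                aligned_length=reg.aligned_length,
                n_substitution_sites=n_sites,
                n_indel_events=n_events,
            )
        )
    return out


# ---------------------------------------------------------------------------


def sliding_identity(
    aln: AlignmentMatrix,
    reference: str,
    window: int = 100,
    step: int = 25,
    taxa: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Percent identity to a reference taxon in sliding column windows.

    Per window and non-reference taxon: 100 × (columns where both carry the
    same base) / (columns where either carries a base). Windows are indexed
    by their starting alignment column; ``windows`` in the result maps each
    window to the reference (ungapped) coordinate of its first column.
    """
    if not (window >= step >= 1):
        raise ValueError("require window ≥ step ≥ 1")
    if window > aln.ncol:
        warnings.warn(
            f"window {window} exceeds alignment length {aln.ncol}; "
            "returning a single truncated window"
        )
        window = aln.ncol
    taxa = [t for t in (taxa or aln.taxa) if t != reference]
    ref = aln.row_array(reference)
    ref_base = _is_base(ref)
    starts = np.arange(0, aln.ncol - window + 1, step)
    refmap = aln.colmap(reference)

    out: dict[str, np.ndarray] = {"window_start_column": starts}
    # reference coordinate of each window: first non-gap ref position ≥ start
    ref_coords = []
    for s in starts:
        seg = refmap[s : s + window]
        nz = seg[seg >= 0]
        ref_coords.append(int(nz[0]) if nz.size else -1)
    out["window_start_reference_coord"] = np.array(ref_coords)

    for t in taxa:
        row = aln.row_array(t)
        match = (ref_base & _is_base(row) & (ref == row)).astype(np.int64)
        either = (ref_base | _is_base(row)).astype(np.int64)
        cm = np.concatenate([[0], np.cumsum(match)])
        ce = np.concatenate([[0], np.cumsum(either)])
        num = cm[starts + window] - cm[starts]
        den = ce[starts + window] - ce[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(den > 0, 100.0 * num / den, np.nan)
        out[t] = pct
    return out


def count_informative_sites(aln: AlignmentMatrix, taxa: list[str] | None = None) -> int:
    """Number of parsimony-informative columns: ≥2 distinct bases, each
    present in ≥2 of the chosen taxa. Gaps and N are not states."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    if len(taxa) < 4:
        raise ValueError("parsimony-informative counting needs ≥4 taxa")
    mat = aln.subset(taxa).matrix
    counts = np.stack([(mat == c).sum(axis=0) for c in _BASE_CODES])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())
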