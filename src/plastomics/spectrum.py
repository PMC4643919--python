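"""Outgroup-polarized mutation spectra.

Substitutions and indels segregating within an ingroup are assigned a
direction (ancestral → derived) using a single outgroup taxon. Event
counting is per derived allele: a derived state shared by several ingroup
taxa is one event, the parsimonious reading on a shallow tree where every
variant has a single origin. Indels are additionally classified by their
local repeat context (homopolymer, tandem repeat, or none), the footprint
expected of slipped-strand mispairing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, AlignmentMatrix
from .divergence import gap_runs

__all__ = [
    "SubstitutionEvent",
    "IndelEvent",
    "SpectrumSummary",
    "PolarizationResult",
    "IndelCallResult",
    "polarize_substitutions",
    "substitution_spectrum",
    "call_and_polarize_indels",
    "classify_indel_context",
    "classify_context",
    "indel_length_spectrum",
    "IndelLengthSpectrum",
    "DIRECTIONS",
    "TRANSITIONS",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"
DIRECTIONS = tuple(f"{a}>{b}" for a in BASES for b in BASES if a != b)
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


def substitution_class(ancestral: str, derived: str) -> str:
    if (ancestral in PURINES) == (derived in PURINES):
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class SubstitutionEvent:
    column: int
    ancestral: str
    derived: str
    carriers: tuple[str, ...]

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived state must differ")

    @property
    def klass(self) -> str:
        return substitution_class(self.ancestral, self.derived)

    @property
    def direction(self) -> str:
        return f"{self.ancestral}>{self.derived}"


@dataclass(frozen=True)
class IndelEvent:
    columns: tuple[int, int]  # half-open alignment column interval
    polarity: str  # insertion | deletion
    carriers: tuple[str, ...]
    seq: str  # the inserted or deleted bases
    context: str = "unclassified"  # homopolymer | tandem_repeat | none

    @property
    def length(self) -> int:
        return self.columns[1] - self.columns[0]


@dataclass
class PolarizationResult:
    events: list[SubstitutionEvent]
    skipped: Counter = field(default_factory=Counter)


def polarize_substitutions(
    aln: AlignmentMatrix, ingroup: list[str], outgroup: str
) -> PolarizationResult:
    """Polarize ingroup substitutions against the outgroup state.

    A column yields one event when (i) every considered taxon carries a
    base (no gap/N), (ii) the ingroup shows exactly two states, and (iii)
    the outgroup state equals one of them. The outgroup state is then
    ancestral and the ingroup taxa bearing the other state are the
    carriers. Columns failing a condition are tallied by skip reason:
    ``gap_or_n``, ``ingroup_invariant``, ``ingroup_multiallelic``,
    ``outgroup_mismatch``.
    """
    if outgroup not in aln.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    ing = aln.subset(list(ingroup)).matrix
    out_row = aln.row_array(outgroup)
    considered = np.vstack([ing, out_row])

    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    is_base = np.isin(considered, base_codes)
    clean = is_base.all(axis=0)

    present = np.stack([(ing == c).any(axis=0) for c in base_codes])  # 4 × ncol
    n_states = present.sum(axis=0)

    result = PolarizationResult(events=[])
    result.skipped["gap_or_n"] = int((~clean).sum())

    biallelic = clean & (n_states == 2)
    result.skipped["ingroup_invariant"] = int((clean & (n_states == 1)).sum())
    result.skipped["ingroup_multiallelic"] = int((clean & (n_states > 2)).sum())

    cols = np.flatnonzero(biallelic)
    for col in cols:
        states = [BASES[i] for i in range(4) if present[i, col]]
        out_state = chr(out_row[col])
        if out_state not in states:
            result.skipped["outgroup_mismatch"] += 1
            continue
        derived = states[0] if states[1] == out_state else states[1]
        carriers = tuple(
            t for t, c in zip(ingroup, ing[:, col]) if chr(c) == derived
        )
        result.events.append(
            SubstitutionEvent(
                column=int(col),
                ancestral=out_state,
                derived=derived,
                carriers=carriers,
            )
        )
    return result


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelLengthSpectrum:
    insertion_lengths: Counter
    deletion_lengths: Counter

    @staticmethod
    def _frac1(c: Counter) -> float | None:
        total = sum(c.values())
        return c[1] / total if total else None

    @property
    def fraction_1bp_insertions(self) -> float | None:
        return self._frac1(self.insertion_lengths)

    @property
    def fraction_1bp_deletions(self) -> float | None:
        return self._frac1(self.deletion_lengths)

    @property
    def max_insertion(self) -> int:
        return max(self.insertion_lengths, default=0)

    @property
    def max_deletion(self) -> int:
        return max(self.deletion_lengths, default=0)


def indel_length_spectrum(events: list[IndelEvent]) -> IndelLengthSpectrum:
    """Per-polarity indel length histogram with 1-bp fractions and maxima."""
    ins = Counter(e.length for e in events if e.polarity == "insertion")
    dele = Counter(e.length for e in events if e.polarity == "deletion")
    return IndelLengthSpectrum(ins, dele)


@dataclass(frozen=True)
class SpectrumSummary:
    """The 12-direction substitution spectrum plus indel totals."""

    direction_counts: dict[str, int]
    n_transitions: int
    n_transversions: int
    n_insertions: int = 0
    n_deletions: int = 0
    n_repeat_associated: int = 0
    indel_lengths: IndelLengthSpectrum | None = None
    overrepresented: tuple[str, ...] = ()
    underrepresented: tuple[str, ...] = ()

    @property
    def n_substitutions(self) -> int:
        return self.n_transitions + self.n_transversions

    @property
    def ts_tv_ratio(self) -> float | None:
        """Transitions / transversions; None (undefined) if no transversions."""
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions


def substitution_spectrum(
    events: list[SubstitutionEvent], indel_events: list[IndelEvent] | None = None
) -> SpectrumSummary:
    """Tally events into the 12 directed substitution cells.

    Cells more than two Poisson standard deviations above (below) the
    uniform expectation total/12 are flagged over-(under-)represented —
    a descriptive screen, not a hypothesis test.
    """
    counts = {d: 0 for d in DIRECTIONS}
    n_ts = n_tv = 0
    for e in events:
        counts[e.direction] += 1
        if e.klass == "transition":
            n_ts += 1
        else:
            n_tv += 1
    total = n_ts + n_tv
    over, under = [], []
    if total:
        expect = total / 12
        sd = max(expect**0.5, 1.0)
        for d in DIRECTIONS:
            if counts[d] > expect + 2 * sd:
                over.append(d)
            elif counts[d] < expect - 2 * sd:
                under.append(d)

    indel_events = indel_events or []
    n_ins = sum(1 for e in indel_events if e.polarity == "insertion")
    n_del = sum(1 for e in indel_events if e.polarity == "deletion")
    n_rep = sum(
        1 for e in indel_events if e.context in ("homopolymer", "tandem_repeat")
    )
    return SpectrumSummary(
        direction_counts=counts,
        n_transitions=n_ts,
        n_transversions=n_tv,
        n_insertions=n_ins,
        n_deletions=n_del,
        n_repeat_associated=n_rep,
        indel_lengths=indel_length_spectrum(indel_events) if indel_events else None,
        overrepresented=tuple(over),
        underrepresented=tuple(under),
    )


# ---------------------------------------------------------------------------


@dataclass
class IndelCallResult:
    events: list[IndelEvent]
    excluded: Counter = field(default_factory=Counter)


def call_and_polarize_indels(
    aln: AlignmentMatrix, ingroup: list[str], outgroup: str
) -> IndelCallResult:
    """Call indel events from gap runs and polarize them with the outgroup.

    Each distinct (column interval, gapped-taxon set) maximal gap run is one
    candidate event. Over its interval:

    * gapped set = proper nonempty ingroup subset, everyone else fully
      base-bearing → **deletion** in the gapped taxa;
    * gapped set = outgroup + a (possibly empty) proper ingroup subset, the
      remaining ingroup fully base-bearing → **insertion** in the
      base-bearing ingroup taxa (the sequence is absent from the outgroup,
      hence ancestrally absent);
    * gap pattern identical across the whole ingroup → not a variant within
      the ingroup, excluded (``not_variable_in_ingroup``);
    * any taxon partially gapped over the interval via a different run
      (staggered boundaries) → excluded as ``unpolarizable``.

    Distinct overlapping runs are separate events; runs are never merged
    across intervening base columns.
    """
    if outgroup not in aln.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    taxa = list(ingroup) + [outgroup]
    sub = aln.subset(taxa)
    runs = gap_runs(sub)
    ingroup_set = frozenset(ingroup)

    result = IndelCallResult(events=[])
    for (s, e), gapped in sorted(runs.items()):
        others = [t for t in taxa if t not in gapped]
        # taxa not in this run must be fully ungapped over [s, e)
        clean_others = [
            t for t in others if not (sub.row_array(t)[s:e] == GAP).any()
        ]
        if len(clean_others) != len(others):
            result.excluded["unpolarizable"] += 1
            continue
        if outgroup not in gapped:
            if gapped == ingroup_set:
                result.excluded["not_variable_in_ingroup"] += 1
                continue
            carriers = tuple(t for t in ingroup if t in gapped)
            donor = outgroup  # any base-bearing taxon carries the deleted bases
            seq = sub.row_array(donor)[s:e].tobytes().decode()
            result.events.append(
                IndelEvent((int(s), int(e)), "deletion", carriers, seq)
            )
        else:
            carriers = tuple(t for t in ingroup if t not in gapped)
            if not carriers:
                result.excluded["all_gap_pattern"] += 1
                continue
            if len(carriers) == len(ingroup_set):
                # only the outgroup is gapped: invariant within the ingroup
                result.excluded["not_variable_in_ingroup"] += 1
                continue
            seq = sub.row_array(carriers[0])[s:e].tobytes().decode()
            result.events.append(
                IndelEvent((int(s), int(e)), "insertion", carriers, seq)
            )
    # N inside a called event sequence would poison context classification
    result.events = [
        e if "N" not in e.seq else IndelEvent(e.columns, e.polarity, e.carriers, e.seq, "none")
        for e in result.events
    ]
    return result


# ---------------------------------------------------------------------------


def classify_context(
    seq: str,
    left_flank: str,
    right_flank: str,
    homopolymer_min_run: int = 4,
) -> str:
    """Repeat-context label for an indel with the given ungapped flanks.

    * ``homopolymer``: the event sequence is a single repeated base lying
      inside a mononucleotide run of total length ≥ ``homopolymer_min_run``
      (counting the event bases plus the adjacent same-base flank bases);
    * ``tandem_repeat``: the event sequence exactly equals the immediately
      adjacent upstream or downstream flank of the same length;
    * ``none`` otherwise.

    Only the homopolymer rule applies to 1-bp events — a single-base tandem
    duplication is just a length-2 mononucleotide run, below the run
    threshold that makes slippage plausible; for longer events the tandem
    test is tried first, then the homopolymer rule.
    """

    def is_homopolymer() -> bool:
        if not seq or len(set(seq)) != 1:
            return False
        b = seq[0]
        left_run = len(left_flank) - len(left_flank.rstrip(b))
        right_run = len(right_flank) - len(right_flank.lstrip(b))
        return left_run + len(seq) + right_run >= homopolymer_min_run

    def is_tandem() -> bool:
        k = len(seq)
        return (len(left_flank) >= k and left_flank[-k:] == seq) or (
            len(right_flank) >= k and right_flank[:k] == seq
        )

    if len(seq) == 1:
        return "homopolymer" if is_homopolymer() else "none"
    if is_tandem():
        return "tandem_repeat"
    if is_homopolymer():
        return "homopolymer"
    return "none"


def classify_indel_context(
    event: IndelEvent,
    aln: AlignmentMatrix,
    homopolymer_min_run: int = 4,
) -> IndelEvent:
    """Classify one called indel using flanks extracted from the alignment.

    Flanks are read, ungapped, from a taxon that carries the indel bases:
    a carrier for insertions, the first non-carrier base-bearing taxon for
    deletions. Flanks of the event's own length are used on each side;
    if a flank is shorter (event at an alignment edge) classification runs
    on what is available, with a warning.
    """
    s, e = event.columns
    if event.polarity == "insertion":
        donor = event.carriers[0]
    else:
        donor = next(t for t in aln.taxa if t not in event.carriers)
    row = aln.row_array(donor)
    need = max(len(event.seq), homopolymer_min_run)

    left, pos = [], s - 1
    while pos >= 0 and len(left) < need:
        if row[pos] != GAP:
            left.append(chr(row[pos]))
        pos -= 1
    right, pos = [], e
    while pos < aln.ncol and len(right) < need:
        if row[pos] != GAP:
            right.append(chr(row[pos]))
        pos += 1
    if len(left) < len(event.seq) or len(right) < len(event.seq):
        warnings.warn(
            f"indel at columns {event.columns}: flank shorter than event; "
            "context computed on available flank"
        )
    context = classify_context(
        event.seq, "".join(reversed(left)), "".join(right), homopolymer_min_run
    )
    return IndelEvent(event.columns, event.polarity, event.carriers, event.seq, context)
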