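"""Reading and writing annotated plastome records and alignments.

Internal coordinates are 0-based half-open throughout; GenBank files and
tabular reports use the 1-based inclusive convention on the way in and out.
The genome is treated as a circular molecule: the sequence origin is a
representation artifact, and downstream operations (inverted-repeat
detection, region extraction) must not depend on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    FeatureLocation,
    SeqFeature,
)
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentMatrix

__all__ = [
    "GenomeFeature",
    "PlastomeRecord",
    "GeneInventory",
    "read_genbank",
    "write_genbank",
    "read_alignment",
    "write_alignment",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "gene_inventory",
    "revcomp",
]

FEATURE_KINDS = ("protein_coding", "tRNA", "rRNA", "pseudogene")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeParseError(ValueError):
    """Raised when an input file cannot be interpreted as a plastome record."""


@dataclass(frozen=True)
class GenomeFeature:
    """An annotated gene with one interval per exon.

    Exons are 0-based half-open intervals ordered along the forward strand
    of the genome; a feature with more than one exon implies at least one
    intron. ``is_duplicate`` marks the second copy of a gene duplicated in
    the inverted repeat.
    """

    name: str
    kind: str
    strand: int
    exons: tuple[tuple[int, int], ...]
    is_duplicate: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval {(s, e)} in {self.name}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass
class PlastomeRecord:
    """A circular annotated plastid genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GenomeFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise PlastomeParseError(
                f"record {self.id}: unsupported sequence characters {sorted(bad)}; "
                "only A,C,G,T,N are accepted"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name} extends past sequence end "
                    f"({f.end} > {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt

    def subsequence(self, start: int, end: int) -> str:
        """Extract [start, end) allowing the interval to wrap the origin."""
        L = self.length
        start %= L
        end = end % L if end % L or end == 0 else L
        if end == 0:
            end = L
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Rotate the circular origin so that old position ``offset`` becomes 0."""
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]

        def shift(iv):
            s, e = (iv[0] - offset) % L, (iv[1] - offset) % L
            if e == 0:
                e = L
            return (s, e)

        feats = []
        for f in self.features:
            exons = tuple(shift(iv) for iv in f.exons)
            # an exon now straddling the new origin is split in two
            fixed = []
            for s, e in exons:
                if s < e:
                    fixed.append((s, e))
                else:
                    fixed.append((s, L))
                    fixed.append((0, e))
            feats.append(replace(f, exons=tuple(fixed)))
        return PlastomeRecord(self.id, seq, self.circular, feats)


@dataclass(frozen=True)
class GeneInventory:
    """Gene counts for one plastome, with the IR-duplicated copies broken out."""

    total_genes: int
    unique_genes: int
    duplicated_in_IR: int
    protein_coding: int
    protein_coding_duplicated: int
    trna: int
    trna_duplicated: int
    rrna: int
    rrna_duplicated: int


def _kind_from_biopython(feat) -> str | None:
    if feat.type == "CDS":
        if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
            return "pseudogene"
        return "protein_coding"
    if feat.type == "tRNA":
        return "tRNA"
    if feat.type == "rRNA":
        return "rRNA"
    if feat.type == "gene" and (
        "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
    ):
        return "pseudogene"
    return None


def _feature_name(feat) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return "unknown"


def read_genbank(path) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a :class:`PlastomeRecord`.

    Gene models are taken from CDS/tRNA/rRNA features (plus ``gene`` features
    flagged ``/pseudo``); join coordinates become multi-exon features. The
    trans-spliced rps12 is left as whatever independent features the file
    declares — its segments are never merged into one feature.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise PlastomeParseError(f"{path}: not a readable GenBank file: {exc}") from exc
    if len(records) != 1:
        raise PlastomeParseError(
            f"{path}: expected exactly one record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 10:
        raise PlastomeParseError(f"{path}: record has no usable sequence")

    features = []
    for feat in rec.features:
        kind = _kind_from_biopython(feat)
        if kind is None:
            continue
        exons = tuple(
            sorted((int(p.start), int(p.end)) for p in feat.location.parts)
        )
        dup = "ir_duplicate" in feat.qualifiers.get("note", [])
        features.append(
            GenomeFeature(
                name=_feature_name(feat),
                kind=kind,
                strand=feat.location.strand or 1,
                exons=exons,
                is_duplicate=dup,
            )
        )
    circular = rec.annotations.get("topology", "circular") == "circular"
    return PlastomeRecord(rec.id or rec.name, seq, circular, features)


_KIND_TO_GB = {
    "protein_coding": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "pseudogene": "gene",
}


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a record as a GenBank flat file re-readable by :func:`read_genbank`."""
    feats = []
    for f in record.features:
        locs = [FeatureLocation(s, e, strand=f.strand) for s, e in f.exons]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.is_duplicate:
            quals["note"] = ["ir_duplicate"]
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        feats.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=quals))
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="",
        features=feats,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path) -> dict[str, str]:
    """Read (unaligned) FASTA into an ordered name → sequence mapping."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise PlastomeParseError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise PlastomeParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> AlignmentMatrix:
    """Read an aligned FASTA file into an :class:`AlignmentMatrix`.

    All rows must have the same aligned length, over {A,C,G,T,N,-}; taxon
    names must be unique.
    """
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise PlastomeParseError(
            f"{path}: ragged alignment, row lengths {sorted(lengths)}"
        )
    return AlignmentMatrix.from_dict(seqs)


def write_alignment(aln: AlignmentMatrix, path, width: int = 70) -> None:
    write_fasta({t: aln.row(t) for t in aln.taxa}, path, width=width)


def read_feature_table(path) -> list[GenomeFeature]:
    """Read the tab-separated annotation sidecar for FASTA input.

    Columns: name, kind, strand (+/-), exon intervals as comma-separated
    ``start..end`` pairs, 1-based inclusive. Lines starting with '#' are
    headers/comments.
    """
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PlastomeParseError(f"{path}:{ln}: expected 4 columns")
            name, kind, strand_s, exons_s = parts[:4]
            dup = len(parts) > 4 and parts[4].strip() == "duplicate"
            exons = []
            for iv in exons_s.split(","):
                a, b = iv.split("..")
                exons.append((int(a) - 1, int(b)))
            feats.append(
                GenomeFeature(
                    name=name,
                    kind=kind,
                    strand=1 if strand_s == "+" else -1,
                    exons=tuple(sorted(exons)),
                    is_duplicate=dup,
                )
            )
    return feats


def write_feature_table(features: list[GenomeFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tkind\tstrand\texons\tduplicate\n")
        for f in features:
            exons = ",".join(f"{s + 1}..{e}" for s, e in f.exons)
            dup = "duplicate" if f.is_duplicate else "."
            strand = "+" if f.strand == 1 else "-"
            fh.write(f"{f.name}\t{f.kind}\t{strand}\t{exons}\t{dup}\n")


def _overlaps_circular(f: GenomeFeature, interval: tuple[int, int], L: int) -> bool:
    s, e = interval
    for xs, xe in f.exons:
        if s <= e:
            if xs < e and xe > s:
                return True
        else:  # interval wraps the origin
            if xe > s or xs < e:
                return True
    return False


def gene_inventory(record: PlastomeRecord, structure) -> GeneInventory:
    """Count genes, marking IR duplicates.

    A feature counts as duplicated when it lies wholly or partly within IRa
    or IRb and a feature of the same name overlaps the other IR copy. tRNA
    isoacceptors at different loci are counted by (name, locus), i.e. not
    collapsed.
    """
    if not record.features:
        warnings.warn(f"record {record.id} has no annotation; empty inventory")
        return GeneInventory(0, 0, 0, 0, 0, 0, 0, 0, 0)
    L = record.length
    ira, irb = structure.ira, structure.irb

    in_ira = [f for f in record.features if _overlaps_circular(f, ira, L)]
    in_irb = [f for f in record.features if _overlaps_circular(f, irb, L)]
    names_a = {f.name for f in in_ira}
    names_b = {f.name for f in in_irb}
    paired = names_a & names_b

    # one of each same-name IR pair is the duplicate: prefer explicit flags,
    # otherwise take the IRa-resident copy
    dup_feats = set()
    for name in paired:
        copies = [f for f in in_ira + in_irb if f.name == name]
        flagged = [f for f in copies if f.is_duplicate]
        chosen = flagged if flagged else [f for f in in_ira if f.name == name][:1]
        dup_feats.update(id(f) for f in chosen)

    def count(kind):
        feats = [f for f in record.features if f.kind == kind]
        dups = sum(1 for f in feats if id(f) in dup_feats)
        return len(feats), dups

    pc, pc_d = count("protein_coding")
    tr, tr_d = count("tRNA")
    rr, rr_d = count("rRNA")
    ps, ps_d = count("pseudogene")
    total = pc + tr + rr + ps
    dup_total = pc_d + tr_d + rr_d + ps_d
    return GeneInventory(
        total_genes=total,
        unique_genes=total - dup_total,
        duplicated_in_IR=dup_total,
        protein_coding=pc,
        protein_coding_duplicated=pc_d,
        trna=tr,
        trna_duplicated=tr_d,
        rrna=rr,
        rrna_duplicated=rr_d,
    )
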