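"""The in-memory multiple-alignment container shared by all analysis stages."""

from __future__ import annotations

import numpy as np

GAP = ord("-")
_BASES = frozenset(b"ACGT")
ALPHABET = frozenset(b"ACGTN-")


class AlignmentError(ValueError):
    pass


class AlignmentMatrix:
    """Taxa × aligned-columns character matrix over {A,C,G,T,N,-}.

    Rows are stored as a uint8 matrix of ASCII codes for vectorized column
    scans. ``colmap`` maps each alignment column to the 0-based ungapped
    sequence coordinate of a taxon (−1 at gap columns), so alignment-space
    results can be reported in genome coordinates.
    """

    def __init__(self, taxa: list[str], matrix: np.ndarray):
        if len(taxa) != len(set(taxa)):
            raise AlignmentError("duplicate taxon names in alignment")
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise AlignmentError("matrix shape does not match taxa")
        bad = set(np.unique(matrix).tobytes()) - set(b"ACGTN-")
        if bad:
            raise AlignmentError(
                f"alignment contains unsupported characters {sorted(chr(b) for b in bad)}"
            )
        if matrix.shape[1] and bool(((matrix == GAP).all(axis=1)).any()):
            raise AlignmentError("alignment contains an all-gap row")
        self.taxa = list(taxa)
        self.matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "AlignmentMatrix":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
        mat = np.frombuffer(
            "".join(seqs[t].upper() for t in taxa).encode(), dtype=np.uint8
        ).reshape(len(taxa), -1) if taxa else np.zeros((0, 0), np.uint8)
        return cls(taxa, mat.copy())

    # -- basic access ------------------------------------------------------
    @property
    def ncol(self) -> int:
        return self.matrix.shape[1]

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise AlignmentError(f"taxon {taxon!r} not in alignment") from None

    def row(self, taxon: str) -> str:
        return self.matrix[self.index(taxon)].tobytes().decode()

    def row_array(self, taxon: str) -> np.ndarray:
        return self.matrix[self.index(taxon)]

    def ungapped(self, taxon: str) -> str:
        r = self.row_array(taxon)
        return r[r != GAP].tobytes().decode()

    def colmap(self, taxon: str) -> np.ndarray:
        """Alignment column → ungapped coordinate for one taxon (−1 at gaps)."""
        r = self.row_array(taxon)
        isbase = r != GAP
        out = np.cumsum(isbase) - 1
        out[~isbase] = -1
        return out

    def subset(self, taxa: list[str]) -> "AlignmentMatrix":
        idx = [self.index(t) for t in taxa]
        return AlignmentMatrix(list(taxa), self.matrix[idx].copy())

    def columns(self, start: int, end: int) -> "AlignmentMatrix":
        return AlignmentMatrix(list(self.taxa), self.matrix[:, start:end].copy())

    def __repr__(self):
        return f"AlignmentMatrix({self.ntaxa} taxa × {self.ncol} columns)"
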