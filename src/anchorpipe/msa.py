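"""A minimal multiple-sequence-alignment container used throughout the pipeline.

Rows are stored as a numpy matrix of single characters so the curation and
supermatrix layers can slice columns cheaply.  '-' is an alignment gap, 'N' an
ambiguous/unknown base, '?' a cell padded in for a taxon absent from a locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
MISSING = "?"

_MISSING_CHARS = frozenset("-?N")


@dataclass
class Msa:
    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_columns) of dtype '<U1'
    meta: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dict(cls, sequences: Mapping[str, str], meta: dict | None = None) -> "Msa":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths; not an alignment")
        matrix = np.array([list(sequences[t].upper()) for t in taxa], dtype="<U1")
        if matrix.ndim == 1:  # zero-column edge case
            matrix = matrix.reshape(len(taxa), 0)
        return cls(taxa, matrix, meta or {})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        return cls.from_dict(records)

    # -- basic accessors -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def to_dict(self) -> dict[str, str]:
        return {t: "".join(r) for t, r in zip(self.taxa, self.matrix)}

    def copy(self) -> "Msa":
        return Msa(list(self.taxa), self.matrix.copy(), dict(self.meta))

    # -- masks ---------------------------------------------------------------
    def missing_mask(self, *, count_gaps: bool = True) -> np.ndarray:
        """Boolean matrix marking cells considered 'missing data'."""
        m = (self.matrix == "N") | (self.matrix == MISSING)
        if count_gaps:
            m |= self.matrix == GAP
        return m

    def ungapped_lengths(self) -> dict[str, int]:
        keep = ~np.isin(self.matrix, (GAP, MISSING))
        return {t: int(k.sum()) for t, k in zip(self.taxa, keep)}

    # -- edits ---------------------------------------------------------------
    def drop_taxa(self, names: Iterable[str]) -> "Msa":
        drop = set(names)
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        return Msa([self.taxa[i] for i in keep], self.matrix[keep], dict(self.meta))

    def slice_columns(self, start: int, stop: int) -> "Msa":
        return Msa(list(self.taxa), self.matrix[:, start:stop], dict(self.meta))

    def take_columns(self, idx: Sequence[int] | np.ndarray) -> "Msa":
        return Msa(list(self.taxa), self.matrix[:, np.asarray(idx, dtype=int)], dict(self.meta))

    # -- io ------------------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=t, description="")
            for t, row in zip(self.taxa, self.matrix)
        ]
        SeqIO.write(records, str(path), "fasta")

    def __eq__(self, other) -> bool:  # structural equality, metadata ignored
        return (
            isinstance(other, Msa)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )
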