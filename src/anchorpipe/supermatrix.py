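"""Concatenation, partition schemes, and matrix-level summary statistics.

The supermatrix is the concatenation of curated, in-frame locus alignments
over a shared taxon universe; taxa absent from a locus are padded with '?'
across that locus's span.  Spans are 0-based half-open internally and
exported 1-based inclusive in partition files (the de facto convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import IUPAC_FRACTIONS
from .msa import GAP, MISSING, Msa

SCHEMES = ("by_gene", "by_codon", "third_removed", "third_only", "amino_acid")

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_AMINO):
    _CODON_TABLE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _a


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: np.ndarray                    # (n_taxa, total_columns) '<U1'
    locus_spans: dict                     # locus -> (start, stop) 0-based half-open
    codon_map: np.ndarray                 # per-column codon position 1/2/3

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def as_msa(self) -> Msa:
        return Msa(list(self.taxa), self.matrix.copy())

    def locus_matrix(self, locus: str) -> np.ndarray:
        a, b = self.locus_spans[locus]
        return self.matrix[:, a:b]


def concatenate(curated_alignments: Mapping[str, Msa],
                taxon_universe: Sequence[str]) -> Supermatrix:
    """Concatenate in-frame locus alignments; pad absent taxa with '?'.

    Every alignment must have length divisible by 3 (in frame); duplicate
    taxon labels within a locus are an error.
    """
    taxa = list(taxon_universe)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels in taxon universe")
    spans = {}
    blocks = []
    codon = []
    pos = 0
    for locus in sorted(curated_alignments):
        msa = curated_alignments[locus]
        if len(set(msa.taxa)) != len(msa.taxa):
            raise ValueError(f"duplicate taxon labels in {locus}")
        L = msa.length
        if L % 3:
            raise ValueError(f"{locus} is not in frame (length {L})")
        block = np.full((len(taxa), L), MISSING, dtype="<U1")
        for i, t in enumerate(taxa):
            if t in msa.taxa:
                block[i] = msa.matrix[msa.taxa.index(t)]
        blocks.append(block)
        spans[locus] = (pos, pos + L)
        codon.append(np.tile([1, 2, 3], L // 3))
        pos += L
    if blocks:
        matrix = np.hstack(blocks)
        codon_map = np.concatenate(codon)
    else:
        matrix = np.empty((len(taxa), 0), dtype="<U1")
        codon_map = np.empty(0, dtype=int)
    return Supermatrix(taxa, matrix, spans, codon_map)


# ---------------------------------------------------------------------------
# site variability (Table-2 style accounting)
# ---------------------------------------------------------------------------

@dataclass
class SiteVariabilityTable:
    """Constant/variable site accounting for the whole matrix and per codon
    position; consistent by construction (constant + variable = total)."""

    table: pd.DataFrame                   # rows: whole, pos1, pos2, pos3

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple]) -> "SiteVariabilityTable":
        """Build from (total, constant, variable) triples keyed by
        'whole', 'pos1', 'pos2', 'pos3' (e.g. a published summary table)."""
        rows = []
        for key in ("whole", "pos1", "pos2", "pos3"):
            total, constant, variable = counts[key]
            if constant + variable != total:
                raise ValueError(f"row {key}: {constant}+{variable} != {total}")
            rows.append({"row": key, "total": total, "constant": constant,
                         "variable": variable})
        return cls(pd.DataFrame(rows).set_index("row"))

    @classmethod
    def from_matrix(cls, sm: Supermatrix) -> "SiteVariabilityTable":
        variable = _variable_columns(sm.matrix)
        counts = {"whole": (sm.length, int((~variable).sum()), int(variable.sum()))}
        for p in (1, 2, 3):
            sel = sm.codon_map == p
            counts[f"pos{p}"] = (int(sel.sum()),
                                 int((~variable[sel]).sum()),
                                 int(variable[sel].sum()))
        return cls.from_counts(counts)

    @property
    def percent_variable(self) -> float:
        """Variable sites as a percentage of the whole matrix."""
        row = self.table.loc["whole"]
        return 100.0 * row["variable"] / row["total"]

    def variable_share_of_position(self, position: int) -> float:
        """Percentage of all variable sites contributed by a codon position."""
        return (100.0 * self.table.loc[f"pos{position}", "variable"]
                / self.table.loc["whole", "variable"])


def _variable_columns(matrix: np.ndarray) -> np.ndarray:
    """A column is variable iff >= 2 distinct unambiguous bases occur among
    its non-missing, non-gap cells (ambiguity codes never create variability;
    all-missing columns count as constant)."""
    variable = np.zeros(matrix.shape[1], dtype=bool)
    seen = np.zeros((4, matrix.shape[1]), dtype=bool)
    for i, b in enumerate("ACGT"):
        seen[i] = (matrix == b).any(axis=0)
    variable = seen.sum(axis=0) >= 2
    return variable


def site_variability(sm: Supermatrix) -> SiteVariabilityTable:
    return SiteVariabilityTable.from_matrix(sm)


# ---------------------------------------------------------------------------
# completeness (Table-3 style accounting)
# ---------------------------------------------------------------------------

def _row_missing_cells(row: np.ndarray, spans: Mapping[str, tuple],
                       mode: str) -> int:
    missing = 0
    for a, b in spans.values():
        seg = row[a:b]
        data = ~np.isin(seg, (GAP, MISSING))
        if not data.any():
            missing += b - a
            continue
        first = int(np.argmax(data))
        last = len(seg) - int(np.argmax(data[::-1]))
        missing += first + (len(seg) - last)          # leading/trailing runs
        if mode == "with_indels":
            missing += int((~data[first:last]).sum())  # interior gaps
    return missing


def completeness(sm: Supermatrix, mode: str) -> float:
    """Overall matrix completeness percentage under three definitions.

    ``trailing_and_missing``: missing-locus cells plus leading/trailing gap
    runs per row per span; ``with_indels`` additionally counts interior
    gaps; ``locus_presence``: mean over species of loci present / total loci.
    """
    if mode not in ("trailing_and_missing", "with_indels", "locus_presence"):
        raise ValueError(f"unknown completeness mode {mode!r}")
    if mode == "locus_presence":
        pres = species_completeness(sm)["pct_presence"]
        return float(pres.mean())
    total = sm.matrix.size
    missing = sum(_row_missing_cells(sm.matrix[i], sm.locus_spans, mode)
                  for i in range(len(sm.taxa)))
    return 100.0 * (1 - missing / total)


def species_completeness(sm: Supermatrix) -> pd.DataFrame:
    """Per-species missing data, loci present, presence %, ungapped lengths."""
    n_loci = len(sm.locus_spans)
    rows = []
    for i, taxon in enumerate(sm.taxa):
        row = sm.matrix[i]
        data = ~np.isin(row, (GAP, MISSING))
        present = sum(1 for a, b in sm.locus_spans.values()
                      if data[a:b].any())
        missing = _row_missing_cells(row, sm.locus_spans, "with_indels")
        ungapped = int(data.sum())
        rows.append({
            "species": taxon,
            "pct_missing": 100.0 * missing / sm.length,
            "loci_present": present,
            "pct_presence": 100.0 * present / n_loci if n_loci else 0.0,
            "ungapped_alignment_length": ungapped,
            "mean_ungapped_locus_length": ungapped / present if present else 0.0,
        })
    return pd.DataFrame(rows)


def overall_completeness_from_species(table: pd.DataFrame,
                                      column: str = "pct_missing") -> float:
    """100 minus the mean per-species missing-data percentage — the overall
    completeness figure implied by a per-species accounting table."""
    return 100.0 - float(table[column].mean())


# ---------------------------------------------------------------------------
# base composition
# ---------------------------------------------------------------------------

def gc_stats(sm: "Supermatrix | np.ndarray", ambiguity_mode: str = "ignore",
             ) -> dict:
    """GC percentage and G-C skew of the matrix.

    ``ignore``: GC = (G+C)/(A+C+G+T) over unambiguous bases only;
    ``fractional``: IUPAC ambiguity codes contribute fractionally to each
    compatible base first.  Skew = (G-C)/(G+C) on unambiguous counts.
    """
    matrix = sm.matrix if isinstance(sm, Supermatrix) else np.asarray(sm)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if ambiguity_mode not in ("ignore", "fractional"):
        raise ValueError(f"unknown ambiguity mode {ambiguity_mode!r}")
    counts = {b: float((matrix == b).sum()) for b in "ACGT"}
    if ambiguity_mode == "fractional":
        for code, frac in IUPAC_FRACTIONS.items():
            if code in "ACGT":
                continue
            n = float((matrix == code).sum())
            if n:
                for b, f in frac.items():
                    counts[b] += n * f
    total = sum(counts.values())
    if total == 0:
        raise ValueError("matrix contains no bases")
    g, c = counts["G"], counts["C"]
    plain = {b: float((matrix == b).sum()) for b in "ACGT"}
    skew_den = plain["G"] + plain["C"]
    return {
        "gc_percent": 100.0 * (g + c) / total,
        "gc_skew": (plain["G"] - plain["C"]) / skew_den if skew_den else 0.0,
    }


def per_species_third_position_gc(sm: Supermatrix) -> pd.Series:
    """Third-codon-position GC% per species (tree-annotation statistic)."""
    third = sm.codon_map == 3
    out = {}
    for i, taxon in enumerate(sm.taxa):
        seg = sm.matrix[i][third]
        out[taxon] = gc_stats(seg.reshape(1, -1))["gc_percent"]
    return pd.Series(out, name="gc3_percent")


# ---------------------------------------------------------------------------
# partition schemes and taxon reduction
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    name: str
    blocks: dict = field(default_factory=dict)   # block name -> column indices
    translated: "Msa | None" = None              # amino_acid scheme only


def build_partitions(sm: Supermatrix, scheme_name: str) -> PartitionScheme:
    """One of the partition schemes applied to the concatenated matrix.

    by_gene: one block per locus; by_codon: three positional blocks;
    third_removed: positions 1-2 only (per gene); third_only: position 3;
    amino_acid: standard-code translation, any codon containing a gap,
    missing cell, N/ambiguity, or an in-frame stop translating to missing.
    """
    if scheme_name not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme_name!r}")
    if scheme_name == "by_gene":
        blocks = {locus: np.arange(a, b)
                  for locus, (a, b) in sorted(sm.locus_spans.items())}
    elif scheme_name == "by_codon":
        blocks = {f"pos{p}": np.nonzero(sm.codon_map == p)[0] for p in (1, 2, 3)}
    elif scheme_name == "third_removed":
        keep = sm.codon_map != 3
        blocks = {locus: np.nonzero(keep & _span_mask(sm, locus))[0]
                  for locus in sorted(sm.locus_spans)}
    elif scheme_name == "third_only":
        blocks = {"pos3": np.nonzero(sm.codon_map == 3)[0]}
    else:
        rows = {}
        for i, taxon in enumerate(sm.taxa):
            aa = []
            for a, b in sorted(sm.locus_spans.values()):
                seg = sm.matrix[i][a:b]
                for c in range(0, b - a, 3):
                    codon = "".join(seg[c:c + 3])
                    res = _CODON_TABLE.get(codon, "X")
                    aa.append("X" if res == "*" else res)
            rows[taxon] = "".join(aa)
        return PartitionScheme("amino_acid", {}, Msa.from_dict(rows))
    return PartitionScheme(scheme_name, blocks)


def _span_mask(sm: Supermatrix, locus: str) -> np.ndarray:
    mask = np.zeros(sm.length, dtype=bool)
    a, b = sm.locus_spans[locus]
    mask[a:b] = True
    return mask


def reduce_taxa(sm: Supermatrix, keep_list: Sequence[str]) -> Supermatrix:
    """Row subset; columns untouched (no re-alignment)."""
    keep = list(keep_list)
    if not keep:
        raise ValueError("empty keep list")
    unknown = set(keep) - set(sm.taxa)
    if unknown:
        raise ValueError(f"taxa not in matrix: {sorted(unknown)}")
    idx = [sm.taxa.index(t) for t in keep]
    return Supermatrix(keep, sm.matrix[idx].copy(), dict(sm.locus_spans),
                       sm.codon_map.copy())


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def write_fasta(sm: Supermatrix, path: str | Path) -> None:
    sm.as_msa().to_fasta(path)


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, whitespace, full row."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t, row in zip(sm.taxa, sm.matrix):
            fh.write(f"{t}  {''.join(row)}\n")


def read_phylip(path: str | Path) -> Msa:
    lines = Path(path).read_text().splitlines()
    n, L = map(int, lines[0].split())
    seqs = {}
    for line in lines[1: n + 1]:
        name, seq = line.split(None, 1)
        seqs[name] = seq.strip()
    msa = Msa.from_dict(seqs)
    assert msa.length == L
    return msa


def write_raxml_partitions(sm: Supermatrix, path: str | Path,
                           scheme: str = "by_gene") -> None:
    """RAxML-style partition file; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        if scheme == "by_gene":
            for locus, (a, b) in sorted(sm.locus_spans.items()):
                fh.write(f"DNA, {locus} = {a + 1}-{b}\n")
        elif scheme == "by_codon":
            for p in (1, 2, 3):
                parts = []
                for locus, (a, b) in sorted(sm.locus_spans.items()):
                    parts.append(f"{a + p}-{b}\\3")
                fh.write(f"DNA, pos{p} = {', '.join(parts)}\n")
        else:
            raise ValueError("partition files support by_gene and by_codon")


def read_raxml_partitions(path: str | Path) -> dict[str, tuple[int, int]]:
    """Inverse of ``write_raxml_partitions`` for the by_gene scheme; returns
    0-based half-open spans."""
    spans = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, rest = line.split(",", 1)
        name, coords = rest.split("=")
        a, b = coords.strip().split("-")
        spans[name.strip()] = (int(a) - 1, int(b))
    return spans


def write_nexus_sets(sm: Supermatrix, path: str | Path) -> None:
    """NEXUS charset block for the per-gene and per-codon partitions."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for locus, (a, b) in sorted(sm.locus_spans.items()):
            fh.write(f"  charset {locus} = {a + 1}-{b};\n")
        for p in (1, 2, 3):
            fh.write(f"  charset pos{p} = {p}-{sm.length}\\3;\n")
        fh.write("end;\n")


def write_species_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
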