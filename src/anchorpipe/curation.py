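"""Alignment, filtering, trimming, frame enforcement and outlier removal.

Each homolog set is aligned (internal star aligner by default; mafft as an
optional external backend) and then pushed through a fixed curation order:

    align -> missing-species filter -> end trimming -> length filter
          -> divergence / long-branch outlier removal
          -> missing-species re-check -> reading-frame enforcement

Every edit (trimmed columns, removed taxa, frame trim) is logged, and the log
can be replayed on the raw alignment to reproduce the curated matrix exactly.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align

from .msa import GAP, Msa

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CurationConfig:
    max_missing_species: int = 2
    trim_start_fraction: float = 1 / 3   # trigger: terminal missingness to start trimming
    trim_stop_fraction: float = 1 / 2    # trim while terminal missingness >= this
    min_length: int = 450
    min_shortest_ungapped: int = 150
    divergence_z_threshold: float = 3.5
    long_branch_ratio: float = 5.0
    long_branch_min_length: float = 0.05
    count_gaps_as_missing: bool = True
    aligner: str = "internal"            # "internal" | "mafft"
    max_noncoding_stops_per_taxon: float = 1.0


@dataclass
class CuratedAlignment:
    locus_id: str
    homolog_index: int
    msa: Msa
    frame_offset: int | None             # None = flagged non-coding
    provenance: list = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return self.msa.taxa

    @property
    def length(self) -> int:
        return self.msa.length


@dataclass
class DistanceReport:
    taxa: list[str]
    matrix: np.ndarray                   # pairwise p-distances
    per_taxon_median: np.ndarray
    z_scores: np.ndarray
    flagged: list[str]


# ---------------------------------------------------------------------------
# alignment backends
# ---------------------------------------------------------------------------

def _pairwise_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    # free end gaps: contigs trim unevenly at their flanks
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def _star_align(sequences: Mapping[str, str]) -> Msa:
    """Progressive star alignment around the longest sequence.

    Each sequence is aligned pairwise (affine gaps, free end gaps) to the
    centre; insertions relative to the centre are merged column-wise
    ("once a gap, always a gap").  Adequate for capture loci, which are
    nearly indel-free in their cores.
    """
    aligner = _pairwise_aligner()
    names = sorted(sequences)
    center = max(names, key=lambda n: (len(sequences[n]), n))
    c_seq = sequences[center]
    Lc = len(c_seq)
    # events[name] = list of (center_pos or ('ins', center_pos, k), char)
    aligned_to_center: dict[str, list] = {}
    ins_len = np.zeros(Lc + 1, dtype=int)  # insertions *before* center position i
    for name in names:
        if name == center:
            continue
        aln = aligner.align(c_seq, sequences[name])[0]
        t_blocks, q_blocks = aln.aligned
        events = []
        prev_t, prev_q = 0, 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            gap_t, gap_q = ts - prev_t, qs - prev_q
            # unaligned query residues become an insertion before center pos ts-gap_t? ;
            # place insertions before the centre position where matching resumes.
            for k in range(gap_q):
                events.append((("ins", ts, k), sequences[name][prev_q + k]))
            ins_len[ts] = max(ins_len[ts], gap_q)
            for k in range(gap_t):
                pass  # deletion: centre positions prev_t..ts-1 get gaps (default)
            for t, q in zip(range(ts, te), range(qs, qe)):
                events.append((t, sequences[name][q]))
            prev_t, prev_q = te, qe
        # trailing unaligned query -> insertion at centre end
        tail = len(sequences[name]) - prev_q
        for k in range(tail):
            events.append((("ins", Lc, k), sequences[name][prev_q + k]))
        ins_len[Lc] = max(ins_len[Lc], tail)
        aligned_to_center[name] = events
    # column layout
    col_of_center = np.zeros(Lc, dtype=int)
    col_of_ins: dict[tuple, int] = {}
    col = 0
    for i in range(Lc + 1):
        for k in range(ins_len[i]):
            col_of_ins[(i, k)] = col
            col += 1
        if i < Lc:
            col_of_center[i] = col
            col += 1
    total = col
    rows = {}
    crow = np.full(total, GAP, dtype="<U1")
    crow[col_of_center] = list(c_seq)
    rows[center] = crow
    for name, events in aligned_to_center.items():
        row = np.full(total, GAP, dtype="<U1")
        for key, ch in events:
            if isinstance(key, tuple):
                _, i, k = key
                row[col_of_ins[(i, k)]] = ch
            else:
                row[col_of_center[key]] = ch
        rows[name] = row
    matrix = np.array([rows[n] for n in names])
    return Msa(names, matrix, {"aligner": "internal"})


def _mafft_align(sequences: Mapping[str, str]) -> Msa:
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        with open(inp, "w") as fh:
            for name in sorted(sequences):
                fh.write(f">{name}\n{sequences[name]}\n")
        out = subprocess.run([exe, "--auto", "--quiet", str(inp)],
                             capture_output=True, text=True, check=True)
    records: dict[str, str] = {}
    name = None
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = ""
        elif name:
            records[name] += line.strip().upper()
    msa = Msa.from_dict(records)
    msa.meta["aligner"] = "mafft"
    return msa


def align_set(sequences: Mapping[str, str], backend: str = "internal") -> Msa:
    """Multiple alignment of one homolog set; records which backend ran."""
    if len(sequences) < 4:
        raise ValueError("need >= 4 sequences to align a homolog set")
    if backend == "mafft":
        return _mafft_align(sequences)
    if backend == "internal":
        return _star_align(sequences)
    raise ValueError(f"unknown aligner backend {backend!r}")


# ---------------------------------------------------------------------------
# filters and trims
# ---------------------------------------------------------------------------

def filter_missing_species(msa: Msa, expected_taxa: Sequence[str],
                           max_missing: int = 2) -> bool:
    """Keep iff at most ``max_missing`` expected taxa are absent."""
    missing = set(expected_taxa) - set(msa.taxa)
    return len(missing) <= max_missing


def trim_ends(msa: Msa, start_fraction: float = 1 / 3,
              stop_fraction: float = 1 / 2, *,
              count_gaps: bool = True) -> tuple[Msa, int, int]:
    """Trim terminal columns dense in missing data.

    From each end: if the terminal column's missing fraction exceeds
    ``start_fraction``, columns are removed while their missing fraction is
    at least ``stop_fraction``; interior columns are never touched.  Returns
    (trimmed, n_left, n_right).
    """
    miss = msa.missing_mask(count_gaps=count_gaps).mean(axis=0)
    n = msa.length
    lo = 0
    if n and miss[0] > start_fraction:
        while lo < n and miss[lo] >= stop_fraction:
            lo += 1
    hi = n
    if n and miss[-1] > start_fraction:
        while hi > lo and miss[hi - 1] >= stop_fraction:
            hi -= 1
    return msa.slice_columns(lo, hi), lo, n - hi


def filter_length(msa: Msa, min_length: int = 450,
                  min_shortest_ungapped: int = 150) -> bool:
    """Keep iff alignment >= 450 columns and shortest ungapped row >= 150 bp."""
    if msa.length < min_length:
        return False
    return min(msa.ungapped_lengths().values()) >= min_shortest_ungapped


# ---------------------------------------------------------------------------
# outlier screens
# ---------------------------------------------------------------------------

def _p_distance_matrix(msa: Msa) -> np.ndarray:
    codes = np.full(msa.matrix.shape, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        codes[msa.matrix == b] = i
    n = msa.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] < 4) & (codes[j] < 4)
            nv = int(valid.sum())
            D[i, j] = D[j, i] = (
                float((codes[i][valid] != codes[j][valid]).sum()) / nv
                if nv else 0.0)
    return D


def flag_divergent_taxa(msa: Msa, z_threshold: float = 3.5,
                        ) -> tuple[DistanceReport, Msa]:
    """Flag taxa whose median pairwise p-distance is a robust outlier.

    Needs >= 5 taxa (otherwise nothing is flagged).  A taxon is flagged when
    its median distance to the others exceeds the across-taxa median by more
    than ``z_threshold`` MAD-based robust standard deviations (one-sided,
    high only).  Flagged rows are removed from the returned alignment.
    """
    D = _p_distance_matrix(msa)
    n = msa.n_taxa
    med = np.array([np.median(np.delete(D[i], i)) for i in range(n)])
    center = np.median(med)
    mad = np.median(np.abs(med - center))
    # Distance floor guards the MAD=0 case and absorbs the correlated
    # sampling noise of per-taxon medians on short clean alignments.
    scale = max(1.4826 * mad, 0.01)
    z = (med - center) / scale
    flagged = [msa.taxa[i] for i in range(n)
               if n >= 5 and z[i] > z_threshold]
    report = DistanceReport(list(msa.taxa), D, med, z, flagged)
    return report, (msa.drop_taxa(flagged) if flagged else msa)


def flag_long_branch_taxa(gene_tree: dendropy.Tree,
                          ratio_threshold: float = 5.0,
                          min_length: float = 0.0) -> list[str]:
    """Terminal branches longer than ``ratio_threshold`` x the median terminal
    branch length, the gene-tree symptom of a paralogous intruder.

    ``min_length`` additionally requires the branch to exceed an absolute
    length (expected substitutions/site); the pipeline uses it to keep
    shape-induced ratio outliers on shallow trees from being flagged.
    """
    lengths = {}
    for leaf in gene_tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise ValueError(f"missing branch length for {leaf.taxon.label}")
        lengths[leaf.taxon.label] = float(leaf.edge.length)
    med = float(np.median(list(lengths.values())))
    if med <= 0:
        return []
    return sorted(t for t, l in lengths.items()
                  if l > ratio_threshold * med and l >= min_length)


# ---------------------------------------------------------------------------
# reading frame
# ---------------------------------------------------------------------------

def _count_stops(msa: Msa, offset: int) -> float:
    """Mean in-frame stop codons per taxon at a given frame offset; codons
    containing gaps/N/? are not counted."""
    n_cod = (msa.length - offset) // 3
    if n_cod <= 0:
        return float("inf")
    total = 0
    for row in msa.matrix:
        seg = row[offset: offset + 3 * n_cod].reshape(-1, 3)
        codons = ["".join(c) for c in seg]
        total += sum(1 for c in codons if c in STOP_CODONS)
    return total / msa.n_taxa


def enforce_reading_frame(msa: Msa, locus_id: str = "locus",
                          homolog_index: int = 1,
                          max_noncoding_stops: float = 1.0,
                          provenance: list | None = None) -> CuratedAlignment:
    """Choose the frame offset (0/1/2) minimising in-frame stop codons.

    Partial codons at both ends are trimmed so the length is divisible by 3.
    If every frame averages more than ``max_noncoding_stops`` stops per taxon
    the locus is flagged non-coding (frame undetermined) and passed through
    untrimmed.
    """
    provenance = provenance if provenance is not None else []
    stops = [_count_stops(msa, off) for off in (0, 1, 2)]
    best = int(np.argmin(stops))
    if min(stops) > max_noncoding_stops:
        provenance.append({"op": "flag_noncoding",
                           "stops_per_frame": [round(s, 3) for s in stops]})
        return CuratedAlignment(locus_id, homolog_index, msa, None, provenance)
    n_cod = (msa.length - best) // 3
    right = msa.length - (best + 3 * n_cod)
    trimmed = msa.slice_columns(best, best + 3 * n_cod)
    if best or right:
        provenance.append({"op": "frame_trim", "left": best, "right": right})
    provenance.append({"op": "set_frame", "offset": best})
    return CuratedAlignment(locus_id, homolog_index, trimmed, best, provenance)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def curate_alignment(msa: Msa, expected_taxa: Sequence[str],
                     config: CurationConfig | None = None,
                     locus_id: str = "locus", homolog_index: int = 1,
                     gene_tree: dendropy.Tree | None = None,
                     ) -> tuple[CuratedAlignment | None, list]:
    """Run the fixed curation order on one aligned homolog set.

    Returns (curated, log); curated is None when a filter discarded the
    locus (the log records which one).  When no ``gene_tree`` is supplied the
    long-branch screen estimates one internally (neighbor joining on JC69
    distances).
    """
    cfg = config or CurationConfig()
    log: list = []
    if not filter_missing_species(msa, expected_taxa, cfg.max_missing_species):
        log.append({"op": "discard", "reason": "missing_species"})
        return None, log
    msa, n_left, n_right = trim_ends(msa, cfg.trim_start_fraction,
                                     cfg.trim_stop_fraction,
                                     count_gaps=cfg.count_gaps_as_missing)
    if n_left:
        log.append({"op": "trim_left", "n": n_left})
    if n_right:
        log.append({"op": "trim_right", "n": n_right})
    if not filter_length(msa, cfg.min_length, cfg.min_shortest_ungapped):
        log.append({"op": "discard", "reason": "length"})
        return None, log
    report, msa2 = flag_divergent_taxa(msa, cfg.divergence_z_threshold)
    for t in report.flagged:
        log.append({"op": "remove_taxon", "taxon": t, "reason": "divergence"})
    msa = msa2
    if msa.n_taxa >= 4:
        if gene_tree is None:
            from .treesupport import distance_matrix, nj_tree
            gene_tree = nj_tree(distance_matrix(msa, model="JC69"))
        present = {l.taxon.label for l in gene_tree.leaf_node_iter()}
        if present >= set(msa.taxa):
            if not present == set(msa.taxa):
                gene_tree = gene_tree.clone(depth=1)
                gene_tree.retain_taxa_with_labels(list(msa.taxa))
            long = flag_long_branch_taxa(gene_tree, cfg.long_branch_ratio,
                                         cfg.long_branch_min_length)
            long = [t for t in long if t in msa.taxa]
            for t in long:
                log.append({"op": "remove_taxon", "taxon": t,
                            "reason": "long_branch"})
            if long:
                msa = msa.drop_taxa(long)
    if not filter_missing_species(msa, expected_taxa, cfg.max_missing_species):
        log.append({"op": "discard", "reason": "missing_species_after_editing"})
        return None, log
    curated = enforce_reading_frame(msa, locus_id, homolog_index,
                                    cfg.max_noncoding_stops_per_taxon,
                                    provenance=log)
    return curated, log


def replay_log(raw: Msa, log: Sequence[dict]) -> Msa:
    """Re-apply a curation log to the raw alignment; reproduces the curated
    matrix exactly (used to audit provenance)."""
    msa = raw.copy()
    for entry in log:
        op = entry["op"]
        if op == "trim_left":
            msa = msa.slice_columns(entry["n"], msa.length)
        elif op == "trim_right":
            msa = msa.slice_columns(0, msa.length - entry["n"])
        elif op == "remove_taxon":
            msa = msa.drop_taxa([entry["taxon"]])
        elif op == "frame_trim":
            msa = msa.slice_columns(entry["left"], msa.length - entry["right"])
        elif op in ("set_frame", "flag_noncoding"):
            continue
        elif op == "discard":
            raise ValueError(f"log records a discard: {entry}")
    return msa


def write_edit_log(log: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("op\tdetail\n")
        for entry in log:
            detail = ";".join(f"{k}={v}" for k, v in entry.items() if k != "op")
            fh.write(f"{entry['op']}\t{detail}\n")
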