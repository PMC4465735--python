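"""Seed-and-extend majority-rule consensus assembly of capture reads.

The contract: reads for one individual are mapped to a per-locus reference
with spaced k-mers tolerant of deep (~45 %) divergence; the best-matching
read anchors a stack in which further reads must overlap by >= 20 bp at
>= 95 % identity; the majority-rule consensus (2x minimum depth) seeds an
extension phase that grows outward over multiple passes through the read
pool; consumed reads are removed and the whole procedure repeats round by
round, so divergent paralogous copies fall into separate rounds instead of
being averaged into one chimeric consensus.  A locus counts as captured when
any round yields a consensus longer than 350 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import BASES, IUPAC, encode, revcomp, revcomp_codes
from .simulate import Read, ReadSet

# Care positions of the spaced k-mer mask: weight 12 spread over a 23 bp span
# (every other position).  Spreading the care positions decorrelates adjacent
# windows so divergent homologs keep seeding, while weight 12 keeps the
# keyspace (4^12) large enough that unrelated reads essentially never collide.
DEFAULT_MASK: tuple[int, ...] = tuple(range(0, 24, 2))


@dataclass
class AssemblyConfig:
    min_overlap: int = 20
    min_identity: float = 0.95
    min_depth: int = 2
    capture_length: int = 350      # contig must exceed this to count as captured
    min_contig: int = 20           # rounds stop when nothing >= this emerges
    max_rounds: int = 5
    mask: tuple[int, ...] = DEFAULT_MASK
    # Spaced keys collide by chance (~0.7 % of unrelated reads "map"), so an
    # anchor must also resemble the reference: genuine copies place at
    # >= ~0.75 identity even at paralog divergence, random reads at ~0.3.
    min_anchor_identity: float = 0.6


@dataclass
class ConsensusContig:
    locus_id: str
    individual: str
    round_index: int
    bases: str                     # may contain N (interior depth < min_depth)
    depth: np.ndarray              # per-column read count
    read_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def name(self) -> str:
        return f"{self.locus_id}_{self.individual}_{self.round_index}"


# ---------------------------------------------------------------------------
# spaced k-mer mapping
# ---------------------------------------------------------------------------

def _spaced_keys(codes: np.ndarray, mask: Sequence[int]) -> np.ndarray:
    """All spaced-kmer keys of a coded sequence; windows containing N dropped."""
    span = max(mask) + 1
    n = codes.size - span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    keys = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i, off in enumerate(mask):
        col = codes[off: off + n]
        keys += col.astype(np.int64) << (2 * i)
        valid &= col < 4
    return keys[valid]


def spaced_kmer_index(reference: str, mask: Sequence[int] = DEFAULT_MASK) -> set:
    """Index of spaced k-mer keys present in a reference sequence.

    A read "maps" to the reference iff it shares at least one spaced key
    (either strand).  A reference shorter than the mask span yields an empty
    index.
    """
    return set(_spaced_keys(encode(reference), mask).tolist())


def read_keys(read_codes: np.ndarray, mask: Sequence[int] = DEFAULT_MASK) -> set:
    """Spaced keys of a read, both strands."""
    keys = set(_spaced_keys(read_codes, mask).tolist())
    keys.update(_spaced_keys(revcomp_codes(read_codes), mask).tolist())
    return keys


def read_maps(read_codes: np.ndarray, index: set,
              mask: Sequence[int] = DEFAULT_MASK) -> bool:
    return not index.isdisjoint(read_keys(read_codes, mask))


# ---------------------------------------------------------------------------
# ungapped overlap scoring (substitutions only, both strands)
# ---------------------------------------------------------------------------

def _overlap_profile(target: np.ndarray, query: np.ndarray):
    """Match and comparable-site counts for every ungapped offset of query.

    Offset ``o`` places query position 0 at target position ``o`` (negative =
    query hangs off the left end).  Sites where either side is N/ambiguous do
    not count as comparable.
    """
    tv = (target < 4).astype(np.float64)
    qv = (query < 4).astype(np.float64)
    matches = np.zeros(target.size + query.size - 1)
    for b in range(4):
        matches += np.correlate((target == b).astype(np.float64),
                                (query == b).astype(np.float64), "full")
    comparable = np.correlate(tv, qv, "full")
    offsets = np.arange(-(query.size - 1), target.size)
    return offsets, matches, comparable


def best_ungapped_placement(target: np.ndarray, query: np.ndarray,
                            min_overlap: int) -> tuple[int, float, int, int] | None:
    """Best (offset, identity, comparable, strand) of query against target.

    The placement maximises the ungapped alignment score
    (matches - mismatches; ties: higher identity, then the smaller offset,
    then the forward strand); identity is reported over that placement's
    comparable sites.  The score objective matters for specificity in both
    directions: a read from a divergent paralog occasionally shows a short,
    locally conserved >= 95 % overlap, but its score-maximal placement is
    the long homologous one, whose identity correctly fails the stacking
    threshold; conversely a true short tip overlap still outscores any
    random long overlap, whose mismatches drive the score negative.
    Returns None when no placement reaches ``min_overlap`` comparable sites.
    """
    best = None
    for strand, q in ((0, query), (1, revcomp_codes(query))):
        offsets, matches, comparable = _overlap_profile(target, q)
        ok = comparable >= min_overlap
        if not ok.any():
            continue
        ident = np.where(ok, matches / np.maximum(comparable, 1), -1.0)
        score = np.where(ok, 2 * matches - comparable, -np.inf)
        order = np.lexsort((offsets, -ident, -score))
        k = order[0]
        cand = (int(offsets[k]), float(ident[k]), int(comparable[k]), strand,
                float(score[k]))
        if best is None or (cand[4], cand[1], -cand[0], -strand) > (
                best[4], best[1], -best[0], -best[3]):
            best = cand
    return best[:4] if best else None


def choose_anchor_read(mapped_reads: Sequence[Read], reference: str,
                       config: AssemblyConfig | None = None) -> Read | None:
    """The read with highest identity to the reference at its best placement.

    Ties broken by longer read, then lexicographically smaller id.  Returns
    None when no read places with sufficient overlap at
    ``min_anchor_identity`` — chance spaced-key collisions put a few
    unrelated reads in every mapped list, and anchoring on one would grow a
    contig belonging to a different locus.
    """
    config = config or AssemblyConfig()
    ref_codes = encode(reference)
    best_key, best_read = None, None
    for read in mapped_reads:
        placement = best_ungapped_placement(ref_codes, encode(read.bases),
                                            config.min_overlap)
        if placement is None or placement[1] < config.min_anchor_identity:
            continue
        key = (placement[1], len(read.bases), _NegStr(read.id))
        if best_key is None or key > best_key:
            best_key, best_read = key, read
    return best_read


def orient_to_reference(anchor: Read, reference: str,
                        config: AssemblyConfig) -> Read:
    """Flip the anchor to the reference strand so every contig grown from it
    is reported in reference orientation."""
    placement = best_ungapped_placement(encode(reference),
                                        encode(anchor.bases),
                                        config.min_overlap)
    if placement is not None and placement[3] == 1:
        return Read(anchor.id, revcomp(anchor.bases))
    return anchor


class _NegStr(str):
    """Orders lexicographically *smaller* strings as larger (for max())."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# the growing read stack
# ---------------------------------------------------------------------------

class ReadStack:
    """Reads placed at integer offsets with an incrementally updated consensus."""

    def __init__(self, anchor: Read, config: AssemblyConfig):
        self.config = config
        codes = encode(anchor.bases)
        self.start = 0                         # global coordinate of column 0
        self.counts = np.zeros((codes.size, 4), dtype=np.int32)
        self.cover = np.zeros(codes.size, dtype=np.int32)
        self.placements: list[tuple[str, int, int]] = []  # (read_id, offset, strand)
        self._placed_codes: dict[str, tuple[int, np.ndarray]] = {}
        self._add_codes(anchor.id, codes, 0, 0)
        self._cons = self._compute_consensus(np.full(codes.size, 255, dtype=np.uint8))

    # -- internals ----------------------------------------------------------
    def _grow(self, lo: int, hi: int) -> None:
        """Ensure global columns [lo, hi) exist."""
        left = self.start - lo
        right = hi - (self.start + self.cover.size)
        if left > 0:
            self.counts = np.vstack([np.zeros((left, 4), np.int32), self.counts])
            self.cover = np.concatenate([np.zeros(left, np.int32), self.cover])
            self._cons = np.concatenate(
                [np.full(left, 255, np.uint8), self._cons])
            self.start = lo
        if right > 0:
            self.counts = np.vstack([self.counts, np.zeros((right, 4), np.int32)])
            self.cover = np.concatenate([self.cover, np.zeros(right, np.int32)])
            self._cons = np.concatenate(
                [self._cons, np.full(right, 255, np.uint8)])

    def _add_codes(self, read_id: str, codes: np.ndarray, offset: int,
                   strand: int) -> None:
        self._grow(offset, offset + codes.size)
        i = offset - self.start
        sl = slice(i, i + codes.size)
        known = codes < 4
        self.counts[sl][known, codes[known]] += 1
        self.cover[sl] += known.astype(np.int32)
        self.placements.append((read_id, offset, strand))
        self._placed_codes[read_id] = (offset, codes)

    def _compute_consensus(self, prev: np.ndarray) -> np.ndarray:
        """Majority per column; ties keep the previous consensus base when it
        is among the leaders, else 255 (rendered as an IUPAC code)."""
        top = self.counts.max(axis=1)
        cons = np.full(self.cover.size, 255, dtype=np.uint8)
        covered = self.cover > 0
        is_top = self.counts == top[:, None]
        n_top = is_top.sum(axis=1)
        clear = covered & (n_top == 1)
        cons[clear] = np.argmax(self.counts[clear], axis=1)
        tied = np.nonzero(covered & (n_top > 1))[0]
        for i in tied:
            if prev[i] < 4 and is_top[i, prev[i]]:
                cons[i] = prev[i]
        return cons

    def reconsense(self) -> None:
        self._cons = self._compute_consensus(self._cons)

    # -- public -------------------------------------------------------------
    @property
    def consensus_codes(self) -> np.ndarray:
        """Working consensus over all covered columns (255 = ambiguous tie)."""
        return self._cons

    def try_place(self, read: Read) -> bool:
        """Place the read if it overlaps the consensus by >= min_overlap
        comparable bases at >= min_identity; returns whether it was placed."""
        target = np.where(self._cons > 3, 4, self._cons).astype(np.uint8)
        placement = best_ungapped_placement(target, encode(read.bases),
                                            self.config.min_overlap)
        if placement is None or placement[1] < self.config.min_identity:
            return False
        offset, _, _, strand = placement
        codes = encode(read.bases)
        if strand == 1:
            codes = revcomp_codes(codes)
        self._add_codes(read.id, codes, self.start + offset, strand)
        self.reconsense()
        return True

    def purge_inconsistent(self) -> set:
        """Evict reads whose identity to the *final* consensus falls below
        the stacking threshold, and re-consense until stable.

        When paralogous copies share a locally conserved window, reads of
        both copies can pass the 95 % rule against a short early stack; the
        finished consensus is then a mosaic against which the minority
        copy's reads no longer qualify.  Evicted reads return to the pool
        (the caller un-marks them as used) and seed later rounds.
        """
        evicted: set = set()
        for _ in range(10):
            target = np.where(self._cons > 3, 4, self._cons).astype(np.uint8)
            removed = []
            for read_id, (offset, codes) in self._placed_codes.items():
                if len(self._placed_codes) - len(removed) <= 1:
                    break
                i = offset - self.start
                seg = target[i: i + codes.size]
                comparable = (seg < 4) & (codes < 4)
                n = int(comparable.sum())
                if n == 0:
                    continue
                ident = float((seg[comparable] == codes[comparable]).sum()) / n
                if ident < self.config.min_identity:
                    removed.append(read_id)
            if not removed:
                break
            for read_id in removed:
                offset, codes = self._placed_codes.pop(read_id)
                i = offset - self.start
                sl = slice(i, i + codes.size)
                known = codes < 4
                self.counts[sl][known, codes[known]] -= 1
                self.cover[sl] -= known.astype(np.int32)
                evicted.add(read_id)
            self.placements = [p for p in self.placements
                               if p[0] not in evicted]
            self.reconsense()
        return evicted

    def finalize(self, locus_id: str, individual: str,
                 round_index: int) -> ConsensusContig | None:
        """Trim low-depth ends; interior columns below min depth become N."""
        depth_ok = self.cover >= self.config.min_depth
        if not depth_ok.any():
            return None
        lo = int(np.argmax(depth_ok))
        hi = int(len(depth_ok) - np.argmax(depth_ok[::-1]))
        cons = self._cons[lo:hi]
        counts = self.counts[lo:hi]
        cover = self.cover[lo:hi]
        chars = []
        for i, c in enumerate(cons):
            if cover[i] < self.config.min_depth:
                chars.append("N")
            elif c < 4:
                chars.append(BASES[c])
            else:  # unresolved tie -> IUPAC code over the tied bases
                top = counts[i].max()
                tied = frozenset(BASES[b] for b in range(4) if counts[i][b] == top)
                chars.append(IUPAC.get(tied, "N"))
        return ConsensusContig(locus_id, individual, round_index,
                               "".join(chars), cover.copy(),
                               [p[0] for p in self.placements])


# ---------------------------------------------------------------------------
# seed, extension, rounds
# ---------------------------------------------------------------------------

def stack_and_consense(anchor: Read, reads: Iterable[Read],
                       config: AssemblyConfig | None = None) -> ReadStack:
    """Build the seed stack: align reads to the anchor/stack (ungapped, >= 20 bp
    overlap at >= 95 % identity) and take the majority-rule consensus.

    Reads are stacked best-score-first against the anchor: building the
    same-copy core before divergent reads are tested means a paralogous read
    faces a long consensus, where its score-maximal placement is the long
    homologous overlap that fails the identity threshold — not a short
    locally conserved patch at a tip.
    """
    config = config or AssemblyConfig()
    stack = ReadStack(anchor, config)
    anchor_codes = encode(anchor.bases)
    scored = []
    for read in reads:
        if read.id == anchor.id:
            continue
        pl = best_ungapped_placement(anchor_codes, encode(read.bases),
                                     config.min_overlap)
        score = pl[1] * pl[2] if pl else -1.0
        scored.append((-score, read.id, read))
    for _, _, read in sorted(scored, key=lambda t: (t[0], t[1])):
        stack.try_place(read)
    return stack


def extend_assembly(stack: ReadStack, read_pool: Mapping[str, Read],
                    used: set, config: AssemblyConfig | None = None,
                    key_cache: Mapping[str, set] | None = None,
                    always_candidates: set | None = None) -> ReadStack:
    """Grow the seed outward with repeated passes through the unused pool.

    Reads overlapping the current consensus by >= 20 bp at >= 95 % agreement
    are added (and marked used); passes repeat until a pass adds nothing.

    With ``key_cache`` (read id -> spaced-key set) each pass only tries
    reads sharing a spaced key with the current consensus (plus
    ``always_candidates``, typically the reference-mapped reads); this keeps
    a pass linear in the related reads instead of the whole pool without
    changing which reads can ultimately join.
    """
    config = config or AssemblyConfig()
    placed = {p[0] for p in stack.placements}
    used.update(placed)
    while True:
        if key_cache is not None:
            cons = stack.consensus_codes
            cons_index = set(_spaced_keys(
                np.where(cons > 3, 4, cons).astype(np.uint8),
                config.mask).tolist())
            candidates = [
                rid for rid in sorted(read_pool) if rid not in used
                and ((always_candidates is not None and rid in always_candidates)
                     or not cons_index.isdisjoint(key_cache[rid]))]
        else:
            candidates = [rid for rid in sorted(read_pool) if rid not in used]
        added = 0
        for rid in candidates:
            if stack.try_place(read_pool[rid]):
                used.add(rid)
                added += 1
        stack.reconsense()
        if added == 0:
            break
    evicted = stack.purge_inconsistent()
    used.difference_update(evicted)
    return stack


def assemble_locus(reads: Sequence[Read], reference: str, locus_id: str,
                   individual: str, config: AssemblyConfig | None = None,
                   ) -> list[ConsensusContig]:
    """All assembly rounds for one (individual, locus) pair."""
    config = config or AssemblyConfig()
    index = spaced_kmer_index(reference, config.mask)
    pool = {r.id: r for r in reads}
    mapped_ids = [r.id for r in reads
                  if read_maps(encode(r.bases), index, config.mask)]
    used: set = set()
    contigs: list[ConsensusContig] = []
    for round_index in range(1, config.max_rounds + 1):
        candidates = [pool[rid] for rid in mapped_ids if rid not in used]
        if not candidates:
            break
        anchor = choose_anchor_read(candidates, reference, config)
        if anchor is None:
            break
        anchor = orient_to_reference(anchor, reference, config)
        stack = stack_and_consense(anchor, candidates, config)
        used.update(p[0] for p in stack.placements)
        stack = extend_assembly(stack, pool, used, config)
        contig = stack.finalize(locus_id, individual, round_index)
        if contig is None or contig.length < config.min_contig:
            break
        contigs.append(contig)
    return contigs


def assemble_all(reads_by_individual: Mapping[str, "ReadSet | Sequence[Read]"],
                 references: Mapping[str, str],
                 config: AssemblyConfig | None = None,
                 ) -> tuple[list[ConsensusContig], pd.DataFrame]:
    """Assemble every individual against every locus reference.

    Rounds run per locus on each individual's shrinking read pool; reads
    consumed by one contig never join another.  Returns all contigs plus a
    per-(individual, locus) capture table.
    """
    config = config or AssemblyConfig()
    contigs: list[ConsensusContig] = []
    records = []
    for individual in sorted(reads_by_individual):
        rs = reads_by_individual[individual]
        reads = list(rs.reads) if isinstance(rs, ReadSet) else list(rs)
        pool = {r.id: r for r in reads}
        index_by_locus = {loc: spaced_kmer_index(ref, config.mask)
                          for loc, ref in references.items()}
        mapped: dict[str, list[str]] = {loc: [] for loc in references}
        key_cache: dict[str, set] = {}
        for r in reads:
            keys = read_keys(encode(r.bases), config.mask)
            key_cache[r.id] = keys
            for loc, idx in index_by_locus.items():
                if not idx.isdisjoint(keys):
                    mapped[loc].append(r.id)
        used: set = set()
        active = set(references)
        for round_index in range(1, config.max_rounds + 1):
            any_new = False
            for locus in sorted(active):
                candidates = [pool[rid] for rid in mapped[locus]
                              if rid not in used]
                if not candidates:
                    active.discard(locus)
                    continue
                anchor = choose_anchor_read(candidates, references[locus], config)
                if anchor is None:
                    active.discard(locus)
                    continue
                anchor = orient_to_reference(anchor, references[locus], config)
                stack = stack_and_consense(anchor, candidates, config)
                used.update(p[0] for p in stack.placements)
                stack = extend_assembly(stack, pool, used, config,
                                        key_cache=key_cache,
                                        always_candidates=set(mapped[locus]))
                contig = stack.finalize(locus, individual, round_index)
                if contig is None or contig.length < config.min_contig:
                    active.discard(locus)
                    continue
                contigs.append(contig)
                any_new = True
            if not any_new or not active:
                break
        for locus in sorted(references):
            locus_contigs = [c for c in contigs
                             if c.individual == individual and c.locus_id == locus]
            best = max((c.length for c in locus_contigs), default=0)
            records.append({
                "individual": individual,
                "locus": locus,
                "n_contigs": len(locus_contigs),
                "captured": best > config.capture_length,
                "contig_length": best,
                "reads_in_contigs": sum(len(c.read_ids) for c in locus_contigs),
            })
    table = pd.DataFrame.from_records(
        records, columns=["individual", "locus", "n_contigs", "captured",
                          "contig_length", "reads_in_contigs"])
    return contigs, table


def capture_summary(capture_table: pd.DataFrame,
                    total_reads: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-individual enrichment summary (loci captured, average locus length,
    reads in contigs, % reads in assembly, reads per captured locus)."""
    rows = []
    for individual, grp in capture_table.groupby("individual"):
        captured = grp[grp["captured"]]
        reads_in = int(grp["reads_in_contigs"].sum())
        total = int(total_reads[individual]) if total_reads else None
        rows.append({
            "individual": individual,
            "loci_captured": int(captured.shape[0]),
            "avg_locus_length": float(captured["contig_length"].mean())
            if len(captured) else 0.0,
            "reads_in_contigs": reads_in,
            "total_reads": total,
            "pct_reads_in_assembly": (100.0 * reads_in / total)
            if total else np.nan,
            "reads_per_locus": (reads_in / len(captured)) if len(captured) else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def read_reads(path: str | Path) -> list[Read]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [Read(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


def write_contigs_fasta(contigs: Sequence[ConsensusContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n{c.bases}\n")


def write_capture_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
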