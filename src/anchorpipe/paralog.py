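"""The "paralog picker": partition per-individual consensus sequences into
putatively orthologous homolog sets against a reference individual.

The procedure is deliberately simple and order-driven: homolog set k is the
reference individual's k-th consensus sequence plus, for every other
individual, its not-yet-assigned sequence that best aligns to that reference;
assigned sequences are removed before set k+1 is formed, and the cycle
repeats until the reference sequences are used up.  After an ancient
whole-genome duplication this separates gene copies without assuming the
loci are protein coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import linear_sum_assignment


@dataclass
class HomologSet:
    locus_id: str
    set_index: int                      # 1-based extraction order
    reference_sequence: str
    members: dict                       # individual -> (sequence_id, sequence)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.members)


@dataclass
class PickResult:
    sets: list[HomologSet]
    unassigned: list[tuple]             # (locus_id, individual, sequence_id, best_score)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _local_aligner()


def best_alignment_score(query: str, reference_seq: str) -> float:
    """Similarity of the best local pairwise alignment, in [0, 1].

    The optimal local alignment (match +1, mismatch -1, gap open -4,
    extend -1) locates the best-matching block; the score is the number of
    identical aligned columns divided by the length of the shorter input.
    Normalising by the shorter sequence rather than the block length makes
    the score coverage-sensitive: identical sequences score 1.0, a 10 %
    mutated copy ~0.9, while unrelated sequences score low because only a
    short block aligns.  Symmetric in its arguments.
    """
    if not query or not reference_seq:
        raise ValueError("empty sequence")
    alignments = _ALIGNER.align(query.upper(), reference_seq.upper())
    counts = alignments[0].counts()
    return counts.identities / min(len(query), len(reference_seq))


def choose_reference_individual(capture_table: pd.DataFrame) -> str:
    """The individual with the best capture efficiency.

    Maximises loci captured; ties broken by larger total contig length, then
    lexicographically smaller name.
    """
    if capture_table.empty:
        raise ValueError("empty capture table")
    stats = capture_table.groupby("individual").agg(
        loci=("captured", "sum"), length=("contig_length", "sum"))
    stats = stats.reset_index()
    stats = stats.sort_values(["loci", "length", "individual"],
                              ascending=[False, False, True])
    return str(stats.iloc[0]["individual"])


def assign_homolog_sets(sequences_by_individual: Mapping[str, Sequence[tuple]],
                        reference_sequences: Sequence[tuple],
                        locus_id: str = "locus",
                        *, min_score: float = 0.5,
                        method: str = "greedy") -> PickResult:
    """Partition one locus's sequences into homolog sets.

    Parameters
    ----------
    sequences_by_individual
        individual -> ordered [(sequence_id, sequence), ...] (multiple entries
        are multiple assembled copies, in assembler round order).
    reference_sequences
        The reference individual's sequences in extraction (round) order:
        [(sequence_id, sequence), ...]; the k-th defines homolog set k.
    min_score
        Sequences scoring below this identity against every remaining
        reference are reported unassigned rather than forced into a set.
    method
        "greedy" (the literal per-individual best-hit reading) or "hungarian"
        (globally optimal one-to-one matching per individual, for comparison).
    """
    if not reference_sequences:
        raise ValueError(f"reference individual has no sequences for {locus_id}")
    refs = list(reference_sequences)
    sets = [HomologSet(locus_id, k + 1, seq, {}) for k, (sid, seq) in enumerate(refs)]
    unassigned: list[tuple] = []
    for individual in sorted(sequences_by_individual):
        entries = list(sequences_by_individual[individual])
        if not entries:
            continue
        score = np.array([[best_alignment_score(seq, ref_seq)
                           for _, ref_seq in refs]
                          for _, seq in entries])
        assigned_rows: set[int] = set()
        if method == "hungarian":
            masked = np.where(score >= min_score, score, -1e6)
            rows, cols = linear_sum_assignment(-masked)
            for r, c in zip(rows, cols):
                if score[r, c] >= min_score:
                    sets[c].members[individual] = entries[r]
                    assigned_rows.add(r)
        elif method == "greedy":
            for k in range(len(refs)):
                best_row, best_val = None, -1.0
                for r in range(len(entries)):
                    if r in assigned_rows:
                        continue
                    if score[r, k] > best_val:
                        best_row, best_val = r, score[r, k]
                if best_row is not None and best_val >= min_score:
                    sets[k].members[individual] = entries[best_row]
                    assigned_rows.add(best_row)
        else:
            raise ValueError(f"unknown method {method!r}")
        for r in range(len(entries)):
            if r not in assigned_rows:
                best = float(score[r].max()) if score.size else 0.0
                unassigned.append((locus_id, individual, entries[r][0], best))
    return PickResult(sets, unassigned)


def pick_all(contig_sequences: Mapping[str, Mapping[str, Sequence[tuple]]],
             reference_individual: str, *, min_score: float = 0.5,
             method: str = "greedy") -> dict[str, PickResult]:
    """Run the picker over every locus.

    ``contig_sequences``: locus -> individual -> [(sequence_id, sequence), ...]
    in assembler round order.  Loci for which the reference individual has no
    sequence are skipped (reported as an empty entry).
    """
    results: dict[str, PickResult] = {}
    for locus in sorted(contig_sequences):
        per_ind = contig_sequences[locus]
        refs = list(per_ind.get(reference_individual, []))
        if not refs:
            results[locus] = PickResult([], [
                (locus, ind, sid, float("nan"))
                for ind in sorted(per_ind) for sid, _ in per_ind[ind]])
            continue
        others = {ind: seqs for ind, seqs in per_ind.items()
                  if ind != reference_individual}
        res = assign_homolog_sets(others, refs, locus,
                                  min_score=min_score, method=method)
        for k, (sid, seq) in enumerate(refs):
            res.sets[k].members[reference_individual] = (sid, seq)
        results[locus] = res
    return results


# ---------------------------------------------------------------------------
# tally
# ---------------------------------------------------------------------------

@dataclass
class HomologTally:
    per_locus: pd.DataFrame            # locus, n_sets
    n_loci: int
    n_sets: int
    distribution: dict = field(default_factory=dict)  # n_sets -> fraction of loci

    @property
    def single_set_fraction(self) -> float:
        return self.distribution.get(1, 0.0)


def tally_homolog_sets(results: Mapping[str, "PickResult | Sequence[HomologSet]"],
                       ) -> HomologTally:
    """Per-locus homolog-set counts, grand totals, and the 1..5 distribution."""
    rows = []
    for locus in sorted(results):
        r = results[locus]
        sets = r.sets if isinstance(r, PickResult) else list(r)
        rows.append({"locus": locus, "n_sets": len(sets)})
    per_locus = pd.DataFrame(rows, columns=["locus", "n_sets"])
    n_loci = len(per_locus)
    n_sets = int(per_locus["n_sets"].sum()) if n_loci else 0
    dist = {}
    if n_loci:
        counts = per_locus["n_sets"].value_counts()
        dist = {int(k): float(v) / n_loci for k, v in counts.items()}
    return HomologTally(per_locus, n_loci, n_sets, dist)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def write_homolog_sets(results: Mapping[str, PickResult], outdir: str | Path) -> None:
    """One FASTA per homolog set, named {locus}_h{set_index}.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, res in sorted(results.items()):
        for hs in res.sets:
            path = outdir / f"{locus}_h{hs.set_index}.fasta"
            with open(path, "w") as fh:
                for ind in hs.taxa:
                    sid, seq = hs.members[ind]
                    fh.write(f">{ind} {sid}\n{seq}\n")


def write_tally(tally: HomologTally, path: str | Path) -> None:
    tally.per_locus.to_csv(path, sep="\t", index=False)


def write_unassigned(results: Mapping[str, PickResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tindividual\tsequence_id\tbest_score\n")
        for locus, res in sorted(results.items()):
            for locus_id, ind, sid, score in res.unassigned:
                fh.write(f"{locus_id}\t{ind}\t{sid}\t{score:.3f}\n")
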