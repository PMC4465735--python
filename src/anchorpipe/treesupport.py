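"""Distance trees, nonparametric bootstrap, and bipartition/clade support.

The internal inference backend is distance + neighbor joining: fast enough to
run hundreds of bootstrap replicates per locus pool inside a rarefaction
sweep, deterministic, and pluggable — any callable mapping an alignment to a
dendropy tree (e.g. a wrapper around an external ML program) can stand in as
``backend``.  Node support is bipartition support: the percentage of
replicate trees containing the internal edge's split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .msa import Msa
from ._seq import stream

LARGE_DISTANCE = 5.0  # assigned (and flagged) when a pair shares < 100 sites
MIN_OVERLAP_SITES = 100


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _codes(msa: Msa) -> np.ndarray:
    codes = np.full(msa.matrix.shape, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        codes[msa.matrix == b] = i
    return codes


@dataclass
class FlaggedDistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    flagged_pairs: list = field(default_factory=list)  # insufficient overlap


def distance_matrix(msa: Msa, model: str = "JC69") -> FlaggedDistanceMatrix:
    """Pairwise distances under p, JC69 or K2P.

    Pairs sharing fewer than 100 comparable (non-missing, non-gap) columns
    receive a flagged large distance; saturated pairs likewise.  A taxon with
    zero non-missing sites is an error.
    """
    if model not in ("p", "JC69", "K2P"):
        raise ValueError(f"unknown model {model!r}")
    codes = _codes(msa)
    valid = codes < 4
    if not valid.any(axis=1).all():
        bad = msa.taxa[int(np.argmin(valid.any(axis=1)))]
        raise ValueError(f"taxon {bad} has zero non-missing sites")
    n = msa.n_taxa
    D = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = int(both.sum())
            if nv < MIN_OVERLAP_SITES:
                D[i, j] = D[j, i] = LARGE_DISTANCE
                flagged.append((msa.taxa[i], msa.taxa[j]))
                continue
            ci, cj = codes[i][both], codes[j][both]
            diff = ci != cj
            p = float(diff.mean())
            if model == "p":
                d = p
            elif model == "JC69":
                arg = 1 - 4 * p / 3
                d = -0.75 * np.log(arg) if arg > 0 else LARGE_DISTANCE
                if arg <= 0:
                    flagged.append((msa.taxa[i], msa.taxa[j]))
            else:  # K2P; transitions A<->G (0,2) and C<->T (1,3) share parity
                ts = float((diff & ((ci % 2) == (cj % 2))).mean())
                tv = p - ts
                a1, a2 = 1 - 2 * ts - tv, 1 - 2 * tv
                if a1 > 0 and a2 > 0:
                    d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
                else:
                    d = LARGE_DISTANCE
                    flagged.append((msa.taxa[i], msa.taxa[j]))
            D[i, j] = D[j, i] = d
    return FlaggedDistanceMatrix(list(msa.taxa), D, flagged)


def jc69_distance(p: float) -> float:
    """Closed-form JC69 correction of a p-distance."""
    arg = 1 - 4 * p / 3
    if arg <= 0:
        return LARGE_DISTANCE
    return -0.75 * float(np.log(arg))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distances: FlaggedDistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, branch lengths clamped at 0).

    Taxa are sorted before the matrix is handed to the NJ solver, so the
    result is a pure function of the distances with ties broken by label
    order.
    """
    if len(distances.taxa) < 4:
        raise ValueError("need >= 4 taxa for an informative unrooted tree")
    if not np.isfinite(distances.matrix).all():
        raise ValueError("non-finite distances")
    order = np.argsort(distances.taxa)
    ids = [distances.taxa[i] for i in order]
    dm = DistanceMatrix(distances.matrix[np.ix_(order, order)], ids)
    sk = _skbio_nj(dm)
    import io as _io
    buf = _io.StringIO()
    sk.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# bipartitions and support
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset) -> set[frozenset]:
    """Internal-edge splits as frozensets of the side not containing the
    alphabetically first taxon (root/trivial edges excluded)."""
    ref = min(all_taxa)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(all_taxa - side) <= 1:
            continue
        splits.add(side if ref not in side else all_taxa - side)
    return splits


@dataclass
class SupportTree:
    tree: dendropy.Tree                 # best tree with supports on internal nodes
    supports: dict                      # frozenset split -> percentage
    n_replicates: int
    replicate_splits: list              # list of set-of-frozenset per replicate
    taxa: frozenset

    def internal_supports(self) -> list[float]:
        return [self.supports[s] for s in sorted(self.supports, key=sorted)]

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)


def default_nj_backend(model: str = "JC69") -> Callable[[Msa], dendropy.Tree]:
    def backend(msa: Msa) -> dendropy.Tree:
        return nj_tree(distance_matrix(msa, model=model))
    return backend


def bootstrap_support(msa: Msa, n_reps: int = 500, seed: int = 0,
                      backend: Callable[[Msa], dendropy.Tree] | None = None,
                      *, codon_aware: bool = False,
                      max_failure_fraction: float = 0.1) -> SupportTree:
    """Nonparametric bootstrap node support.

    Columns (or codon triplets when ``codon_aware``) are resampled with
    replacement; a tree is inferred per replicate; bipartition frequencies
    are mapped onto the best tree from the original alignment.  Failed
    replicates are dropped and logged; more than 10 % failures is an error.
    Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    backend = backend or default_nj_backend()
    rng = stream(seed, "bootstrap")
    best = backend(msa)
    all_taxa = frozenset(msa.taxa)
    L = msa.length
    replicate_splits = []
    failures = 0
    for _ in range(n_reps):
        if codon_aware and L % 3 == 0:
            tri = rng.integers(0, L // 3, size=L // 3)
            idx = (tri[:, None] * 3 + np.arange(3)).ravel()
        else:
            idx = rng.integers(0, L, size=L)
        rep = msa.take_columns(idx)
        try:
            t = backend(rep)
        except Exception:
            failures += 1
            continue
        replicate_splits.append(_bipartitions(t, all_taxa))
    if failures > max_failure_fraction * n_reps:
        raise RuntimeError(f"{failures}/{n_reps} bootstrap replicates failed")
    n_ok = len(replicate_splits)
    supports = {}
    for split in _bipartitions(best, all_taxa):
        count = sum(split in reps for reps in replicate_splits)
        supports[split] = 100.0 * count / n_ok
    # annotate best tree
    ref = min(all_taxa)
    for node in best.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = side if ref not in side else all_taxa - side
        if key in supports:
            node.label = f"{supports[key]:.0f}"
    return SupportTree(best, supports, n_ok, replicate_splits, all_taxa)


# ---------------------------------------------------------------------------
# clades
# ---------------------------------------------------------------------------

@dataclass
class CladeDefinition:
    name: str
    taxon_set: frozenset
    kind: str = "monophyly"             # "monophyly" | "mrca"

    def __post_init__(self):
        self.taxon_set = frozenset(self.taxon_set)
        if not self.taxon_set:
            raise ValueError("empty clade definition")
        if self.kind not in ("monophyly", "mrca"):
            raise ValueError(f"unknown clade kind {self.kind!r}")


def parse_clade_file(path: str | Path) -> list[CladeDefinition]:
    """Plain-text clade definitions: ``name: taxon1, taxon2, ...`` per line;
    prefix the name with ``mrca `` for MRCA-defined clades."""
    clades = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, taxa = line.partition(":")
        name = name.strip()
        kind = "monophyly"
        if name.lower().startswith("mrca "):
            kind, name = "mrca", name[5:].strip()
        clades.append(CladeDefinition(
            name, frozenset(t.strip() for t in taxa.split(",") if t.strip()),
            kind))
    return clades


def clade_support(support_tree: SupportTree, clade: CladeDefinition) -> float:
    """Bootstrap percentage for a clade.

    Monophyly: frequency of the exact bipartition separating the clade's
    taxa.  MRCA-defined: frequency of the smallest split on the best tree
    containing the named taxa.
    """
    taxa = support_tree.taxa
    if not clade.taxon_set <= taxa:
        raise ValueError(f"clade {clade.name} names taxa absent from the tree")
    ref = min(taxa)
    if clade.kind == "monophyly":
        target = (clade.taxon_set if ref not in clade.taxon_set
                  else taxa - clade.taxon_set)
    else:
        sides = []
        for s in _bipartitions(support_tree.tree, taxa):
            for side in (s, taxa - s):
                if clade.taxon_set <= side:
                    sides.append((len(side), s))
        if not sides:  # MRCA is the root: no internal edge defines it
            return 0.0
        target = min(sides)[1]
    if len(target) <= 1 or len(taxa - target) <= 1:
        return 100.0  # trivial split, present in every tree
    count = sum(target in reps for reps in support_tree.replicate_splits)
    return 100.0 * count / support_tree.n_replicates


def clade_support_from_replicates(replicate_trees: Sequence[dendropy.Tree],
                                  clade: CladeDefinition,
                                  taxa: frozenset) -> float:
    """Monophyly frequency across an explicit list of replicate trees."""
    ref = min(taxa)
    target = clade.taxon_set if ref not in clade.taxon_set else taxa - clade.taxon_set
    count = 0
    for t in replicate_trees:
        if target in _bipartitions(t, taxa):
            count += 1
    return 100.0 * count / len(replicate_trees)


def average_node_support(support_tree: SupportTree) -> float:
    """Mean bootstrap support over internal edges of the best tree."""
    vals = list(support_tree.supports.values())
    if not vals:
        raise ValueError("tree has no internal edges")
    return float(np.mean(vals))


def count_nodes_above(support_tree: SupportTree, threshold: float) -> int:
    """Internal edges with support strictly greater than ``threshold``."""
    return sum(1 for v in support_tree.supports.values() if v > threshold)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def read_trees(path: str | Path) -> list[dendropy.Tree]:
    return list(dendropy.TreeList.get(path=str(path), schema="newick"))
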