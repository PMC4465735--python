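"""Synthetic anchored-enrichment datasets with known truth.

Everything downstream of sequencing is testable against this module: it draws
a species tree, duplicates a fraction of loci at the root of that tree (the
scenario created by an ancient whole-genome duplication predating all sampled
taxa), loses copies along branches, evolves in-frame coding sequences under a
GTR model with codon-position rate multipliers, and shears capture reads with
a probe-centred trapezoidal coverage profile and species-specific capture
efficiency.  Every read carries a truth record (locus, copy, individual,
0-based start on the source sequence).

Randomness: one master seed; per-locus/per-stage streams are derived by
hashing ``(locus_id, stage)`` so adding loci never perturbs earlier loci.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import yaml
from dendropy.simulate import treesim
from scipy.linalg import expm

from ._seq import decode, encode, revcomp_codes, stream

STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + codon-position multipliers.

    ``codon_rates`` scales branch lengths cyclically at positions 1/2/3; the
    default makes third positions evolve fastest, matching the site-variability
    pattern typical of protein-coding capture loci.
    """

    exchangeabilities: tuple = (0.9, 3.0, 0.8, 1.1, 3.2, 1.0)  # AC AG AT CG CT GT
    base_freqs: tuple = (0.26, 0.23, 0.24, 0.27)
    codon_rates: tuple = (0.3, 0.2, 1.0)

    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix (mean rate 1 at equilibrium)."""
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        pi = np.asarray(self.base_freqs, dtype=float)
        pi = pi / pi.sum()
        R = np.array([
            [0.0, ac, ag, at],
            [ac, 0.0, cg, ct],
            [ag, cg, 0.0, gt],
            [at, ct, gt, 0.0],
        ])
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a 29-taxon anchored-enrichment capture: locus lengths span
    450-1605 bp, ~40 % of loci carry a root-level duplication, lineage-specific
    loss prunes copies, and coverage is probe-centred with species-specific
    efficiency multipliers.
    """

    n_taxa: int = 29
    n_loci: int = 50
    duplicate_fraction: float = 0.4
    loss_prob: float = 0.05
    locus_length: int | None = None          # None -> draw 450..1605 per locus
    locus_length_range: tuple = (450, 1605)
    subst_model: SubstitutionModel = field(default_factory=SubstitutionModel)
    tree_height: float = 0.04                # root-to-tip expected subs/site (rate 1)
    paralog_depth: float = 0.25              # stem length added to each WGD copy
    duplication_placement: str = "root"      # "root" | "random" (mid-tree)
    secondary_duplication_prob: float = 0.35  # extra duplications, copy count capped at 5
    max_copies: int = 5
    read_length: int = 100
    target_coverage: float = 10.0
    probe_length: int = 120
    flank_decay: float = 0.003               # coverage weight lost per bp from probe core
    per_species_efficiency: float | Mapping[str, float] = 1.0
    error_rate: float = 0.01
    enforce_orf: bool = True                 # forbid in-frame stops in evolved leaves
    seed: int = 0

    def __post_init__(self):
        for name in ("duplicate_fraction", "loss_prob", "error_rate",
                     "secondary_duplication_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.target_coverage <= 0 or self.read_length <= 0:
            raise ValueError("coverage and read length must be positive")
        if self.locus_length is not None and self.locus_length <= 0:
            raise ValueError("locus_length must be positive")

    def efficiency(self, taxon: str) -> float:
        if isinstance(self.per_species_efficiency, Mapping):
            return float(self.per_species_efficiency.get(taxon, 1.0))
        return float(self.per_species_efficiency)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["per_species_efficiency"], Mapping):
            d["per_species_efficiency"] = dict(d["per_species_efficiency"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "subst_model" in d and isinstance(d["subst_model"], dict):
            sm = d["subst_model"]
            for k in ("exchangeabilities", "base_freqs", "codon_rates"):
                if k in sm:
                    sm[k] = tuple(sm[k])
            d["subst_model"] = SubstitutionModel(**sm)
        for k in ("locus_length_range",):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneCopy:
    index: int
    tree: dendropy.Tree           # pruned copy of the species tree
    stem_length: float            # extra divergence above the copy's root
    lost_taxa: frozenset
    origin: str                   # which duplication event produced this copy


@dataclass
class GeneFamily:
    locus_id: str
    length: int                   # bp, multiple of 3
    copies: list[GeneCopy]
    root_sequence: str | None = None
    sequences: dict = field(default_factory=dict)  # (copy_index, taxon) -> str

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class Read:
    id: str
    bases: str


@dataclass
class ReadSet:
    reads: list[Read]
    truth: dict  # read_id -> (locus_id, copy_index, individual, start)

    def extend(self, other: "ReadSet") -> None:
        self.reads.extend(other.reads)
        self.truth.update(other.truth)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_taxa: int, seed: int, *, tree_height: float = 0.04,
                          birth_rate: float = 1.0, death_rate: float = 0.0,
                          ) -> dendropy.Tree:
    """Draw a rooted binary species tree (birth-death) scaled to a root height.

    Branch lengths are expected substitutions per site at relative rate 1.
    Deterministic given ``seed``.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa (capture rule requires >= 4 species)")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_taxa, rng=rng,
    )
    # Stable, readable labels: sp01.. in the order dendropy created them.
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    factor = tree_height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length * factor, 1e-9)
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# gene families (duplication + loss)
# ---------------------------------------------------------------------------

def _prune_copy(species_tree: dendropy.Tree, loss_prob: float,
                rng: np.random.Generator) -> tuple[dendropy.Tree | None, frozenset]:
    """Clone the species tree and drop whole subtrees via per-branch loss."""
    tree = species_tree.clone(depth=1)
    lost = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if rng.random() < loss_prob:
            lost.update(l.taxon.label for l in node.leaf_iter())
    keep = [t for t in tree.taxon_namespace
            if t.label not in lost]
    if len(keep) < 4:
        return None, frozenset(lost)
    tree.retain_taxa_with_labels([t.label for t in keep])
    return tree, frozenset(lost)


def simulate_gene_families(species_tree: dendropy.Tree, config: SimulationConfig,
                           ) -> list[GeneFamily]:
    """Duplicate-and-lose gene families on a species tree.

    A fraction ``duplicate_fraction`` of loci receive a duplication (at the
    root by default); each copy then loses taxa independently per branch with
    ``loss_prob``; copies retaining < 4 taxa are dropped.  Families are
    resampled (bounded retries) if no copy would retain >= 4 taxa, so every
    family is assemblable.
    """
    families = []
    for i in range(config.n_loci):
        locus_id = f"L{i + 1:04d}"
        rng = stream(config.seed, locus_id, "family")
        if config.locus_length is not None:
            length = config.locus_length
        else:
            lo, hi = config.locus_length_range
            length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        n_initial = 1
        if rng.random() < config.duplicate_fraction:
            n_initial = 2
        while (n_initial < config.max_copies
               and n_initial > 1
               and rng.random() < config.secondary_duplication_prob):
            n_initial += 1
        copies: list[GeneCopy] = []
        for attempt in range(25):
            copies = []
            for c in range(n_initial):
                loss_p = config.loss_prob if n_initial > 1 else 0.0
                pruned, lost = _prune_copy(species_tree, loss_p, rng)
                if pruned is None:
                    continue
                stem = config.paralog_depth if n_initial > 1 else 0.0
                copies.append(GeneCopy(
                    index=len(copies), tree=pruned, stem_length=stem,
                    lost_taxa=lost,
                    origin="wgd" if n_initial > 1 else "single"))
            if copies:
                break
        if not copies:  # pathological loss_prob: keep one full, loss-free copy
            full, _ = _prune_copy(species_tree, 0.0, rng)
            copies = [GeneCopy(0, full, 0.0, frozenset(), "forced")]
        families.append(GeneFamily(locus_id=locus_id, length=length, copies=copies))
    return families


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _transition(Q: np.ndarray, t: float, cache: dict) -> np.ndarray:
    key = round(float(t), 12)
    if key not in cache:
        P = expm(Q * t)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        cache[key] = np.cumsum(P, axis=1)
    return cache[key]


def _evolve_branch(parent: np.ndarray, t_codes: np.ndarray, Pcum_by_class: list,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve one branch; ``t_codes`` gives the rate class of each site."""
    child = np.empty_like(parent)
    u = rng.random(parent.size)
    for cls, Pcum in enumerate(Pcum_by_class):
        idx = np.nonzero(t_codes == cls)[0]
        if idx.size == 0:
            continue
        rows = Pcum[parent[idx]]
        child[idx] = (rows < u[idx, None]).sum(axis=1)
    return child


def evolve_along_tree(tree: dendropy.Tree, root_codes: np.ndarray,
                      model: SubstitutionModel, rng: np.random.Generator,
                      *, site_classes: np.ndarray | None = None,
                      stem_length: float = 0.0) -> dict[str, np.ndarray]:
    """Evolve a sequence down a tree under GTR with per-site rate classes.

    Returns leaf label -> uint8 codes.  Public so tests can exercise the
    substitution process directly against closed-form expectations.
    """
    Q = model.rate_matrix()
    L = root_codes.size
    if site_classes is None:
        site_classes = np.arange(L) % 3
    mults = np.asarray(model.codon_rates, dtype=float)
    cache: dict = {}

    def pcum_for(t: float) -> list:
        return [_transition(Q, t * m, cache) for m in mults]

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    start = root_codes
    if stem_length > 0:
        start = _evolve_branch(root_codes, site_classes, pcum_for(stem_length), rng)
    seqs[id(root)] = start
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            if node.is_leaf():
                out[node.taxon.label] = seqs[id(node)]
            continue
        t = node.edge.length or 0.0
        if t <= 0:
            child = seqs[id(node.parent_node)].copy()
        else:
            child = _evolve_branch(seqs[id(node.parent_node)], site_classes,
                                   pcum_for(t), rng)
        seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = child
    return out


def _sample_root(length: int, model: SubstitutionModel, rng: np.random.Generator,
                 avoid_stops: bool) -> np.ndarray:
    pi = np.asarray(model.base_freqs, dtype=float)
    pi = pi / pi.sum()
    codes = rng.choice(4, size=length, p=pi).astype(np.uint8)
    if avoid_stops:
        for c in range(0, length - 2, 3):
            while tuple(codes[c:c + 3]) in STOP_CODONS:
                codes[c:c + 3] = rng.choice(4, size=3, p=pi)
    return codes


def evolve_sequences(family: GeneFamily, config: SimulationConfig) -> dict:
    """Evolve all copies of a family from a shared ancestral sequence.

    Fills ``family.root_sequence`` and ``family.sequences`` and returns the
    latter ({(copy_index, taxon) -> str}).  When ``enforce_orf`` is set,
    frame-0 codon columns that produced a stop in any leaf are re-evolved
    (bounded rejection), so emitted sequences are in frame with no internal
    stop codons.
    """
    if family.length <= 0:
        raise ValueError("zero-length locus")
    rng = stream(config.seed, family.locus_id, "evolve")
    model = config.subst_model
    root = _sample_root(family.length, model, rng, config.enforce_orf)

    def run(cols: np.ndarray, root_slice: np.ndarray) -> dict:
        res = {}
        classes = cols % 3
        for copy in family.copies:
            leaves = evolve_along_tree(copy.tree, root_slice, model, rng,
                                       site_classes=classes,
                                       stem_length=copy.stem_length)
            for taxon, codes in leaves.items():
                res[(copy.index, taxon)] = codes
        return res

    all_cols = np.arange(family.length)
    result = run(all_cols, root)
    if config.enforce_orf:
        for _ in range(30):
            bad = set()
            for codes in result.values():
                cods = codes[: family.length - family.length % 3].reshape(-1, 3)
                stops = [i for i, c in enumerate(map(tuple, cods))
                         if c in STOP_CODONS]
                bad.update(stops)
            if not bad:
                break
            cols = np.sort(np.concatenate([np.arange(3 * i, 3 * i + 3)
                                           for i in sorted(bad)]))
            pi = np.asarray(model.base_freqs, dtype=float)
            pi = pi / pi.sum()
            for i in sorted(bad):
                root[3 * i: 3 * i + 3] = rng.choice(4, size=3, p=pi)
                while tuple(root[3 * i: 3 * i + 3]) in STOP_CODONS:
                    root[3 * i: 3 * i + 3] = rng.choice(4, size=3, p=pi)
            redo = run(cols, root[cols])
            for key, codes in redo.items():
                result[key][cols] = codes
        else:  # pragma: no cover - bounded-rejection fallback
            for key, codes in result.items():
                cods = codes[: family.length].reshape(-1, 3)
                for i, c in enumerate(map(tuple, cods)):
                    if c in STOP_CODONS:
                        codes[3 * i: 3 * i + 3] = root[3 * i: 3 * i + 3]
    family.root_sequence = decode(root)
    family.sequences = {k: decode(v) for k, v in result.items()}
    return family.sequences


# ---------------------------------------------------------------------------
# read shearing
# ---------------------------------------------------------------------------

def coverage_profile(length: int, config: SimulationConfig) -> np.ndarray:
    """Trapezoid coverage weight per base: flat probe core, linear flank decay."""
    x = np.arange(length)
    core_lo = max(0, (length - config.probe_length) // 2)
    core_hi = min(length, core_lo + config.probe_length)
    dist = np.maximum(np.maximum(core_lo - x, x - (core_hi - 1)), 0)
    return np.clip(1.0 - config.flank_decay * dist, 0.0, 1.0)


def shear_reads(sequence: str, locus_id: str, copy_index: int, individual: str,
                config: SimulationConfig,
                rng: np.random.Generator | None = None) -> ReadSet:
    """Shear probe-centred capture reads from one source sequence.

    Expected depth at the probe core is ``target_coverage x efficiency`` and
    decays linearly over the flanks; substitution errors at ``error_rate``;
    every read appears exactly once in the truth map.
    """
    L = len(sequence)
    rl = config.read_length
    if L < rl:
        raise ValueError("sequence shorter than read length")
    if rng is None:
        rng = stream(config.seed, locus_id, "reads", copy_index, individual)
    eff = config.efficiency(individual)
    profile = coverage_profile(L, config)
    csum = np.concatenate([[0.0], np.cumsum(profile)])
    weights = (csum[rl:] - csum[:-rl]) / rl  # mean profile under each read placement
    total_weight = weights.sum()
    if total_weight <= 0:
        return ReadSet([], {})
    n_reads = rng.poisson(config.target_coverage * eff * profile.sum() / rl)
    starts = rng.choice(L - rl + 1, size=n_reads, p=weights / total_weight)
    codes_full = encode(sequence)
    reads, truth = [], {}
    for i, s in enumerate(sorted(map(int, starts))):
        codes = codes_full[s:s + rl].copy()
        if config.error_rate > 0:
            err = np.nonzero(rng.random(rl) < config.error_rate)[0]
            if err.size:
                codes[err] = (codes[err] + rng.integers(1, 4, size=err.size)) % 4
        if rng.random() < 0.5:
            codes = revcomp_codes(codes)
        rid = f"{individual}_{locus_id}_c{copy_index}_{i:05d}"
        reads.append(Read(rid, decode(codes)))
        truth[rid] = (locus_id, copy_index, individual, s)
    return ReadSet(reads, truth)


# ---------------------------------------------------------------------------
# dataset assembly-side bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    species_tree: dendropy.Tree
    families: list[GeneFamily]
    references: dict            # locus_id -> reference sequence (ancestral)
    reads_by_individual: dict   # individual -> ReadSet

    @property
    def taxa(self) -> list[str]:
        return sorted(l.taxon.label for l in self.species_tree.leaf_node_iter())

    def truth_sequence(self, locus_id: str, copy_index: int, individual: str) -> str:
        fam = next(f for f in self.families if f.locus_id == locus_id)
        return fam.sequences[(copy_index, individual)]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """End-to-end draw: tree -> families -> sequences -> capture reads."""
    tree = simulate_species_tree(config.n_taxa, config.seed,
                                 tree_height=config.tree_height)
    families = simulate_gene_families(tree, config)
    references = {}
    reads_by_ind: dict[str, ReadSet] = {}
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    for fam in families:
        evolve_sequences(fam, config)
        references[fam.locus_id] = fam.root_sequence
        for (copy_idx, taxon), seq in sorted(fam.sequences.items()):
            rs = shear_reads(seq, fam.locus_id, copy_idx, taxon, config)
            reads_by_ind.setdefault(taxon, ReadSet([], {})).extend(rs)
    for t in taxa:
        reads_by_ind.setdefault(t, ReadSet([], {}))
    return SyntheticDataset(config, tree, families, references, reads_by_ind)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_reads_fasta(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f">{r.id}\n{r.bases}\n")


def write_reads_fastq(readset: ReadSet, path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{quality * len(r.bases)}\n")


def write_truth_table(dataset_or_readset, path: str | Path) -> None:
    """Tab-separated truth map: read_id, locus, copy, individual, start (0-based)."""
    if isinstance(dataset_or_readset, SyntheticDataset):
        items = []
        for rs in dataset_or_readset.reads_by_individual.values():
            items.extend(rs.truth.items())
    else:
        items = list(dataset_or_readset.truth.items())
    with open(path, "w") as fh:
        fh.write("read_id\tlocus\tcopy\tindividual\tstart\n")
        for rid, (locus, copy_idx, ind, start) in sorted(items):
            fh.write(f"{rid}\t{locus}\t{copy_idx}\t{ind}\t{start}\n")


def write_gene_trees(families: list[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in families:
            for copy in fam.copies:
                newick = copy.tree.as_string(schema="newick").strip()
                fh.write(f"[{fam.locus_id} copy {copy.index}] {newick}\n")


def write_references_fasta(references: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus, seq in sorted(references.items()):
            fh.write(f">{locus}\n{seq}\n")
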