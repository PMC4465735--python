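"""End-to-end benchmark workflows on synthetic data with known truth.

Each function simulates a dataset under stated study conditions, runs the
relevant pipeline stages, and measures recovery against the recorded truth.
They are the basis of the acceptance checks and of the reproduction script;
all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from ._seq import encode
from .assembly import assemble_all, best_ungapped_placement
from .msa import Msa
from .paralog import choose_reference_individual, pick_all, tally_homolog_sets
from .rarefaction import RarefactionConfig, plateau_detect, run_rarefaction
from .simulate import (SimulationConfig, evolve_sequences,
                       simulate_gene_families, simulate_species_tree,
                       simulate_dataset)
from .treesupport import CladeDefinition


def contig_truth_identity(contig_bases: str, truth: str,
                          min_overlap: int = 20) -> float:
    """Identity of a contig against its truth sequence at the best ungapped
    placement (contigs carry no indels relative to their source)."""
    placement = best_ungapped_placement(encode(truth), encode(contig_bases),
                                        min_overlap)
    return placement[1] if placement else 0.0


def assembly_recovery(seed: int, n_loci: int = 50, n_taxa: int = 6,
                      locus_length: int = 600, coverage: float = 10.0,
                      error_rate: float = 0.01) -> dict:
    """Single-copy recovery: simulate clean loci at uniform coverage,
    assemble every individual, and score capture and contig identity."""
    cfg = SimulationConfig(n_taxa=n_taxa, n_loci=n_loci,
                           duplicate_fraction=0.0, locus_length=locus_length,
                           target_coverage=coverage, flank_decay=0.0,
                           error_rate=error_rate, seed=seed)
    ds = simulate_dataset(cfg)
    contigs, table = assemble_all(ds.reads_by_individual, ds.references)
    identities = []
    for c in contigs:
        if c.length <= 350:
            continue
        truth = ds.truth_sequence(c.locus_id, 0, c.individual)
        identities.append(contig_truth_identity(c.bases, truth))
    return {
        "n_pairs": int(table.shape[0]),
        "capture_rate_pct": 100.0 * float(table["captured"].mean()),
        "mean_identity_pct": 100.0 * float(np.mean(identities)),
        "min_identity_pct": 100.0 * float(np.min(identities)),
        "n_contigs": len(identities),
    }


def _contig_truth_copy(contig, truth_map) -> int:
    """Majority truth copy among the reads stacked into a contig."""
    votes = Counter(truth_map[rid][1] for rid in contig.read_ids
                    if rid in truth_map)
    return votes.most_common(1)[0][0]


def paralog_separation(seed: int, n_loci: int = 50, n_taxa: int = 6,
                       locus_length: int = 600, coverage: float = 10.0,
                       error_rate: float = 0.01) -> dict:
    """Duplicated-locus separation and picking accuracy.

    Two full root copies per locus (inter-copy divergence ~20 %, ortholog
    divergence <= ~5 % under the default tree height); the assembler should
    produce one contig per copy per individual, and the picker should
    reassemble homolog sets that match the truth copies.
    """
    cfg = SimulationConfig(n_taxa=n_taxa, n_loci=n_loci,
                           duplicate_fraction=1.0, loss_prob=0.0,
                           secondary_duplication_prob=0.0,
                           locus_length=locus_length,
                           target_coverage=coverage, flank_decay=0.0,
                           error_rate=error_rate, seed=seed)
    ds = simulate_dataset(cfg)
    contigs, table = assemble_all(ds.reads_by_individual, ds.references)
    truth_map = {}
    for rs in ds.reads_by_individual.values():
        truth_map.update(rs.truth)
    big = [c for c in contigs if c.length > 350]
    pair_counts = Counter((c.individual, c.locus_id) for c in big)
    expected_pairs = [(i, l) for i in ds.taxa for l in ds.references]
    two_rate = float(np.mean([pair_counts.get(p, 0) == 2
                              for p in expected_pairs]))
    # A copy is recoverable only when its reads tile the locus without a
    # break (successive starts within read_length - min_overlap) over a
    # comfortably captured span; Poisson shearing occasionally leaves a
    # coverage gap that no assembler could bridge, and those pairs are
    # scored separately.
    starts: dict = {}
    for rs in ds.reads_by_individual.values():
        for rid, (locus, copy_idx, ind, start) in rs.truth.items():
            starts.setdefault((ind, locus, copy_idx), []).append(start)
    max_step = cfg.read_length - 20

    def recoverable(key) -> bool:
        ss = sorted(starts.get(key, []))
        if not ss:
            return False
        best = span = cfg.read_length
        first = ss[0]
        for prev, nxt in zip(ss, ss[1:]):
            if nxt - prev > max_step:
                best = max(best, prev + cfg.read_length - first)
                first = nxt
        best = max(best, ss[-1] + cfg.read_length - first)
        return best >= 500

    evaluable = [p for p in expected_pairs
                 if recoverable((p[0], p[1], 0)) and recoverable((p[0], p[1], 1))]
    two_rate_eval = float(np.mean([pair_counts.get(p, 0) == 2
                                   for p in evaluable])) if evaluable else 0.0
    # picker on the assembled contigs, in round order
    reference = choose_reference_individual(table)
    contig_sequences: dict = {l: {} for l in ds.references}
    for c in sorted(big, key=lambda c: (c.locus_id, c.individual,
                                        c.round_index)):
        contig_sequences[c.locus_id].setdefault(c.individual, []).append(
            (c.name, c.bases))
    truth_copy = {c.name: _contig_truth_copy(c, truth_map) for c in big}
    results = pick_all(contig_sequences, reference)
    correct = total = 0
    for locus, res in results.items():
        for hs in res.sets:
            if reference not in hs.members:
                continue
            ref_copy = truth_copy[hs.members[reference][0]]
            for ind, (name, _) in hs.members.items():
                if ind == reference:
                    continue
                total += 1
                correct += truth_copy[name] == ref_copy
    return {
        "two_contig_rate_pct": 100.0 * two_rate,
        "two_contig_rate_evaluable_pct": 100.0 * two_rate_eval,
        "n_evaluable": len(evaluable),
        "assignment_accuracy_pct": 100.0 * correct / total if total else 0.0,
        "n_assigned": total,
        "n_pairs": len(expected_pairs),
        "reference_individual": reference,
    }


def homolog_tally(seed: int, n_loci: int = 107, n_taxa: int = 12,
                  locus_length: int = 600) -> dict:
    """Homolog-set tally under the default duplication/loss regime.

    The picker runs on the true per-copy sequences (no assembly), so the
    tally reflects the duplication/loss process plus picking, mirroring the
    published per-locus homolog-set distribution's shape.
    """
    cfg = SimulationConfig(n_taxa=n_taxa, n_loci=n_loci,
                           locus_length=locus_length, seed=seed)
    tree = simulate_species_tree(n_taxa, seed, tree_height=cfg.tree_height)
    families = simulate_gene_families(tree, cfg)
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    contig_sequences: dict = {}
    for fam in families:
        evolve_sequences(fam, cfg)
        per_ind: dict = {}
        for (copy_idx, taxon), seq in sorted(fam.sequences.items(),
                                             key=lambda kv: kv[0]):
            per_ind.setdefault(taxon, []).append(
                (f"{taxon}_{copy_idx}", seq))
        contig_sequences[fam.locus_id] = per_ind
    reference = taxa[0]
    results = pick_all(contig_sequences, reference)
    tally = tally_homolog_sets(results)
    return {
        "n_loci": tally.n_loci,
        "n_sets": tally.n_sets,
        "single_set_pct": 100.0 * tally.single_set_fraction,
        "one_or_two_set_pct": 100.0 * (tally.distribution.get(1, 0.0)
                                       + tally.distribution.get(2, 0.0)),
        "sets_per_locus": tally.n_sets / tally.n_loci,
        "distribution": tally.distribution,
    }


def simulate_locus_alignments(seed: int, n_loci: int = 40, n_taxa: int = 10,
                              locus_length: int = 450,
                              tree_height: float = 0.03):
    """Single-copy locus alignments evolved on one species tree (indel-free,
    so the truth alignment is the sequence matrix itself)."""
    cfg = SimulationConfig(n_taxa=n_taxa, n_loci=n_loci,
                           duplicate_fraction=0.0,
                           locus_length=locus_length,
                           tree_height=tree_height, seed=seed)
    tree = simulate_species_tree(n_taxa, seed, tree_height=tree_height)
    families = simulate_gene_families(tree, cfg)
    alignments = {}
    for fam in families:
        evolve_sequences(fam, cfg)
        alignments[fam.locus_id] = Msa.from_dict(
            {t: fam.sequences[(0, t)] for t in sorted(
                l.taxon.label for l in tree.leaf_node_iter())})
    return tree, alignments


def _tracked_clades(tree) -> list[CladeDefinition]:
    """A positive control (a cherry of the generating tree) and a negative
    control (a pair crossing that cherry's boundary)."""
    cherry = None
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            cherry = {c.taxon.label for c in children}
            break
    outside = next(l.taxon.label for l in tree.leaf_node_iter()
                   if l.taxon.label not in cherry)
    inside = sorted(cherry)[0]
    return [CladeDefinition("true_cherry", frozenset(cherry)),
            CladeDefinition("absent_pair", frozenset({inside, outside}))]


def rarefaction_benchmark(seed: int, n_loci: int = 40, n_taxa: int = 10,
                          locus_length: int = 450, draws: int = 20,
                          bootstrap_replicates: int = 100) -> dict:
    """The scaled rarefaction sweep on homogeneous simulated loci."""
    tree, alignments = simulate_locus_alignments(seed, n_loci, n_taxa,
                                                 locus_length)
    clades = _tracked_clades(tree)
    cfg = RarefactionConfig(increment=5, draws_per_size=draws,
                            bootstrap_replicates=bootstrap_replicates,
                            master_seed=seed)
    curve = run_rarefaction(alignments, clades, cfg)
    series = curve.mean_support_series()
    sizes = list(curve.summary["pool_size"])
    plateau = plateau_detect(series, window=3, tolerance=2.0, sizes=sizes)
    full = curve.summary[curve.summary["pool_size"] == max(sizes)].iloc[0]
    first = curve.summary[curve.summary["pool_size"] == min(sizes)].iloc[0]
    return {
        "curve": curve,
        "sizes": sizes,
        "mean_support_first_pct": float(first["mean_support_mean"]),
        "mean_support_full_pct": float(full["mean_support_mean"]),
        "full_pool_sd": float(full["mean_support_std"]),
        "plateau_pool_size": plateau,
        "true_clade_full_pct": float(full["clade_true_cherry_mean"]),
        "absent_clade_max_pct": float(
            curve.summary["clade_absent_pair_mean"].max()),
    }
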