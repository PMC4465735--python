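"""Generator contracts: tree shapes, duplication/loss statistics, the
substitution process against closed forms, and read-shearing coverage."""

import math

import dendropy
import numpy as np
import pytest

from anchorpipe._seq import revcomp, stream
from anchorpipe.simulate import (GeneFamily, SimulationConfig,
                                 SubstitutionModel, coverage_profile,
                                 evolve_along_tree, evolve_sequences,
                                 shear_reads, simulate_dataset,
                                 simulate_gene_families, simulate_species_tree)

JC_MODEL = SubstitutionModel(
    exchangeabilities=(1, 1, 1, 1, 1, 1),
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    codon_rates=(1.0, 1.0, 1.0),
)


def jc_expected_p(d: float) -> float:
    return 0.75 * (1 - math.exp(-4 * d / 3))


class TestSpeciesTree:
    @pytest.mark.parametrize("n", [4, 29])
    def test_rooted_binary_shape(self, n):
        tree = simulate_species_tree(n, seed=1)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == n
        edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
        assert len(edges) == 2 * n - 2  # rooted binary tree
        assert all(e.length > 0 for e in edges)
        assert len({l.taxon.label for l in leaves}) == n

    def test_deterministic_given_seed(self):
        a = simulate_species_tree(8, seed=7).as_string(schema="newick")
        b = simulate_species_tree(8, seed=7).as_string(schema="newick")
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(3, seed=1)


class TestGeneFamilies:
    def test_no_duplication_means_single_copy(self):
        tree = simulate_species_tree(8, seed=2)
        cfg = SimulationConfig(n_taxa=8, n_loci=20, duplicate_fraction=0.0,
                               seed=2)
        fams = simulate_gene_families(tree, cfg)
        assert all(f.n_copies == 1 for f in fams)

    def test_forced_duplication_no_loss(self):
        tree = simulate_species_tree(8, seed=2)
        cfg = SimulationConfig(n_taxa=8, n_loci=20, duplicate_fraction=1.0,
                               loss_prob=0.0, secondary_duplication_prob=0.0,
                               seed=2)
        fams = simulate_gene_families(tree, cfg)
        for f in fams:
            assert f.n_copies == 2
            for c in f.copies:
                assert len(list(c.tree.leaf_node_iter())) == 8

    def test_copy_count_support(self):
        tree = simulate_species_tree(10, seed=3)
        cfg = SimulationConfig(n_taxa=10, n_loci=100, duplicate_fraction=0.6,
                               secondary_duplication_prob=0.5, seed=3)
        fams = simulate_gene_families(tree, cfg)
        assert all(1 <= f.n_copies <= 5 for f in fams)
        assert all(any(len(list(c.tree.leaf_node_iter())) >= 4
                       for c in f.copies) for f in fams)

    def test_duplicate_fraction_matches_loss_adjusted_expectation(self):
        """Observed >= 2-copy fraction within 3 binomial SD of the analytic
        expectation, with copy survival estimated by an independent
        simulation of the per-branch loss process."""
        n_taxa, dup, loss, n_loci = 10, 0.4, 0.05, 500
        tree = simulate_species_tree(n_taxa, seed=3)
        # independent survival estimate: a copy survives iff >= 4 leaves keep
        # every edge on their root path
        edges = []
        leaf_paths = []
        for i, leaf in enumerate(tree.leaf_node_iter()):
            path = []
            node = leaf
            while node.parent_node is not None:
                path.append(id(node))
                node = node.parent_node
            leaf_paths.append(path)
        r = np.random.default_rng(99)
        surv = 0
        reps = 4000
        all_edge_ids = sorted({e for p in leaf_paths for e in p})
        for _ in range(reps):
            lost = {e for e in all_edge_ids if r.random() < loss}
            kept = sum(1 for p in leaf_paths if not (set(p) & lost))
            surv += kept >= 4
        s = surv / reps
        # families are resampled until >= 1 copy survives:
        p2 = dup * s * s / (1 - (1 - s) ** 2)
        cfg = SimulationConfig(n_taxa=n_taxa, n_loci=n_loci,
                               duplicate_fraction=dup, loss_prob=loss,
                               secondary_duplication_prob=0.0, seed=3)
        fams = simulate_gene_families(tree, cfg)
        obs = sum(f.n_copies >= 2 for f in fams) / n_loci
        sd = math.sqrt(p2 * (1 - p2) / n_loci)
        assert abs(obs - p2) < 3 * sd + 1e-9


class TestEvolution:
    def _two_taxon_tree(self, d1, d2):
        t = dendropy.Tree.get(data=f"(A:{d1},B:{d2});", schema="newick")
        return t

    def test_zero_branch_lengths_reproduce_root(self):
        tree = self._two_taxon_tree(0.0, 0.0)
        rng = stream(1, "x")
        root = rng.integers(0, 4, 300).astype(np.uint8)
        leaves = evolve_along_tree(tree, root, JC_MODEL, rng)
        assert (leaves["A"] == root).all() and (leaves["B"] == root).all()

    def test_jc_pdistance_matches_closed_form(self):
        """Two taxa at total distance d: observed p-distance within 3
        binomial SD of (3/4)(1 - e^(-4d/3))."""
        d = 0.3
        L = 3000
        tree = self._two_taxon_tree(d / 2, d / 2)
        rng = stream(5, "jc")
        root = rng.integers(0, 4, L).astype(np.uint8)
        leaves = evolve_along_tree(tree, root, JC_MODEL, rng)
        p_obs = float((leaves["A"] != leaves["B"]).mean())
        p_exp = jc_expected_p(d)
        sd = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * sd

    def test_third_positions_most_variable(self):
        """With multipliers (0.3, 0.2, 1.0) third positions carry the
        largest share of differing sites, echoing coding-locus behaviour."""
        model = SubstitutionModel(codon_rates=(0.3, 0.2, 1.0))
        tree = self._two_taxon_tree(0.15, 0.15)
        counts = np.zeros(3)
        for rep in range(50):
            rng = stream(rep, "rank")
            root = rng.choice(4, size=900,
                              p=np.array(model.base_freqs)
                              / sum(model.base_freqs)).astype(np.uint8)
            leaves = evolve_along_tree(tree, root, model, rng)
            diff = leaves["A"] != leaves["B"]
            for p in range(3):
                counts[p] += diff[p::3].sum()
        assert counts[2] > counts[0] > counts[1]

    def test_no_internal_stops_in_frame(self):
        cfg = SimulationConfig(n_taxa=6, n_loci=3, duplicate_fraction=1.0,
                               loss_prob=0.0, locus_length=300, seed=4)
        tree = simulate_species_tree(6, seed=4)
        fams = simulate_gene_families(tree, cfg)
        for fam in fams:
            evolve_sequences(fam, cfg)
            for seq in fam.sequences.values():
                codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
                assert not set(codons) & {"TAA", "TAG", "TGA"}

    def test_zero_length_locus_rejected(self):
        tree = simulate_species_tree(4, seed=1)
        cfg = SimulationConfig(n_taxa=4, n_loci=1, seed=1)
        fam = GeneFamily("L1", 0, simulate_gene_families(tree, cfg)[0].copies)
        with pytest.raises(ValueError):
            evolve_sequences(fam, cfg)


class TestShearing:
    def _config(self, **kw):
        base = dict(n_taxa=4, n_loci=1, locus_length=1200, read_length=100,
                    target_coverage=30.0, flank_decay=0.0, error_rate=0.0,
                    seed=8)
        base.update(kw)
        return SimulationConfig(**base)

    def _sequence(self, L=1200):
        r = np.random.default_rng(0)
        return "".join("ACGT"[i] for i in r.integers(0, 4, L))

    def test_flat_profile_mean_depth_near_target(self):
        """Poisson coverage oracle: with efficiency 1 and no flank decay the
        empirical mean depth is within 10 % of the target (5 replicates)."""
        cfg = self._config()
        seq = self._sequence()
        depths = []
        for i in range(5):
            rs = shear_reads(seq, f"L{i}", 0, "sp01", cfg)
            depth = np.zeros(len(seq))
            for rid, (_, _, _, start) in rs.truth.items():
                depth[start:start + cfg.read_length] += 1
            depths.append(depth.mean())
        assert abs(np.mean(depths) - cfg.target_coverage) < 0.1 * cfg.target_coverage

    def test_efficiency_scales_read_count(self):
        seq = self._sequence()
        n_hi = sum(len(shear_reads(seq, f"L{i}", 0, "sp01",
                                   self._config()).reads) for i in range(5))
        n_lo = sum(len(shear_reads(seq, f"L{i}", 0, "sp01",
                                   self._config(per_species_efficiency=0.1),
                                   ).reads) for i in range(5))
        # both are Poisson sums; 10 % scaling within 3 SD
        expected = 0.1 * n_hi
        sd = math.sqrt(expected + 0.01 * n_hi)
        assert abs(n_lo - expected) < 3 * sd

    def test_error_free_reads_are_exact_substrings(self):
        cfg = self._config(error_rate=0.0)
        seq = self._sequence()
        rs = shear_reads(seq, "L1", 0, "sp01", cfg)
        assert rs.reads
        for read in rs.reads:
            assert read.bases in seq or revcomp(read.bases) in seq

    def test_truth_starts_inside_source(self):
        cfg = self._config()
        seq = self._sequence()
        rs = shear_reads(seq, "L1", 0, "sp01", cfg)
        ids = [r.id for r in rs.reads]
        assert sorted(ids) == sorted(rs.truth)  # truth map complete, no dupes
        for _, (_, _, _, start) in rs.truth.items():
            assert 0 <= start <= len(seq) - cfg.read_length

    def test_trapezoid_profile_shape(self):
        cfg = self._config(flank_decay=0.005, locus_length=600,
                           probe_length=120)
        prof = coverage_profile(600, cfg)
        core = slice((600 - 120) // 2, (600 - 120) // 2 + 120)
        assert (prof[core] == 1.0).all()
        assert prof[0] < prof[100] <= 1.0


class TestDeterminism:
    def test_identical_configs_are_byte_identical(self):
        cfg = SimulationConfig(n_taxa=5, n_loci=3, locus_length=450, seed=42)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.references == b.references
        for ind in a.reads_by_individual:
            ra = [(r.id, r.bases) for r in a.reads_by_individual[ind].reads]
            rb = [(r.id, r.bases) for r in b.reads_by_individual[ind].reads]
            assert ra == rb
            assert a.reads_by_individual[ind].truth == b.reads_by_individual[ind].truth

    def test_adding_loci_preserves_earlier_loci(self):
        """Per-locus seed streams: growing the locus count never changes the
        sequences of loci already simulated."""
        small = simulate_dataset(SimulationConfig(
            n_taxa=5, n_loci=2, locus_length=450, seed=42))
        big = simulate_dataset(SimulationConfig(
            n_taxa=5, n_loci=4, locus_length=450, seed=42))
        for locus in small.references:
            assert small.references[locus] == big.references[locus]

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_taxa=5, n_loci=3, seed=9,
                               per_species_efficiency={"sp05": 0.15})
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestWriters:
    def test_reads_fasta_fastq_roundtrip(self, tmp_path):
        from anchorpipe.assembly import read_reads
        from anchorpipe.simulate import (simulate_dataset, write_reads_fasta,
                                         write_reads_fastq, write_truth_table,
                                         write_references_fasta,
                                         write_gene_trees)
        ds = simulate_dataset(SimulationConfig(
            n_taxa=4, n_loci=2, locus_length=450, seed=77))
        rs = ds.reads_by_individual["sp01"]
        fa, fq = tmp_path / "r.fasta", tmp_path / "r.fastq"
        write_reads_fasta(rs, fa)
        write_reads_fastq(rs, fq)
        for path in (fa, fq):
            back = read_reads(path)
            assert [(r.id, r.bases) for r in back] == \
                [(r.id, r.bases) for r in rs.reads]
        truth = tmp_path / "truth.tsv"
        write_truth_table(ds, truth)
        lines = truth.read_text().splitlines()
        assert lines[0] == "read_id\tlocus\tcopy\tindividual\tstart"
        assert len(lines) - 1 == sum(
            len(r.truth) for r in ds.reads_by_individual.values())
        write_references_fasta(ds.references, tmp_path / "refs.fasta")
        write_gene_trees(ds.families, tmp_path / "trees.nwk")
        assert (tmp_path / "trees.nwk").read_text().count("(") >= 2
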