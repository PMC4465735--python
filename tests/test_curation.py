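"""Curation contracts: aligner behaviour, the filter/trim rule traces,
outlier screens with planted intruders, frame enforcement, idempotence, and
provenance replay."""

import math

import dendropy
import numpy as np
import pytest

from anchorpipe._seq import stream
from anchorpipe.curation import (align_set, curate_alignment,
                                 enforce_reading_frame, filter_length,
                                 filter_missing_species, flag_divergent_taxa,
                                 flag_long_branch_taxa, replay_log, trim_ends)
from anchorpipe.msa import Msa
from anchorpipe.simulate import SubstitutionModel, evolve_along_tree

UNIFORM = SubstitutionModel(exchangeabilities=(1,) * 6,
                            base_freqs=(0.25,) * 4, codon_rates=(1.0,) * 3)


def _star_tree(branches: dict) -> dendropy.Tree:
    newick = "(" + ",".join(f"{t}:{l}" for t, l in branches.items()) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def _evolved_alignment(branches: dict, L=300, seed=0, orf=False) -> Msa:
    tree = _star_tree(branches)
    rng = stream(seed, "curation")
    root = rng.integers(0, 4, L).astype(np.uint8)
    if orf:  # resample frame-0 stop codons in the root
        stops = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}
        for c in range(0, L - 2, 3):
            while tuple(root[c:c + 3]) in stops:
                root[c:c + 3] = rng.integers(0, 4, 3)
    leaves = evolve_along_tree(tree, root, UNIFORM, rng)
    return Msa.from_dict({t: "".join("ACGT"[c] for c in v)
                          for t, v in leaves.items()})


class TestAligner:
    def test_identical_sequences_align_without_gaps(self):
        seqs = {f"t{i}": "ACGTACGTAAAC" for i in range(4)}
        msa = align_set(seqs)
        assert msa.length == 12
        assert not (msa.matrix == "-").any()

    def test_three_bp_deletion_gives_one_gap_run(self):
        base = "ATGGCCAAATTTGGGCCCAAATTTGGG"
        deleted = base[:9] + base[12:]
        seqs = {"a": base, "b": base, "c": base, "d": deleted}
        msa = align_set(seqs)
        row = msa.row("d")
        assert row.count("-") == 3
        gap_start = row.index("-")
        assert row[gap_start:gap_start + 3] == "---"
        assert "-" not in row[gap_start + 3:]

    def test_fewer_than_four_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_set({"a": "ACGT", "b": "ACGT"})

    def test_backend_recorded(self):
        msa = align_set({f"t{i}": "ACGTAACCGGTT" for i in range(4)})
        assert msa.meta["aligner"] == "internal"

    def test_internal_agrees_with_mafft_on_clean_orthologs(self):
        """Backend-agreement oracle: on indel-free sequences at ~5 %
        divergence the internal star aligner and mafft produce matrices
        differing in < 5 % of columns (10 loci)."""
        import shutil
        if shutil.which("mafft") is None:
            pytest.skip("mafft not on PATH")
        diffs = []
        for seed in range(10):
            msa_data = _evolved_alignment(
                {f"t{i}": 0.025 for i in range(6)}, L=420, seed=seed)
            seqs = msa_data.to_dict()
            internal = align_set(seqs, "internal")
            external = align_set(seqs, "mafft")
            if internal.length != external.length:
                diffs.append(1.0)
                continue
            same = np.mean([
                (internal.matrix[internal.taxa.index(t)]
                 == external.matrix[external.taxa.index(t)]).mean()
                for t in internal.taxa])
            diffs.append(1 - same)
        assert np.mean(diffs) < 0.05


class TestFilters:
    def test_missing_species_boundary(self):
        expected = [f"t{i}" for i in range(29)]
        present27 = Msa.from_dict({t: "ACGT" for t in expected[:27]})
        present26 = Msa.from_dict({t: "ACGT" for t in expected[:26]})
        assert filter_missing_species(present27, expected)
        assert not filter_missing_species(present26, expected)

    def test_recheck_after_taxon_removal(self):
        expected = [f"t{i}" for i in range(29)]
        msa = Msa.from_dict({t: "ACGT" for t in expected[:27]})
        edited = msa.drop_taxa(["t0"])
        assert not filter_missing_species(edited, expected)

    def test_length_boundaries(self):
        keep = Msa.from_dict({"a": "A" * 450, "b": "A" * 300 + "-" * 150})
        assert filter_length(keep)  # shortest ungapped exactly 150
        short = Msa.from_dict({"a": "A" * 449, "b": "A" * 449})
        assert not filter_length(short)
        long_thin = Msa.from_dict({"a": "A" * 1605,
                                   "b": "A" * 149 + "-" * 1456})
        assert not filter_length(long_thin)  # shortest row 149 < 150


class TestTrimEnds:
    def test_clean_alignment_untouched(self):
        msa = Msa.from_dict({f"t{i}": "ACGTACGT" for i in range(4)})
        trimmed, left, right = trim_ends(msa)
        assert (left, right) == (0, 0)
        assert trimmed == msa

    def test_majority_missing_flank_removed(self):
        """Ten taxa; first 30 columns missing in six of them -> all 30
        removed (6/10 >= 1/2)."""
        rows = {}
        for i in range(10):
            prefix = "-" * 30 if i < 6 else "A" * 30
            rows[f"t{i:02d}"] = prefix + "C" * 70
        trimmed, left, right = trim_ends(Msa.from_dict(rows))
        assert (left, right) == (30, 0)
        assert trimmed.length == 70

    def test_rule_trace_stops_below_half(self):
        """Flank missing fractions 0.6, 0.45, 0.2: exactly one column goes
        (trigger 1/3 engages; 0.45 < 1/2 stops the trim)."""
        cols = [0.6, 0.45, 0.2]
        n = 20
        rows = {f"t{i:02d}": "" for i in range(n)}
        for frac in cols:
            k = int(frac * n)
            for i in range(n):
                rows[f"t{i:02d}"] += "-" if i < k else "A"
        for i in range(n):
            rows[f"t{i:02d}"] += "G" * 10
        trimmed, left, right = trim_ends(Msa.from_dict(rows))
        assert (left, right) == (1, 0)

    def test_interior_columns_never_touched(self):
        rows = {f"t{i}": "A" + "-" * 5 + "A" for i in range(4)}
        trimmed, left, right = trim_ends(Msa.from_dict(rows))
        assert (left, right) == (0, 0)
        assert trimmed.length == 7


class TestDivergenceScreen:
    def test_equal_distances_flag_nothing(self):
        msa = _evolved_alignment({f"t{i}": 0.02 for i in range(8)}, seed=1)
        report, edited = flag_divergent_taxa(msa)
        assert report.flagged == []
        assert edited == msa

    def test_planted_intruder_flagged(self):
        """A paralog intruder at ~3x the ortholog divergence among ten taxa
        is flagged at z = 3.5 (plant-and-recover)."""
        found = 0
        for seed in range(20):
            branches = {f"t{i}": 0.02 for i in range(9)}
            branches["intruder"] = 0.02 * 6
            msa = _evolved_alignment(branches, L=450, seed=seed)
            report, edited = flag_divergent_taxa(msa, 3.5)
            found += "intruder" in report.flagged
        assert found >= 18

    def test_null_false_flag_rate(self):
        """Clean ortholog sets: false-flag rate <= 5 % over 100 loci."""
        flags = 0
        for seed in range(100):
            msa = _evolved_alignment({f"t{i}": 0.02 for i in range(8)},
                                     L=300, seed=1000 + seed)
            report, _ = flag_divergent_taxa(msa, 3.5)
            flags += bool(report.flagged)
        assert flags <= 5

    def test_fewer_than_five_taxa_disables_flagging(self):
        branches = {"a": 0.01, "b": 0.01, "c": 0.01, "d": 0.3}
        msa = _evolved_alignment(branches, seed=2)
        report, edited = flag_divergent_taxa(msa)
        assert report.flagged == []


class TestLongBranchScreen:
    def test_star_tree_flags_nothing(self):
        tree = _star_tree({f"t{i}": 0.05 for i in range(6)})
        assert flag_long_branch_taxa(tree, 5.0) == []

    def test_ten_x_branch_flagged(self):
        branches = {f"t{i}": 0.05 for i in range(6)}
        branches["bad"] = 0.5
        assert flag_long_branch_taxa(_star_tree(branches), 5.0) == ["bad"]

    def test_missing_branch_length_is_an_error(self):
        tree = dendropy.Tree.get(data="(a:1,b:1,(c,d):1);", schema="newick")
        with pytest.raises(ValueError):
            flag_long_branch_taxa(tree, 5.0)

    def test_planted_paralog_detected_in_nj_gene_trees(self):
        """Plant-and-recover through the tree backend: an intruder at >= 3x
        the ortholog depth is flagged in >= 90 % of 50 replicates."""
        from anchorpipe.treesupport import distance_matrix, nj_tree
        found = 0
        for seed in range(50):
            branches = {f"t{i}": 0.02 for i in range(7)}
            branches["intruder"] = 0.25
            msa = _evolved_alignment(branches, L=300, seed=3000 + seed)
            tree = nj_tree(distance_matrix(msa, "JC69"))
            flagged = flag_long_branch_taxa(tree, 5.0, min_length=0.05)
            found += "intruder" in flagged
        assert found >= 45


class TestReadingFrame:
    def _orf(self, rng, n_codons):
        codons = []
        while len(codons) < n_codons:
            c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        return "".join(codons)

    def test_clean_orf_keeps_frame_zero(self, rng):
        seq = self._orf(rng, 60)
        msa = Msa.from_dict({f"t{i}": seq for i in range(4)})
        cur = enforce_reading_frame(msa)
        assert cur.frame_offset == 0
        assert cur.msa.length == 180

    def test_prepended_column_shifts_frame(self, rng):
        seq = self._orf(rng, 60)
        msa = Msa.from_dict({f"t{i}": "G" + seq for i in range(4)})
        cur = enforce_reading_frame(msa)
        assert cur.frame_offset == 1
        assert cur.msa.length % 3 == 0

    def test_random_sequence_flagged_noncoding(self, rng):
        """Multinomial expectation: uniform random DNA carries ~3/64 stops
        per codon in every frame, so every frame fails and the locus is
        flagged non-coding."""
        L = 3000
        rows = {f"t{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, L))
                for i in range(6)}
        msa = Msa.from_dict(rows)
        cur = enforce_reading_frame(msa)
        assert cur.frame_offset is None
        from anchorpipe.curation import _count_stops
        n_codons = L // 3
        expect = 3 / 64 * n_codons
        sd = math.sqrt(n_codons * (3 / 64) * (61 / 64) / 6)
        for off in (0, 1, 2):
            assert abs(_count_stops(msa, off) - expect) < 4 * sd


class TestPipeline:
    def _clean_curated(self, seed=0):
        msa = _evolved_alignment({f"t{i:02d}": 0.02 for i in range(8)},
                                 L=480, seed=seed, orf=True)
        taxa = sorted(msa.taxa)
        cur, log = curate_alignment(msa, taxa, locus_id="L1")
        return msa, cur, log

    def test_clean_locus_passes_through(self):
        raw, cur, log = self._clean_curated()
        assert cur is not None
        assert cur.frame_offset in (0, 1, 2)
        assert cur.msa.length % 3 == 0

    def test_idempotence(self):
        _, cur, _ = self._clean_curated(seed=5)
        again, log2 = curate_alignment(cur.msa, cur.msa.taxa, locus_id="L1")
        assert again is not None
        assert again.msa == cur.msa
        assert [e for e in log2 if e["op"].startswith(("trim", "remove"))] == []

    def test_replay_log_reproduces_curated_matrix(self):
        branches = {f"t{i:02d}": 0.02 for i in range(9)}
        branches["zz_intruder"] = 0.3
        raw = _evolved_alignment(branches, L=480, seed=7, orf=True)
        # dirty flanks: first 6 columns missing for most taxa
        m = raw.matrix.copy()
        m[:7, :6] = "-"
        raw = Msa(raw.taxa, m)
        cur, log = curate_alignment(raw, raw.taxa, locus_id="L1")
        assert cur is not None
        assert any(e["op"] == "remove_taxon" for e in log)
        assert replay_log(raw, log) == cur.msa

    def test_discard_is_logged(self):
        msa = _evolved_alignment({f"t{i}": 0.02 for i in range(8)},
                                 L=200, seed=9)
        cur, log = curate_alignment(msa, sorted(msa.taxa))
        assert cur is None
        assert log[-1] == {"op": "discard", "reason": "length"}
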