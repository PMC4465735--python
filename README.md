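# anchorpipe

Locus processing and analysis for anchored hybrid enrichment (AHE)
phylogenomics: from capture reads to curated locus alignments, supermatrix
statistics, and rarefaction curves of phylogenetic node support.

## The problem

Hybrid enrichment captures *all* homologues of a targeted locus.  In
teleost fishes, where a whole-genome duplication predates every living
lineage, that means a capture experiment routinely returns two or more
paralogous copies per locus — and aligning paralogs as if they were
orthologs distorts species-tree inference.  `anchorpipe` implements the
processing chain that deals with this:

1. **Assembly** — reads are mapped to locus references with
   divergence-tolerant spaced k-mers; the best-matching read seeds a stack
   in which reads must overlap by ≥ 20 bp at ≥ 95 % identity; the
   majority-rule consensus (2× minimum depth) is grown outward over
   repeated passes through the read pool.  Because paralogous reads fail
   the 95 % rule, repeated assembly rounds on the shrinking pool recover
   one consensus per gene copy; a locus is "captured" when a contig
   exceeds 350 bp.
2. **Paralog picker** — per-individual consensus sequences are partitioned
   into homolog sets against a reference individual (the one with the best
   capture efficiency): set *k* is the reference's *k*-th sequence plus
   each individual's best-aligning unassigned sequence, iterated until the
   references are used up.
3. **Alignment curation** — each homolog set is aligned and filtered:
   ≤ 2 missing species, terminal-missingness trimming (trigger 1/3, stop
   1/2), ≥ 450 bp with the shortest ungapped row ≥ 150 bp, robust
   divergence and long-branch outlier removal, and reading-frame
   enforcement; every edit is logged and replayable.
4. **Supermatrix** — concatenation with per-locus spans and codon map;
   constant/variable site accounting by codon position; three
   matrix-completeness definitions; GC/GC-skew; partition schemes (by
   gene, by codon, third positions removed/only, amino-acid translation);
   taxon reduction.
5. **Tree support & rarefaction** — a distance + neighbor-joining backend
   with nonparametric bootstrap (pluggable with an external ML tool)
   feeds rarefaction curves: random locus pools in increments of five,
   twenty draws per pool size, tracking average bipartition support,
   named-clade support, and node counts above 50/70/90 %.

A synthetic-data generator (species tree → root duplication with
lineage-specific loss → GTR sequences with codon-position rates →
probe-centred reads with known truth) makes the entire chain testable
without any sequence download.

## Worked example

Simulate a small capture experiment with duplicated loci, assemble it, and
pick homolog sets:

```python
from anchorpipe.workflows import paralog_separation

stats = paralog_separation(seed=202, n_loci=50, n_taxa=6)
print(stats)
```

prints (numbers from this exact call):

```
{'two_contig_rate_pct': 99.33333333333333,
 'two_contig_rate_evaluable_pct': 99.66442953020133, 'n_evaluable': 298,
 'assignment_accuracy_pct': 99.59514170040485, 'n_assigned': 494,
 'n_pairs': 300, 'reference_individual': 'sp03'}
```

i.e. on 50 duplicated 600 bp loci at 10× coverage and 1 % read error, 298
of the 300 (individual, locus) pairs had both gene copies tiled by reads
without a coverage break, 99.7 % of those yielded exactly two >350 bp
contigs — one per copy — and the picker assigned 99.6 % of the 494
non-reference contigs to the homolog set of their true copy.

The matrix-level summaries run directly on bundled published-scale tables:

```python
from anchorpipe.datasets import example_site_counts
from anchorpipe.supermatrix import SiteVariabilityTable

t = SiteVariabilityTable.from_counts(example_site_counts())
print(round(t.percent_variable), round(t.variable_share_of_position(3)))
# 43 67  — 43 % of the 82,782 sites variable; 67 % of variable sites at codon position 3
```

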