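# Methods

`anchorpipe` re-implements, as a tested library, the locus-processing chain
used in anchored hybrid enrichment (AHE) phylogenomics of teleost fishes:
capture reads are assembled per individual into locus consensus sequences,
gene copies created by the ancient teleost whole-genome duplication (WGD)
are sorted into homolog sets, homolog sets are aligned and curated into
supermatrix-ready locus alignments, and node support is tracked along locus
rarefaction curves.  Because the real capture data are not required, every
stage is exercised against a synthetic-data generator that records complete
truth (which read came from which copy of which locus at which coordinate).

## Synthetic data model

The generator draws a rooted, ultrametric birth–death species tree (pure
birth by default) and rescales it to a root-to-tip height in expected
substitutions per site (`tree_height`, default 0.04).  With the default
codon-position rate multipliers (see below) this yields pairwise ortholog
divergences of at most ~4–5 %, the regime in which the assembler's 95 %
stacking rule treats conspecific reads as compatible.

**Duplication and loss.**  A fraction `duplicate_fraction` (default 0.4) of
loci receives a duplication at the root of the species tree — the topology
produced by a WGD that predates all sampled taxa.  Additional duplications
occur with probability `secondary_duplication_prob` (default 0.35, copy
count capped at 5), so the per-locus homolog-set count has support 1–5 with
~60 % single-copy loci and ~1.6 copies per locus, matching the shape of the
published per-locus homolog-set distribution.  Each copy then loses whole
subtrees: every branch independently drops the copy with probability
`loss_prob` (default 0.05), and copies retaining fewer than four taxa are
discarded.  Families are redrawn (bounded retries) if no copy retains four
taxa, so every simulated family is assemblable.  Each surviving WGD copy
carries a stem branch of `paralog_depth` (default 0.25) expected
substitutions per site, putting inter-copy divergence near 20 % — far above
ortholog divergence, as required for copy separation to be well-posed.

**Sequences.**  A root sequence is drawn from the model's base frequencies
with frame-0 stop codons rejected; it evolves down every copy under a GTR
process (exchangeabilities and frequencies are configurable; transition
matrices come from the matrix exponential of the normalised rate matrix).
Codon positions 1/2/3 receive rate multipliers (default 0.3/0.2/1.0), so
third positions carry most of the variable sites, as in coding capture
loci.  Codon columns that produce an in-frame stop in any leaf are
re-evolved (bounded rejection), keeping all emitted sequences in open
reading frame.  Indels, selection and recombination are deliberately out of
scope: the assembler's contract is substitution-tolerant ungapped stacking,
and the curation layer is tested on terminal-missingness patterns that
arise from coverage decay rather than from indel evolution.

**Reads.**  Coverage follows a trapezoid: flat over a central probe-sized
window (`probe_length`, default 120 bp) and declining linearly in the
flanks at `flank_decay` per bp — the qualitative probe-centred coverage
shape of hybrid capture.  Read count is Poisson with mean
`target_coverage x efficiency x (profile mass / read length)`; start
positions are drawn proportional to the profile; strands are random;
substitution errors occur per base at `error_rate` (default 0.01).
Species-specific capture efficiency is a multiplier in (0, 1]; setting one
species low (e.g. 0.15) reproduces the familiar pattern of a single
poorly-captured lineage.  What the generator does *not* emulate — indels,
quality-correlated errors, chimeric fragments, contamination — bounds what
the passing tests show: they certify the algorithms against the stated
generative model, not against every artefact of real libraries.

**Seeding.**  One master seed; every (locus, stage) pair derives its own
stream by hashing, so adding loci or stages never perturbs earlier draws,
and identical configurations are byte-identical.

## Assembly

Per individual, reads are mapped to each locus reference by spaced k-mers:
a read maps if it shares at least one spaced key (either strand) with the
reference.  The default mask has weight 12 over a 23 bp span (care
positions every other base).  Spreading the care positions decorrelates
adjacent windows, which is what lets seeds survive deep divergence; weight
12 keeps the keyspace (4^12) large enough that unrelated reads collide with
a reference only ~0.3 % of the time.  (A weight-8 mask, whatever its span,
cannot achieve a low random-mapping rate against ~600 bp references: with a
65 536-key space the expected number of shared keys between a random read
and the reference is already ~0.7.)

The best-matching read (highest ungapped identity at its best placement;
ties to the longer read, then the lexicographically smaller id) anchors a
stack; it is first flipped to the reference strand, so contigs are reported
in reference orientation.  Because spaced keys collide by chance, an anchor
must also reach 0.6 identity against the reference — genuine copies place
at >= ~0.75 even at paralog divergence, unrelated reads at ~0.3, and
anchoring on a collision would grow a contig belonging to another locus.
Reads join the stack only if they overlap the current consensus by at
least 20 comparable bases at >= 95 % identity, substitutions only — no
gapped read alignment.  Placement maximises the ungapped alignment score
(matches − mismatches) rather than identity; this matters in both
directions: a paralogous read occasionally shows a short, locally
conserved >= 95 % overlap, but its score-maximal placement is the long
homologous one, which correctly fails the identity threshold, while a true
short tip overlap still outscores any random long overlap.  Seed stacks
place reads best-score-first so divergent reads are tested against a long
consensus rather than a bare 100 bp anchor.  The majority-rule consensus
resolves ties toward the previous consensus base when it is among the
leaders, otherwise an IUPAC ambiguity code.  Extension then makes repeated
passes, recruiting candidate reads that share a spaced key with the
current consensus (plus all reference-mapped reads), adding qualifying
reads and re-consensing until a pass adds nothing; a final consistency
sweep evicts any read whose identity to the finished consensus falls below
the stacking threshold, returning it to the pool.  Consumed reads leave
the pool.  Rounds repeat per locus (cap 5, the maximum observed
homolog-set count) while they keep producing contigs of >= 20 bp;
divergent paralogous copies fail the 95 % rule against the first round's
stack and therefore seed later rounds.  Final contigs trim terminal
columns below 2x depth and mark interior sub-2x columns `N`; a locus
counts as captured when any round's contig exceeds 350 bp.

Two residual imperfections are inherent rather than implementation
artefacts, and the truth-scored benchmarks account for them: Poisson
shearing occasionally (~1 % of copies at 10x/600 bp) leaves a read-start
gap wider than read length minus the minimum overlap, which no assembler
can bridge, so separation benchmarks score such pairs separately; and when
the realized local inter-copy divergence dips below the 5 % stacking
tolerance over a window, reads genuinely bridge the two copies there and a
locally consistent chimeric patchwork can form (~0.3 % of pairs under the
default divergence regime).

## Paralog picker

A reference individual is chosen by capture efficiency (most loci captured;
ties by total contig length, then name).  For each locus, homolog set *k*
is the reference individual's *k*-th consensus (assembler round order) plus,
for every other individual, its highest-scoring not-yet-assigned sequence;
assigned sequences are removed and the cycle repeats.  The similarity score
is the identity count of the best local alignment (match +1, mismatch −1,
gap open −4, extend −1) divided by the length of the shorter sequence.
Normalising by the shorter length rather than by the aligned block makes
the score coverage-sensitive: identical sequences score 1.0, a 10 %-mutated
copy ~0.9, and unrelated sequences ~0.1, because only a short block aligns.
(Identity over the aligned block alone is uninformative here — optimal
local blocks are short and match-rich, so even unrelated sequences score
~0.9 by that definition.)  Sequences scoring below 0.5 against every
remaining reference are reported unassigned rather than forced into a set;
surplus copies beyond the reference's count likewise remain unassigned.  A
globally optimal one-to-one matching per individual (Hungarian algorithm)
is available behind a flag for comparison; on unambiguous inputs it agrees
with the greedy rule.

## Alignment curation

Homolog sets are aligned by an internal star aligner (pairwise affine-gap
global alignments with free end gaps, merged around the longest sequence;
adequate because capture loci are nearly indel-free in their cores) or by
mafft when requested; the backend used is recorded.  The fixed filter order
is: missing-species filter → end trimming → length filter → divergence and
long-branch screens → missing-species re-check → reading-frame enforcement.

* **Missing species**: discard when more than two expected taxa are absent;
  re-checked after any taxon removal.
* **End trimming**: at each end, if the terminal column's missing fraction
  exceeds 1/3, columns are removed while their missing fraction is at least
  1/2; interior columns are never touched.  Both fractions are config keys;
  gaps count as missing by default (switchable).
* **Length**: keep only alignments of >= 450 columns whose shortest
  ungapped row is >= 150 bp.
* **Divergence screen**: a taxon is removed when its median pairwise
  p-distance exceeds the across-taxa median by more than 3.5 robust
  (MAD-based) standard deviations, one-sided.  The scale has a floor of
  0.01 substitutions/site: with MAD alone, correlated sampling noise on
  short clean alignments produces ~10 % false flags, and the floor brings
  the null false-flag rate under 5 % while leaving 3x-divergence intruders
  detected essentially always.
* **Long-branch screen**: terminal branches of the locus NJ tree longer
  than 5x the median terminal branch *and* longer than 0.05
  substitutions/site are removed.  The absolute floor matters because on
  shallow trees the median terminal branch can be ~0.001, so a pure ratio
  rule flags legitimate lone deep lineages.
* **Reading frame**: the frame offset (0/1/2) minimising in-frame stop
  codons is chosen and partial codons trimmed so the length is divisible by
  3.  If every frame averages more than one stop per taxon the locus is
  flagged non-coding and passed through with the frame undetermined
  (uniform random DNA carries 3/64 stops per codon in every frame, so the
  flag fires reliably on non-coding input).

Every trim and removal is logged; replaying the log on the raw alignment
reproduces the curated matrix exactly, and curation is idempotent.

## Supermatrix

Curated in-frame loci are concatenated over a shared taxon universe; taxa
absent from a locus are padded with `?` across its span.  Spans are 0-based
half-open internally and exported 1-based inclusive (partition-file
convention).  A column is *variable* iff at least two distinct unambiguous
bases occur among its non-missing, non-gap cells — ambiguity codes alone
never create variability, and all-missing columns count as constant; the
accounting is reported for the whole matrix and per codon position, with
row sums consistent by construction.  Completeness has three definitions:
counting missing loci plus leading/trailing gap runs; additionally counting
interior gaps (always <= the former); and mean per-species locus presence.
GC content is computed either over unambiguous bases or with IUPAC codes
contributing fractionally; G−C skew uses unambiguous counts; third-position
GC is reported per species.  Partition schemes: by gene, by codon position,
third positions removed, third positions only, and a standard-code amino
acid translation in which any codon containing a gap, missing cell,
ambiguity, or in-frame stop translates to missing.  Taxon reduction drops
rows and never re-aligns columns.

## Tree support

The internal inference backend is distance + neighbor joining (p, JC69 or
K2P distances; pairs sharing fewer than 100 comparable sites, or saturated
pairs, receive a flagged large distance).  Taxa are sorted before NJ so the
tree is a pure function of the distances; negative NJ branch lengths are
clamped to zero.  Nonparametric bootstrap resamples columns (or codon
triplets, on request) with replacement, infers a replicate tree, and maps
bipartition frequencies onto the best tree from the original alignment;
failed replicates are dropped, with more than 10 % failures an error.
"Node support" means internal-edge bipartition support; threshold counts
use strict inequality.  The backend is a callable, so an external ML
program can be plugged in; replicate trees from any source can be counted
against clade definitions (taxon-set monophyly, or the smallest split on
the best tree containing named taxa for MRCA-defined clades).  NJ-based
supports are methodologically parallel to, but not numerically comparable
with, ML bootstrap values; nothing here claims to match published support
figures, which would require the original supermatrix and an ML engine.

## Rarefaction

Locus pools of increasing size (increment 5, up to the full set, the full
set always included) are drawn 20 times each, uniformly without
replacement.  Each draw concatenates its loci, runs the bootstrap backend,
and records mean internal support, tracked-clade supports, and node counts
above 50/70/90 %.  Draw subsets are deterministic in (master seed, pool
size, draw index); the bootstrap seed is derived from the *subset* rather
than the draw index, so identical subsets give identical results — at the
full pool every draw coincides and the across-draw SD is exactly zero —
and results are cached per distinct subset.  Plateau detection reports the
smallest pool size after which every later mean deviates by less than a
tolerance (default 2 support points) from the running mean of its trailing
window (default 3 sizes, windows confined to the candidate's right); a
series that climbs faster than the tolerance to its end never plateaus.

## Problem sizes and numerical defaults

The synthetic benchmarks run at deliberately modest scale chosen to make
truth recovery statistically meaningful: 50 loci x 6 individuals for
assembly recovery and paralog separation (600 bp loci, uniform 10x
coverage, 1 % read error), 107 loci x 12 individuals for the homolog-set
tally, and 40 loci x 10 taxa (450 bp) with 20 draws per pool size and 100
bootstrap replicates for the rarefaction sweep.  Bootstrap replicates
default to 500 in `bootstrap_support` itself; the rarefaction configuration
uses 100, which sets the support granularity at 1 % while keeping a full
sweep to a few minutes.  Distance-tie behaviour, consensus tie rules,
flagged large distances (5.0) and the minimum comparable-site count (100)
are all stated above or in the API docstrings.

## Known limitations

The internal aligner is a star aligner: sufficient for near-indel-free
loci, not a general progressive MSA.  The picker's greedy rule is order-
dependent exactly where scores tie; with vanishing inter-paralog divergence
assignments become arbitrary (documented, not asserted).  The NJ backend
understates what an ML engine would recover from the same data, so
rarefaction curves should be read for their shape, not their absolute
values.  The generator omits indels; curation's gap handling is therefore
exercised mainly through constructed fixtures.
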