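# Methods

This note documents the statistical procedures, conventions and design
choices in `cistarget_compare`, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All in-memory intervals are 0-based half-open, the BED convention.  BED is
read and written verbatim; GFF3 (1-based closed on disk) is shifted to
`(start-1, end)` on read and back on write, so printed coordinates round-trip
exactly.  Sequences are restricted to {A, C, G, T, N} and upper-cased on
read; parsers fail loudly with the offending line number rather than
guessing.  The motif library is a small JSON dialect (IUPAC consensus
strings or position probability matrices with a log-odds threshold) because
the classical commercial motif databases cannot be redistributed; a
JASPAR-style PFM importer is provided for convenience.

## Peak annotation

A putative target is the gene nearest to a peak, where distance is the
edge-to-edge gap between the peak interval and the gene body (0 when they
overlap).  Gene-body distance rather than TSS distance is deliberate:
in sparsely annotated non-model genomes TSS calls are unreliable, and a
strand-agnostic gap is robust and symmetric.  Strand is ignored for
assignment; the reported relation ('upstream'/'downstream'/'overlapping')
refers to the peak's position relative to the gene in genome + orientation.
Exact ties are all reported, flagged `tie=True`; downstream set construction
deduplicates naturally.  The default assignment radius is
`max_distance_bp = 10000`; peaks with no gene inside it are counted in the
log and dropped.  The radius is a screening choice, not an estimate — at
the synthetic gene densities used here (one gene per ~5 kb) it is
effectively unbounded.

Replicates are reconciled conservatively by default: a peak survives only
if every replicate has an overlapping call (≥ `min_overlap_bp`, default 1),
and the merged peak is the intersection interval with the mean score and
the union of replicate ids.  A `union` mode merges extents instead for
sensitivity-oriented analyses.

## Ortholog mapping and set comparison

Species target sets are projected into a reference gene space by taking,
for each member with an ortholog entry, the union of its reference ids;
many-to-many relations therefore collapse to the union, and members without
entries are counted as unmapped.  The Venn partition over 2–4 sets is
exhaustive (all 2^k − 1 regions, empty ones reported as 0) and refuses to
mix id namespaces unless forced, which catches the common mistake of
partitioning an unmapped species set against a reference-space set.

Overlap significance uses the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(U, |A|, |B|), with
fold = k·U/(|A|·|B|).  The default universe U is the number of reference
genes with at least one ortholog entry — the population from which mapped
targets can actually be drawn.  A broader universe (e.g. all reference
genes) makes overlaps look more significant and should be set explicitly
when wanted.

## Category statistics

`category_proportions` divides by the full set size, so unannotated genes
dilute proportions — matching how category frequency bar charts are usually
drawn.  Pairwise fold over-representation between two sets is the ratio of
their proportions, accompanied by a two-sided Fisher exact p-value on the
2×2 annotated/not table; when the denominator proportion is 0 the fold is
flagged undefined (∞ or NaN) rather than silently clipped.  Set-vs-universe
enrichment is a per-category hypergeometric upper tail with
Benjamini–Hochberg step-up q-values across exactly the categories tested.
These p-values are supplementary: the fold is the primary comparative
statistic, and the hypergeometric test replaces an external web-service
annotation tool with an auditable in-package computation.

The differential-expression filter is unsigned
(max ratio in either direction ≥ `min_fold`, inclusive), with pseudocount
default 1.0 to tame zeros in count-like tables; rows that are 0/0 with
pseudocount 0 are skipped and counted.  The filter accepts any normalized
two-condition table; it does not model replicates or dispersion — it is a
threshold rule, not a DE test.

## Motif analysis

Consensus motifs match by per-position IUPAC set membership; a sequence 'N'
satisfies only the motif code 'N' (an unknown base is never evidence for a
site).  Matrix motifs are pseudocounted (0.01/cell), row-normalized and
scored as base-2 log-odds against a uniform background; the default
threshold is 80% of the motif's maximum achievable score, a conventional
permissive cutoff users should override with calibrated values when they
have them.  Reverse-strand hits are reported at forward coordinates of the
match start, and overlapping hits are all counted (no greedy masking) so
densities are comparable across motif lengths.

Fold-enrichment compares the foreground hit density (hits/kb over the
concatenated ChIP sequences, both strands) with the mean density over
`n_draws` (default 200) random background sets.  Each background set is
drawn fresh from the genome with the same multiset of lengths as the
foreground — length matching removes the dominant bias in density
comparisons — and rejects windows that intersect a gene body or contain N.
The empirical p-value uses the add-one rule (1 + #{draws ≥ fg})/(n + 1), so
it is never 0 and is uniform under the null.  Background draws exclude gene
bodies but not ChIP peaks themselves; with realistic peak fractions
(a few percent of non-coding space) the resulting attenuation of measured
folds is small, and the planted-recovery tests bound it at well under 20%.

The k-mer ranking (canonical form = lexicographic minimum of k-mer and its
reverse complement, background pseudo-frequency 0.5 occurrences) is a
deliberately simple over-representation screen, not a replacement for
EM/Gibbs de-novo discovery, which is out of scope.

Binding-site arrays collect every library motif's hits within
`window_bp` (default 500) of an anchor — the peak summit when recorded,
otherwise the interval midpoint — at signed offsets, and array comparison
partitions TFs into shared/A-only/B-only, pairing each shared TF's offsets
with the nearest counterpart.  The comparison is at TF-name level: two
different motif variants for the same factor (e.g. species-specific
versions of a MAD1 site) count as the same TF being present, which is the
biologically relevant statement.

## Synthetic data: what it emulates and what it does not

The generator builds two species' genomes with uniform base composition,
places genes sequentially with 3–5 kb spacers, plants one ChIP peak
(two replicates, ≥ 90% mutual overlap, jittered intervals) 100–800 bp from
each chosen target gene, and constructs an ortholog table so that exactly
`round(shared_target_fraction · n_peaks)` targets of each species map to
shared reference ids.  Key guarantees, each load-bearing for the end-to-end
tests:

* peaks are unambiguous — spacer geometry ensures no gene is nearer than
  the intended target, so nearest-gene recovery is exact;
* every target gene has an ortholog entry (`ortholog_coverage` thins only
  non-target genes), so Venn region counts equal the configured values
  exactly;
* category annotation is planted with exact counts per stratum
  (`round(rate·n)` genes without replacement, at `base_rate·fold` in shared
  targets and `base_rate` elsewhere), so the realised fold equals the
  configured fold up to rounding.  Per-gene Bernoulli annotation was
  rejected: at a few hundred genes per set the fold ratio estimator's
  sampling deviation (≈ 1.2 at fold 4) would swamp the quantity the
  generator is supposed to control;
* DE ratios are separated by construction (non-DE < 1.8, DE ≥ 2.25 on
  baselines ≥ 10), so the 2-fold filter recovers the planted set exactly
  for any pseudocount in [0, 1];
* motif instances are injected at Poisson-distributed counts at the
  configured densities, at non-colliding positions (an overwritten instance
  would silently lower the realised density).

Defaults are desk-scale renditions of a real two-species ChIP study: a
2.4 Mb genome per species (4 × 600 kb scaffolds), 300 genes, 60 targets,
shared fraction 0.2 (the "15–20% of targets shared" regime), ortholog
coverage 0.85, one planted 8-mer motif at 3/kb foreground vs 1/kb
background, a 4-fold wing-development category plant at base rate 0.05, and
2% of genes differentially expressed ≥ 2-fold.  Tests scale
sizes up or down from these (e.g. 400-target configs for category-fold
statistics at set sizes ≥ 200, 600 kb scaffolds for motif recovery) as
their statistic requires.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: realistic base composition and repeat
structure (an optional GC skew is out of scope; uniform composition makes
incidental motif rates analytically small), peak-width and signal-shape
distributions, fragmented or mis-assembled gene models, many-to-many
ortholog tangles at realistic rates, correlated categories, and any
read-level noise (the pipeline starts from peak calls by design).  Recovery
being exact on synthetic data demonstrates the algebra and conventions are
right, not that the biology of a real study would be.

## Numerical and reproducibility choices

One global seed drives everything.  The pipeline splits it into per-stage
substreams (`numpy` `SeedSequence.spawn`) so stages are individually
reproducible; generator output and pipeline reports are byte-identical
under identical config and seed.  Ties are broken deterministically
throughout (lexicographic gene ids for assignment ties, lexicographic
k-mers at equal fold, offset-then-name ordering in arrays).  Report JSON
rounds to 4 significant figures; full precision lives in the stage TSVs.
Degenerate inputs fail early with named errors (empty gene sets where a
proportion would divide by zero, universes smaller than the union,
inverted intervals), and undefined folds are flagged, never fabricated.
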