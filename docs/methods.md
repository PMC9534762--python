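# Methods

## Scope and model of the data

`panpav` re-creates, at desk scale, the analytical core of a pan-genome PAV
study of a resequencing panel: a single high-quality reference, per-accession
draft assemblies, SNP genotypes, per-gene read-coverage summaries, and a
per-window selection-score track.  Everything upstream of these inputs
(assembly, annotation, variant calling, score computation) is out of scope
and is represented by the synthetic-data module, which generates inputs with
the same statistical structure plus machine-readable truth.

## Iterative pan-sequence augmentation

Each accession is processed in a fixed order (lexicographic by id, unless
configured otherwise).  Contigs are aligned to the *current* pan-reference;
qualifying aligned segments (identity ≥ 0.90 AND length ≥ 100 bp, both
inclusive) are unioned and subtracted from the contig; complement runs of
≥ 100 bp are appended to the pan-reference with provenance (accession,
contig, interval, iteration) before the next accession is aligned.  The
retained-length floor of 100 bp mirrors the alignment-length floor; runs
below it are discarded but still accounted for, so qualifying + retained +
discarded bases exactly partition every contig.

The aligner is a built-in exact k-mer anchor-chain method (default k = 21):
anchors are grouped per (target segment, strand, diagonal) — substitutions
preserve the diagonal, insertions break it, so chains correspond to
contiguous backbone pieces — filled gap-free, and extended outward with a
best-endpoint X-drop rule (match +1, mismatch −3, drop 30).  Reporting the
best-scoring endpoint rather than the abandonment point keeps boundary
overshoot into novel sequence to ~1 bp on average, which is what makes
base-level novel-sequence recall ≥ 99% attainable.  Identity is exact
matches over the columns of the induced gap-free correspondence; N never
counts as a match.  Repetitive k-mers are capped at 16 occurrences.  The
choice of a built-in aligner (rather than an external one) makes the
artifact self-contained; a dynamic-programming alignment oracle validates
reported identities in the tests.  The aligner is gap-free by construction,
so backbones with indel divergence would fragment into more chains; the
synthetic panels use substitution-only backbone noise (default 1%, up to
the 2% the contract covers).

## PAV matrix

Pan-gene clusters come from greedy length-sorted clustering: genes sorted by
decreasing length; each joins the first existing cluster (creation order)
whose representative validates at gap-free identity ≥ 0.90, else founds a
new cluster.  This is a deliberate stand-in for phylogenetic orthogroup
inference; the downstream contract is only "one cluster id per pan-gene".
Exactly identical input rows are deduplicated, making clustering idempotent
under concatenation of the same list.

Presence is the OR of annotation membership and the map-to-pan rule:
breadth ≥ 0.99 of gene length AND depth ≥ 3.0×, both inclusive.  Depth is
*mean* fold-coverage over the gene (the alternative, minimum depth, is
stricter and not used).  Per-presence provenance records which rule fired.

## Occupancy classification and curves

Class bands — core ≥ 99%, soft-core [90%, 99%), shell [15%, 90%), cloud
(0%, 15%) — are evaluated in exact integer arithmetic
(100·count ≥ q·N), so boundary cases at any panel size are exact.  The
accumulation curves use the strict definitions pan(n) = |union| and
core(n) = |intersection| over the first n genomes of each random ordering
(the strict core is intentionally distinct from the ≥ 99% classification
band; both semantics are exposed).  Means over 100 orderings by default; an
exhaustive mode enumerates all N! orderings for small panels.  Curve models
are the field's convention where no specific functional form is mandated:
Heaps-type power law P(n) = A·n^γ + C for the pan curve and exponential
decay K(n) = κ·e^(−n/τ) + Ω for the core curve, fitted by
nonlinear least squares; non-convergence and degenerate (constant) core
curves are flagged, never silent.  The pan-genome is called "open" when
γ exceeds twice its standard error.

## PAV structure

Default accession distance is simple matching (fraction of clusters whose
presence differs); Jaccard is available, with empty-union pairs defined as
distance 0 plus a warning.  The heatmap-style clustering is "ward.D":
the Lance–Williams update with α_i = (n_i+n_k)/(n_i+n_j+n_k),
β = −n_k/(n_i+n_j+n_k), γ = 0 applied to squared-Euclidean dissimilarities
(for binary rows, the Hamming count).  It is computed through the standard
ward linkage on the raw rows — whose internal recurrence operates on
exactly those squared distances — with heights squared afterwards; merges
and labels are identical, verified against a hand-applied Lance–Williams
calculation.  The cut into K clusters (default 8) labels clusters A, B, …
by decreasing size, ties by first-row index; the clustered axis (genes or
accessions) is a parameter.

Neighbor joining follows Saitou–Nei with the Q criterion; ties resolve to
the smallest (i, j) pair in the current agglomeration order, and branch
lengths use the standard two-point formulas.  Negative branch lengths are
reported as computed (an optional clamp-at-zero flag exists, off by
default), which keeps the estimator exact on additive matrices.

## Population-genetic statistics

Per-site diversity is the unbiased estimator π_site = 2c(n−c)/(n(n−1)) with
missing genotypes excluded site-wise; a window's value is the sum over its
sites divided by the window *span* in bp (not the covered bases), on a
sliding grid of 1,000-kb windows every 100 kb by default.  An optional cap
on SNPs assayed per window (600 by the scan convention) exists for
score-track inputs and is off for π.

F_ST is the Weir–Cockerham (1984) variance-component estimator with the
diploid heterozygote correction; the genome/window estimate is
Σa / Σ(a+b+c) over sites where every population has data.  Negative
estimates are reported raw so that oracle equivalence is exact.

LD decay uses phased haplotype frequencies (r² = D²/(p_A q_A p_B q_B)),
falling back to squared Pearson correlation of dosages when phase is
absent; pair distances are binned, means smoothed with a 3-bin moving
average, and the half-decay distance is the smallest bin midpoint at or
below half the smoothed maximum.

The composite sweep filter interprets "normalized" scores as genome-wide
z-scores and implements both percentile stages by rank so tie behaviour is
deterministic: keep the top ⌈0.05·W⌉ windows by score (ties by genomic
order), then — among those windows only, which is how the antecedent of
"selective regions" is read here — the top ⌈0.50·m⌉ by
ROD = π_wild/π_dom, with π_dom = 0 (infinite ROD) ranked strongest and
π_wild = 0 windows excluded with a log message.  Survivors merge at
distance 0 (overlap or bookend), the default of the standard BED merge
tool.  All intermediate window lists are emitted for audit.

## Synthetic panels

The generators are pure functions of (config, seed); each consumes its own
fixed stream spawned from the global seed, so stages can be rerun
independently and identical configs give byte-identical outputs.

* **Panel**: 116 accessions in three species-like groups (79/22/15) by
  default.  Pan-gene class counts default to 155/62/410/501
  (core/soft-core/shell/cloud) — the proportions typical of a crop
  pan-genome at 1/100 scale — plus 25 group-preferred genes per group.
  Occupancy counts are drawn uniformly within each class band (the
  empirical within-band distribution of real panels is not modelled; it is
  configurable).  Group-preferred genes occupy ≥ 80% of their group and at
  most a configurable small fraction (default 2%) elsewhere.
* **Assemblies**: contigs are reference fragments with substitution noise
  (default 1%) and GC-matched random novel inserts (default 2 per contig,
  150–1,000 bp) at recorded positions; a shared-pool option lets inserts
  recur across accessions (never twice within one accession, which would
  make total novel bp order-dependent).  Novel segments are random
  sequence, not mobilized repeats — the augmentation contract depends only
  on non-homology to the reference.
* **Genotypes**: Balding–Nichols — ancestral frequency Uniform(0.05, 0.95),
  group frequency Beta(p(1−F)/F, (1−p)(1−F)/F), haplotypes Bernoulli —
  chosen because F equals the expected Weir–Cockerham θ, giving a
  closed-form recovery target.  Default genome: one 10-Mb chromosome with
  5,000 SNPs (full crop genomes are three orders of magnitude larger; the
  statistics are size-invariant).
* **Tracks**: lognormal background scores (σ = 0.3); windows overlapping a
  planted sweep have their score multiplied (default ×10) and the
  domesticated π multiplied by the reduction factor (default 0.2).
  Overlapping planted sweeps are merged in the truth with a warning.
* **Coverage**: present genes get breadth 1.0 and ~10× depth with lognormal
  jitter; dropout and spurious-pass probabilities model miscalls; at zero
  noise the emitted evidence reproduces the planted matrix exactly.  Every
  planted cluster keeps at least one annotated carrier, since a pan-gene
  cluster only exists if some accession annotated it.

What passing on these panels shows — and does not show: the statistics,
thresholds and filters are implemented exactly (oracle equivalence, planted
truth recovery, boundary semantics), under substitution-only divergence,
uniform coverage and free recombination.  Real panels add indels and SVs,
mapping bias, LD and annotation artifacts that these generators do not
emulate; conclusions about the method's behaviour under those conditions
require real data.

## Numerical choices

Class-band and threshold comparisons use integer arithmetic; float
thresholds (breadth/depth, identity) are compared inclusively as printed.
The sweep-recovery experiment plants one 300-kb sweep on a 100-kb tiling
grid of a 10-Mb chromosome (W = 100): the top-5% stage keeps 5 windows and
the ROD stage 3, matching the sweep's window count so interval recovery is
well-posed; the generator's default scan grid remains the 1,000-kb/100-kb
sliding convention.  Curve fits use analytic-free p0 heuristics
(A ≈ pan range, γ = 0.5, C = 0; κ ≈ core range, τ ≈ N/3, Ω ≈ last core
value) with up to 20,000 function evaluations.  Problem sizes in the test
and acceptance runs (10-Mb references, 2–4 accessions for augmentation,
5,000-site genotype panels, 10 seeds for recovery experiments) were chosen
as the smallest scales at which the Monte-Carlo tolerances are comfortably
stable.

## Known limitations

The aligner has no affine-gap chaining, so diverged backbones with indels
over-fragment; greedy clustering can split a pan-gene when copies diverge
near the threshold (the pipeline then suffixes the duplicate cluster id);
`fcluster`-style cutting may return fewer than K groups when merge heights
tie at zero; LD half-decay is undefined (NaN) for panels without linkage,
such as the free-recombination synthetic genotypes.
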