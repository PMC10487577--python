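# Methods

## Spectral model and preprocessing

A fingerprint enters the pipeline as a centroided peak list (m/z in Da to
one decimal, nonnegative intensity in arbitrary units) restricted to the
2–20 kDa detection window. Peaks colliding at one decimal are summed
(conserving total ion signal); peaks outside the window are dropped with a
logged count.

Comparability across spectra requires a common support, so peaks are
resampled onto a fixed grid (default 2000–20000 Da, 1 Da step, 18001
points) by round-half-up binning, each bin taking the **maximum** of the
peaks it receives (a bin holds at most one true peak at MALDI-TOF
resolution; max is robust to satellite centroids). Intensities are then
log₁₀-converted as `log10(1 + I)`. The +1 offset is a deliberate choice:
the empty baseline (I = 0) must stay at exactly 0 rather than −∞, and for
the intensity scales involved (10²–10⁴) the offset is negligible.

Denoising slides a `window_width` (default 100 Da) window across the grid
in `step` (default 1 Da) increments; every grid point lies in at least one
full window (the final window start is clamped). Within a window the top
`ceil(keep_fraction · w)` points (default 20 % of 100 = 20) by intensity
are marked signal; ties break by higher intensity first, then lower m/z,
so runs are bit-reproducible. Because windows overlap, a combine rule is
needed:

* `union` (default): a point survives if **any** covering window marks
  it. A locally maximal peak is then never zeroed by a neighbouring
  window that happens to contain taller peaks.
* `per_window`: the last covering window decides — kept for sensitivity
  analysis; it is more aggressive near large peaks.

The default stage order is log → denoise. The alternative order is
configurable but provably yields the same retained support: log₁₀ is
strictly increasing, so within-window rankings are unchanged (asserted as
a property test, not assumed).

## Composite correlation index

The CCI of two preprocessed spectra splits the grid into `n_intervals`
(default 10) equal-width contiguous blocks, computes Pearson's *r* per
block, and averages the block correlations. Splitting into mass intervals
makes the index sensitive to agreement across the whole mass range rather
than letting a few dominant low-mass peaks carry the global correlation.
Design choices:

* Blocks where either spectrum is flat (zero variance — typically empty
  mass ranges) carry no pairwise information and are **excluded** from the
  mean rather than scored 0; a pair with no informative interval at all is
  an error.
* The mean is clamped to [0, 1] (configurable) to match the conventional
  heat-map scale; `n_intervals = 1` with clamping reduces the CCI to plain
  clamped Pearson correlation, so both composed and global readings of the
  index are available.
* With replicates, the matrix is computed at spectrum level; the
  strain-level matrix entry (A, B) is the mean CCI over all replicate
  pairs, diagonal 1 by definition.

Bray–Curtis dissimilarity `Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` on the preprocessed
intensity vectors feeds the ordination; all-zero spectra are rejected by
name.

## Ordination

PCoA is classical scaling: Gower double-centering of −½ D², symmetric
eigendecomposition, coordinates = eigenvectors × √eigenvalue, axes ordered
by eigenvalue. Bray–Curtis is generally non-Euclidean, so negative
eigenvalues occur; their axes are **dropped and reported** (count and most
negative value) rather than corrected (Cailliez/Lingoes), keeping retained
coordinates interpretable as distances. Axis signs are fixed by forcing
the largest-magnitude loading positive. Eigenvalues within
`max(|λ|)·1e-10` of zero are treated as null space.

Separation quality is quantified (rather than eyeballed from a scatter
plot) by seeded k-medoids (PAM build + swap, 10 restarts, best total
within-cluster distance) on the leading axes, scored against the true
labels with the adjusted Rand index. k-medoids is implemented in-package
because no installed library provides it.

## Clustering and tree comparison

The mass-profile dendrogram is agglomerative **single linkage** on
`1 − CCI` (keeping the dendrogram and the CCI heat map on one scale;
Bray–Curtis input is an option, and average linkage exists for robustness
checks only). Ties in merge distance break by the lexicographically
smallest pair of cluster keys (a cluster's key is its smallest member
label). Heights are non-decreasing, hence the cophenetic matrix is
ultrametric. Newick serialization uses branch length = parent merge
height − child height; labels with metacharacters are quoted. `cut(k)`
removes the k−1 highest merges; groups are named by smallest member for
diffable outputs.

The 16S side: pairwise distances from an existing alignment under p,
JC69 (`−¾ ln(1 − 4p/3)`) or K2P models with pairwise deletion of gaps and
ambiguities by default (complete deletion by flag); saturated pairs
(p ≥ ¾ or K2P log-domain violations) are errors naming the pair. The tree
is Saitou–Nei neighbor joining with the standard Q-criterion; Q is
explicitly symmetrized (float summation order otherwise breaks exact tie
detection), ties break on smallest label pair, and negative branch-length
estimates are clamped to 0 with the clamped total recorded. NJ is exact on
additive matrices, which the tests exploit: random trees → additive
distances → NJ must return RF distance 0 and patristic error < 1e-9.
Bootstrap supports resample alignment columns with replacement (seeded),
rebuild the tree per replicate, and annotate each original internal
bipartition with the fraction of successful replicates containing it;
replicates with undefined distances are skipped and counted (> 50 %
skipped is an error). The default is 1000 replicates; the test suite and
pipeline default use 25–100 for runtime.

Grouping concordance between the (rooted) dendrogram and the
midpoint-rooted NJ tree is operationalized through **spanning-clade
co-group sets**: for species S, take the smallest clade containing all of
S's strains; S co-groups with every species having a strain inside that
clade; S is consistent when its co-group set is identical in both trees;
the grouping similarity is the consistent fraction of species. This
criterion needs no cut heights, reduces to "monophyletic and separated ⇒
consistent", and flags interleaved species pairs symmetrically. A
cut-based alternative (cut both trees to k groups, compare species
co-membership) is selectable. The Sankey table is the plain contingency
table of two flat groupings. Robinson–Foulds distance (symmetric
difference of non-trivial bipartitions) backs the NJ oracle tests and is
cross-checked against dendropy.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with one seed driving three named substreams (hierarchy, spectra,
sequences):

* **Hierarchy**: genus peak sets drawn disjointly from candidate positions
  spaced 10 Da apart (so m/z jitter can never merge peaks of different
  origin); species peak sets = genus peaks ∪ fresh species-specific peaks;
  per-strain lognormal intensity multipliers. A rooted species tree with
  genera monophyletic by construction: genus stems 0.08–0.12
  substitutions/site, within-genus edges 0.005–0.03 (deep inter-genus,
  shallow inter-species divergence, as for 16S).
* **Spectra**: per replicate, each species peak survives dropout
  (default 5 %), gets intensity `base × strain multiplier × lognormal
  scatter (σ = 0.25)`, and position jitter uniform ±0.3 Da; sparse
  exponential baseline noise (density 0.002/grid point ≈ 36 peaks,
  scale 30) is added. Peak base intensities are lognormal
  (median ≈ 1500 a.u., σ = 0.8), typical of MALDI arbitrary-unit scales.
* **Sequences**: a uniform-random root sequence evolves by Jukes–Cantor
  (site substitutes with `p = ¾(1 − e^(−4d/3))`, then moves to one of the
  other three bases uniformly) along the species tree; each strain adds a
  0.002-substitutions/site private branch. No indels, so the output is
  aligned by construction. Default length 1200 nt (a near-full 16S gene).

The default study design is 4 genera / 22 species / 61 strains with one
dominant genus (13 species, 40 strains) and 3 replicates per strain —
sized like a realistic culture-collection survey of plant-associated
endophytes. What the generator does **not** emulate: isotopic envelopes,
detector saturation, mass-dependent resolution, peak-shape effects,
systematic batch drift, indel evolution and rate heterogeneity. Passing
tests therefore demonstrate correctness of the algorithms and
recoverability of hierarchical structure under idealized noise — not
instrument-level performance on real spectra.

## Problem sizes in tests and acceptance runs

The test suite and `scripts/acceptance.py` size their runs for a single
CPU: denoiser-vs-oracle on 120 random spectra (20–150 points); the CCI
pair-category ordering on the full 61-strain design over 5 seeds;
PCoA recovery on 3 species × 15 replicates; NJ exactness on 100 random
additive matrices of 5–10 taxa; Jukes–Cantor closed-form agreement at
10⁴ sites (3 binomial SEs); end-to-end concordance over 10 seeds with
1 replicate/strain and 2000 nt sequences, comparing a low-noise condition
(dropout 1 %, jitter 0.1 Da) against an elevated one (dropout 20 %,
jitter 1 Da, 5× baseline density, σ = 0.6 scatter); and byte-level
determinism of two identical `run-all` invocations on a 12-strain design.

## Package shape

The transform-shaped stages are sklearn-compatible estimators —
`SpectrumPreprocessor` (TransformerMixin over raw peak lists), `PCoA`
(fit/fit_transform with trailing-underscore attributes) and
`SingleLinkage` (fit on a precomputed distance matrix exposing `labels_`)
— so they compose with sklearn pipelines and model selection. Phylogeny,
concordance and simulation are not fit/predict-shaped and are provided as
plain functions over domain objects; module-level functions (`pcoa`,
`linkage_single`, ...) wrap the estimators for script use.

## Known limitations

* The CCI interval count of the original vendor index is not
  standardized; results at other `n_intervals` values differ smoothly and
  `n_intervals=1` recovers global Pearson.
* Single linkage chains by design; the genus cut is reliable when
  inter-genus similarity is near 0, as fingerprints show, but noisy
  intermediate similarities can bridge clusters.
* Midpoint rooting of the NJ tree can misplace the root when rate
  variation is strong, shifting spanning clades and hence co-group sets.
* The denoiser's `per_window` rule is order-dependent by definition; only
  `union` is order-free.
* Bray–Curtis PCoA axes explain shares of the **positive** inertia only;
  with many negative eigenvalues the two leading axes may understate
  structure.
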