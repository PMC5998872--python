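# Methods

## The model

celldecon treats a bulk expression profile as a linear mixture of cell-type
profiles.  For gene *i* in mixture sample *j*,

    M_ij = Σ_k S_ik F_kj ,        in matrix form  M ≈ S F,

where *S* (t genes × r cell types) holds the representative expression of
t discriminating genes in each of r cell types and *F* (r × n mixtures)
holds the relative proportions of the types, constrained to be non-negative
and to sum to one per sample.  The model assumes (a) expression adds
linearly across cell populations on the intensity scale, (b) the reference
profiles represent the cell states actually present in the mixtures, and
(c) the signature genes are not expressed appreciably by cell types outside
the panel — which is what the black-list filtering and marker selection
work to ensure.

All statistics operate on linear-scale intensities; files stored as log2
values are anti-logged at load (`log2=True`).  Fold changes are reported in
log2 units computed from linear class means.

## Reference quality control

Reference arrays are screened before any differential testing:

* **Clustering.**  Samples are clustered by complete linkage on Euclidean
  distance between expression columns, giving a dendrogram in which
  replicates of a type should form tight subtrees.  Class pairs whose
  leaves interleave (the smallest subtree containing both classes contains
  nothing else, yet neither class is pure on its own) are reported as merge
  candidates.
* **Correlation rule.**  For each array, Pearson correlations to every
  other array of its class are computed; the array is flagged as an outlier
  when strictly more than 2/3 of those pairs fall below r = 0.85.  Both
  thresholds are parameters; the defaults are the method's published
  operating point.  Correlations are computed on log2(x+1) intensities by
  default: on the linear scale the one or two brightest genes carry most of
  the variance, so the correlation would measure the agreement of a handful
  of genes rather than of the profiles.  A `correlation_scale="linear"`
  option preserves the raw-scale behaviour.

Flagged arrays and suggested merges are *reported, never applied*: dropping
samples (`drop_samples`) and merging classes (`merge_classes`) are explicit
calls, so the QC trail stays auditable.

## Signature construction

1. **Quantile normalization.**  Every reference column is mapped onto the
   across-column mean of order statistics.  Ties within a column receive
   the mean of the target quantiles they span — the deterministic,
   symmetric rule.  A consequence worth knowing: with ties present, a
   second application is not bit-identical (the tie rule slightly reshapes
   the pooled target), so idempotence holds exactly only for tie-free
   (continuous) data, which is what real intensity data look like.
2. **Black lists.**  Genes enriched in non-hematopoietic normal tissues
   (enrichment score > 0 in strictly more than 5% of tissues; the ES table
   is consumed as input) and genes expressed in cancer cell lines
   (log2 > 7 in at least one line) are removed *before* ranking, so a
   black-listed gene can never enter the signature.
3. **Pairwise differential expression.**  For each of the C(r,2) class
   pairs, a two-sided unequal-variance (Welch) t-test per gene;
   Benjamini–Hochberg q-values are computed within each pair's family
   (not pooled across pairs), and genes with q < 0.3 are kept.  An optional
   Storey-style estimator rescales the BH values by an estimated null
   proportion π₀ (λ = 0.5); it is not the default because π₀ estimation is
   unstable for small families.  Classes need ≥ 2 replicates; exactly 2 is
   allowed with a logged warning about power.  Degenerate genes whose two
   groups are both constant get t = 0, p = 1 when the means agree and
   t = ±inf, p = 0 when they differ (the scalar `welch_t_test` API instead
   raises in the latter case, where the statistic is undefined; the
   vectorized path must not abort a whole-matrix scan on one noiseless
   gene).
4. **Ranking and union lists.**  Within each pair, significant genes are
   ranked by |log2 fold change| of the class means, descending, with a
   pseudocount of 1 on the linear means so dim genes cannot produce
   unbounded ratios; ties break by gene id so ranks are reproducible.  For
   a list size G, every pair contributes its top G genes and the union
   (deduplicated, sorted by gene id) is the candidate signature.
5. **Condition-number selection.**  For G from 5 to 100 the candidate
   matrix of per-class means is assembled and its 2-norm condition number
   κ = σ_max/σ_min recorded; the G minimizing κ wins, ties going to the
   smaller G.  κ is computed on the un-standardized linear-scale means —
   standardization happens later, at deconvolution time.  G values whose
   union is smaller than r are skipped (the system would be
   underdetermined); rank-deficient candidates report κ = ∞.

## Deconvolution

Mixtures are quantile-normalized among themselves, restricted to the genes
shared with the signature (an error if the overlap is smaller than r), and
standardized: the signature as one block (global mean/sd over all entries,
preserving the relative magnitudes of the columns; a per-column option
exists) and each mixture column over its signature-gene entries (sample sd,
n−1 denominator).

Each sample is then solved independently by ν-support-vector regression
with a linear kernel: the signature genes are the training points, the r
columns the features, and the fitted hyperplane normal w is the raw
proportion estimate.  ν bounds the fraction of support vectors and of
training errors, which makes the fit robust to genes that deviate from the
linear model.  The model is fitted at every ν in {0.25, 0.5, 0.75}; the fit
with the lowest RMSE between the standardized mixture and the fitted model
S·w + b wins (ties: smallest ν).  The intercept b is part of the fitted
model and is included in the reconstruction — without it even a noiseless
mixture would retain a constant offset, because the mixture is z-scored but
S·w is not centred.  The winning raw coefficients are post-processed:
negatives clipped to zero, the remainder normalized to sum to one.  No
re-fit is performed after clipping.

Numerical settings: SVR cost constant C = 1.0 (ν controls the
support-vector fraction; C only scales the penalty and is exposed in
`DeconvolutionConfig`), solver tolerance 1e-6, proportions reported in
full double precision and printed to 12 significant digits.  Solving
samples one at a time means any execution order yields identical output.

## Benchmarking

Validation data usually type only a subset of the panel, sometimes at
coarser resolution.  `rescale_subset` first sums fine classes into
benchmark classes via a user map (e.g. resting + activated NK → NK), then
restricts to the benchmarked classes and renormalizes each sample to sum to
one.  `benchmark` reports per-class Pearson r and RMSE across samples,
per-sample metrics across classes, and pooled metrics over all entries.
Proportion-space RMSE and the deconvolver's expression-space reconstruction
RMSE (in the per-sample diagnostics) are distinct quantities and are
labelled as such.

## Synthetic data

The generator emulates replicated microarray references and bulk mixtures:

* baseline intensities per gene are log2-normal (mean 6, sd 2 on the log2
  scale), giving positive, right-skewed values spanning the dynamic range
  typical of array data;
* each of r classes elevates a disjoint block of marker genes by
  `marker_effect` (default 8-fold, a realistic magnitude for cell-type
  markers);
* replicates multiply the class profile by log-normal noise
  (`noise_sd` on the log2 scale, default 0.01; additive Gaussian noise
  with sd proportional to intensity is available);
* mixtures are S·F with F drawn row-wise from a symmetric Dirichlet
  (α = 1, i.e. flat over the simplex; default 50 mixtures) plus the same
  noise model.  At noise 0 the mixtures satisfy the linear model exactly.

Defaults (8 classes, 1000 genes, 5 markers/class, 3 replicates) are the
study conditions used by the verification suite and the acceptance script.
What the generator does **not** emulate: probe-level artifacts, batch
effects, cross-hybridization, platform-specific intensity distributions,
and cell types absent from the reference panel.  Passing tests on this
generator therefore demonstrate the correctness of the pipeline's
machinery and its behaviour under the linear mixing model, not performance
on any particular real cohort.

A deliberate property of the generator interacts with G selection: when
all markers of a class share exactly the same effect size, their fold
changes are nearly identical, so every pair's top-G list repeats the same
few strongest markers and the union can stay well below the full planted
set while κ is already minimal.  Marker *recovery* of the chosen list is
therefore guaranteed only when markers-per-class is below the scan floor
g_min (then at most the globally weakest marker can be shadowed in every
pair).  Fraction recovery is unaffected — a class needs some markers in
the signature, not all of them.

## Known limitations

* Proportions are relative to the panel; absolute abundances are out of
  scope, as are significance values for deconvolution calls.
* ν-SVR weights are bounded by C; a class whose surviving signature genes
  are all dim can, for unlucky draws, saturate the bound and leak part of
  its weight diffusely to the other classes even for a pure sample.
* κ-driven G selection optimizes conditioning, not marker completeness
  (see above).
* With only 2 replicates per class, Welch tests are low-powered and the
  q < 0.3 gate is permissive by design; the black lists and the |log2 FC|
  ranking are what keep the candidate lists specific.
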