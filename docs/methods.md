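# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `opershape`, in the spirit of the methods documentation of
comparative-methods packages.

## Shape variables

Landmark configurations are 2-D (the opercle is effectively flat): k = 18
points, four fixed landmarks (hyomandibular joint socket, ventral and
posterior apices) and fourteen semilandmarks placed at regular intervals
along the bone edge. Semilandmarks are treated as fixed points — no
sliding/bending-energy step — because the digitization scheme places them
at constant arc intervals rather than optimizing them, and the analyses
downstream treat all points identically.

Generalized Procrustes analysis centers each configuration, scales it to
unit centroid size (full Procrustes; size is removed), and iteratively
rotates each configuration onto the consensus via the SVD of the
cross-covariance matrix. Reflections are disallowed during fitting
(`allow_reflection=False`); configurations photographed from the left side
are mirrored onto the right beforehand, which leaves all pairwise shape
distances unchanged. Convergence is declared when the consensus
root-mean-square displacement falls below 1e-10 (default), max 100
iterations; the reported consensus is the plain coordinate-wise mean of the
aligned shapes, so residuals sum to zero exactly. Analyses operate on the
aligned coordinates directly, without a separate tangent-space projection:
at the shape variances involved here (Procrustes distances well below 0.3)
the difference between the sphere and its tangent plane is far below the
statistical noise floor of every downstream test.

Replicate specimens of one taxon are superimposed together and averaged
coordinate-wise before analysis; culling multiple species to one exemplar
per family is the caller's responsibility via the input table.

## Morphospace

PCA is performed on the covariance matrix of the flattened aligned
coordinates (units are homogeneous, so correlation PCA would be wrong).
Eigenvector signs are fixed by making each component's largest-magnitude
loading positive; axis polarity is otherwise arbitrary, so plots may be
mirrored relative to any particular published figure.

The density landscape is a product-Gaussian kernel density estimate on a
200 x 200 grid spanning the scores padded by three bandwidths, with
per-axis Silverman bandwidths sigma * n^(-1/6) and contour levels at ten
equal quantiles of the positive density values. The original analyses used
a proprietary "nonparametric density" routine whose bandwidth and
contouring rules are not documented; the KDE here is a stated stand-in with
the same qualitative behavior (integral within 2% of 1 on the default
grid). Focal regions (occupancy peaks, off-peak areas) are ellipse
definitions in the (PC1, PC2) plane supplied by the user — published peak
outlines are hand-drawn and not exactly recoverable, so regions are
configuration inputs, not constants.

## Trees and ancestral states

Trees are ultrametric and time-calibrated (branch lengths in My);
polytomies are accepted as-is. Pruning preserves root-to-tip path lengths
and collapses unbranched internal nodes. Zero-length branches are replaced
by 1e-8 x tree depth with a warning.

Phylomorphospace internal-node positions use squared-change parsimony in
its branch-length-weighted form (each squared change divided by branch
length), the Brownian-motion-consistent variant used by Mesquite-style
phylomorphospaces; the unweighted variant is available via
`weighted=False`. The minimization is solved exactly as a sparse linear
system, one factorization per tree, so repeated solves across null
simulations are cheap. Ancestors are computed on PC scores (the plotted
plane), not on raw coordinates.

## Comparative statistics

**Kmult.** The multivariate K statistic is the ratio of the summed squared
deviations of tips from the GLS phylogenetic mean to the same quantity
computed after whitening by the inverse tree covariance, divided by its
expectation under Brownian motion, `(tr C - n / (1' C^-1 1)) / (n - 1)`.
For one trait this reduces exactly to Blomberg's K (tested against an
independently coded direct-formula oracle). The permutation test shuffles
taxa across tips; p = (count of permuted K >= observed + 1) / (n_perm + 1).
The default permutation count is 10,000, enough to resolve p-values of
1e-4.

**Disparity.** Procrustes variance of a group is the mean squared
deviation of members from the group mean shape (divisor n — the sum of
coordinate-wise variances). The permutation test reassigns group labels
and compares absolute variance differences (maximum pairwise difference
for more than two groups); the fold difference reported is max/min.

**Rates.** Per-group sigma^2_mult is the mean squared whitened residual
per trait dimension, with residuals taken from the GLS root estimate and
whitened by the inverse square root of the tree covariance. Significance
of the max/min ratio comes from simulating datasets under a single pooled
rate on the same tree (the `compare.evol.rates`-style simulation test; the
permutation alternative is not implemented).

**Model selection.** BM, WN, OU and EB are fitted to one trait (one PC) at
a time, matching the published table's per-PC design; joint multivariate
fitting is out of scope. All four models profile the ancestral state z0
(GLS) and the rate sigma^2 analytically; OU's alpha and EB's decay r are
optimized by bounded scalar search with alpha in [1e-8, 50]/depth (on a
log scale) and r in [-10, 0]/depth, with the r = 0 boundary (pure BM)
checked explicitly. OU uses the fixed-root convention on an ultrametric
tree — covariance sigma^2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha
s_ij)) with s the shared depth and d the patristic distance — so the
optimum theta coincides with z0 and the OU parameter count is 3 (sigma^2,
alpha, z0), as in GEIGER's fitContinuous; theta is still reported. AICc =
-2 lnL + 2k + 2k(k+1)/(n-k-1); dAICc is relative to the best model. The
published table's additional "dAICc_SE" column has no documented formula
and is not reproduced.

## Convergence metrics

For a focal pair of tips, Dtip is their Euclidean distance in the (PC1,
PC2) plane and Dmax the maximum distance between any two states, one from
each lineage traced back to the common ancestor — states at tips and at
reconstructed internal nodes only, no interpolation along edges. C1 = 1 -
Dtip/Dmax, C2 = Dmax - Dtip, C3 = C2 / (total state change along the two
lineages), C4 = C2 / (total state change in the clade descending from the
common ancestor). Multi-taxon focal sets aggregate pairwise values by the
mean (configurable to min/max). C5 counts edges whose parent point lies
outside a focal region and whose child point lies inside; an edge passing
entirely through the region between its endpoints is not counted, a known
limitation on coarse trees. A secondary count (`c5_tip_entries`) considers
only entries actually reached from tips still inside the region.

Null distributions come from Brownian-motion simulations on the tree with
per-axis ML rates estimated from the observed scores and no trait
correlation (the published analysis does not state a simulation
covariance). Convergence p-values use the bare count / n_sims convention —
a reported p of 0 means no simulation reached the empirical value —
deliberately diverging from the (count+1)/(N+1) estimator used by every
other test in the package, to mirror the convention of the convergence
literature's tables.

## Elliptical Fourier outlines

Closed outlines (default 400 points) are resampled to equal arc-length
spacing and decomposed into H = 30 harmonics (counting the first) with the
piecewise-linear Kuhl-Giardina formulas. The default parametrization
assigns each segment an equal parameter increment — appropriate because
inputs are equally spaced after resampling, and exact for uniformly
sampled ellipses (a uniformly sampled ellipse is represented by its first
harmonic alone); chord-length parametrization is available for raw
unevenly spaced input. Normalization follows the first-harmonic
convention: starting-point phase, orientation, and size removed, leaving
a1 = 1, b1 = c1 = 0, d1 >= 0, the last fixing traversal direction. The
landmark-vs-outline comparison is delivered as a concordance report
(rank correlation of inter-taxon distance matrices), since the claim it
checks is qualitative.

## Synthetic data generator

The generator emulates the study design, not opercle anatomy in detail: a
pure-birth tree conditioned on n (simulation stops at the n-th lineage and
places the present one truncated exponential interval later; the slight
conditioning bias of this stop-at-n scheme is acceptable for fixtures),
latent traits evolving by BM or OU, and shapes built as
`template + sum_d trait_d * basis_d` where the basis vectors are smooth
trigonometric edge-displacement fields, projected off translations and
orthonormalized. Because the basis is orthonormal in flattened coordinate
space, latent traits map near-linearly into Procrustes/PC space and
parameter-recovery tests have analyzable ground truth. Defaults mirror the
study's scale: 100 tips, birth rate 0.0167/My (Yule crown depth ~250 My),
2 deformation axes (the PC1-PC2 analyses), BM rate 2.5e-5 per My per trait
(tip shape SD ~0.08 Procrustes units), replicate landmark noise SD 0.005,
OU alpha 0.008/My (alpha x depth ~ 2). Convergent regimes paint a shared
optimum onto every edge whose descendant tips all belong to a designated
tip set; edges outside regimes relax toward the baseline optimum 0.

What the generator does not emulate: anatomical spines/struts and realistic
outline texture, fossil sampling, non-ultrametric trees, correlated
measurement error between landmarks, and within-family species sampling
structure. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the generating models — not that any
particular empirical dataset satisfies those models.

## Test problem sizes and numerical choices

Calibration tests use the sizes a desk machine handles comfortably: 500
replicates for Kmult calibration on a 64-tip tree (permutation size 199
per replicate), 200 replicates each for disparity/rate calibration and
the 4x rate-contrast recovery, 200 replicates of 128-tip OU recovery
(alpha x depth = 3), and 100 replicates each for convergence null
calibration and power (32 tips, 200 BM simulations per test). The
convergent-regime power check uses the weakest selection strength the
scenario family is specified for (alpha x depth = 2); the generator
ground-truth check that designated clades actually meet at a shared
optimum uses strong selection (alpha x depth = 15, phylogenetic half-life
~5% of tree depth) so the clades equilibrate within their regime branches.

Degenerate inputs are rejected loudly: zero-centroid-size configurations
name the offending specimen, mismatched landmark counts name the record,
missing taxa are listed, non-PSD rate matrices and non-ultrametric trees
(for OU) raise. Ties in optimal rotations (reflection case) are resolved
by forcing det(R) = +1 unless reflections are explicitly allowed.

## Known limitations

- No sliding semilandmarks and no tangent projection (documented above).
- C5 cannot see transits that enter and leave a region within one edge.
- The OU fit is single-regime, fixed-root, ultrametric-only.
- Squared-change-parsimony ancestors understate uncertainty; no
  uncertainty propagation into the convergence metrics is attempted.
- The pure-birth generator produces no extinction and no rate variation
  across the tree unless a convergent regime requests it.
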