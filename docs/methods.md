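# Methods

This note documents the models, parameter choices and known limits of
`senetrace`.  It covers the generative model behind the synthetic data, each
analysis stage's assumptions and defaults, and what the test suite does and
does not establish about real data.

## The synthetic time course

The generator emulates a senescence-induction experiment: an untreated
control day plus 12 post-induction time points over 31 days
(`{0, 2, 4, 7, 9, 11, 14, 17, 21, 24, 26, 28, 31}`; only a handful of these
days are fixed by the study design, the rest are an evenly spread choice and
are configurable), 16 protein markers (nine named senescence/SASP/signaling
proteins — p53, p21, p16, p-p65, GATA4, PARP1, JAK2, pSTAT3, IL-6 — plus
seven neutral fillers that preserve dimensionality), and six biological
roles:

| role | nuclear area | signature |
|---|---|---|
| healthy | 1.0× | baseline everywhere |
| senescent transitional | 1.55× | senescence totals 1.5–2.2×, p21 spike→decline |
| non-senescent transitional | 1.25× | filler markers 1.4–2.4× |
| large-nuclear senescent | 2.8× | senescence totals 2.2–2.8×, concentrations *below* baseline |
| high-concentration senescent | 1.45× | senescence totals 2.6×, top concentrations, cytoplasmic IL-6/JAK2/pSTAT3 4–5× |
| non-senescent terminal | 1.35× | filler markers 1.8–3.5×, no senescence markers |

Three structural commitments matter downstream:

* **Dilution coupling.**  A cell's nuclear mean is always computed as
  total / area; it is never an independent draw.  The large-nuclear role's
  area outgrows its totals, so its concentrations fall — the signature the
  dilution analysis must recover.  Measurement noise is applied to the
  intensity field (the mean), and the recorded total is area × noisy mean,
  so `total = area × mean` holds exactly in every emitted record.
* **Staged emergence.**  Role mixture weights per day form a fixed schedule
  (rows sum to 1): day 0 is pure control; the senescent transitional role
  holds 17% at day 2; the large-nuclear role first appears at day 11; the
  high-concentration role first appears at day 17 and reaches 7.8% at day
  31, non-decreasing throughout.
* **Transition continuum.**  Each non-healthy cell carries a progress
  latent `u = 1 − 0.5·Beta(1, 1.5)` and its state is the log-space
  interpolation between its parent state and its full role state at
  fraction `u`.  Terminal roles approach through their transitional parent
  (large-nuclear and high-concentration via the senescent transitional
  state; the non-senescent terminal via its own transitional state), so the
  population contains the density bridges that diffusion embedding and
  principal curves assume.  `u` is bounded at the path midpoint, so a
  cell's nearest role state is always its own — composition estimates stay
  unbiased.  Nuclear area ramps to its plateau as `min(day, 11)/11`; marker
  states are role properties, except p21, which spikes (2.2×) at day 2 in
  the transitional role, declines below baseline by day 11, and re-rises
  (2.5×) only in the large-nuclear role.

Noise defaults: multiplicative lognormal with σ = 0.10 (biological,
per-cell) and σ = 0.05 (measurement) on intensities; additive Gaussian with
σ = 0.10 on log-area.  These are typical imaging coefficients of variation
for a clonal cell line; they were set together with the factor tables so
that the planted roles are separable in z-space (closest-pair centroid gap
about twice the within-role spread) — a regime in which control-anchored
clustering is informative.

Rendered scenes place non-overlapping elliptical nuclei (uniform intensity
= true nuclear mean; a Chebyshev-width-5 cytoplasm band carries the true
ring mean) with at least 11 px clearance so rings never collide, and apply
known integer translations between rounds.  The drawn pixel count *is* the
ground-truth area, so quantification can be tested exactly.

## Quantification

Round alignment is translation-only phase correlation; the reported offset
is the displacement of the moving round (a round shifted by (5, −3) reports
(5, −3)), and a normalized cross-correlation score at the estimated offset
replaces manual inspection (flag threshold configurable, default 0.9).
Segmentation for phantoms is Otsu + distance-transform watershed; real
masks from a learned segmenter can be supplied instead, through the same
labeled-mask interface.  The cytoplasmic ring is the set of background
pixels within Chebyshev distance 5 of a nucleus; pixels reachable from
several nuclei belong to the nearest one, ties to the smaller label; a ring
with no admissible pixels yields a missing (NaN) cytoplasmic mean.  The
artifact screen drops border-touching labels and labels outside
configurable area bounds, logging a reason code per exclusion; it is
idempotent.

## Embedding

Features are z-normalized column-wise with the population-SD convention;
constant columns are dropped with a warning, and rows with missing
cytoplasmic values are dropped by default (median imputation optional).
Subsampling reimplements density-preserving sketching: cells are hashed
into the boxes of a random-projection lattice (5 projections; resolution
doubled until ≥ n boxes are occupied) and boxes are sampled round-robin.
Rare populations therefore keep more than their population share — the
property that matters at a 1,200-cells-per-time-point subsampling depth.

The embedding follows the diffusion-potential construction: adaptive
α-decay kernel (bandwidth = distance to the knn-th neighbor; defaults
knn = 15, α = 40), symmetrization, row normalization into `P`, and `P^t`
evaluated exactly through the eigendecomposition of the symmetric conjugate
operator.  With `t=None` the diffusion time is the von Neumann entropy
knee; the pipeline default is `t = 40` because on strongly clustered data
the entropy knee falls before the time scale at which diffusion has mixed
across the thin inter-cluster bridges, and the relative positions of rare
terminal clusters are then poorly determined.  MDS uses classical
(Torgerson) initialization refined by SMACOF (cap 300 iterations, tolerance
1e-6); the stress trace is retained and is non-increasing by construction.

The MDS metric defaults to the **square-root potential** `2·sqrt(P^t)`
(a Hellinger-type diffusion distance) rather than the log potential
`−log(P^t + ε)`.  The log potential weights the deep tail of the
transition distribution, where every weakly connected subpopulation looks
alike; on mixtures with a rare terminal state this collapses the rare
cluster onto whichever other peripheral cluster is nearest in saturation
profile, even when `P^t` itself orders the affinities correctly.  The
square-root potential weights strong transitions, placing subpopulations by
whom they actually exchange diffusion mass with.  `potential='log'`
restores the classical transform.

## Clustering and role mapping

k-means (best of `n_init=10` k-means++ starts) runs on the full
z-normalized feature matrix, not the 3D embedding (a flag allows the
latter).  The cluster count maximizes `score(k) = max_c recall(c)·purity(c)`
for the day-0 control cells — the literal "fraction of control cells in one
cluster" is maximized trivially at k=1, and purity alone at k=n; the
product is the smallest modification that keeps the anchoring idea
well-posed.  Ties break toward smaller k and the full score trace is kept.
Note that on data where the control population remains present at later
time points (as here, where healthy cells persist), the score plateaus once
the control state is isolated; the selected k is then the smallest k on
that plateau, which may exceed the number of biological roles when a role
has internal day structure; several clusters then share one role after
mapping.

Role mapping encodes what is usually a manual cluster-sorting step as deterministic
rules: (1) the healthy cluster anchors the map (argmax recall×purity);
(2) terminal candidates are non-healthy clusters whose occupancy
concentrates in the final third of the time course (> 1.2× the uniform
share — an aggregate statistic chosen over the single argmax day, which is
noisy) and whose centroid distance from healthy is at least the median,
relaxed to the three most distant late-concentrated clusters when that
gate under-selects; (3) among terminals, the largest centroid area is
large-nuclear, the highest mean senescence-marker concentration is
high-concentration, the rest non-senescent terminal (with a 1-z-unit
signature rule when more than three candidates exist); (4) clusters on the
centroid-MST path from healthy to a senescent terminal are senescent
transitional; (5) everything else merges into non-senescent transitional.
Missing roles are reported, never guessed.

## Lineage inference

The lineage tree is the Euclidean MST over cluster centroids in embedding
space (Kruskal with lexicographic tie-breaks), rooted at the healthy
cluster; by default clusters are first merged into their six roles so the
tree has one node per biological state and the leaves are the terminal
roles.  Each root-to-leaf path gets a principal curve: initialized as the
piecewise-linear path through its centroids, extended past both end
centroids to span the member cells (otherwise cells beyond an end centroid
collapse onto the curve tip), then iterated — project members onto the
curve, lowess-smooth each coordinate against arc length (span 0.6),
re-parameterize — until mean curve movement < 1e-3 of the pseudotime range
or 50 iterations.  Pseudotime is the arc length of a cell's projection;
cells in clusters shared by several lineages get inverse-squared-distance
weights across those lineages.

Backward-time truncation smooths each member cell's experimental day along
pseudotime with a running mean (window 5% of cells, at least 25) and
truncates at the global peak of that curve if the smoothed day later falls
more than `slack` below it.  The function default is slack = 0.5 day (the
scale of a genuine reversal in a clean constructed lineage); the pipeline
default is 2.0 days because the windowed mean of experimental day
fluctuates by about one day under the default population structure, and a
first-crossing rule at 0.5 would truncate healthy-end noise.

## Pseudotime statistics

Trend curves are local linear regressions with tricube weights (span 0.3,
100 grid points over the truncated lineage length) — exact on linear data —
with a band equal to the tricube-weighted residual SD in the same local
window.  Lineage comparisons are two-sample KS tests on per-cell feature
values (full lineage or final-10% window).  The p-value is the asymptotic
survival function; its tail is evaluated in log space
(`log p = log 2 − 2λ²` when the series underflows), so the star scale —
ns, `*` < 0.05, `**` < 1e-100, `***` < 1e-200, `****` < 1e-300 — remains
well-defined where double precision cannot represent p.  The asymptotic
form is also the calibrated choice: at 200 cells per arm its null
rejection rate at α = 0.05 is ≈ 0.051, while the exact discrete null is
conservative (≈ 0.039).  A curve-difference mode (max |Loess A − Loess B|
on a shared grid, permutation p-value) exists for the literal reading of
comparing plotted curves; the per-cell test is the default because a KS
test on smoothed curve evaluations is not a valid sampling model.  No
multiple-testing correction is applied across the marker × lineage family
by default; a Benjamini–Hochberg pass can be layered on by the caller.

## Problem sizes and determinism

Full-size runs (1,200 cells per time point, 15,600 cells) are used wherever
the embedding is not required — composition recovery, cluster-count
selection, KS calibration.  Stages that need the dense diffusion embedding
(O(n²) memory, O(n³) eigendecomposition) are exercised at 150 cells per
time point (1,950 cells), a size at which ten independent end-to-end
replicates run in a couple of minutes; the planted effects are large
relative to sampling error at both sizes.  All stages are deterministic
given their seed; the pipeline derives per-stage seeds from one global seed
by a fixed counter scheme.

In the cluster-count recovery experiments, the planted mixture is
constructed so the true count is identifiable: the control component is
both in the closest pair (first merged as k decreases) and the largest
(first split as k grows), so the anchoring score peaks uniquely at the true
k.  With equally spaced, equally sized components the criterion is
genuinely tie-degenerate — merging two non-control components leaves the
control cluster pure — and the tie-break toward smaller k would report a
smaller count.

## What passing tests do and do not show

The synthetic data share the emulated design's statistical skeleton — staged discrete
states with a transition continuum, dilution coupling, rare late
subpopulations, lognormal noise — but not its optics: no illumination
gradients, bleaching, stitching seams, segmentation errors, cell motion
between rounds beyond global translation, or antibody cross-reactivity.
Pixel-exact quantification identities therefore validate the bookkeeping,
not robustness to imaging artifacts; composition and topology recovery show
the inference machinery works in the intended regime, not that real data
are in that regime.  The three-lineage topology is recovered from planted
geometry; on real data the MST over role centroids inherits all the usual
sensitivity of tree inference to embedding distortion.
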