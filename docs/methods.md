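# Methods

## Scope and model

fcgraph analyses case-control resting-state fMRI cohorts at the level of
extracted ROI time series. The underlying model is the standard binary
functional connectome: after temporal cleaning, the pairwise Pearson
correlation matrix (Fisher r-to-z transformed) is thresholded into a
family of binary undirected graphs with fixed edge counts across subjects,
and topology is summarised by small-world and efficiency metrics
normalised against degree-preserving random nulls, by a-priori six-module
connectivity strengths, and by data-driven modularity. Group inference is
a covariate-adjusted linear model on the per-subject AUC of each metric
over the sparsity grid.

Volume-space preprocessing (slice timing, realignment, normalisation,
smoothing) is out of scope; the package assumes its inputs are ROI means
already extracted from preprocessed images.

## Signal cleaning

Fixed order: linear detrend → ideal band-pass → nuisance regression →
scrubbing.

- **Detrend** removes a per-ROI least-squares line (intercept + slope).
- **Band-pass** is an ideal (rectangular) FFT-domain filter retaining the
  discrete bins with 0.01 ≤ f ≤ 0.08 Hz. A rectangular mask rather than an
  IIR design (e.g. Butterworth) was chosen because it matches the
  ideal-filter convention of the common resting-state toolboxes and is
  exactly testable bin by bin. DC is removed whenever the low edge is
  positive.
- **Nuisance regression** residualises each ROI on a user-supplied design:
  the 24-parameter motion expansion [p, p², p_lag1, p_lag1²] for the six
  rigid-body parameters, plus externally supplied global/white-matter/CSF
  columns (the package has no voxel data; synthetic cohorts provide
  surrogate columns). An intercept is always appended; rank-deficient
  designs are repaired by QR-pivoted column dropping with a logged
  warning.
- **Framewise displacement** is the Power convention
  FD_t = Σ|Δtranslation| + r·Σ|Δrotation|, rotations in radians projected
  on a sphere of radius r = 50 mm (the field convention; no units were
  fixed by the problem statement, so this is a documented choice).
  FD_0 = 0.
- **Scrubbing** replaces frames with FD > 0.5 mm by per-ROI linear
  interpolation between the nearest retained frames; leading/trailing bad
  frames copy the nearest retained frame. Scrubbing after filtering and
  regression is a documented ordering convention, not a claim about any
  particular toolbox's internal order. A subject with every frame bad is
  an error (such subjects should be excluded); a cohort-level exclusion
  flag (>2 mm translation or >2° rotation) is available.

Cleaning never changes frame or ROI counts.

## Network construction

- Pearson correlations require ≥3 frames and positive per-ROI variance;
  |r| is clamped at 1−1e−12 before atanh so duplicated ROIs give a large
  finite z and a recorded flag.
- Only strictly positive z values are eligible as edges. At sparsity S the
  target edge count is k = round(S·N(N−1)/2) with round-half-up (the
  rounding convention is not dictated by any external source; it is fixed
  and tested here). The k largest positive-z edges are kept; ties are
  broken by ascending (i, j) index so results are reproducible. If fewer
  than k positive edges exist, all positives are kept and a warning is
  recorded — degenerate matrices produce empty graphs, never failures.
- All sparsity levels share one edge ranking, so edge sets are nested
  across the grid.

**Sparsity grid.** The conventional grid specification "0.05 to 0.4 in
steps of 0.02" cannot include both endpoints (0.40 is not reachable from
0.05 in 0.02 steps). The package defines the default grid as 18 evenly
spaced levels from 0.05 to 0.40 inclusive (spacing ≈ 0.0206), which keeps
the intended range, level count, and AUC width (0.35) exact.

## Graph metrics

- **C_p**: mean local clustering, 2·(edges among neighbours)/(k(k−1));
  degree < 2 contributes 0.
- **L_p**: harmonic-mean convention, L_p = N(N−1)/Σ_{i≠j}(1/d_ij), with
  disconnected pairs contributing 0 to the sum. This keeps sparse,
  fragmented graphs finite — essential at S = 0.05 — and makes
  L_p = 1/E_glob. Only an edgeless graph is an error.
- **E_glob**: mean inverse shortest-path length over ordered pairs.
- **E_loc**: mean over nodes of the global efficiency of the subgraph
  induced by each node's neighbours (node excluded; shortest paths
  restricted to the subgraph — one of the two published variants, chosen
  and documented here).
- **Null models**: Maslov–Sneppen double-edge swaps with
  attempts = 10·|E| (configurable), rejecting self-loops and multi-edges;
  degree sequences are preserved exactly. Graphs admitting no valid swap
  (e.g. complete graphs) are returned unchanged with a flag. The swap
  loop is JIT-compiled (numba) with all randomness pre-drawn from a numpy
  Generator, so results are identical with or without compilation.
- **Normalisation**: C_p^rand and L_p^rand are means over n_null rewired
  graphs (default 100; the validation suite and the acceptance script use
  20, which keeps the null-mean standard error well below the effects of
  interest). Metrics are averaged across nulls first and ratios formed
  after — the documented choice between the two possible orders.
  γ = C_p/C_p^rand, λ = L_p/L_p^rand, σ = γ/λ. Nulls with zero clustering
  are excluded with a warning (relevant only for very small sparse
  graphs); if every null is excluded the call errors.
- **AUC**: trapezoid rule over the sparsity grid; needs ≥2 strictly
  increasing levels.

Per-(subject, sparsity, null) random streams are spawned deterministically
from one master seed via numpy SeedSequence, so results are independent of
evaluation order.

## Modular analysis

- **A-priori blocks**: the six functional systems with default ROI counts
  32/21/34/33/22/18 (cingulo-opercular, fronto-parietal, default,
  sensorimotor, occipital, cerebellum). The exact per-module counts of any
  particular 160-ROI atlas are configurable; the defaults only shape block
  dimensions, not logic.
- **Block strength** at sparsity S is Σ z_ij·a_ij(S) divided by the number
  of ROI pairs in the block (within: unordered pairs inside the module;
  between: all cross pairs). Dividing by all block pairs — absent edges
  contributing 0 — makes strength monotone in S and comparable across
  subjects with equal edge counts; the retained-edges-only denominator is
  available behind a switch.
- **Spectral modularity**: Newman leading-eigenvector bisection of the
  (generalised) modularity matrix, refined by Kernighan–Lin-style single
  node moves (each pass moves every node once, keeping the best
  configuration), recursing until the leading eigenvalue is non-positive
  (tolerance 1e−9) or the split no longer increases Q (1e−12).
  Q = Σ_c(e_cc − a_c²) is always re-evaluated directly on the returned
  partition. Group comparisons use the a-priori blocks; data-driven Q is
  reported per subject/threshold.

## Group inference

- **Adjusted comparison**: one linear model
  value ~ 1 + group + age + sex, rather than residualise-then-t-test, so
  the degrees of freedom (n − 4) are accounted correctly. Constant
  covariate columns are dropped, which collapses the model to the
  classical pooled two-sample t. Direction is patient minus control.
  Sex is encoded F = 0, M = 1.
- **FDR**: Benjamini–Hochberg step-up, applied separately per analysis
  family (global metrics; module blocks) at level 0.05.
- **Hedges' g**: J·(mean_p − mean_c)/s_pooled with J = 1 − 3/(4n − 9);
  95% CI by the normal approximation
  SE² = n/(n_p·n_c) + g²/(2(n − 2)). Magnitude labels follow the Cohen
  bands (|g| < 0.2 very small, 0.2–0.49 small, 0.5–0.79 medium, 0.8–1.19
  large, 1.2–1.99 very large, ≥ 2 huge; lower edges inclusive).
- **Partial correlation**: residualise both variables on the covariates
  (with intercept), Pearson on residuals, p from
  t = r√(df/(1−r²)), df = n − 2 − k, two-sided. Clinical correlations are
  reported uncorrected.
- **Demographics**: Pearson χ² on the 2×2 sex table without continuity
  correction (df = 1), and a plain two-sample t for age.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not fMRI physics:

- **Spatial model**: a block correlation matrix with within-module
  correlation 0.4, between-module 0.1, over six modules totalling 160
  ROIs. Patients get block offsets: −0.15 on the intra-DMN block and
  +0.10 on the cingulo-opercular↔occipital block. If a requested block
  matrix is indefinite, eigenvalues are clipped at 1e−6 and the matrix is
  rescaled to unit diagonal, with a repair flag.
- **Temporal model**: 130 frames at TR = 2 s from a zero-mean Gaussian
  with the block covariance and stationary AR(1) smoothing (φ = 0.3 —
  mild temporal autocorrelation typical of band-passed BOLD). There is no
  hemodynamic convolution: the analysis consumes correlations only, so a
  Gaussian surrogate with the right second-order structure suffices.
- **Motion**: six random-walk parameters (translation step SD 0.02 mm,
  rotation step SD 4e−4 rad) with persistent translation steps
  ("repositioning" spikes) at probability 0.05 per frame, each spike
  sized to push exactly one frame's FD above the 0.5 mm threshold.
- **Clinical link**: seizure frequency = max(0, 13 − 40·z̄ + ε),
  ε ~ N(0, 1), where z̄ is the patient's realised intra-DMN mean Fisher z.
  The intercept and slope were chosen once so frequencies land in a
  realistic 1–10 events/day range at the cohort's typical z̄ ≈ 0.25 and the
  planted correlation is strong enough to be recoverable at n = 16; the
  pre-truncation planted correlation is documented in the generator's
  output metadata.
- **Demographics**: ages uniform on 4–40 months drawn from the same
  distribution for both groups (matched by construction), sex Bernoulli
  with P(F) = 0.35, durations uniform 1–24 months for patients.
- **Seeding**: per-subject streams derive from
  SeedSequence([master_seed, crc32(subject_id)]), so cohorts are
  reproducible and independent of generation order.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: physiological noise spectra, spatially
correlated motion artefacts, hemodynamic lag, inter-subject anatomical
variability, distance-dependent connectivity, and non-Gaussian BOLD
features. Recovery of the planted effects shows the pipeline's statistics
are correct and sensitive under the assumed covariance model, not that
any particular clinical finding replicates.

## Validation problem sizes

The test suite validates exact metrics against brute-force oracles
(triangle enumeration, Floyd–Warshall, exhaustive set-partition search for
modularity) on graphs of ≤ 10 nodes; small-world detection and null-model
self-similarity on full-size 160-node graphs with 20 nulls per graph;
planted-effect recovery over 100 cohort seeds at the default cohort size;
and type-I error over 500 null simulations. Pipeline-level tests use a
miniature 24-ROI, 11-subject cohort with the grid starting at 0.20,
because at S = 0.05 a 24-node graph has so few edges that rewired nulls
can lose every triangle (the full-size cohort is nowhere near this
regime).

## Known limitations

- Binary undirected graphs only; no weighted, signed, or directed
  variants, and no nodal metrics.
- The harmonic-mean L_p convention, all-pairs block-strength denominator,
  mean-then-ratio null normalisation, and round-half-up edge counts are
  fixed conventions; alternatives exist in the literature and would shift
  absolute values (not the package's group contrasts, which compare like
  with like).
- The Hedges' g confidence interval uses the normal approximation, which
  is slightly anticonservative below n ≈ 20.
- Spectral modularity is a greedy optimiser; it can return a local
  optimum on graphs with weak community structure (Q is exact for the
  returned partition, which is verified directly).
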