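# Methods

This note records the model, the numerical choices, and the limits of what
the tests demonstrate. Notation: n experiments, settings x_i ∈ R³
(throughput kg/h, screw speed rpm, liquid-to-solid ratio), histograms
w_i ∈ Δ^{b−1} on a fixed size grid with b bins.

## Size grid

Granule sizes span three decades, so the grid is geometric: b bins between
`lo` and `hi` μm, default b = 35, lo = 8.46, hi = 6765.36 — the bin layout
of the dynamic image-analysis instrument this workflow targets. "35 bins
between 8.46 and 6765.36" is read as 36 log-spaced *edges* with those
values outermost ("bins" counts intervals); bin centers are geometric means
of adjacent edges, so log10 centers are equally spaced. The alternative
reading (35 log-spaced *centers*) is available via `grid_mode="centers"` in
the config.

## Kernels and their hyperparameters

Two Gaussian RBF kernels, k(x, x') = exp(−‖x − x'‖²/(2σ²)):

* **Settings kernel k** on z-scored settings. Standardization removes the
  column mean and divides by the population (divide-by-n) standard
  deviation, computed once on the full training design and reused for
  queries and during leave-one-out evaluation (fold-wise re-standardization
  would break the closed-form LOO identity below). Default bandwidth
  σ²_k = 5.0, i.e. k(x, x') = exp(−0.1·‖x − x'‖²). This calibration
  matters: on a standardized three-level factorial the nearest distinct
  design points sit at squared distance ≈ 1.5, so a bandwidth of σ² = 0.1
  would make the Gram matrix essentially diagonal (nearest-neighbor kernel
  value e^{−7.5} ≈ 5·10⁻⁴), every leave-one-out prediction would collapse
  toward the zero embedding, and the recovered histograms would degenerate
  (see "pre-image edge artifact" below). With the default, the kernel is
  smooth across the whole design and leave-one-out predictions at interior
  points are accurate. The coefficient 0.1 in the exponent is the
  convention most ML libraries call `gamma`; σ² = 1/(2·0.1) = 5 is the same
  kernel written in bandwidth form. The σ²-literal alternative is one
  config line away (`kernel_k: {bandwidth_sq: 0.1}`).
* **Size-grid kernel l** on log10 bin centers (the log transform keeps the
  three-decade grid from degenerating the kernel). Bandwidth by the median
  heuristic: σ²_l = median over unordered pairs i < j of
  (log10 y_i − log10 y_j)². Self-pairs are excluded — including the b zero
  distances would deflate the median. On the default grid σ²_l ≈ 0.832.
* **Diagonal biases.** For numerical stability a nugget is added to the
  diagonal of each square Gram matrix: 0.05 on K and 0.1 on L by default.
  The nugget is a property of a training set with itself; train–query
  cross-kernel vectors never carry it, which keeps prediction at new points
  well defined (standard jitter semantics).

An inhomogeneous polynomial kernel (⟨x, x'⟩ + 1)^p is implemented alongside
the RBF because it makes the information content of an embedding checkable:
with p = 1 the squared MMD between two histograms over the same atoms
equals the squared difference of their means exactly, a property the test
suite verifies on random simplex pairs.

## Conditional mean embedding regression

Histograms are embedded as μ_w = Σ_j w_j l(y_j, ·); everything downstream
is a quadratic or linear form in the coefficient vectors, evaluated through
the Gram matrix L — feature maps are never materialized. The conditional
embedding at x is μ̂(x) = Σ_i β_i(x) μ_{w_i} with
β(x) = (K + λI)⁻¹ k_x: kernel ridge regression with vector (histogram)
outputs. Predicted coefficient vectors a(x) = Wᵀβ(x) are unconstrained;
only the pre-image step restores the simplex.

One effective regularizer λ is used consistently in the fit, the hat
matrix, the LOO shortcut and the λ search. (Writing the estimator with nλ
and the hat matrix with λ changes nothing — only the product with the
identity matters — and consistency is exactly what makes the shortcut
below an identity rather than an approximation.)

**Closed-form LOOCV.** The fitted values are a linear smoother with hat
matrix H_λ = K(K + λI)⁻¹, so the n leave-one-out predictions are
Â = (I − diag H)⁻¹ (H − diag H) W. This equals, row for row, an explicit
refit on the other n − 1 rows of the same (nugget-biased) Gram matrix with
prediction through the unbiased cross column; the test suite asserts
agreement to 1e-8 for n ∈ {3, 5, 10}. Rows with H_ii → 1 (duplicated
settings at λ = 0) make the system singular and raise an error.

**λ selection.** λ* minimizes J(λ) = Σ_i (w_i − â_i(λ))ᵀ L_b (w_i − â_i(λ)),
the LOO squared embedding error, with the biased L by default (the bias is
applied before calibration; a `metrics.use_biased_l` switch recomputes
with unbiased L). The search is deterministic: 25 log-spaced candidates on
[1e-8, 1e2] followed by golden-section refinement (tolerance 1e-3 in log10
λ) around the best candidate, with an eigendecomposition of K making each
J evaluation O(n²). Two behavioral facts worth knowing:

* With the 0.05 nugget on K, J(λ) is monotone increasing in λ on smooth
  (noise-free or mildly noisy) data — the nugget already supplies the
  regularization floor, so λ* lands at the bottom of the search window.
  That is the correct minimizer, not a search failure.
* Remove the nugget and add sampling noise, and J becomes U-shaped with an
  interior λ* (≈ 3·10⁻⁴ at 2000 counts per experiment on the packaged
  fixture); the suite tests this configuration explicitly.

## Pre-image

A predicted coefficient vector a is mapped to a histogram by

    α̂ = argmin_{α ≥ 0, Σα = 1}  αᵀ(L + rI)α − 2 αᵀ L a,

which, up to a constant, minimizes MMD²(μ_α, μ_a) + r‖α‖². The linear term
uses the RKHS inner product c = L·a (dotting α with the raw coefficients
instead would not correspond to a distance between embeddings). The default
ridge r equals the l-kernel nugget 0.1 — that nugget exists "especially for
the pre-imaging problem", and passing it as r makes the QP's quadratic the
biased Gram matrix while keeping the linear term unbiased; both knobs are
exposed. An entropic (KL-penalized) variant would be a natural extension
but is out of scope.

The solver is accelerated projected gradient: FISTA with Euclidean
projection onto the simplex (the sort-based algorithm), gradient-based
adaptive restart, step 1/L with L = 2λ_max(L + rI), an iteration cap of
10 000, and termination when the KKT stationarity residual
max(max_i (ν − g_i)₊, max_i |α_i(g_i − ν)|) with ν = gᵀα drops below
`solver_tol` (default 1e-8). Feasibility is exact by construction of the
projection. When λ_min(L + rI) < 1e-12 a ridge floor of 1e-10 is applied
automatically so the degenerate (flat-kernel) QP stays well posed. On
failure the best feasible iterate is attached to the raised error. An
independent sequential-quadratic-programming solve of the same QP agrees
to 1e-6 in the tests.

**Edge artifact.** When the predicted coefficients sum to less than one
(inevitable for queries far from all training points), the excess
probability mass is placed where it adds least RKHS energy — the outermost
bins, which have the fewest close neighbors under l. Predictions therefore
show spurious weight in the first and last bins exactly when the model is
extrapolating; it is a property of the ridge-plus-pre-image formulation,
not of the solver.

## Metrics

Per experiment, against the measured weights: squared MMD
(α − α̂)ᵀL(α − α̂) with the *unbiased* L by default so that the
self-distance is exactly zero (the biased variant, which inflates it by
bias·‖α − α̂‖², is available for strict replication of a biased-Gram
convention); the Euclidean distance ‖α − α̂‖ reported under the customary
"RMSE" label (a divide-by-√b variant exists behind `normalize=True`); and
KL divergence Σ_i α_i log(α_i/max(α̂_i, floor)) with floor 1e-12 and
0·log 0 = 0. The report appends the arithmetic column means as a final row.

## Synthetic data generator

The generator emulates the structure of a granulation campaign, not its
physics. Ground truth at standardized settings z is a two-component
mixture in log10 size: a fines mode (lognormal, median 50 μm, 0.35 dex SD)
and a coarse granule mode (median 10^(3.0 + b·z) μm, 0.25 dex SD) with
coarse fraction π(z) = logistic(−0.2 − 0.15 z₁ − 0.10 z₂ + 0.8 z₃) — the
liquid-to-solid ratio is the dominant driver of both the coarse fraction
and the coarse median (wetter granulation → larger granules), with mild
negative throughput and screw-speed effects. Bin masses are mixture-CDF
differences across the bin edges, renormalized over the grid support.
These defaults were chosen once to reproduce the shape repertoire of real
campaigns (monomodal, strongly right-skewed, bimodal) with smooth
dependence on the settings; they are not claims about any particular
product. Optional multinomial noise (`count_n` draws per experiment)
emulates counting statistics; per-experiment streams are seeded by
(scenario seed, CRC32 of the experiment id) so they survive row
reordering. `count_n = 0` (default) is noise-free.

What the generator does **not** emulate: instrument optics and correlated
measurement error, day effects and drift, physical constraints linking the
modes (binder saturation, breakage), or mass- vs number-weighting of the
distribution. Passing the end-to-end tests therefore certifies that the
pipeline can learn a smooth distribution-valued response on a realistic
design — it does not certify predictive accuracy on any real granulator.

The packaged 29-run design is a 3³ factorial over throughput
{5, 12.5, 25} kg/h, screw speed {450, 675, 900} rpm, and L/S
{0.3, 0.45, 0.6} (25 of the 27 cells) plus four star points on the L/S
axis at {0.337, 0.375, 0.525, 0.563}; the star values follow the
three-level design's L/S axis and are documented here rather than asserted
as ground truth. "Interior" points — all three coordinates strictly inside
the design range — are the five near-center runs (N14, N26–N29).

## Problem sizes and tolerances in the tests

The end-to-end checks run the full 29-experiment, 35-bin pipeline
(≈ 4 s: λ search plus 29 QP solves); unit tests use 3–10 experiments and
4–12 atoms so every oracle (per-fold refits, O(n²) double sums, SQP) stays
exact and fast. The end-to-end recovery thresholds — mean KL ≤ 0.15 and
mean L2 ≤ 0.10 over the interior design points of the noise-free scenario
— are engineering thresholds certifying that learning happened, chosen
with the defaults above; measured values are ≈ 0.10 and ≈ 0.06. Agreement
tolerances: 1e-8 for the LOO identity and QP feasibility/KKT, 1e-6 for
cross-solver agreement, 1e-10 for algebraic identities. Cross-check
comparisons of the LOO objective across different linear-algebra paths use
a relative slack of 1e-5: with the nugget, hat-matrix diagonals approach 1
and the (1 − H_ii)⁻¹ ratios amplify float64 noise to ~10⁻⁷ of J.

## Known limitations

* Leave-one-out quality depends strongly on the settings-kernel bandwidth;
  the default is calibrated for z-scored three-level designs and should be
  revisited for very different designs (the median heuristic is a
  reasonable starting point there too).
* The "constant-output" sanity case (all experiments sharing one
  histogram) is reproduced only approximately: a ridge smoother does not
  interpolate constants exactly unless the kernel is flat, and the default
  pre-image ridge pulls feasible inputs slightly toward uniform. The test
  uses a near-flat kernel and a ridge-free pre-image, where the error is
  < 1e-4.
* KL divergence with a floor of 1e-12 is extremely sensitive to predicted
  zeros in populated bins; comparisons across pipelines should fix the
  floor.
* The model file embeds the training matrices as JSON; it is meant for
  tens of experiments, not thousands.
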