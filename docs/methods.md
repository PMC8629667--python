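# Methods

## Pipeline overview

Three stages, each a pure function of its input and a seed:

1. **Preprocessing** — an exact square-window median filter (odd window,
   default 3; replicate or reflect borders). The median is an order
   statistic, so output values are a subset of the neighborhood values
   and constant images are fixed points.
2. **Lung-lobe extraction** — Bayesian fuzzy clustering of intensities
   followed by a geometric selection of the lung fields.
3. **Tumor segmentation** — a dictionary-based deformable model confined
   to the lobe mask, with either a plain explicit-Euler curve update or
   the stochastic water-cycle/bat update.

## Bayesian fuzzy clustering (lobes)

Model: pixel intensities are Gaussian around one of `O` cluster
prototypes with shared scale `noise_sigma`; memberships carry a
symmetric Dirichlet prior. Inference alternates

* a membership update proportional to the Gaussian likelihood tempered
  by `1/(fuzzifier−1)` (computed in log space; with `noise_sigma = 0`
  the limit is hard nearest-prototype assignment, ties to the lowest
  index), and
* a prototype update — the membership^fuzzifier-weighted mean, the
  exact maximizer of the recorded complete-data log-posterior given the
  memberships. A cluster with no mass has its prototype resampled
  uniformly from the seeded stream.

The sweep with the highest log-posterior is returned, so a late
degradation cannot replace a better earlier state. In the noiseless
regime the alternation reaches its fixed point monotonically; with
observation noise the trace may wiggle, which the best-sweep rule
absorbs. Initialization is deterministic (intensity quantiles at
`(w+0.5)/O`), so identical seeds give identical results; restarts are
available through the seed.

Defaults: `n_clusters 3` (air, parenchyma, soft tissue), `fuzzifier 2`,
`dirichlet_concentration 1` (the symmetric prior then cancels in the
normalization), `noise_sigma 0.05`, `n_sweeps 50`.

**Lung-ROI selection** is deliberately simple plumbing: walk clusters
from the darkest prototype upward and keep connected components that do
not touch the image border (lung fields are interior; the air
background reaches the edge) and exceed 2% of the image. A 3×3 opening
suppresses texture speckle first; a short binary closing followed by
hole-filling keeps a bright nodule inside the lobe mask even when its
blur bleeds through a thin parenchyma ring. The pipeline clusters a
σ=2 px Gaussian-smoothed copy of the filtered image — lobes are
regional intensity structure, and strong parenchymal texture otherwise
fragments the clusters — while the tumor stage uses the unsmoothed
filtered image. Users with their own lobe masks can bypass this stage
entirely.

## Water-cycle/bat optimizer

Population of `pop_size` raindrops in a box; after evaluation the best
member is the sea, the next `n_sr − 1` are rivers, the rest streams.
Per iteration:

* streams move by `L + rand·z·(guide − L)` toward their assigned river
  or sea (`z = 2`, the canonical step-scale constant);
* rivers move by the bat-blended update
  `L·(1 − rand·z·(2 − l_b)/l_b) + rand·z·(L_prev + Q)` with frequency
  `l_b` drawn uniformly from `[l_min, l_max] = [0, 100]` and velocity
  `Q` defined as the previous displacement (zero-initialized; the
  near-zero-frequency singularity falls back to the plain river step);
* promotion swaps any member that beats its guide, so the sea always
  holds the population minimum;
* evaporation/raining: when a river is within `b_max` of the sea its
  streams re-scatter uniformly over the box; a sea-bound stream within
  `b_max` of the sea re-scatters in a Gaussian cloud `sea + δ·randn`
  (`δ = 0.1`), which concentrates the late search;
* `b_max` decays by `b_max/max_iter` per iteration, from a default
  initial value of 1e-2 times the box diagonal.

Stream counts per entity follow the shifted-cost share
`round(|B_i − B_first_stream| / Σ · n_streams)` with the rounding
remainder absorbed by the sea, so cheaper entities attract more streams
and the counts sum exactly. All randomness flows from one generator
seeded per run; traces are bit-reproducible, and the sea is elitist so
the best-so-far trace is non-increasing.

## Dictionary-based deformable model

Curve = zero set of φ, inside at φ < 0.

* **Dictionary**: all fully-contained T×T patches at stride 1 (default
  `T = 9`), Euclidean k-means with `d = 50` atoms, k-means++ seeding,
  tolerance 1e-6, nearest-center assignment with lowest-index ties.
  When a restriction mask is given (the lung lobes), only patches fully
  inside the mask enter the dictionary: the label competition is then
  between the region's own textures, not against the unrelated
  surroundings whose area would bias the normalization.
* **Biadjacency `G`**: pixel p links to dictionary pixel
  `atom·T² + offset` for every covering patch; row sums are coverage
  counts, total entries equal patches × T².
* **Transforms**: label layers → per-dictionary-pixel frequencies
  (column-normalized), area normalization `g̃_x ∝ g_x/|ψ_x|^γ`, back to
  per-pixel probabilities by row-normalized averaging, then the
  contrast transform `Ẽ_x = e_x/(e_x + max_{n≠x} e_n)` (for two labels
  this is `e₁/(e₁+e₂)`). Uncovered dictionary pixels or image pixels
  get the uninformative 1/X. A majority-vote pull-back variant
  (`aggregation="vote"`) is exposed for study; averaging is the default.
* **Evolution**: `∂φ/∂t = (1/2 − Ẽ + w·κ)‖∇φ‖` with Godunov upwind
  gradient norms; explicit Euler (`mode="plain"`) or the stochastic
  water-cycle/bat update (`mode="wcba"`). Labels are re-derived from
  sign(φ) each iteration; φ is rebuilt as a signed distance function
  every `k_reinit = 10` steps from Euclidean distance transforms with a
  half-pixel offset (interface between the ±0.5 bands, ‖∇φ‖ ≈ 1).

### Numerical choices and why

* **Time step and regularization.** `dt = 0.5`,
  `curvature_weight = 0.2`. The dictionary data force is
  `|Ẽ − 1/2| ≲ 0.3`; a curvature weight of order 1 exceeds it and
  freezes or erases small structures, while 0.2 still regularizes
  bulges (`κ ~ 1/R`).
* **Reinitialization quantization as a deadband.** The distance
  transform rebuilds φ from the sign pattern only, discarding sub-pixel
  front positions. This is deliberate: the label→dictionary→probability
  feedback has a slow self-reinforcing outward drift (each newly
  claimed shell retrains the dictionary labels in its favor), and the
  quantization arrests any force below ≈ one pixel per reinit cycle
  (0.1 in speed units at the defaults). A sub-pixel-accurate PDE
  reinitialization removes this deadband and the boundary drifts
  without bound.
* **Tempered area normalization in the loop** (`area_exponent 0.5`).
  With very asymmetric regions the full `1/|ψ|` correction lifts
  dictionary pixels with marginal small-region coverage above parity
  and displaces the decision boundary ~2 px outward; no correction
  displaces it ~2 px inward. The square-root exponent roughly centers
  it, and coincides with the full form when the regions are comparable.
  The `area_normalize` function itself defaults to the full form.
* **Stochastic update form.** `wcba_curve_update` implements two
  printed forms of the frequency/velocity-blended update. The fully
  rearranged form (the default of the function, and the formula checked
  against an independent elementwise oracle) algebraically reverses the
  sign of the `Δt·∂φ/∂t` forcing relative to the explicit step, so a
  loop driven by it evolves against the evidence; `segment()` therefore
  uses the direct pre-rearrangement form
  `φ^{t+1} = φ^t + (1 − rand·z)·l_b·(φ^{t−1}+Q)/D + Δt·∂φ/∂t`.
  One scalar `(rand, l_b)` pair is drawn per step and applied
  field-wise — per-pixel draws destroy the level-set property (a
  per-pixel mode exists behind a flag for study). Near-singular
  denominators (|D| or |D − l_b| < 1e-6) fall back to the plain step.
  The stochastic momentum coefficient can cross −1/2 and negate the
  field wholesale, which merely swaps the in/out label names, so the
  loop re-anchors orientation by negating φ whenever more than half the
  pixels flip sign in one step.
* **Convergence.** Stop when the fraction of pixels changing label
  stays below `tol = 1e-4` for 5 consecutive iterations, tested only
  after `min_iter = 50` (with sub-pixel steps the first label flips
  take tens of iterations, which would otherwise read as instant
  convergence). Non-converged runs return the most label-stable iterate
  with a warning in the diagnostics; a collapsed region (empty side)
  returns the last non-degenerate state.
* **Pipeline seeding.** The tumor curve starts from a thresholded,
  4-px-eroded anomaly region inside the eroded lobe. Two robust
  channels are scored against the lobe-interior median/MAD and
  window-averaged (13 px) so sustained regions outrank speckle: a
  two-sided smoothed-intensity deviation, and a one-sided local-standard-
  deviation *deficit* (a solid nodule is smoother than vesicular
  parenchyma). The intensity channel is used only when its peak is
  decisive (≥ 6 MAD units — an order of magnitude above what a
  signal-free lung produces); otherwise the smoothness channel decides.
  Starting eroded exploits a measured hysteresis: the model recovers a
  boundary reliably by growing outward, but sheds an overshoot poorly.

## Synthetic phantoms

A phantom is a piecewise-constant composite — dark background, bright
elliptical body (semi-axes 58×62 on a 128×128 grid), two dark lung
ellipses (42×22), one tumor ellipse (24×14) inside the right lung —
modulated by per-region multiplicative textures (smoothed seeded white
noise with region-specific correlation length and amplitude), plus
additive Gaussian noise and optional salt-and-pepper impulses. Masks
are exact rasterizations; all randomness flows from one seed through
named substreams.

The fixed suite: **easy** (tumor intensity-separated from parenchyma),
**texture** (tumor at the parenchymal mean: a nearly solid nodule,
amplitude 0.05, inside strongly mottled parenchyma, amplitude 0.40,
grain 1.5 — only patch-scale texture statistics carry the boundary),
and **noisy** (intensity-separated plus 5% impulses and stronger
Gaussian noise, exercising the median filter).

Structures are sized so that overlap metrics reflect texture
discrimination rather than the method's patch-scale boundary blur: at a
~1060 px tumor one pixel of uniform boundary error costs ≈ 0.06 Dice.
The solid-vs-mottled contrast is the texture contrast a raw-patch
Euclidean dictionary can actually represent: with low-amplitude
*structured* texture the k-means atoms memorize locations instead of
generalizing (each atom's occurrences cluster spatially), and curve
growth stalls at atom-territory borders.

What the phantoms do **not** emulate: Hounsfield calibration, ribs,
vessels, partial-volume effects, 3-D continuity between slices, or
scanner-specific noise. Passing the suite shows the pipeline's stages
compose correctly and that texture-driven delineation works under
controlled contrast; it does not certify clinical performance.

## Known limitations

* On purely texture-defined contrast the label→probability chain blurs
  the decision boundary over roughly the patch radius; the
  self-consistent equilibrium sits a 1.5–2 px shell inside the true
  boundary (about 0.1 Dice at the suite's nodule size). Intensity
  contrast sharpens the atoms and removes the effect — the acceptance
  checks report this gap honestly rather than hiding it behind easier
  test conditions.
* The rearranged stochastic update is exposed for fidelity but is not
  usable as a dynamical rule (see above).
* The lung-ROI heuristic assumes dark interior lung fields in a
  properly windowed slice; it is bypassable by supplying a lobe mask.
* Two-label segmentation only in `segment()`; the transforms support
  X ≥ 2 and are tested with three labels, but no multi-φ loop is wired.
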