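# Methods

This note documents the models and numerical choices behind `phyloniche`,
and what the synthetic-data generator does and does not emulate.

## The presence-background niche model

Each species' geographic suitability is modeled as a Gibbs distribution over
the study cells: `P(i) ∝ exp(λ·f(i))`, with the partition function summed
over a background sample of cells drawn uniformly (without replacement,
default 10 000) from inside the minimum convex polygon of all species'
pooled occurrence points. Features per climate variable are the
background-standardized value `z = (x − m)/s` and its restandardized square
`(z² − m₂)/s₂`; restandardizing the square keeps both features on comparable
scales so a single penalty strength treats them evenly. `λ` maximizes

```
ℓ(λ) = mean over presences of λ·f(x) − log Σ_background exp(λ·f(j)) − β Σ_k |λ_k|
```

by proximal gradient ascent (soft-thresholding step, step halving on the
penalized objective, growth factor 1.2, cap 16). The objective is concave,
so accepted iterates are non-decreasing — an invariant the tests assert.
Convergence is the gradient-mapping sup-norm dropping below `tol` (1e-6);
otherwise the iteration cap (default 5000) is reached and logged.
Zero-variance features are zeroed and flagged, and the fit warns about them.

Parameters with units and defaults:

| parameter | meaning | default |
|---|---|---|
| `beta` | L1 penalty weight, per-feature (features are unit-scale) | 0.1 |
| `max_iter` | iteration cap of the proximal loop | 5000 |
| `background_n` | background cells inside the convex polygon | 10000 |
| `train_fraction` | train share of an 80/20 split | 0.8 |
| `cv_max_points` | up to this many points, leave-one-out CV is used | 12 |
| `replicates` | re-seeded split/fit replicates averaged per species | 20 |

The **RAW** surface normalizes `exp(λ·f)` over *all* valid study cells (not
only the background), because the downstream overlap and PNO sums run over
the whole study mask. Species with fewer than 10 spatially unique points are
rejected. Cross-validated or replicate surfaces are averaged cell-wise and
renormalized; the reported AUC is the mean held-out AUC (rank-based with
mid-ranks, presences vs background).

**Relaxed fit.** The L1 penalty shrinks each active weight by an additive
amount, which distorts the *ratio* of a variable's linear and quadratic
weights — exactly the quantity the implied response optimum
`x* = m + s·(−λ_lin s₂ / 2λ_quad)` depends on. `MaxEnt.fit(relax=True)`
therefore refits both features of every variable with at least one active
feature, without penalty, by L-BFGS on the smooth likelihood. Surfaces use
the penalized fit; response-curve readouts use the relaxed one.

**Variable contributions** are permutation importances, not the path-based
heuristic of the original MaxEnt implementation: both features of a
variable are permuted together across cells, the AUC drop is averaged over
permutations (default 10), floored at zero and normalized to sum to 100. A
variable absent from the model contributes exactly 0%. If no variable
produces a drop, the mass is spread evenly so the sum-to-100 contract
holds. Variables are ranked by mean contribution across species, ties
broken alphabetically; the top 10 are kept for the downstream stages.

## Overlap, PNO, niche history, DTT

**Overlap.** `D = 1 − ½Σ|p−q|` and `I = 1 − ½Σ(√p−√q)²` over the cells
valid in both surfaces, each surface renormalized over that common set so
the unit-mass premise holds. Both indices are clipped to [0, 1] against
floating-point drift. The matrix CSV rounds to 2 decimals; internals keep
full precision.

**PNO.** Bin edges come from the variable's global min/max over its valid
study cells — shared by all species so profiles, reconstructions and
disparity values are comparable on one axis (per-species ranges would
decouple the axes). Bins are half-open with the last closed; masses are
renormalized (a no-op unless a custom `bin_range` clips mass). Draws return
bin midpoints; uniform within-bin jitter is an option. `gaussian_profile`
builds the profile of a parametric Gaussian tolerance curve directly, which
is how the recovery tests construct profiles with known truth.

**Brownian reconstruction.** Ancestral states are Gaussian conditional
expectations given the tips, computed by two-pass message passing on the
tree (upward precision-weighted pruning, downward fusion). This equals
brute-force GLS with the explicit phylogenetic covariance matrix — asserted
to 1e-8 against an independent oracle. The rate σ² is the ML estimate,
`Σ(standardized contrasts²)/n` (REML's `n−1` is not used; the divide-by-n
convention matches the maximum-likelihood framing; estimates of node states
do not depend on σ²). Tip-value uncertainty is propagated by repeating the
reconstruction over replicate PNO draws (default 100) and summarizing each
node by the mean and the 80% central-density interval across draws. That
interval reflects PNO-sampling spread only — it is *not* a confidence
interval for the ancestral state, and its coverage of a known root state is
near-nominal only when tolerance widths exceed the BM-accrued spread (the
regime of the generator defaults; see below).

**DTT.** Disparity is the mean *squared* pairwise difference among terminal
taxa (the mean absolute difference is a config switch; the squared form
follows the method's standard implementation and is what the curve figures
describe). The curve value at a node's age is the mean, over the lineages
alive just after that age, of their terminal disparity divided by
whole-tree disparity; the root point is 1 by construction and the curve is
anchored at (1, 0). Tied node heights collapse to one time point. The null
re-simulates tip values under BM on the same fixed tree (rate and root from
the observed tips) and evaluates curves at the observed node times; MDI is
the trapezoid integral of observed minus null-median over relative time.
Clade-based DTT extracts each clade's subtree (re-rooted at the clade MRCA,
branch lengths preserved, its own relative time scale — each subtree spans
[0, 1] independently) and requires at least 3 tips; smaller clades are
skipped with a warning. Whole-tree DTT tip values are the
suitability-weighted PNO means; a per-draw mode attaches the MDI
distribution across PNO draws instead.

Degenerate inputs: all-equal tip values are rejected ("degenerate trait");
the null simulator re-draws the measure-zero event of a constant simulated
dataset.

## The synthetic-data generator

The generator emulates the study inputs at desk scale:

* **Climate layers** — independent Gaussian random fields (white noise
  smoothed by an isotropic Gaussian kernel, default length 6 cells,
  restandardized), affinely rescaled to bioclim-like ranges (temperatures
  in 0.1 °C, precipitation in mm): mean at the range midpoint, sd a sixth
  of the range width. Default grid 60×80 at 0.0417° resolution.
* **Tree** — a crown Yule process (splits at rate λ per lineage, default 1)
  run until `n_taxa` lineages plus one further exponential wait, rescaled
  to the configured height (default 10 Myr, a root age in the range of the
  motivating radiation). Clades are the 4 oldest subtrees, monophyletic by
  construction.
* **Niches** — per-variable optima evolve by Brownian motion along the
  tree. The rate is parameterized as `bm_sd_frac` (default 0.12): the sd
  accrued over the whole tree height as a fraction of the variable's range
  width. Tolerance widths are `tau_frac` (default 0.25) of the range width.
  These two defaults encode the empirical regime of the study system —
  species' tolerance profiles are broad and heavily overlapping relative to
  the spread of species' optima — and were fixed once, by a design-stage
  power analysis, before the statistical tests were frozen.
* **Occurrences** — cells drawn proportional to the Gaussian-response truth
  surface, without replacement (Gumbel top-k), placed at cell centers:
  spatially unique by construction. Default 30 points per species, minimum
  10 enforced.

What it does **not** emulate: geographic range structure (suitability
depends only on climate, so allopatric look-alike species and the very high
AUCs of real range-restricted species do not arise), topography and
elevation gradients, sampling bias, correlated climate layers, and niche
multimodality. Passing tests therefore demonstrate the estimators' internal
correctness and calibration under a clean generative model, not performance
on museum-record data.

## Numerical choices and limitations

* Grids are stored north-to-south (ASCII-grid convention); point-in-cell
  uses the half-open floor rule, so snapping is deterministic on
  boundaries. Readers reject malformed input rather than repairing it;
  write∘read is the identity (floats are written with shortest-exact
  `repr`).
* Surfaces must sum to 1 within 1e-9 at construction; overlap/PNO
  renormalize explicitly whenever a mask or bin range removes mass.
* Ultrametricity tolerance is 1e-6 × tree height; the error names the worst
  tip. Trees must be binary.
* Every stochastic operation takes an explicit seed or Generator; the
  pipeline derives per-stage, per-species generators from the master seed
  by CRC32 hashing of the labels, so a rerun is byte-identical and adding a
  species does not shift another species' stream.
* Scale choices in the statistical tests (replicate counts such as 50
  coverage replicates, 100 MDI datasets × 200 null simulations, 5 recovery
  datasets) were sized to keep the default suite fast while leaving the
  Monte-Carlo margins measured at design time; the ENM recovery check
  compares the median error across replicate datasets because single
  landscape realizations are heavy-tailed.
* Known limitations: no Ornstein–Uhlenbeck or rate-shift alternatives to
  the BM null; no niche-equivalency permutation tests; no hinge/product/
  threshold features, clamping, or projection onto other regions or past
  climates; no raster projections beyond WGS84 lon/lat.
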