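# Methods

## Model and assumptions

Two spot populations are modeled as marked point patterns inside a window
Ω (the cell mask). The null hypothesis is complete spatial randomness
(CSR) of channel 2 given channel 1: channel-2 points uniform and
independent in Ω. Coupling is the alternative where a fraction of
channel-2 objects sit at a characteristic distance from channel-1
objects. The method does not model within-channel clustering beyond what
the Monte-Carlo null conditions on (channel-1 positions are held fixed),
and it treats coupling as isotropic: only distances enter, not
directions.

Distances are partitioned into K concentric rings
0 = r₀ < r₁ < … < r_K (half-open binning [r_{k−1}, r_k); a distance
exactly on a boundary belongs to the outer ring). Per ring the
edge-corrected bivariate Ripley statistic is

    K̂ₖ = |Ω| / (N₁·N₂) · Σ w_ij     over pairs with r_{k−1} ≤ d_ij < r_k,

whose CSR expectation is the ring measure Aₖ (area in 2D, shell volume in
3D). The construction of coupling probabilities from ring excesses —
pₖ = (K̂ₖ − Aₖ)/K̂ₖ in significant rings, pair and per-spot probability
sums, probability-weighted distance moments, Šidák-corrected one-sided
ring test, global p-value 1 − (1 − Φ̄(maxₖ Gₖ))^K — is this package's
fixed statistical contract; all tests target it.

The reported coupling distance is the probability-weighted mean ± weighted
sd of retained pair distances and is labeled as such: random pairs that
fall inside significant rings contribute their ring's probability, so the
estimate is a mixture mean, slightly biased toward ring centers when
rings are wide relative to the true jitter.

## Edge correction

w(x, d) is the reciprocal of the fraction of the circle (2D) or sphere
surface (3D) of radius d centred at x that lies inside Ω, evaluated at
the channel-1 member of each pair (channel 1 is the reference
population; the transposed analysis is available as a second run). The
fraction is measured by testing mask membership of M equally spaced
surface points — M = 360 angles in 2D, M = 512 Fibonacci-sphere
directions in 3D — and floored at 0.05, capping w at 20 so that thin
processes (neurites) cannot contribute unbounded variance. Two numerical
choices matter:

- the 2D angles are offset by half a step, (m + ½)·2π/M, so axis-aligned
  mask edges are never sampled exactly on the boundary, which keeps the
  symmetry-forced values (w = 2 on a straight edge, w = 4 at a square
  corner) exact rather than tie-dependent;
- a Euclidean distance transform of the mask gives an exact fast path:
  when d plus one pixel diagonal is below the distance to the nearest
  background pixel the circle cannot leave Ω and w = 1 without sampling.
  This changes nothing statistically — it is the same estimator — but
  makes dense-pattern nulls tractable.

Membership of a continuous point is membership of the pixel containing it
(floor of coordinate / pixel size); points outside the grid are outside
the mask.

## Null model and calibration

Ring standard deviations come from a seeded Monte-Carlo null: channel-1
positions fixed, channel-2 redrawn B times uniformly in Ω (implemented as
a uniform choice of foreground pixel plus uniform jitter inside the
pixel, which is exactly uniform on Ω), recomputing the full weighted
statistic each time. The ring score is Gₖ = (K̂ₖ − Aₖ)/σₖ, i.e. centred
on the analytic expectation with MC spread; the MC mean is itself checked
against Aₖ (unbiasedness) by the test suite. σ is floored at 1e-12 so
degenerate rings yield huge negative scores and contribute nothing.

B defaults to 500 in the API. The benchmarks and tests run B = 200
(B = 100 at SMLM density); an explicit convergence check (B = 100 vs
B = 1000, same seed) bounds the sd estimation error at ~25%, which moves
the Šidák threshold by far less than one ring sd. With ten 30 nm rings
and N = 300 per channel, inner rings hold Poisson-level counts whose
right-skew inflates the one-sided tail slightly above nominal; the
measured type-I error sits near 0.06–0.07 at α = 0.05, inside the
acceptance band. At SMLM density (N = 5000) counts per ring are large and
calibration tightens.

## Defaults and units

All coordinates are physical nanometres; the origin is the corner of
pixel (0,0) and pixel centres sit at (i + ½)·pixel size. Defaults:

| parameter | default | rationale |
|---|---|---|
| rings | 30 nm width up to 300 nm | protein-complex length scales; ~1 px rings for conventional images |
| α | 0.05 | conventional test level |
| B (null resamples) | 500 | sd stable to a few % |
| detection scales | {2} | spot diameters ~2–6 px |
| k·σ threshold | 3.0 | MAD-based σ, robust to spots in the tail |
| min spot size | 2 px | rejects single-pixel noise |
| K-means classes | 3 (sweep from 2) | counterstain bg/dim/bright |
| mask closing radius | 2 px | fills staining holes |
| weight cap | 20 | bounds neurite-edge variance |

The association flag used only for map coloring is Pᵢ > 0.5; tabulated
counts use the probability sums, not the flags.

## Segmentation

Thresholds come from 1D Lloyd K-means on a 256-bin intensity histogram
with deterministic quantile initialisation — affine-covariant, fast, and
reproducible, unlike per-pixel K-means with random starts. The pipeline
uses the K-sweep variant: try K = 2 upward and keep the smallest K whose
largest component fits the size bounds. The flat variant with K = 3 and
top-2 foreground classes is appropriate for counterstains with a genuine
dim-intermediate class, but on strongly bimodal images it splits the
background and floods the mask, which is why the sweep is the pipeline
default.

## Synthetic data: what it emulates, what it does not

The generator produces a binary mask (rectangle, disk, or a dilated
random-walk neurite of 500 lattice steps and 4 px radius), N₁ channel-1
points uniform in the mask, and N₂ channel-2 points of which round(q·N₂)
are placed at distance |N(d_c, σ_c²)| from a uniformly drawn channel-1
partner in a uniform direction; directions are resampled until the point
falls inside the mask, so the distance law is preserved conditional on
feasibility. Baseline study conditions: 10 × 10 µm rectangle at 100 nm
pixels, N₁ = N₂ = 300, q = 0.5, d_c = 50 nm, σ_c = 10 nm. Rendering
splats each spot as a Gaussian PSF (σ = 1.5 px, integral =
photon_scale · intensity) over a uniform background with Poisson shot
noise.

Not emulated: SMLM blinking/repeat localizations, drift, astigmatic 3D
PSFs, within-channel clustering, and intensity-dependent localization
precision. Passing tests therefore demonstrate the statistics are correct
under the stated point-process model, not that detection or calibration
survive every artifact of real acquisitions.

Benchmark problem sizes (the package's own choices): detection quality
uses 40 spots ≥ 6 px apart on a 128 × 128 px field (peak SNR ≈ 18) —
sparse-labeling density; on much larger empty fields the k = 3 threshold
admits occasional noise components, which is the documented
false-positive behavior of a fixed-k detector, not a benchmark target.
Type-I error uses 200 CSR datasets (20 at SMLM density in a 20 × 20 µm
window); recovery uses q ∈ {0.2, 0.5, 0.8} × d_c ∈ {30, 80} nm with 10
seeds per cell.

## Degenerate inputs and tie-breaks

All-zero images detect zero spots (not an error); masks that come up
empty after size filtering raise "no cell found"; histograms with fewer
distinct values than classes raise "degenerate histogram". Pairs at
exactly a ring boundary go to the outer ring. Coincident points (d = 0)
get weight 1. When no ring is significant the result is n_coupled = 0,
coupling fractions 0, distance moments NaN, p-value from the maximal
(possibly negative) ring score. The global p-value is computed via
log1p/expm1 so self-colocalization yields values far below 1e-6 without
underflow to an uninformative constant.

## Known limitations

- The ring test treats rings as independent (Šidák); rings share the
  same channel-1 pattern so scores are weakly dependent, and inner-ring
  count skew makes the test slightly liberal at sparse density (measured,
  see above).
- The coupling-distance estimator inherits ring granularity; rings much
  wider than the true jitter bias the mean toward ring centers.
- Edge-correction sampling is exact only up to the M-direction
  quadrature and the pixel-membership rule; weights are capped at 20.
- The hierarchy in the mask sweep is a single size-criterion loop, not a
  full per-component recursive split.
- 3D rendering of synthetic images is not implemented (3D analyses accept
  point tables and 3D masks directly).
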