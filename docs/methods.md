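# Methods

This note documents the models implemented in `transcoloc`, the
assumptions behind them, the defaults and numerical choices, and what the
synthetic-data generator does and does not emulate.

## Imaging model and spot detection

Transcripts labelled by tiled single-fluorophore probes appear as
diffraction-limited spots. The detection chain is the standard smFISH
sequence: maximum projection over Z, background subtraction, Gaussian blur
(σ = 1 px by default) for signal-to-noise, local-maximum candidate
detection, and a least-squares 2D Gaussian fit (amplitude, centre,
isotropic width, offset) in a 7-px window per candidate. Total spot
intensity is the fitted Gaussian mass `amp · 2π σ²`; positions are
converted to nm with the 106.3-nm pixel. On 3D stacks the axial centre and
width are fitted separately from the per-plane profile (anisotropic PSF);
the lateral analysis stays on the projection.

Quality thresholds reject non-specific signal: fitted width within
0.6–2.5 px and a minimum amplitude. Numerical choices worth recording:

- The default peak threshold is median + 5 robust SD (1.4826·MAD) of the
  blurred image. Inside the full `detect_spots` pipeline the noise scale
  is estimated on the *unclipped* background residual: the clipped
  non-negative image underestimates the MAD roughly twofold and admits
  noise maxima.
- A matched Gaussian blur halves the peak of a σ = 1 px spot, so accepted
  fits must additionally have an (unblurred) amplitude of at least twice
  the blurred-peak threshold. This amplitude floor is what keeps precision
  high; the width floor could then be relaxed to 0.6 px, because at
  realistic noise the fitted width of a genuine σ = 1 px spot scatters by
  ~0.1 px and a 0.7 px floor costs 2–3% recall for no precision benefit.
- `subtract_background` offers the morphological rolling-ball and a
  Gaussian high-pass ("log" method: image minus a wide Gaussian blur, the
  band-pass a Laplacian-of-Gaussian stage effects in FISH pipelines,
  implemented in the form that preserves spot amplitude). Both are
  invariant to constant offsets and map flat images to ~0.
- Candidate maxima closer than the 3-px separation keep the brighter one.

On rendered fields at peak SNR ≈ 6 (100 spots, 512² image) this chain
achieves precision and recall ≥ 0.95 with localization RMSE < 0.3 px.

## Single-mRNA intensity calibration

Spot intensities pool single transcripts and clusters, so the pooled
histogram is fitted with a sum of K Gaussians sharing one baseline,

y = y0 + Σ_k A_k/(w_k √(π/2)) · exp(−2 (x − x_ck)² / w_k²),

by weighted least squares (Poisson bin errors, σ = √count floored at 1).
Component centres are free, initialized by multi-start at integer
multiples of the histogram mode and at data quantiles; K is selected by
BIC over 1..6 when not forced. The single-mRNA intensity is the centre of
the lowest-centre component whose area amplitude is at least 10% of the
largest.

Numerical choices:

- Bin width follows Freedman–Diaconis but is capped so the histogram has
  at least 60 bins: multimodal pools have a large IQR and the raw FD width
  can bury the single-molecule component in one or two bins.
- Free-centre mixtures occasionally split a skewed first peak into two
  near-coincident components. Components whose centres lie within one
  component width are therefore merged (area-weighted) before extraction —
  two Gaussians that close are not resolved as distinct copy-number
  classes.
- A numerically constant sample short-circuits to a single degenerate
  component at that value.

On pooled samples of n = 2611 spots from a copies-1..6 mixture with 15%
multiplicative intensity noise, the unit intensity is recovered within 4%
(max over 20 generator seeds; median ≈ 1%). Copy numbers are assigned as
`max(1, round(intensity / single))`; at 15% noise this is reliable for
small clusters (≥ 90% exact for copies ≤ 3) but necessarily degrades for
large ones, where the absolute intensity noise exceeds half a unit — a
limit of the measurement, not of the estimator.

## Chance-corrected association

Matching is greedy nearest-first one-to-one per cell: candidate pairs
within the criterion distance are sorted by centre distance (ties broken
by spot indices) and accepted while both spots are unused. On sparse
random fields this equals the maximum-cardinality matching (checked
against an exhaustive oracle); it is symmetric in channel order by
construction of the distance sort. Triples attach an unused protein spot
to an accepted pair when it lies within the criterion of either centroid,
again greedily by distance.

Expected-by-chance counts use the stated union-area form
E_m = N₁N₂(2πr² − I)/A with the disc radius r = mean fitted FWHM/2 and
per-cell N₁, N₂, A. Two properties of this form matter in practice:

- It increases strictly with d only up to d = 2r and is constant beyond
  (I = 0 there), so criteria coarser than the spot diameter share one
  expectation.
- It is **not** the expectation of chance centroid matches at distance d;
  for sparse uniform fields that is ≈ N₁N₂πd²/A, which the union form
  exceeds several-fold at sub-diameter criteria. The union form is kept as
  the default for fidelity to the published analysis; the classical
  encounter-area null is available via `null="classical"` and is the
  correct reference when validating the *statistical calibration* of the
  paired t test on simulated uniform fields (type-I rate 0.05–0.08 at
  α = 0.05 in 200-replicate simulations; power ≈ 1.0 for a planted 25%
  fraction across 40 cells).

Significance per criterion is a paired two-tailed t test of observed vs
expected across cells, Bonferroni-corrected by the number of criteria.
Degenerate zero-variance differences follow a count-data rule: all ties →
p = 1; a constant shift of ≥ 1 particle per cell → p = 0; a constant
sub-unit shift (identical integer counts against a fractional
expectation) cannot be distinguished from ties and gives p = 1.

The analyzed area A passed to the model should be the region the spots
can occupy; for simulated cells that is the cytoplasm (cell minus
nucleus). Using the full cell area inflates observed-over-expected by the
nuclear area fraction.

## Spatial profiles

Distance from the nucleus is the Euclidean distance from the spot
centroid to the nearest nucleus-boundary pixel centre (exact nearest-
neighbour query), zero inside the nucleus — projected signal can overlie
the nuclear edge. Profiles are normalized histograms with 5-µm bins, with
exact cumulative fractions at query radii; the area-weighted null profile
(distance distribution over cytoplasm pixels) validates the geometry
handling against uniform placement.

## Correlation

Pearson R = Cov(x, y)/(σx σy) with significance from the regression F
statistic R²(n−2)/(1−R²) on (1, n−2) df (upper tail — identical to the
two-sided t test on the slope); Spearman ρ applies the same formula to
mid-ranks with a two-tailed t approximation. The product σx·σy in the
denominator is the only reading under which R ∈ [−1, 1]; a subtraction
there (as sometimes typeset) is dimensionally and numerically
impossible, and is treated as a typo. |R| within 1e−12 of 1 is snapped to
±1 so exactly monotone data report p = 0.

## qPCR relative expression

2^−ΔΔCt with technical replicates averaged at the Ct level, ΔCt within
(sample, condition) against the reference gene, ΔΔCt within biological
replicate against the control condition. Replicate standardization —
natural-log transform, per-replicate mean centering and autoscaling to
unit SD — absorbs the scale variability of independent differentiations;
control-condition folds (identically 1 by construction) are excluded from
the standardized set as they carry no information. Summaries report both
the standardized-scale mean with Student-t 95% CI (n_bio − 1 df) and the
back-transformed geometric-mean fold with its CI; with 6 biological
replicates and 0.2-cycle Ct noise a 50% knockdown's CI excludes 1.

## Voltage clamp

Activation and availability are fitted exactly in the printed forms (see
README). With the exponent (V − V_half)/k, activation rising with
depolarization implies k < 0; results report |k| plus a direction flag.
The availability form tends to I_min for strong hyperpolarization — the
printed orientation, retained verbatim; conventional availability curves
are obtained by data orientation, not by silently altering the model.
Fits are multi-start nonlinear least squares (V_half seeded at the
half-amplitude voltage, k ∈ {±3, ±7, ±15} mV); the reversal potential can
be fixed from the recording solutions, which is the recommended (and
tested) configuration for I–V fits — with 9 voltage points and 5% noise,
the free-V_rev fit leaves V_half underdetermined by ~1 mV.

Steady-state current is the mean over the final 5 ms of the step; tail
and peak currents are signed extrema within their epochs (polarity
configurable). The late-current integral is the trapezoidal charge over
50–800 ms from pulse onset in pA·ms, with interpolated window endpoints
so constant currents integrate exactly; the zero-current baseline comes
from the 10-ms pre-pulse holding segment (configurable), since amplifier
offset would otherwise bias the integral. The transient-outward current
analysis reuses the steady-state + activation-fit path; no separate code
exists for it.

## Synthetic-data generator

The generator emulates, per cell: an elliptical cell with an 8-µm round
nucleus on a 512×512 grid at 106.3 nm/px (200 nm Z); cytoplasmic spot
placement with probability ∝ exp(−distance-to-nucleus/λ), λ = 10 µm by
default (∞ = uniform); per-cell counts fixed or drawn from a range
(5–200 spans the observed biology), optionally rank-correlated between
the paired species via a Gaussian copula; cluster sizes from a mixture
anchored at ~25% singles and ~20% in clusters of ≥ 6 transcripts with
smoothly decaying intermediate classes (the intermediate values are a
modelling choice; only the two anchor fractions are constrained by
observation); intensity = copies × unit × lognormal(mean 1, CV 15%);
a planted colocalized fraction f of species-A spots given a partner
uniformly within one pixel (round(f·N_A) pairs exactly), optionally
extended to planted protein triples. Images are rendered as
pixel-integrated Gaussians (erf-based, exact to < 0.1%) plus Poisson
noise, 16-bit unsigned; noiseless rendering returns the float
expectation. Ct tables follow Ct = ct_ref − log₂(fold) + N(0, σ) with an
optional shared per-prep offset; sweep families relax exponentially to
the Boltzmann steady state with optional late plateau and white noise.
All randomness in a generator call flows from one `numpy` Generator
created from its seed; outputs are bit-reproducible.

Not emulated: probe hybridization chemistry, photobleaching, camera gain
beyond Poisson statistics, chromatic offsets between channels, 3D spot
overlap in thick cells, ER ultrastructure, primer efficiencies, series
resistance or capacitance transients. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical structure, not
robustness to these instrument effects.

## Problem sizes

Tests and the acceptance script run the study-scale configurations:
40-cell fields at ~100 spots/channel/cell for association recovery (10
seeds per planted fraction; 200 replicates for the type-I rate), pooled
n = 2611 intensities × 20 seeds for calibration, 100-spot rendered 512²
images for detection, n = 41 cells × 500 replicates for correlation
recovery, and 20–40 noise replicates for the Boltzmann round-trips.
These sizes keep the full suite under a minute of compute per stage.

## Known limitations

- The union-area chance model is reported verbatim; its inferential
  calibration against uniform randomness is poor by construction (it
  overstates chance at tight criteria), which is documented rather than
  corrected by default.
- Greedy matching can in principle fall below the maximum matching on
  adversarial configurations; at smFISH densities this was never observed
  in randomized checks.
- Copy-number assignment saturates in accuracy for large clusters at
  realistic intensity noise (see calibration section).
- The 2D analysis ignores axial distance in colocalization; criteria are
  projected distances, as in projection-based workflows.
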