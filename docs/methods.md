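# Methods

## The model

A dendritic spine's head outline is represented as a closed 2D polyline
Γ of n vertices **x**¹…**x**ⁿ (micrometres, y up).  Two contiguous vertex
stretches are pinned: the postsynaptic density (PSD) at height h_PSD and
the neck at h_neck; all other vertices move overdamped,

    d**x**ᵏ/dt = ζ (**F**_mem(**x**ᵏ) + **F**_fil(**x**ᵏ)),

with mobility ζ.  **F**_mem = −∂E/∂**x**ᵏ is the analytic gradient of the
discrete Helfrich free energy

    E = P·Ω + τ·L + 2κ Σₖ Hₖ² Δsₖ,

where Ω is the enclosed area (shoelace), L the contour length, and Hₖ the
turning angle at vertex k divided by the mean adjacent edge length (a
second-order polyline curvature that converges to 1/r on a sampled
circle).  A free circular contour has the closed-form energy
P·πr² + 2πτr + 4πκ/r, whose stationary radius solves
P r³ + τ r² − 2κ = 0; both identities are used as test oracles.

Actin pushes through *polymerization foci*.  A focus nucleates near the
PSD with probability γ_f·Δt per step (uniform along the PSD, half-Gaussian
offset into the head, scale σ), carrying one filament.  Every filament has
an uncapped barbed (+) end; per step each filament independently

* branches with probability γ_branch·Δt (new filament, minus end capped),
* caps its barbed end with probability γ_cap·Δt (filament removed),
* uncaps its minus end with probability γ_uncap·Δt (if capped),
* is severed with probability γ_sever·Δt (if its minus end is uncapped),

and every barbed end adds one monomer, so the per-step polymerization
count equals the barbed-end count B.  The branching rate carries the
force feedback

    γ_branch = φ k_on δ a · exp(−|F_mem| δ / (k_B T B)) / B,

a Brownian-ratchet slowdown of the treadmilling velocity under the local
membrane load |F_mem| shared by B barbed ends.  |F_mem| is read out as the
kernel-weighted mean force magnitude Σ wₖ‖**F**_mem(**x**ᵏ)‖ with
normalized Gaussian weights around the focus's membrane contact point.
The force field of a focus on vertex k is W(‖**x**ᵏ−X_c‖)·B·V with
W(r) = α/(σ√2π)·exp(−r²/2σ²) and V the unit vector from the nucleation
point X_n to the vertex.

Two readings of the kernel centre X_c are implemented.  The default
tracks the membrane vertex nearest X_n — the filament network's contact
point — clipped to a maximum span (`reach`) from X_n, because actin
filaments are a few hundred nanometres long.  This keeps the pushing and
the force sensing co-located for arbitrarily large deformations; with a
static centre (`kernel_center="static"`), a sustained avalanche can push
the wall beyond the kernel's range, the sensed force collapses while a
weak push continues, and the feedback loop silently dies, which lets
hour-long runs ratchet into unbounded growth.

The *non-feedback* control model freezes |F_mem| = 7 pN and B = 4 inside
γ_branch, making branching a constant-rate process.

PSD and neck remodel slowly: eight independent Bernoulli(γ·Δt) events per
step (γ = 1/75 s⁻¹ each) elongate/shrink the PSD at either end, move the
whole PSD up/down by d_mov = d_min, and grow/shrink the neck
symmetrically so the neck centre (the shape-descriptor origin) stays put.
PSD/neck changes are applied after the actin dynamics.

### Why this parameter point

The published lineage of this model defers its numerical constants to an
earlier study's supplementary table that is not available, so the
defaults were fixed once from order-of-magnitude physics plus the two
anchors the model itself states, and then frozen:

* k_BT = 4.114·10⁻³ pN·µm, δ = 2.7 nm (one actin monomer),
  k_on·a ≈ 11.6 s⁻¹ (µM-scale profilin-actin), so the zero-force
  treadmilling velocity k_on δ a ≈ 31 nm/s — with Δt = 0.1 s and one
  monomer per barbed end per step, δ/Δt = 27 nm/s, consistent.
* The resting-shape anchor: the local membrane force at likely nucleation
  sites of the relaxed shape is a few pN (the control model is anchored
  at 7 pN).  With τ = 5 pN, P = 8 pN/µm², κ = 0.02 pN·µm the measured
  resting value is ≈ 4–5 pN.
* The criticality anchor: the per-focus branching/death ratio
  λ/μ = C e^{−0.656 F/B}/(γ_d B) (C = φ k_on δ a, 0.656 = δ/k_BT per pN)
  is maximal at B* = 0.656·F — the control model's (F = 7, B = 4) sits at
  that maximum.  φ = 151 µm⁻¹ puts the feedback model marginally
  supercritical at the resting force, so membrane deformation sweeps the
  foci back and forth across criticality (the self-organized-critical
  mechanism), while the frozen-force control model sits safely
  subcritical (λ/μ ≈ 0.9).
* γ_cap = γ_sever = 0.5 s⁻¹, γ_uncap = 0.05 s⁻¹ set the filament
  turnover time to ~2 s, which reproduces the reported avalanche-lifetime
  statistics at Δt = 0.1 s; γ_f = 0.3 s⁻¹ leaves the spine quiescent
  roughly half the time, giving well-separated avalanches.
* ζ = 0.05 µm/(pN·s) makes a focus-sized bump relax in a few seconds,
  between the barbed-end correlation time and the 10-s sampling grid.

This single calibration was performed against the reference simulation
statistics (mean 1/f exponent, avalanche-lifetime exponent, area
correlations, tendency-label shares) and then frozen; no per-quantity
retuning was done afterwards.

## Numerics

* Explicit Euler with mechanical substepping: stochastic events advance at
  Δt = 0.1 s; the membrane integrates with substeps Δt/n_sub because
  explicit stability requires ζ·Δt_sub·k_max ≲ 1 with k_max ≈ 64κ/ℓ³ for
  edge length ℓ.  The substep count adapts to the current shortest edge
  (capped at `n_substeps`), and the step is split into four chunks with
  mesh maintenance (remeshing, contact resolution) between them.
* Remeshing keeps every edge in [d_min, d_max] = [0.018, 0.054] µm by
  midpoint merges and splits; pinned vertices are never deleted.
* Excluded volume: non-neighbouring vertex pairs closer than 2.5·d_min
  are pushed apart (jitted sort-and-sweep).  Without it, the opposite
  walls of thin protrusions pass through each other; self-intersection is
  still *checked* every 100 steps and aborts the run with the step index
  rather than being silently repaired.
* The contour may not dip below the neck plane (the spine is attached to
  the dendrite there), and a run aborts if the contour exceeds 900
  vertices — tens of micrometres of outline cannot fit a spine's membrane
  reservoir, so such a state is outside the model's validity envelope
  (feedback-model runs peak near 450).
* The resting shape is the constrained minimum of the Helfrich energy: a
  stadium-like seed polygon minimized by L-BFGS with the analytic
  gradient plus a weak shape-neutral edge-uniformity spring (the discrete
  energy is indifferent to tangential vertex spacing, which would
  otherwise collapse).  The spring is weakened geometrically with a
  backtracking floor; convergence is declared on the *normal* component
  of ζ·Δt·F.  Dynamic stepping never uses this path.
* The jitted force kernel mirrors the reference numpy implementation to
  machine precision (tested).

## Shape descriptors

From the neck centre, 24 rays at 15° sample the outline distance
dROI(θᵢ) (farthest intersection; 0 on a miss).  Trigonometric
interpolation on the 24 regular angles gives coefficients A₀..A₁₂,
B₁..B₁₁ exactly; terms with standardized coefficient below 0.1 are
dropped one by one, weakest first, each drop accepted when an
extra-sum-of-squares F-test at level 0.1 finds no significant change.
When the current model still interpolates the data exactly (zero
residual), the classical F statistic is 0/0, so the drop is judged
against the restricted model's own residual variance instead.  The
retained series splits into S = A₀ (size), D(θ) = odd harmonics
(directional selectivity) and O(θ) = even harmonics (orientational
selectivity), which are averaged as

    D = (1/2π)∫|D(θ)|dθ · 100/S,      O = (1/π)∫₀^π |dO/dθ| dθ · 100/S,

in percent of S and percent of S per radian respectively (the derivative
in O is what yields the per-radian unit; the literal |O(θ)| reading is
available via `o_derivative=False`).  Trapezoidal quadrature on ≥ 2048
nodes keeps the quadrature error below 0.1 %.

## Time-series analyses

*Tendency*: ARIMA(p,d,q) with p,d,q ∈ {0,1} in the auto-ARIMA spirit — a
KPSS unit-root pretest fixes d, the four (p,q) candidates compete by AIC,
and the winner must have residuals that pass an augmented Dickey-Fuller
test (trend regression, lag 0, p < 0.01) without ACF/PACF spikes beyond
the 95 % band in the first ten lags; otherwise all eight orders compete.
Labels: WN (0,0,0), RW (0,1,0), AR (1,0,0), ES (0,1,1).

*1/f detection*: 1/f noise lies between white noise (spectral exponent
α = 0, ARIMA d = 0) and a random walk (α = 2, d = 1), so fractional d is
estimated by ARFIMA(1,d,1).  The estimator is an approximate Gaussian MLE:
the demeaned series is fractionally differenced with the binomial weights
of (1−L)^d truncated at min(N, 100) lags, and a conditional-sum-of-squares
ARMA(1,1) likelihood is maximized over (d, ar, ma) (L-BFGS-B, multiple
starts); se(d) comes from the numerical observed information with the
asymptotic √(6/π²N) fallback.  The series is called 1/f when d is
significantly positive (one-sided z, 5 %) *and* the ARFIMA AIC undercuts
an ARIMA(1,0,1) fitted with the same likelihood machinery (one common
scale; the lower-is-better reading follows the reference analysis's own
printed AIC values).  α = 2d.

*Avalanches*: maximal runs of nonzero total barbed ends; size = summed
barbed ends over the run (= polymerization events), duration in steps,
η = gap to the previous avalanche; truncated boundary runs are excluded
from fits.  Exponents use the continuous Pareto MLE
α = 1 + n/Σln(xᵢ/x_min) with se = (α−1)/√n; x_min defaults to the
minimum observed value (the convention under which the reported lifetime
exponent is reproduced), with fixed or KS-scan selection available.  The
log-log linearity screen fits a line to the log-binned density (bins with
≥ 10 samples) and reports R².

## The synthetic generators

`SyntheticShapeSpec` polygonizes r(θ) = base + Σ aₖcos kθ + bₖ sin kθ
about the neck centre, so the descriptor ground truth is known in closed
form.  `SurrogateSeriesSpec` draws white noise, random walks, AR(1), or
fractionally integrated ARMA noise (truncated (1−L)^{−d} weights, 500
samples of burn-in); `sample_power_law` inverse-transforms
x = x_min(1−u)^{−1/(α−1)}.  All generators are deterministic under a
fixed seed.  These surrogates emulate the *statistical* structure the
analyses assume — they contain no imaging noise, segmentation error, or
optical blur, so passing tests demonstrate estimator correctness, not
robustness to microscopy artefacts.

## Problem sizes used by the test suite and the acceptance script

The reference analysis uses ten 60-minute simulations.  The package's
acceptance script runs eight 60-minute replicates (about 10–15 minutes on
one CPU) and the test suite four, plus an LTP experiment with five
replicates per arm over 18 minutes (reference: thirty per arm, 25-minute
window) and 100-seed recovery checks for the detectors.  Estimator checks
(ARFIMA recovery, power-law recovery) use n = 2000 and n = 10⁴ samples.

## Known limitations

* The trade-off between the area series' long memory (1/f exponent) and
  the instantaneous area–barbed-end correlation is steeper in this
  implementation than in the reference account: parameter points that
  reproduce α ≈ 0.7–0.9 give a per-step Pearson correlation of ≈ 0.35–0.55
  rather than ≈ 0.68.
* At desk-scale sample sizes the log-binned distributions of both model
  variants look similarly straight; the expected straight-vs-curved
  contrast between feedback and control would require far larger pooled
  avalanche counts than the scaled runs provide.
* The control (non-feedback) model equilibrates at a several-fold larger
  spine than the feedback model, because nothing couples its constant
  branching back to the membrane state.  Its runs are correspondingly
  slower, and in hour-long runs — or under the tripled nucleation rate of
  the LTP protocol — the control contour can fold into a contact-limited
  labyrinth that eventually self-intersects, at which point the
  simulation aborts by design.  The control model is therefore reliable
  only for runs of roughly half an hour at the baseline nucleation rate.
* 2D contour model: no volume conservation, no membrane-neck fusion, no
  explicit monomer pool; minus-end dynamics are bookkeeping only.
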