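# spinedyn

Dendritic spines — the micron-sized protrusions that carry most excitatory
synapses — visibly change shape on a timescale of seconds, driven by
actin polymerization against the spine membrane.  `spinedyn` is a
biophysical model of these fluctuations together with the statistical
tool-chain used to characterize them:

* **Simulator** — the spine outline is a closed 2D polyline pinned at the
  postsynaptic density (PSD) and at the neck, moving overdamped under the
  discrete Helfrich free energy `E = P·Ω + τ·L + 2κ∮H²ds`.  Stochastic
  *polymerization foci* nucleate near the PSD; each focus is a cluster of
  branched filaments whose barbed-end count `B` both pushes the membrane
  (a Gaussian force kernel) and feeds back on the branching rate through
  a Brownian-ratchet factor, `γ_branch ∝ exp(−|F_mem|δ/(k_BT·B))/B`.
  The feedback keeps the foci hovering around criticality, so the total
  barbed-end count comes in avalanches with power-law size and lifetime
  statistics and the spine area exhibits 1/f noise.  A constant-rate
  control model ("non-feedback") and a structural-LTP protocol (a
  sustained three-fold increase of the nucleation rate) are included.
* **Shape descriptors** — `S` (mean neck-to-outline distance), `D`
  (directional selectivity: odd Fourier harmonics of the outline,
  percent of `S`) and `O` (orientational selectivity: even harmonics,
  percent of `S` per radian), computed by ray sampling every 15°,
  trigonometric regression with F-test pruning, and odd/even splitting.
* **Time-series analysis** — ARIMA tendency classification (auto-ARIMA
  style with a KPSS pretest and residual diagnostics), augmented
  Dickey-Fuller stationarity tests, autocorrelation with 95 % bands, and
  a Wagenmakers-style 1/f test: an in-package ARFIMA(1,d,1) estimator
  whose fractional order gives the spectral exponent `α = 2d`.
* **Criticality statistics** — avalanche segmentation from barbed-end
  traces, power-law exponents via the Pareto MLE
  `α = 1 + n/Σln(xᵢ/x_min)`, log-binned distributions and a log-log
  linearity screen.
* **Synthetic fixtures** — polygons with analytically known descriptors
  and surrogate series (white/random-walk/AR(1)/fractional noise), so
  every analysis is testable without microscopy data.

See `docs/methods.md` for the model equations, parameter rationale and
numerical choices.

## Worked example

```python
import numpy as np
from spinedyn import SimConfig, run_simulation, mesh_to_roi
from spinedyn import descriptors_from_polygon, detect_one_over_f
from spinedyn import extract_avalanches, newman_mle

cfg = SimConfig(duration=1800.0, seed=7, log_events=False)  # 30 min
traj = run_simulation(cfg)

area = traj.sampled_areas                     # every 10 s
print(f"mean area {area.mean():.3f} um^2, CV {area.std()/area.mean():.2f}")

sd = descriptors_from_polygon(mesh_to_roi(traj.snapshots[-1]))
print(f"S={sd.S:.3f} um  D={sd.D:.1f}%  O={sd.O:.1f}%/rad")

verdict = detect_one_over_f(area)
print(f"1/f: {verdict.is_one_over_f}  alpha={verdict.alpha:.2f}")

avalanches = [a for a in extract_avalanches(traj.total_B) if not a.truncated]
fit = newman_mle(np.array([a.duration_steps for a in avalanches], float), 1.0)
print(f"{len(avalanches)} avalanches, lifetime exponent "
      f"{fit.exponent:.2f} +- {fit.se:.2f}")
```

prints

```
mean area 0.406 um^2, CV 0.15
S=0.292 um  D=90.2%  O=66.2%/rad
1/f: True  alpha=0.97
261 avalanches, lifetime exponent 1.35 +- 0.02
```

The spine breathes around 0.4 µm² with 15 % fluctuations.  The large D
reflects the ray origin: measured from the neck centre, a spine head
necessarily extends away from its neck, a strong directional asymmetry;
O picks up the head's elongation.  The area series carries 1/f noise
with a spectral exponent near one, and the avalanche lifetimes follow a
power law with exponent ≈ 1.35 — the self-organized-critical signature.
A single 30-minute run takes tens of seconds; statistics over replicates
(as below) sharpen the exponents toward their ensemble values.

The same analyses run from the shell:

```bash
spinedyn simulate --seed 7 --duration 1800 --out out/run7
spinedyn tendency --series out/run7/series.csv
spinedyn avalanches --traj out/run7
```

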