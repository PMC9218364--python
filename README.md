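# melsum

Silent-substitution stimulus design and phase-summation analysis for
melanopsin–rod–cone psychophysics.

Human vision in mesopic and photopic light is driven by five photoreceptor
classes: L-, M- and S-cones, rods, and the melanopsin-expressing ipRGCs.
Because the melanopsin pathway is slow and insensitive, measuring how it
interacts with rod- and cone-mediated vision requires (i) stimuli that
modulate one photoreceptor class while *silencing* the others, and (ii) an
analysis that can tell whether two pathway signals combine as independent
detectors or as phase-sensitive phasors.  `melsum` implements both halves
for researchers working with multi-primary photostimulators:

* **Stimulus design** — five-primary silent substitution.  With a 5×5
  class-by-primary excitation matrix `E`, background weights `w` and a
  requested signed Michelson contrast vector `c`, the modulation solves
  `E·Δp = c ∘ (E·w)` exactly; residual intrusion under observer spectral
  variability and instrument gamut limits are quantified.  Receptor
  sensitivities come from the Govardovskii A1 pigment nomogram, normalised
  so an equal-energy spectrum at 1 photopic troland gives excitations
  (l, m, s, r, i) = (0.6667, 0.3333, 1, 1, 1).
* **Psychometrics** — method-of-constant-stimuli designs and two-parameter
  Weibull fits, `P(x) = γ + (1 − γ)(1 − exp(−(x/α)^β))`, with the guessing
  rate γ estimated from catch trials and corrected before fitting; the
  threshold α is the 63.21 % point.
* **Summation models** — the threshold ratio TR (combined / individual
  threshold) across relative phase φ is described either by probability
  summation, `TR = n` (reported as `20·log10(1/n)` dB), or by vector
  summation, `TR(φ) = 1 / √(x² + y² − 2xy·cos(φ − φ_xy))`, with one global
  phase difference φ_xy across observers and per-observer sensitivities.
  Model selection uses a repeated-measures ANOVA of TR across phase;
  φ_xy converts to a pathway latency difference via `(φ/360)·(1000/f)` ms.
* **Temporal contrast sensitivity** — difference-of-Gaussians TCSF fits,
  critical flicker frequency at a criterion contrast, Weber (TVI) slopes
  `W = Δ log ΔI / Δ log I`, Ferry–Porter lines, and a saturating
  steady-state photopigment bleach model `p = I/(I + I₀)`.
* **Synthetic observer** — a generative model of the whole study (three
  observers, 200/2000 Td, six photoreceptor-directed conditions, five
  phases, 24 + 6 trials per contrast level) so every stage is testable
  end to end without any external data.

## Worked example

```python
import numpy as np
from melsum import substitution as sub
from melsum.io import RunConfig, run_pipeline

# 17 % melanopsin-directed stimulus at the 200 Td working point
primaries, receptors, w = sub.study_background(200.0)
sol = sub.solve_modulation(primaries, receptors, w, sub.contrast_vector(i=0.17))
print(sol.achieved[4], np.abs(sol.residual).max())
# 0.17000000000000004 2.2518986570738e-16

# simulate and analyse a reduced melanopsin-rod study
report = run_pipeline(RunConfig(seed=7, illuminances_td=[200.0],
                                conditions=["i", "R", "i+R"]))
res = report.classifications[(200.0, 1.0, "i+R")]
print(res.model, round(res.fit.phi_xy_deg, 1), round(res.fit.latency_ms, 1))
# linear 34.5 96.0
```

The melanopsin-directed modulation achieves exactly the requested 17 %
contrast with numerically zero rod/cone intrusion for the nominal observer,
and the synthetic melanopsin+rod study at 1 Hz is classified as *linear*
(phase-dependent) summation with a shared phase difference near the
generative truth of 30.4° — a rod lead of roughly 96 ms at 1 Hz.

The numbered drivers under `analysis/` run the full narrative — stimulus
design and intrusion Monte Carlo (`01`), the complete 1 Hz / 10 Hz phase
summation study (`02`), the contrast-ratio summation squares (`03`), and
the TCSF/adaptation analyses (`04`) — writing small tables to `results/`.

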