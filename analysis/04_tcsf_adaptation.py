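#!/usr/bin/env python
"""Temporal contrast sensitivity and adaptation analyses on synthetic data.

Generates photoreceptor-directed temporal contrast-sensitivity functions
with the qualitative shapes of the measured pathways (melanopsin low-pass
and slow; rod and cone band-pass, cones fastest), fits difference-of-
Gaussians models, extracts critical flicker frequencies at the measurement
contrasts (melanopsin 17 %, rod 15 %, LMS 28 %), and summarises adaptation
behaviour: rod TVI Weber slopes with a photopic break, the cone
Ferry-Porter line, steady-state rhodopsin bleaching, and the photopic to
scotopic troland conversion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from melsum import spectral as sp
from melsum.tcsf import (
    cff_from_model,
    dog_sensitivity,
    ferry_porter_fit,
    fit_dog_tcsf,
    tvi_two_branch,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
RNG = np.random.default_rng(20220603)

# DoG truths (contrast sensitivity vs Hz) shaped after the measured pathways:
# melanopsin slow/low-pass (CS ~ 8 near 1 Hz, imperceptible beyond ~6 Hz);
# rod band-pass peaking near 4 Hz; cones band-pass peaking near 8 Hz.
PATHWAYS = {
    "melanopsin": dict(A=16.0, mu=0.30, sigma=0.50, crit=0.17,
                       freqs=np.logspace(np.log10(0.5), np.log10(5.0), 8)),
    "rod": dict(A=42.0, mu=0.75, sigma=0.55, crit=0.15,
                freqs=np.logspace(0.0, np.log10(25.0), 10)),
    "cone": dict(A=75.0, mu=1.05, sigma=0.55, crit=0.28,
                 freqs=np.logspace(np.log10(1.5), np.log10(45.0), 10)),
}


def main() -> None:
    print("== TCSF fits and critical flicker frequencies ==")
    rows = []
    for name, p in PATHWAYS.items():
        cs = dog_sensitivity(p["freqs"], p["A"], p["mu"], p["sigma"])
        cs = cs * np.exp(RNG.normal(0, 0.06, cs.size))
        fit = fit_dog_tcsf(p["freqs"], cs)
        cff = cff_from_model(fit, p["crit"])
        rows.append(
            {
                "pathway": name,
                "amplitude": round(fit.amplitude, 2),
                "center_logf": round(fit.center_logf, 3),
                "sigma": round(fit.sigma, 3),
                "criterion_contrast_pct": 100 * p["crit"],
                "cff_hz": None if cff is None else round(cff, 2),
            }
        )
        print(f"{name:>10}: peak CS {fit.amplitude * 0.7:5.1f} at "
              f"{10 ** fit.center_logf:4.1f} Hz; CFF at "
              f"{100 * p['crit']:.0f} % contrast = "
              f"{'none' if cff is None else f'{cff:.1f} Hz'}")
    pd.DataFrame(rows).to_csv(RESULTS / "tcsf_fits.csv", index=False)
    print("  (melanopsin CFF of ~6 Hz reproduces its slow, low-pass character;")
    print("   rod and cone CFFs are progressively higher)")

    print("\n== rod TVI: Weber behaviour with a photopic break ==")
    I = np.array([200.0, 400.0, 800.0, 1500.0, 3000.0, 4000.0, 6000.0, 8000.0])
    log_break = np.log10(3000.0)
    log_di = np.where(
        I <= 3000.0,
        -1.0 + 1.05 * np.log10(I),
        -1.0 + 1.05 * log_break + 1.27 * (np.log10(I) - log_break),
    ) + RNG.normal(0, 0.01, I.size)
    tvi = tvi_two_branch(I, 10.0**log_di)
    print(f"branch slopes W = {tvi.slopes[0]:.2f} (to "
          f"{tvi.branches[0][1]:.0f} Td), {tvi.slopes[1]:.2f} beyond; "
          f"break near {tvi.breakpoint_td:.0f} Td")
    print("  (near-Weber behaviour that steepens above ~3000 Td: reduced rod")
    print("   contrast sensitivity without saturation)")

    print("\n== cone Ferry-Porter line ==")
    I_fp = np.logspace(np.log10(20.0), 4, 6)
    cff_cone = 14.0 + 9.0 * np.log10(I_fp) + RNG.normal(0, 0.6, 6)
    fp = ferry_porter_fit(I_fp, cff_cone)
    print(f"CFF = {fp.intercept:.1f} + {fp.slope:.1f} * log10(I) Hz "
          f"(r = {fp.rvalue:.3f})")

    print("\n== adaptation levels: bleach and scotopic trolands ==")
    levels = [100.0, 200.0, 2000.0, 3000.0, 8000.0]
    table = pd.DataFrame(
        {
            "photopic_td": levels,
            "scotopic_td": [round(sp.scotopic_from_photopic(i), 0) for i in levels],
            "bleach_pct": [round(100 * sp.steady_state_bleach(i), 2) for i in levels],
            "rhodopsin_available_pct": [
                round(100 * (1 - sp.steady_state_bleach(i)), 1) for i in levels
            ],
        }
    )
    table.to_csv(RESULTS / "adaptation_levels.csv", index=False)
    print(table.to_string(index=False))
    print("  (rod vision remains possible at 8000 Td: ~80 % of rhodopsin "
          "is still available)")


if __name__ == "__main__":
    main()
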