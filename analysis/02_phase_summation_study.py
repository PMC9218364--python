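#!/usr/bin/env python
"""Phase-summation study on the synthetic observer: simulate, fit, classify.

Runs the full pipeline at 1 Hz and 10 Hz for both illuminations: simulates
method-of-constant-stimuli trials from the generative truth, fits Weibull
psychometric functions per cell, forms threshold ratios across relative
phase, and selects probability vs. linear summation per condition.  The
expected pattern mirrors the study: melanopsin+rod linear (inhibitory) at
1 Hz but probability (facilitatory) at 10 Hz; melanopsin+cone probability
throughout; rod+cone linear.
"""

from pathlib import Path

import numpy as np

from melsum.io import RunConfig, run_pipeline
from melsum.summation import summation_index_db

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)

SEED = 20220603


def main() -> None:
    cfg = RunConfig(seed=SEED, frequencies_hz=[1.0, 10.0])
    report = run_pipeline(cfg)
    print(f"simulated {len(report.trials)} trials; "
          f"{len(report.psychometric_fits)} psychometric fits "
          f"({len(report.failures)} failures)")

    # bulk tables go to scratch; small summaries to results
    report.trials.to_csv(SCRATCH / "trials_full_study.csv", index=False)
    report.threshold_ratios.to_csv(RESULTS / "threshold_ratios.csv", index=False)
    report.summary.to_csv(RESULTS / "summation_summary.csv", index=False)

    alphas = (
        report.psychometric_fits.groupby(["frequency_hz", "illum_td", "condition"])
        [["alpha", "beta"]].agg(["mean", "sem"]).round(2)
    )
    alphas.to_csv(RESULTS / "psychometric_table.csv")
    print("\n== psychometric parameters (mean over observers/repeats) ==")
    print(alphas.to_string())

    print("\n== summation classification ==")
    for key, res in sorted(report.classifications.items()):
        illum, freq, cond = key
        line = f"{cond:>6} @ {illum:>6g} Td, {freq:g} Hz -> {res.model:<11}"
        if res.model == "linear":
            line += (f" phi={res.fit.phi_xy_deg:6.1f} deg "
                     f"(latency {res.fit.latency_ms:6.1f} ms)")
        else:
            n_mean = np.mean(list(res.fit.n.values()))
            line += (f" n={n_mean:.2f} "
                     f"({summation_index_db(n_mean):.2f} dB facilitation)")
        line += f"  GOF chi2 p={res.gof_p:.3f}"
        print(line)

    ir = {k: v for k, v in report.classifications.items() if k[2] == "i+R"}
    low = [v.model for k, v in ir.items() if k[1] == 1.0]
    high = [v.model for k, v in ir.items() if k[1] == 10.0]
    print("\nmelanopsin-rod interaction: "
          f"{set(low)} at 1 Hz vs {set(high)} at 10 Hz "
          "(inhibitory linear summation within the melanopsin temporal "
          "resolution, facilitatory probability summation beyond it)")


if __name__ == "__main__":
    main()
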