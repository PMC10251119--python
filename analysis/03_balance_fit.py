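"""Extract the drift-selection balance parameters from the sweep output.

Aggregates the re-run table of analysis/02 into a p_thrive profile along
the unchanged-K_s line, fits the logistic threshold model, and reports mu50
(the growth-rate advantage giving the loser 50-50 odds of thriving), the
steepness k, and the spread widths where neither drift nor selection
dominates.  Bootstrap intervals quantify the uncertainty from the finite
seed panel.

Writes results/sweep_pthrive.csv and results/sweep_balance.csv.

Usage: python analysis/03_balance_fit.py [--runs results/sweep_runs.csv]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from driftbalance.balance_fit import bootstrap_ci, fit_pmap
from driftbalance.probability_maps import compute_pthrive, monotonicity_qc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--runs", default="results/sweep_runs.csv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)

    runs = pd.read_csv(args.runs)
    reruns = runs[runs["run_id"].str.startswith("rerun")]
    pmap = compute_pthrive(reruns)
    pmap.to_csv(outdir / "sweep_pthrive.csv", index=False)
    print("p_thrive profile (dKs = 0):")
    print(pmap[["dmu_pct", "n_seeds", "n_thrive", "p_thrive"]]
          .to_string(index=False))

    qc = monotonicity_qc(pmap)
    if qc.empty:
        print("\nQC: no monotonicity violations beyond binomial noise")
    else:
        print("\nQC: flagged non-monotone steps:")
        print(qc.to_string(index=False))

    balance = fit_pmap(pmap)
    row = balance.iloc[0]
    if not row.converged:
        print("logistic fit did not converge on this profile")
    else:
        n_seeds = int(pmap["n_seeds"].iloc[0])
        ci = bootstrap_ci(pmap["dmu_pct"], pmap["p_thrive"], n_seeds,
                          n_boot=499, rng=np.random.default_rng(1))
        print(f"\nmu50 = {row.mu50:+.1f}% change in mu_max "
              f"(95% CI {ci['mu50'][0]:+.1f} .. {ci['mu50'][1]:+.1f})")
        print(f"k    = {row.k:.4f} per % "
              f"(95% CI {ci['k'][0]:.4f} .. {ci['k'][1]:.4f})")
        print(f"spread95 = {row.spread95:.1f}%, spread68 = {row.spread68:.1f}% "
              f"(mu_max-change range where drift and selection both matter)")
        if row.extrapolated:
            print("note: mu50 lies outside the swept range; treat as extrapolation")
    balance.to_csv(outdir / "sweep_balance.csv", index=False)
    print(f"\nwrote {outdir}/sweep_pthrive.csv and sweep_balance.csv")


if __name__ == "__main__":
    main()
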