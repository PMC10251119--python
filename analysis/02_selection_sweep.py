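"""Scaled-down kinetic sweep: can an altered mu_max rescue the biggest loser?

Runs the same-seed re-run protocol for 9 founders spaced 10 diameters apart
along the line of unchanged K_s: each seed's baseline run identifies the
biggest loser, which is then granted a percent change in mu_max (-50..+50 in
steps of 10) and the simulation replayed with the identical seed.  Output is
a long-form run table (appended incrementally, so the sweep is resumable),
from which later stages build the p_thrive profile and extract mu50.

Desk-scale conditions: stop at 5% biomass volume fraction (lineage fates are
set early, and the drift/selection contrast is already sharp there), 20
seeds.  Expect a few hours on one CPU at these settings.

Usage: python analysis/02_selection_sweep.py [--seeds 20] [--stop 0.05]
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

from driftbalance.experiment_design import make_rerun
from driftbalance.simulator import (
    RUN_TABLE_COLUMNS, SimulationConfig, run, run_to_rows,
)

DMU_LEVELS = list(range(-50, 51, 10))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=20)
    ap.add_argument("--stop", type=float, default=0.05)
    ap.add_argument("--out", default="results/sweep_runs.csv")
    args = ap.parse_args()

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    done = set()
    if out.exists():
        prev = pd.read_csv(out)
        done = set(prev["run_id"].unique())
        print(f"resuming: {len(done)} runs already recorded")
    else:
        pd.DataFrame(columns=RUN_TABLE_COLUMNS).to_csv(out, index=False)

    t0 = time.time()
    for seed in range(1, args.seeds + 1):
        cfg = SimulationConfig(n_initial=9, spacing=10.0, seed=seed,
                               stop_volume_fraction=args.stop)
        base_id = f"base_seed{seed}"
        base = run(cfg)
        if base_id not in done:
            _append(out, run_to_rows(base, base_id))
        print(f"[{time.time()-t0:7.0f}s] seed {seed}: baseline loser = lineage "
              f"{base.loser_id} (fraction {base.fraction(base.loser_id):.4f})",
              flush=True)
        for dmu in DMU_LEVELS:
            rid = f"rerun_k0_m{dmu}_seed{seed}"
            if rid in done:
                continue
            if dmu == 0:
                rows = run_to_rows(base, rid)  # null re-run == baseline
            else:
                spec = make_rerun(base, dKs_pct=0, dmu_pct=dmu)
                rows = run_to_rows(run(spec.config), rid)
            for r in rows:
                r["is_loser"] = r["lineage_id"] == base.loser_id
                r["dKs_pct"], r["dmu_pct"] = 0.0, float(dmu)
            _append(out, rows)
        print(f"[{time.time()-t0:7.0f}s] seed {seed}: sweep complete", flush=True)
    print(f"done: {args.seeds} seeds x {1 + len(DMU_LEVELS)} runs "
          f"-> {out} in {time.time()-t0:.0f}s")


def _append(out: Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=RUN_TABLE_COLUMNS).to_csv(
        out, mode="a", header=False, index=False)


if __name__ == "__main__":
    sys.exit(main())
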