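"""MLR versus GAM as descriptions of the p_thrive surface.

The simulator campaign behind a full 3 x 3 x 11 x 11 probability map is a
cluster-scale undertaking, so this stage fits both model families to a
synthetic surface with the qualitative structure the simulations exhibit:
a logistic cliff in (mu_p, K_p) whose location and steepness are modulated
by crowding (population size and spacing), sampled with binomial noise at
120 seeds per grid point.  The comparison shows which families can express
the spread structure: linear models capture the cliff's location but not
its width; only smooths with interactions reproduce both.

Writes results/model_comparison.csv and results/model_selection.json.

Usage: python analysis/04_descriptive_models.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from driftbalance import descriptive_models as dm
from driftbalance.pipeline import generate_fixture_pmap


def crowding_surface(rng) -> pd.DataFrame:
    ks, mu50s = {}, {}
    for n0 in (4, 9, 16):
        for sp in (2.5, 5.0, 10.0):
            # moderate spacing widens the spread; crowding raises mu50
            ks[(n0, sp)] = -0.08 - 0.05 * (sp == 5.0) - 0.0025 * n0
            mu50s[(n0, sp)] = 8 + 0.6 * n0 + 1.2 * sp
    return generate_fixture_pmap(true_k=ks, true_mu50=mu50s, mu50_slope=0.8,
                                 n_seeds=120, rng=rng)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    rng = np.random.default_rng(args.seed)
    pmap = crowding_surface(rng)

    fits = {
        "mlr_main_effects": dm.fit_mlr(pmap, dm.mlr_spec_main_effects()),
        "mlr_with_interactions": dm.fit_mlr(pmap, dm.mlr_spec_study()),
        "gam_main_effects": dm.fit_gam(pmap, dm.gam_spec_main_effects()),
        "gam_smooths_interactions": dm.fit_gam(pmap, dm.gam_spec_study()),
    }
    rows = []
    for name, fit in fits.items():
        rows.append({"model": name, "rmse": fit.rmse,
                     "r_squared": fit.r_squared, "aic": fit.aic,
                     "edf": fit.edf_total,
                     "predictions_outside_unit": fit.predictions_clipped})
        print(f"{name:26s} RMSE {fit.rmse:.4f}  R^2 {fit.r_squared:.3f} "
              f"AIC {fit.aic:9.1f}  edf {fit.edf_total:6.1f}")
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "model_comparison.csv", index=False)
    best = table.loc[table.rmse.idxmin(), "model"]
    print(f"\nlowest RMSE: {best}")

    spec, fit = dm.backward_select(pmap, dm.factorial_spec("mlr"))
    report = {
        "backward_selected_mlr_terms": [t.name for t in spec.terms],
        "dropped": list(spec.dropped),
        "rmse": fit.rmse, "r_squared": fit.r_squared, "aic": fit.aic,
    }
    (outdir / "model_selection.json").write_text(json.dumps(report, indent=2))
    print(f"backward-selected MLR terms: {report['backward_selected_mlr_terms']}")
    print(f"wrote {outdir}/model_comparison.csv and model_selection.json")


if __name__ == "__main__":
    main()
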