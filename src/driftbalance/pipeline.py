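"""End-to-end campaign orchestration at configurable scale.

``run_campaign`` executes the whole protocol -- baseline runs, biggest-loser
identification, same-seed re-runs over the kinetic grid, classification,
probability maps, logistic balance fits and (optionally) the descriptive
models -- writing each stage's table under an output directory.  Campaigns
are deterministic: per-run Park-Miller seeds are derived from the global
seed as ``global_seed + i`` for i = 1..n_seeds, and the identical seed panel
is reused across every factor combination (paired design).

``generate_fixture_pmap`` synthesises p_thrive surfaces with known logistic
parameters, which lets the fitting and modelling stages be exercised and
calibrated without running the simulator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import balance_fit, descriptive_models, experiment_design, probability_maps
from .simulator import (
    RUN_TABLE_COLUMNS, SimulationConfig, run, run_to_rows,
)

logger = logging.getLogger(__name__)

__all__ = ["CampaignConfig", "StageError", "run_campaign", "generate_fixture_pmap"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class CampaignConfig:
    """Scalable campaign description (defaults: study factor levels)."""

    spacings: tuple[float, ...] = (2.5, 5.0, 10.0)
    populations: tuple[int, ...] = (4, 9, 16)
    dKs_levels: tuple[float, ...] = tuple(range(-50, 51, 10))
    dmu_levels: tuple[float, ...] = tuple(range(-50, 51, 10))
    n_seeds: int = 120
    global_seed: int = 0
    fit_models: bool = False
    # simulator resolution knobs applied to every run
    sim_overrides: tuple[tuple[str, object], ...] = ()

    @property
    def seeds(self) -> list[int]:
        return [self.global_seed + i for i in range(1, self.n_seeds + 1)]

    def base_config(self, n_initial: int, spacing: float, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_initial=n_initial, spacing=spacing, seed=seed,
            **dict(self.sim_overrides),
        )


def run_campaign(config: CampaignConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute every stage, writing long-form CSV artifacts to ``out_dir``.

    Returns a mapping of stage name to artifact path.  Any stage failure
    raises :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # ---- baseline runs ----------------------------------------------------
    stage = "baseline"
    try:
        baseline_rows, baseline_results = [], {}
        for n0 in sorted(config.populations):
            for sp_ in sorted(config.spacings):
                for seed in config.seeds:
                    cfg = config.base_config(n0, sp_, seed)
                    res = run(cfg)
                    key = (n0, sp_, seed)
                    baseline_results[key] = res
                    rid = f"base_n{n0}_s{sp_:g}_seed{seed}"
                    baseline_rows.extend(run_to_rows(res, rid))
        baseline_df = pd.DataFrame(baseline_rows, columns=RUN_TABLE_COLUMNS)
        artifacts["baseline"] = out / "baseline.csv"
        baseline_df.to_csv(artifacts["baseline"], index=False)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(e)) from e

    # ---- drift fairness on the baselines ----------------------------------
    stage = "fairness"
    try:
        from .lineage_metrics import fairness_test
        m = len(config.populations) * len(config.spacings)
        frows = []
        for (n0, sp_), grp in baseline_df[baseline_df.is_loser].groupby(
                ["n_initial", "spacing"]):
            counts = (grp["lineage_id"].value_counts()
                      .reindex(range(1, n0 + 1), fill_value=0).to_numpy())
            ft = fairness_test(counts, n_conditions=m)
            frows.append({
                "n_initial": n0, "spacing": sp_, "statistic": ft.statistic,
                "pvalue": ft.pvalue, "alpha": ft.alpha,
                "significant": ft.significant, "m": m,
            })
        artifacts["fairness"] = out / "fairness.csv"
        pd.DataFrame(frows).to_csv(artifacts["fairness"], index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- same-seed re-runs over the kinetic grid ---------------------------
    stage = "rerun"
    try:
        rerun_rows = []
        for (n0, sp_, seed), base_res in baseline_results.items():
            for dks in sorted(config.dKs_levels):
                for dmu in sorted(config.dmu_levels):
                    rid = f"rerun_n{n0}_s{sp_:g}_k{dks:g}_m{dmu:g}_seed{seed}"
                    if dks == 0 and dmu == 0:
                        # the null re-run replays the baseline exactly
                        # (paired-seed identity); reuse its result
                        rows = run_to_rows(base_res, rid)
                        for r in rows:
                            r["dKs_pct"], r["dmu_pct"] = 0.0, 0.0
                    else:
                        spec = experiment_design.make_rerun(base_res, dks, dmu)
                        rows = run_to_rows(run(spec.config), rid)
                    # the map aggregates the *baseline* loser's fate
                    for r in rows:
                        r["is_loser"] = r["lineage_id"] == base_res.loser_id
                    rerun_rows.extend(rows)
        rerun_df = pd.DataFrame(rerun_rows, columns=RUN_TABLE_COLUMNS)
        artifacts["reruns"] = out / "reruns.csv"
        rerun_df.to_csv(artifacts["reruns"], index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- probability map ----------------------------------------------------
    stage = "map"
    try:
        pmap = probability_maps.compute_pthrive(rerun_df,
                                                expected_seeds=config.seeds)
        artifacts["pmap"] = out / "pmap.csv"
        pmap.to_csv(artifacts["pmap"], index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- logistic balance fits ---------------------------------------------
    stage = "fit"
    try:
        balance = balance_fit.fit_pmap(pmap)
        artifacts["balance"] = out / "balance.csv"
        balance.to_csv(artifacts["balance"], index=False)
        reg_rows = []
        for response in ("mu50", "spread95", "spread68"):
            try:
                for reg in balance_fit.regress_balance(balance, response):
                    reg_rows.append(dataclasses.asdict(reg))
            except ValueError as e:
                logger.warning("balance regression (%s) skipped: %s", response, e)
        if reg_rows:
            artifacts["balance_regression"] = out / "balance_regression.csv"
            pd.DataFrame(reg_rows).to_csv(artifacts["balance_regression"],
                                          index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- descriptive models -------------------------------------------------
    if config.fit_models:
        stage = "model"
        try:
            report = {}
            for label, spec in (
                ("mlr", descriptive_models.mlr_spec_study()),
                ("gam", descriptive_models.gam_spec_study()),
            ):
                fit = descriptive_models.fit_model(pmap, spec)
                report[label] = _fit_report(fit)
            artifacts["models"] = out / "models.json"
            artifacts["models"].write_text(json.dumps(report, indent=2))
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    # ---- manifest -----------------------------------------------------------
    manifest = {
        "campaign": dataclasses.asdict(config),
        "seeds": config.seeds,
        "stages": {k: v.name for k, v in artifacts.items()},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = mpath
    return artifacts


def _fit_report(fit: "descriptive_models.ModelFit") -> dict:
    return {
        "terms": [t.name for t in fit.spec.terms],
        "term_pvalues": fit.term_pvalues,
        "term_edf": fit.term_edf,
        "rmse": fit.rmse,
        "r_squared": fit.r_squared,
        "aic": fit.aic,
        "edf_total": fit.edf_total,
        "predictions_clipped": fit.predictions_clipped,
        "lambdas": fit.lambdas,
    }


def generate_fixture_pmap(
    true_k: float | dict = -0.2,
    true_mu50: float | dict = 15.0,
    mu50_slope: float = 0.0,
    n_seeds: Optional[int] = 120,
    rng: Optional[np.random.Generator] = None,
    spacings: Sequence[float] = (2.5, 5.0, 10.0),
    populations: Sequence[int] = (4, 9, 16),
    dKs_levels: Sequence[float] = tuple(range(-50, 51, 10)),
    dmu_levels: Sequence[float] = tuple(range(-50, 51, 10)),
) -> pd.DataFrame:
    """Synthetic long-form p_thrive map with known logistic structure.

    For each crowding condition the true surface is
    ``p = 1 / (1 + exp(-k (mu50(dKs) - dmu)))`` with
    ``mu50(dKs) = mu50 + mu50_slope * dKs``; ``true_k`` and ``true_mu50``
    may be scalars or dicts keyed by ``(n_initial, spacing)``.  With
    ``n_seeds`` set, observed maps are binomial draws (n_seeds trials per
    grid point, needing ``rng``); with ``n_seeds=None`` the analytic
    probabilities are returned (the infinite-seed limit).
    """
    rows = []
    for n0 in sorted(populations):
        for sp_ in sorted(spacings):
            k = _lookup(true_k, n0, sp_)
            mu50_0 = _lookup(true_mu50, n0, sp_)
            if k == 0:
                raise ValueError("true_k must be nonzero")
            for dks in sorted(dKs_levels):
                mu50 = mu50_0 + mu50_slope * dks
                for dmu in sorted(dmu_levels):
                    p = balance_fit.logistic_pthrive(dmu, k, mu50)
                    if n_seeds is None:
                        n_s, n_t, p_obs = 0, float("nan"), p
                    else:
                        if rng is None:
                            raise ValueError("rng required when n_seeds is set")
                        n_t = int(rng.binomial(n_seeds, p))
                        n_s, p_obs = n_seeds, n_t / n_seeds
                    rows.append({
                        "n_initial": n0, "spacing": sp_, "dKs_pct": dks,
                        "dmu_pct": dmu, "n_seeds": n_s, "n_thrive": n_t,
                        "p_thrive": p_obs,
                    })
    return pd.DataFrame(rows, columns=probability_maps.PMAP_COLUMNS)


def _lookup(value, n0, sp_):
    if isinstance(value, dict):
        return value[(n0, sp_)]
    return value
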