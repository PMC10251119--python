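"""Factorial campaign design and the same-seed re-run protocol.

The study design crosses 3 spacings x 3 initial population sizes x 11 percent
changes to K_s x 11 percent changes to mu_max (1089 combinations), each run
under a common panel of seeds (paired design: the same seed values are reused
across every combination).  For each baseline run the "biggest loser" -- the
lineage with the lowest final relative biomass -- is identified, and the run
is repeated with the same seed but the loser's kinetics scaled by the factor
levels.  Because the seed replays the identical sequence of random events,
any change in the loser's fate is attributable to the kinetic alteration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .simulator import LoserOverride, RunResult, SimulationConfig

__all__ = [
    "FactorGrid",
    "RerunSpec",
    "build_factor_grid",
    "enumerate_runs",
    "biggest_loser",
    "make_rerun",
]

_SPACINGS = (2.5, 5.0, 10.0)
_POPULATIONS = (4, 9, 16)
_PCT_LEVELS = tuple(range(-50, 51, 10))


@dataclass(frozen=True)
class FactorGrid:
    """The factor levels of the campaign (defaults reproduce the study grid)."""

    spacings: tuple[float, ...] = _SPACINGS
    populations: tuple[int, ...] = _POPULATIONS
    dKs_pct: tuple[float, ...] = _PCT_LEVELS
    dmu_pct: tuple[float, ...] = _PCT_LEVELS

    def __len__(self) -> int:
        return (len(self.spacings) * len(self.populations)
                * len(self.dKs_pct) * len(self.dmu_pct))

    def combinations(self) -> pd.DataFrame:
        """All combinations, deterministically ordered (spacing, population,
        dKs, dmu ascending)."""
        rows = [
            (s, n, dks, dmu)
            for s in sorted(self.spacings)
            for n in sorted(self.populations)
            for dks in sorted(self.dKs_pct)
            for dmu in sorted(self.dmu_pct)
        ]
        return pd.DataFrame(
            rows, columns=["spacing", "n_initial", "dKs_pct", "dmu_pct"]
        )


def build_factor_grid(
    spacings: Sequence[float] = _SPACINGS,
    populations: Sequence[int] = _POPULATIONS,
    dKs_pct: Sequence[float] = _PCT_LEVELS,
    dmu_pct: Sequence[float] = _PCT_LEVELS,
) -> FactorGrid:
    """The campaign factor grid; defaults give the full 3x3x11x11 design."""
    return FactorGrid(
        spacings=tuple(spacings),
        populations=tuple(populations),
        dKs_pct=tuple(dKs_pct),
        dmu_pct=tuple(dmu_pct),
    )


def enumerate_runs(grid: FactorGrid, n_seeds: int,
                   seeds: Sequence[int] | None = None) -> pd.DataFrame:
    """Run manifest: every (combination, seed) pair of the paired design.

    Seeds default to 1..n_seeds and are identical across combinations, so
    each kinetic alteration is compared against the baseline that experienced
    the very same sequence of random events.
    """
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    if seeds is None:
        seeds = list(range(1, n_seeds + 1))
    else:
        seeds = list(seeds)
        if len(seeds) != n_seeds:
            raise ValueError("len(seeds) must equal n_seeds")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    combos = grid.combinations()
    manifest = combos.loc[combos.index.repeat(len(seeds))].reset_index(drop=True)
    manifest["seed"] = np.tile(seeds, len(combos))
    manifest.insert(0, "run_id", [
        f"n{int(r.n_initial)}_s{r.spacing:g}_k{r.dKs_pct:g}_m{r.dmu_pct:g}_seed{int(r.seed)}"
        for r in manifest.itertuples()
    ])
    return manifest


def biggest_loser(result: RunResult) -> int:
    """Lineage with the minimum final biomass fraction (ties: lowest id)."""
    fractions = np.asarray(result.final_fractions)
    if fractions.size == 0:
        raise ValueError("run result has no lineages")
    return int(np.argmin(fractions)) + 1


@dataclass(frozen=True)
class RerunSpec:
    """A same-seed re-run with the baseline's loser given altered kinetics."""

    config: SimulationConfig
    seed: int
    loser_id: int
    dKs_pct: float
    dmu_pct: float


def make_rerun(baseline: RunResult, dKs_pct: float, dmu_pct: float) -> RerunSpec:
    """Build the re-run spec for a baseline result.

    Only the loser lineage's kinetics are scaled (``K_s' = K_s(1+dKs/100)``,
    ``mu_max' = mu_max(1+dmu/100)``); the seed is preserved so the random
    event stream is replayed identically.
    """
    if dKs_pct <= -100:
        raise ValueError(f"dKs_pct must be > -100 (K_s must stay positive), got {dKs_pct}")
    if dmu_pct <= -100:
        raise ValueError(f"dmu_pct must be > -100, got {dmu_pct}")
    loser = biggest_loser(baseline)
    override = LoserOverride(lineage_id=loser, dKs_pct=dKs_pct, dmu_pct=dmu_pct)
    cfg = replace(baseline.config, loser_override=override, seed=baseline.seed)
    return RerunSpec(config=cfg, seed=baseline.seed, loser_id=loser,
                     dKs_pct=dKs_pct, dmu_pct=dmu_pct)
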