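"""Thriving-probability surfaces.

For each crowding condition (initial population size x spacing) and each
kinetic alteration (dKs_pct, dmu_pct), ``p_thrive`` is the fraction of seeds
in which the baseline run's biggest loser ended the re-run classified as
thriving.  It estimates the probability that the imposed selective advantage
outweighs drift-driven failure under those conditions.

Maps are kept long-form (one row per combination) so partial sweeps remain
valid inputs to the fitting stages.  Missing or duplicated (combination,
seed) records are hard errors: silently renormalising would break the
paired-seed design.
"""

from __future__ import annotations

import pandas as pd

from .lineage_metrics import THRIVING

__all__ = ["PMAP_COLUMNS", "compute_pthrive", "loser_records",
           "monotonicity_qc", "MapIntegrityError"]

PMAP_COLUMNS = [
    "n_initial", "spacing", "dKs_pct", "dmu_pct",
    "n_seeds", "n_thrive", "p_thrive",
]

_KEY = ["n_initial", "spacing", "dKs_pct", "dmu_pct"]


class MapIntegrityError(ValueError):
    """The classified re-run table violates the paired-seed design."""


def loser_records(classified: pd.DataFrame) -> pd.DataFrame:
    """Select the one loser-lineage row per re-run from a long run table."""
    missing = [c for c in ("is_loser",) if c not in classified.columns]
    if missing:
        raise MapIntegrityError(f"run table lacks columns: {missing}")
    return classified[classified["is_loser"].astype(bool)].copy()


def compute_pthrive(classified: pd.DataFrame,
                    expected_seeds: list[int] | None = None) -> pd.DataFrame:
    """Aggregate classified re-runs into a long-form p_thrive map.

    Parameters
    ----------
    classified
        Long run table (one row per lineage per run) or pre-filtered loser
        rows; must contain the key columns, ``seed``, ``is_loser`` and
        ``status``.
    expected_seeds
        If given, every combination must have exactly this seed panel;
        otherwise the union of observed seeds is required for every
        combination (the paired design reuses one panel everywhere).

    Returns
    -------
    DataFrame with columns ``n_initial, spacing, dKs_pct, dmu_pct, n_seeds,
    n_thrive, p_thrive``.
    """
    required = set(_KEY + ["seed", "is_loser", "status"])
    missing = required - set(classified.columns)
    if missing:
        raise MapIntegrityError(f"run table lacks columns: {sorted(missing)}")
    losers = loser_records(classified)
    if losers.empty:
        raise MapIntegrityError("no loser records in the classified table")

    dup = losers.duplicated(subset=_KEY + ["seed"])
    if dup.any():
        bad = losers.loc[dup, _KEY + ["seed"]].drop_duplicates()
        raise MapIntegrityError(
            "duplicate loser records for (combination, seed):\n"
            f"{bad.to_string(index=False)}"
        )

    if expected_seeds is None:
        expected = set(losers["seed"].unique().tolist())
    else:
        expected = set(expected_seeds)
    gaps = []
    for key, grp in losers.groupby(_KEY, sort=True):
        got = set(grp["seed"].tolist())
        if got != expected:
            missing_seeds = sorted(expected - got)
            extra = sorted(got - expected)
            gaps.append((key, missing_seeds, extra))
    if gaps:
        lines = [
            f"  combination {key}: missing seeds {miss}" + (f", unexpected {extra}" if extra else "")
            for key, miss, extra in gaps
        ]
        raise MapIntegrityError(
            "incomplete seed panels (paired design requires every seed in "
            "every combination):\n" + "\n".join(lines)
        )

    losers = losers.assign(_thrive=(losers["status"] == THRIVING).astype(int))
    out = (
        losers.groupby(_KEY, sort=True)
        .agg(n_seeds=("seed", "size"), n_thrive=("_thrive", "sum"))
        .reset_index()
    )
    out["p_thrive"] = out["n_thrive"] / out["n_seeds"]
    return out[PMAP_COLUMNS]


def monotonicity_qc(pmap: pd.DataFrame, z: float = 3.0) -> pd.DataFrame:
    """Flag decreases of p_thrive along increasing dmu beyond binomial noise.

    A growth-rate improvement cannot hurt the loser, so along any fixed
    (crowding, dKs) line p_thrive should be nondecreasing in dmu up to
    sampling noise.  Adjacent level pairs whose drop exceeds ``z`` binomial
    standard deviations are returned for inspection (an empty frame is a
    clean report).
    """
    import numpy as np

    flags = []
    group_key = ["n_initial", "spacing", "dKs_pct"]
    for key, grp in pmap.groupby(group_key, sort=True):
        grp = grp.sort_values("dmu_pct")
        p = grp["p_thrive"].to_numpy()
        n = grp["n_seeds"].to_numpy().astype(float)
        dmu = grp["dmu_pct"].to_numpy()
        for a in range(len(grp) - 1):
            drop = p[a] - p[a + 1]
            sd = np.sqrt(p[a] * (1 - p[a]) / max(n[a], 1)
                         + p[a + 1] * (1 - p[a + 1]) / max(n[a + 1], 1))
            if drop > z * sd and drop > 0:
                flags.append(dict(zip(group_key, key)) | {
                    "dmu_lo": dmu[a], "dmu_hi": dmu[a + 1],
                    "p_lo": p[a], "p_hi": p[a + 1],
                    "drop": drop, "z_score": drop / sd if sd > 0 else np.inf,
                })
    return pd.DataFrame(flags, columns=group_key + [
        "dmu_lo", "dmu_hi", "p_lo", "p_hi", "drop", "z_score"])
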