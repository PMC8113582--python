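"""Exotic-dominance analysis: realised vs planted share of exotic plant biomass.

For each mesocosm the proportion of total (alive) plant biomass contributed by
exotic plants is compared, per planting level crossed with herbivore
treatment, against the expected proportion given the planted composition.
Levels planted at 0% or 100% exotic are excluded (the realised proportion is
pinned there by design).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import DominanceSummary

INTERMEDIATE_LEVELS = (0.25, 0.5, 0.75)


def exotic_biomass_proportion(plants: pd.DataFrame,
                              mesocosm_id: str | None = None,
                              partition: str = "total"):
    """Proportion of mesocosm plant biomass contributed by exotic plants.

    Dead plants are excluded.  ``partition`` selects total (above+below) or
    aboveground biomass.  Mesocosms whose alive plants sum to zero biomass get
    NaN with a warning.  Returns a Series over mesocosms, or a float when a
    single ``mesocosm_id`` is requested.
    """
    alive = plants[plants["alive"]].copy()
    if partition == "total":
        alive["b"] = alive["aboveground_biomass_g"] + alive["belowground_biomass_g"]
    elif partition == "aboveground":
        alive["b"] = alive["aboveground_biomass_g"]
    else:
        raise ValueError(f"unknown biomass partition {partition!r}")

    total = alive.groupby("mesocosm_id")["b"].sum()
    exotic = (alive[alive["provenance"] == "exotic"]
              .groupby("mesocosm_id")["b"].sum()
              .reindex(total.index, fill_value=0.0))
    zero = total <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} mesocosms have zero alive plant biomass; "
            "proportion undefined (NaN)", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = exotic / total.where(~zero)
    prop.name = "prop_exotic_biomass"
    if mesocosm_id is not None:
        return float(prop.loc[mesocosm_id])
    return prop


def _ci(values: np.ndarray, method: str, level: float,
        rng: np.random.Generator | None, n_boot: int) -> tuple[float, float]:
    n = len(values)
    mean = values.mean()
    if method == "t":
        if n < 2:
            return (np.nan, np.nan)
        sd = values.std(ddof=1)
        if sd == 0:
            return (mean, mean)
        half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sd / np.sqrt(n)
        return (mean - half, mean + half)
    if method == "bootstrap":
        if n < 2:
            return (np.nan, np.nan)
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = values[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [(1 - level) / 2, 0.5 + level / 2])
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def dominance_ci_table(proportions: pd.Series,
                       mesocosms: pd.DataFrame,
                       method: str = "t",
                       level: float = 0.95,
                       n_boot: int = 2000,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Group means and CIs of realised exotic biomass proportion vs expected.

    Groups are planted exotic proportion (intermediate levels only) crossed
    with herbivore treatment.  ``exceeds_expected`` flags groups whose CI lies
    entirely above the planted proportion; ``ci_overlaps_other_treatment``
    flags whether the group's CI overlaps the CI of the opposite herbivore
    treatment at the same planting level.
    """
    meta = mesocosms.set_index("mesocosm_id")[
        ["prop_exotic_planted", "herbivore_treatment"]]
    df = meta.join(proportions.rename("prop"), how="inner").dropna(subset=["prop"])
    df = df[df["prop_exotic_planted"].isin(INTERMEDIATE_LEVELS)]

    rows: list[DominanceSummary] = []
    for (planted, ht), g in df.groupby(["prop_exotic_planted", "herbivore_treatment"]):
        vals = g["prop"].to_numpy(float)
        n = len(vals)
        if n < 2:
            warnings.warn(
                f"group (planted={planted}, {ht}) has n={n} < 2; CI unavailable",
                stacklevel=2)
        lo, hi = _ci(vals, method, level, rng, n_boot)
        rows.append(DominanceSummary(
            prop_exotic_planted=float(planted),
            herbivore_treatment=str(ht),
            n=n,
            mean_realised_prop=float(vals.mean()),
            ci_low=lo,
            ci_high=hi,
            expected=float(planted),
            exceeds_expected=bool(np.isfinite(lo) and lo > planted),
        ))
    out = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        ["prop_exotic_planted", "herbivore_treatment"]).reset_index(drop=True)

    # CI overlap between the two herbivore treatments within each planting level
    overlap = []
    for _, row in out.iterrows():
        others = out[(out["prop_exotic_planted"] == row["prop_exotic_planted"])
                     & (out["herbivore_treatment"] != row["herbivore_treatment"])]
        if others.empty or not np.isfinite(row["ci_low"]):
            overlap.append(np.nan)
            continue
        o = others.iloc[0]
        if not np.isfinite(o["ci_low"]):
            overlap.append(np.nan)
            continue
        overlap.append(bool(row["ci_low"] <= o["ci_high"] and o["ci_low"] <= row["ci_high"]))
    out["ci_overlaps_other_treatment"] = overlap
    return out
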