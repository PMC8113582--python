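"""Potential for apparent competition (PAC) from quantitative interaction matrices.

For a plants x herbivores biomass matrix ``alpha``, the pairwise statistic is

    d[i, j] = sum_k (alpha[i, k] / sum_l alpha[i, l]) * (alpha[j, k] / sum_m alpha[m, k])

i.e. the share of the herbivore pressure on plant i that is channelled through
herbivores also feeding on plant j, with each herbivore's contribution split
among its hosts in proportion to biomass.  Terms with a zero denominator
(plants with no herbivores, herbivores with no hosts) contribute 0, so plants
sharing no herbivores have d = 0 and zero-load plants have all-zero rows.
Rows of d for plants with positive load sum to exactly 1 (diagonal included).

Community aggregation weights the heterospecific sums by herbivore biomass:
``pac_exerted[i] = B_i * sum_{j != i} d[j, i]`` (how much pressure plant i can
channel onto others, scaled by its own herbivore load) and
``pac_received[i] = B_{-i} * sum_{j != i} d[i, j]`` (how much of the rest of
the community's load can reach plant i).  The opposite reading of the
aggregation is available via ``direction="swapped"``.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import InteractionMatrix, PACResult


def _as_alpha(matrix) -> np.ndarray:
    alpha = matrix.alpha if isinstance(matrix, InteractionMatrix) else np.asarray(matrix, float)
    if alpha.ndim != 2:
        raise ValueError("alpha must be a 2-D matrix")
    if np.any(alpha < 0):
        raise ValueError("interaction strengths must be non-negative")
    return alpha


def pairwise_pac(matrix) -> np.ndarray:
    """Pairwise PAC matrix d (receiver rows i, donor columns j).

    Accepts an :class:`InteractionMatrix` or a raw non-negative 2-D array.
    """
    alpha = _as_alpha(matrix)
    row_tot = alpha.sum(axis=1, keepdims=True)
    col_tot = alpha.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        share_of_plant = np.where(row_tot > 0, alpha / np.where(row_tot > 0, row_tot, 1.0), 0.0)
        share_of_herb = np.where(col_tot > 0, alpha / np.where(col_tot > 0, col_tot, 1.0), 0.0)
    return share_of_plant @ share_of_herb.T


def aggregate_pac(d: np.ndarray, matrix,
                  direction: str = "mueller") -> tuple[np.ndarray, np.ndarray]:
    """Biomass-weighted community-level PAC per plant.

    Returns ``(pac_exerted, pac_received)``.  Intraspecific (diagonal) terms
    are excluded.  ``direction="mueller"`` treats d[i, j] as the potential
    effect of donor j on receiver i; ``"swapped"`` flips the reading.
    """
    alpha = _as_alpha(matrix)
    d = np.asarray(d, float)
    n = alpha.shape[0]
    if d.shape != (n, n):
        raise ValueError(f"d has shape {d.shape}, expected ({n}, {n})")

    focal = alpha.sum(axis=1)             # B_i
    other = focal.sum() - focal           # B_-i
    diag = np.diag(d)
    row_off = d.sum(axis=1) - diag        # sum_{j != i} d[i, j]
    col_off = d.sum(axis=0) - diag        # sum_{j != i} d[j, i]
    if direction == "mueller":
        exerted = col_off * focal
        received = row_off * other
    elif direction == "swapped":
        exerted = row_off * focal
        received = col_off * other
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return exerted, received


def compute_pac(matrix: InteractionMatrix, direction: str = "mueller") -> PACResult:
    """Pairwise + aggregated PAC for one mesocosm."""
    d = pairwise_pac(matrix)
    exerted, received = aggregate_pac(d, matrix, direction=direction)
    focal = matrix.alpha.sum(axis=1)
    return PACResult(
        mesocosm_id=matrix.mesocosm_id,
        plants=list(matrix.plants),
        d=d,
        pac_exerted=exerted,
        pac_received=received,
        focal_biomass=focal,
        other_biomass=focal.sum() - focal,
    )


def pac_table(results: Iterable[PACResult],
              plants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack per-mesocosm PAC results into one long table.

    If a plants table is given, species and provenance are attached.
    """
    frames = [r.to_frame() for r in results]
    if not frames:
        return pd.DataFrame(columns=["mesocosm_id", "plant_id", "pac_exerted",
                                     "pac_received", "focal_biomass_g",
                                     "other_biomass_g"])
    out = pd.concat(frames, ignore_index=True)
    if plants is not None:
        out = out.merge(plants[["plant_id", "species", "provenance"]],
                        on="plant_id", how="left")
    return out


def _log_offset(values: np.ndarray) -> float:
    """Offset for log-transforming data containing zeros: half the smallest
    positive observation (0 when no zeros or no positive values)."""
    pos = values[values > 0]
    if len(pos) == 0 or not np.any(values == 0):
        return 0.0
    return float(pos.min() / 2.0)


def pac_treatment_summary(pac: pd.DataFrame,
                          mesocosms: pd.DataFrame,
                          group_cols: tuple[str, ...] = (
                              "provenance", "herbivore_treatment", "soil_treatment"),
                          ) -> pd.DataFrame:
    """Grouped means/SEs of log-transformed PAC by provenance and treatments.

    Both PAC measures are log-transformed; when zeros are present the offset
    log(x + min_positive/2) is used and recorded in ``DataFrame.attrs``.
    Missing group combinations yield NaN rows with a warning.
    """
    df = pac.merge(
        mesocosms[["mesocosm_id", "herbivore_treatment", "soil_treatment"]],
        on="mesocosm_id", how="left")
    measures = ("pac_exerted", "pac_received")
    offsets = {m: _log_offset(df[m].to_numpy(float)) for m in measures}

    rows = []
    levels = [sorted(mesocosms[c].dropna().unique()) if c in mesocosms.columns
              else sorted(df[c].dropna().unique()) for c in group_cols]
    grouped = df.groupby(list(group_cols))
    index = pd.MultiIndex.from_product(levels, names=group_cols)
    for key in index:
        try:
            g = grouped.get_group(key if len(group_cols) > 1 else key[0])
        except KeyError:
            warnings.warn(f"no observations for group {dict(zip(group_cols, key))}",
                          stacklevel=2)
            g = None
        row = dict(zip(group_cols, key))
        row["n"] = 0 if g is None else len(g)
        for m in measures:
            if g is None or len(g) == 0:
                row.update({f"{m}_mean": np.nan, f"log_{m}_mean": np.nan,
                            f"log_{m}_se": np.nan})
                continue
            x = g[m].to_numpy(float)
            logx = np.log(x + offsets[m]) if offsets[m] > 0 else np.log(
                np.where(x > 0, x, np.nan))
            logx = logx[np.isfinite(logx)]
            row[f"{m}_mean"] = float(x.mean())
            row[f"log_{m}_mean"] = float(logx.mean()) if len(logx) else np.nan
            row[f"log_{m}_se"] = (float(logx.std(ddof=1) / np.sqrt(len(logx)))
                                  if len(logx) > 1 else np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["log_offsets"] = offsets
    return out


def pac_results_for_mesocosms(matrices: Mapping[str, InteractionMatrix],
                              direction: str = "mueller") -> list[PACResult]:
    return [compute_pac(m, direction=direction)
            for _, m in sorted(matrices.items())]
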