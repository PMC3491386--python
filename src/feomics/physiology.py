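"""Cylinder-model cell morphometry and RT-qPCR delta-delta-CT.

The diatom cell is modeled as a regular closed cylinder that grows by a
gradual two-fold increase of its height over the cell cycle. Because an
unsynchronized culture samples cells across that growth range, a
population mean of any growth-variable parameter (volume, surface) sits
inside a range ``[L, 2L]``; the "cellular unit" — a freshly divided cell
at the start of its cycle — is back-calculated as the lower end ``L`` of
the range whose arithmetic center is the mean, i.e. ``L = mean / 1.5``.

RT-qPCR relative expression follows the housekeeping-normalized
threshold-cycle convention

    dCT       = CT(gene) - CT(housekeeping)     per condition
    ddCT      = dCT@Fe(+) - dCT@Fe(-)

so a positive ddCT means induction at low iron.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CylinderMetrics",
    "cylinder_metrics",
    "unit_cell",
    "unit_cell_from_population",
    "sv_change",
    "ddct",
]

CONDITION_PLUS = "Fe_plus"
CONDITION_MINUS = "Fe_minus"


@dataclass(frozen=True)
class CylinderMetrics:
    """Closed-cylinder volume (µm³), surface (µm²) and their ratio (µm⁻¹)."""

    volume: float
    surface: float

    @property
    def sv_ratio(self) -> float:
        return self.surface / self.volume


def cylinder_metrics(diameter: float, length: float) -> CylinderMetrics:
    """Volume and surface of a closed cylinder with both caps.

    V = pi (d/2)^2 h;  S = 2 pi (d/2)^2 + pi d h.
    """
    if diameter <= 0 or length <= 0:
        raise ValueError("cell diameter and length must be positive")
    r = diameter / 2.0
    volume = math.pi * r * r * length
    surface = 2.0 * math.pi * r * r + math.pi * diameter * length
    return CylinderMetrics(volume=volume, surface=surface)


def unit_cell(
    population_mean: float,
    convention: Literal["arithmetic_center", "geometric_center"] = "arithmetic_center",
) -> float:
    """Back-calculate the start-of-cycle value from a population mean.

    Growth doubles the parameter over the cycle, so the population spans
    ``[L, 2L]``. Under ``arithmetic_center`` the mean is the midpoint
    1.5 L, so ``L = mean / 1.5`` (the default, matching a uniform spread
    of cells over the range). ``geometric_center`` instead takes the mean
    as sqrt(2) L.
    """
    if population_mean <= 0:
        raise ValueError("population mean must be positive")
    if convention == "arithmetic_center":
        return population_mean / 1.5
    if convention == "geometric_center":
        return population_mean / math.sqrt(2.0)
    raise ValueError(f"unknown back-calculation convention: {convention!r}")


def unit_cell_from_population(
    measures: pd.DataFrame,
    convention: Literal["arithmetic_center", "geometric_center"] = "arithmetic_center",
) -> dict[str, float]:
    """Unit-cell volume and surface from a table of per-cell (diameter, length).

    Per-cell cylinder metrics are averaged, then the volume is
    back-calculated via :func:`unit_cell`. The unit surface is reported
    under two conventions, which need not agree:

    - ``unit_surface_direct``: mean surface back-calculated directly;
    - ``unit_surface_from_volume``: surface re-derived from the unit
      volume at the mean diameter (growth changes height, not diameter,
      so ``h_unit = V_unit / (pi r^2)`` with ``r`` from the mean
      diameter).

    With a single cell the /1.5 division is applied verbatim and is
    biased (one cell is not a population mean); this is flagged in the
    returned ``n_cells``.
    """
    if len(measures) == 0:
        raise ValueError("empty cell-measurement table")
    required = {"diameter_um", "length_um"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measurement table needs columns {sorted(required)}")
    per_cell = [
        cylinder_metrics(d, h)
        for d, h in zip(measures["diameter_um"], measures["length_um"])
    ]
    mean_v = sum(m.volume for m in per_cell) / len(per_cell)
    mean_s = sum(m.surface for m in per_cell) / len(per_cell)
    mean_d = float(measures["diameter_um"].mean())
    unit_v = unit_cell(mean_v, convention)
    unit_s_direct = unit_cell(mean_s, convention)
    r = mean_d / 2.0
    h_unit = unit_v / (math.pi * r * r)
    unit_s_from_v = cylinder_metrics(mean_d, h_unit).surface
    if len(per_cell) == 1:
        logger.warning(
            "unit_cell_from_population called with a single cell; the /1.5 "
            "back-calculation assumes a population spread over the growth range"
        )
    return {
        "n_cells": len(per_cell),
        "mean_volume": mean_v,
        "mean_surface": mean_s,
        "mean_diameter": mean_d,
        "unit_volume": unit_v,
        "unit_surface_direct": unit_s_direct,
        "unit_surface_from_volume": unit_s_from_v,
    }


def sv_change(sv_a: float, sv_b: float) -> float:
    """Percent change of surface/volume ratio a relative to b: 100 (a/b - 1)."""
    if sv_b <= 0:
        raise ValueError("reference surface/volume ratio must be positive")
    return 100.0 * (sv_a / sv_b - 1.0)


def ddct(records: pd.DataFrame) -> pd.DataFrame:
    """Delta-delta-CT per gene from a threshold-cycle table.

    Parameters
    ----------
    records : DataFrame with columns ``gene_id``, ``housekeeping_id``,
        ``condition`` (``Fe_plus`` / ``Fe_minus``) and ``ct``. Housekeeping
        genes appear as their own rows (``gene_id == housekeeping_id``).

    Returns
    -------
    DataFrame with ``gene_id``, ``housekeeping_id``, ``dct_plus``,
    ``dct_minus`` and ``ddct = dct_plus - dct_minus``. Genes missing a
    condition or their housekeeping reference are skipped with a log entry.
    """
    required = {"gene_id", "housekeeping_id", "condition", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    bad_cond = set(records["condition"]) - {CONDITION_PLUS, CONDITION_MINUS}
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    if (records["ct"] <= 0).any():
        raise ValueError("threshold cycle values must be positive")

    ct = {
        (g, c): v
        for g, c, v in zip(records["gene_id"], records["condition"], records["ct"])
    }
    rows = []
    seen = set()
    for g, hk in zip(records["gene_id"], records["housekeeping_id"]):
        if g == hk or (g, hk) in seen:
            continue
        seen.add((g, hk))
        keys = [
            (g, CONDITION_PLUS),
            (g, CONDITION_MINUS),
            (hk, CONDITION_PLUS),
            (hk, CONDITION_MINUS),
        ]
        if any(k not in ct for k in keys):
            logger.warning("gene %s skipped: missing CT for gene or housekeeping %s", g, hk)
            continue
        dct_plus = ct[(g, CONDITION_PLUS)] - ct[(hk, CONDITION_PLUS)]
        dct_minus = ct[(g, CONDITION_MINUS)] - ct[(hk, CONDITION_MINUS)]
        rows.append(
            {
                "gene_id": g,
                "housekeeping_id": hk,
                "dct_plus": dct_plus,
                "dct_minus": dct_minus,
                "ddct": dct_plus - dct_minus,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "housekeeping_id", "dct_plus", "dct_minus", "ddct"])
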