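"""Lumped-parameter pesticide run-off loss (OECD run-off indicator).

For one active ingredient (AI), one grid cell and one month, the dissolved
run-off loss as a percentage of the applied amount is

    L%_ro = (Q/P) · f · exp(−3·ln2 / DT50Soil) · 100/(1 + Kd)

with Q monthly surface run-off (mm), P monthly precipitation (mm), f a
dimensionless correction for terrain slope, plant interception and buffer
strips, DT50Soil the soil dissipation half-life in days (the constant 3 is
the assumed lag in days between application and the run-off event), and
Kd = Koc · %OC/100 the soil–water distribution coefficient from the
organic-carbon partition coefficient and the local soil organic carbon
content. Each factor lies in [0, 1] (the last in [0, 100]), so
0 ≤ L%_ro ≤ 100 whenever Q ≤ P.

Application dose is deliberately not modelled: the output is a relative
hazard contribution per AI, not a mass flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pestmap.grids import EnvGrid

__all__ = [
    "AiParams",
    "CellEnvironment",
    "LAG_DAYS",
    "soil_water_coefficient",
    "degradation_factor",
    "slope_interception_buffer_factor",
    "runoff_loss_percent",
    "monthly_loss_grid",
    "load_ai_table",
    "write_ai_table",
]

#: days between application and the run-off event (fixed in the indicator;
#: exposed for sensitivity use only)
LAG_DAYS = 3.0

AI_CLASSES = ("insecticide", "fungicide", "herbicide")


@dataclass(frozen=True)
class AiParams:
    """Physicochemical constants for one active ingredient."""

    name: str
    cas: str
    ai_class: str
    koc: float  # L/kg
    dt50_soil_days: float  # days

    def __post_init__(self):
        if self.ai_class not in AI_CLASSES:
            raise ValueError(f"unknown AI class {self.ai_class!r}")
        if self.koc < 0:
            raise ValueError("koc must be >= 0")
        if self.dt50_soil_days <= 0:
            raise ValueError("dt50_soil_days must be > 0")


@dataclass(frozen=True)
class CellEnvironment:
    """Monthly environment of one cell: hydrology, slope, soil carbon."""

    q_mm: float
    p_mm: float
    slope_deg: float = 0.0
    soc_percent: float = 0.0
    f_override: float | None = None

    def __post_init__(self):
        if self.q_mm < 0 or self.p_mm < 0:
            raise ValueError("q_mm and p_mm must be >= 0")
        if self.f_override is not None and not 0 <= self.f_override <= 1:
            raise ValueError("f_override must lie in [0, 1]")


def soil_water_coefficient(koc, soc_percent):
    """Kd = Koc · (%OC/100), in L/kg. Accepts scalars or arrays."""
    koc = np.asarray(koc, dtype=float)
    soc = np.asarray(soc_percent, dtype=float)
    if np.any(koc < 0) or np.any(soc < 0):
        raise ValueError("koc and soc_percent must be >= 0")
    out = koc * soc / 100.0
    return float(out) if out.ndim == 0 else out


def degradation_factor(dt50_days):
    """exp(−LAG_DAYS·ln2/DT50): fraction surviving the lag before run-off."""
    dt50 = np.asarray(dt50_days, dtype=float)
    if np.any(dt50 <= 0):
        raise ValueError("dt50_days must be > 0")
    out = np.exp(-LAG_DAYS * math.log(2) / dt50)
    return float(out) if out.ndim == 0 else out


def slope_interception_buffer_factor(slope_deg, interception_frac=0.0,
                                     buffer_frac=0.0):
    """f = f_slope · (1 − interception) · (1 − buffer), each in [0, 1].

    f_slope follows the OECD run-off indicator polynomial in slope percent
    s = 100·tan(slope): f_slope = min(1, 0.001423·s² + 0.02153·s), which
    saturates at 1 near s ≈ 20%.
    """
    slope_deg = np.asarray(slope_deg, dtype=float)
    icept = np.asarray(interception_frac, dtype=float)
    buf = np.asarray(buffer_frac, dtype=float)
    if np.any(slope_deg < 0) or np.any(slope_deg > 90):
        raise ValueError("slope_deg outside [0, 90]")
    if np.any((icept < 0) | (icept > 1)) or np.any((buf < 0) | (buf > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    s = 100.0 * np.tan(np.radians(slope_deg))
    f_slope = np.minimum(1.0, 0.001423 * s**2 + 0.02153 * s)
    out = f_slope * (1.0 - icept) * (1.0 - buf)
    return float(out) if out.ndim == 0 else out


def runoff_loss_percent(env: CellEnvironment, ai: AiParams) -> float:
    """L%_ro for one cell/month/AI; see module docstring for the expression.

    Q=P=0 is a dry month: Q/P := 0, so the loss is 0. Q>0 with P=0 is
    physically inconsistent input and is rejected.
    """
    if math.isnan(env.q_mm) or math.isnan(env.p_mm):
        raise ValueError("NaN hydrology input")
    if env.p_mm == 0:
        if env.q_mm > 0:
            raise ValueError("runoff > 0 with zero precipitation")
        return 0.0
    qp = env.q_mm / env.p_mm
    f = (env.f_override if env.f_override is not None
         else slope_interception_buffer_factor(env.slope_deg))
    kd = soil_water_coefficient(ai.koc, env.soc_percent)
    return qp * f * degradation_factor(ai.dt50_soil_days) * 100.0 / (1.0 + kd)


def monthly_loss_grid(grid: EnvGrid, ai: AiParams, month: int,
                      f_override: float | None = None,
                      interception_frac: float = 0.0,
                      buffer_frac: float = 0.0) -> np.ndarray:
    """Elementwise L%_ro over the grid for one AI and month.

    Requires layers slope_deg, soc_percent, precip_mm[month], runoff_mm[month].
    Nodata in any input propagates as NaN in the output.
    """
    if not 0 <= month < grid.n_months:
        raise IndexError(f"month {month} outside [0, {grid.n_months})")
    p = grid.precip(month)
    q = grid.runoff(month)
    slope = grid.layer("slope_deg")
    soc = grid.layer("soc_percent")
    bad = (grid.mask(f"precip_mm[{month}]") | grid.mask(f"runoff_mm[{month}]")
           | grid.mask("slope_deg") | grid.mask("soc_percent"))

    with np.errstate(divide="ignore", invalid="ignore"):
        qp = np.where(p > 0, q / np.where(p > 0, p, 1.0), 0.0)
    if np.any((p == 0) & (q > 0) & ~bad):
        raise ValueError("runoff > 0 with zero precipitation in grid")
    if f_override is not None:
        f = f_override
    else:
        f = slope_interception_buffer_factor(slope, interception_frac,
                                             buffer_frac)
    kd = soil_water_coefficient(ai.koc, soc)
    loss = qp * f * degradation_factor(ai.dt50_soil_days) * 100.0 / (1.0 + kd)
    loss = np.where(bad, np.nan, loss)
    return loss


def load_ai_table(path) -> list[AiParams]:
    """Read an AI inventory CSV: name, cas, class, koc_L_per_kg, dt50_soil_days."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "cas", "class", "koc_L_per_kg", "dt50_soil_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"AI table missing columns: {sorted(missing)}")
    return [
        AiParams(name=str(r["name"]), cas=str(r["cas"]),
                 ai_class=str(r["class"]), koc=float(r["koc_L_per_kg"]),
                 dt50_soil_days=float(r["dt50_soil_days"]))
        for _, r in df.iterrows()
    ]


def write_ai_table(path, ais: list[AiParams]) -> None:
    import pandas as pd

    pd.DataFrame(
        {"name": [a.name for a in ais], "cas": [a.cas for a in ais],
         "class": [a.ai_class for a in ais], "koc_L_per_kg": [a.koc for a in ais],
         "dt50_soil_days": [a.dt50_soil_days for a in ais]}
    ).to_csv(path, index=False)
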