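"""Sensor design scoring and selection over the study grid.

Each (wavelength, separation) cell of the 10 x 3 study grid is scored
on three criteria:

* *reduced noise* — the mean penetration depth must exceed the bottom
  of the bloodless layers (stratum corneum + epidermis, 0.27 mm by
  default), so the signal carries blood information rather than surface
  noise;
* *high sensitivity* — the magnitude of the ordinary-least-squares
  slope of absorbance against lactate concentration;
* *optimal power level* — the relative detected power must reach a
  usable threshold (0.1% of the incident power by default).

The selector keeps cells passing both boolean criteria and returns the
one with the largest sensitivity; ties break towards the larger
wavelength, then the smaller separation.  This is one concrete
formalisation of a qualitative multi-criteria judgement; the thresholds
are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WAVELENGTH_CATEGORIES",
    "DesignCriteria",
    "InfeasibleDesignError",
    "sensitivity_slope",
    "score_design",
    "select_optimal",
]

#: The three spectral categories partitioning the ten study wavelengths.
WAVELENGTH_CATEGORIES = {
    "lactate_peak": (1684.0, 1730.0, 1752.0, 2129.0, 2259.0, 2299.0),
    "water_peak": (1920.0,),
    "non_peak": (1310.0, 1550.0, 1650.0),
}

SCORE_COLUMNS = [
    "wavelength_nm",
    "separation_mm",
    "mean_penetration_depth_mm",
    "relative_power_pct",
    "sensitivity",
    "linearity_r2",
    "noise_ok",
    "power_ok",
    "feasible",
]


@dataclass(frozen=True)
class DesignCriteria:
    """Scoring thresholds for the three design criteria."""

    noise_depth_mm: float = 0.27       # bottom of the bloodless layers
    power_threshold_pct: float = 0.1
    use_normalized_slope: bool = False
    reference_c_mmol_l: float = 2.0    # concentration at which power/depth are read

    def __post_init__(self) -> None:
        if self.power_threshold_pct <= 0:
            raise ValueError("power threshold must be positive")


class InfeasibleDesignError(RuntimeError):
    """No grid cell satisfies the boolean criteria."""

    def __init__(self, failures: pd.DataFrame):
        self.failures = failures
        lines = [
            f"  ({row.wavelength_nm:g} nm, {row.separation_mm:g} mm): "
            + ", ".join(
                c for c, bad in (("noise", not row.noise_ok), ("power", not row.power_ok)) if bad
            )
            for row in failures.itertuples()
        ]
        super().__init__("no feasible design cell; failing criteria:\n" + "\n".join(lines))


def sensitivity_slope(concentrations, absorbances) -> tuple[float, float]:
    """OLS slope and r^2 of absorbance against concentration.

    Evaluated from the closed-form normal equations.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size:
        raise ValueError("concentration and absorbance lengths differ")
    if c.size < 3:
        raise ValueError(f"need >= 3 concentrations for a slope, got {c.size}")
    dc = c - c.mean()
    da = a - a.mean()
    sxx = float(dc @ dc)
    if sxx == 0.0:
        raise ValueError("concentrations are all identical")
    sxy = float(dc @ da)
    syy = float(da @ da)
    slope = sxy / sxx
    r2 = 0.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return slope, r2


def _normalized(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)


def score_design(
    sweep: pd.DataFrame,
    criteria: DesignCriteria = DesignCriteria(),
) -> pd.DataFrame:
    """Score every (wavelength, separation) cell of a concentration sweep.

    ``sweep`` is the long-format frame produced by
    :func:`swirmc.analysis.grid_sweep`.  Cells with fewer than three
    concentrations are dropped with a warning column-free partial grid.
    """
    import warnings

    rows = []
    for (wl, d), cell in sweep.groupby(["wavelength_nm", "separation_mm"]):
        cell = cell.sort_values("c_lactate_mmol_l")
        if len(cell) < 3:
            warnings.warn(
                f"cell ({wl} nm, {d} mm) has {len(cell)} concentrations; skipped",
                RuntimeWarning,
            )
            continue
        a = cell["absorbance_au"].to_numpy()
        if criteria.use_normalized_slope:
            a = _normalized(a)
        slope, r2 = sensitivity_slope(cell["c_lactate_mmol_l"].to_numpy(), a)
        # read depth and power at the reference concentration (nearest row)
        iref = (cell["c_lactate_mmol_l"] - criteria.reference_c_mmol_l).abs().idxmin()
        d_m = float(cell.loc[iref, "mean_penetration_depth_mm"])
        power = float(cell.loc[iref, "relative_power_pct"])
        noise_ok = bool(d_m > criteria.noise_depth_mm)
        power_ok = bool(power >= criteria.power_threshold_pct)
        rows.append(
            {
                "wavelength_nm": wl,
                "separation_mm": d,
                "mean_penetration_depth_mm": d_m,
                "relative_power_pct": power,
                "sensitivity": abs(slope),
                "linearity_r2": r2,
                "noise_ok": noise_ok,
                "power_ok": power_ok,
                "feasible": noise_ok and power_ok,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def select_optimal(scored: pd.DataFrame) -> tuple[float, float]:
    """Pick the (wavelength, separation) cell to build the sensor around.

    Feasibility filter, then maximal sensitivity; deterministic
    tie-break towards larger wavelength, then smaller separation.
    """
    feasible = scored[scored["feasible"]]
    if feasible.empty:
        raise InfeasibleDesignError(scored)
    best = feasible.sort_values(
        ["sensitivity", "wavelength_nm", "separation_mm"],
        ascending=[False, False, True],
    ).iloc[0]
    return float(best["wavelength_nm"]), float(best["separation_mm"])
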