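"""Redox potentiometry: equilibrium electron partitioning and Nernst analysis.

The xanthine/xanthine-oxidase method delivers electrons slowly enough that an
enzyme couple and an indicator dye stay at mutual redox equilibrium.  At each
step the solution potential E satisfies both Nernst relations

    ln(red/ox)_couple = n_couple * F * (E_m,couple - E) / (R*T)

together with the electron balance
n_enz*[E]_tot*f_enz + n_dye*[dye]_tot*f_dye = delivered.  The midpoint of the
enzyme couple is then recovered from the linearized Nernst plot of
ln(red/ox)_enzyme against ln(red/ox)_dye, whose slope is n_enz/n_dye and
whose intercept is (n_enz*F/RT)*(E_m,enz - E_m,dye).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .params import RateParameterSet, T_POTENTIOMETRY, thermal_voltage_mv


class PotentiometryError(ValueError):
    pass


@dataclass
class TitrationSeries:
    """Stepwise redox-equilibration record of an enzyme couple and a dye."""

    delivered: np.ndarray           # mol/L electron equivalents, non-decreasing
    potential: np.ndarray           # mV, non-increasing
    frac_red_enzyme: np.ndarray
    frac_red_dye: np.ndarray
    abs_enzyme: np.ndarray          # projected enzyme-band absorbance, AU
    abs_dye: np.ndarray             # projected dye 600 nm absorbance, AU
    enzyme_total: float             # mol/L
    dye_total: float                # mol/L
    em_dye: float                   # mV
    n_dye: int
    temperature: float = T_POTENTIOMETRY
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("delivered", "potential", "frac_red_enzyme",
                     "frac_red_dye", "abs_enzyme", "abs_dye"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.delivered) < 0):
            raise ValueError("delivered electrons must be non-decreasing")
        if np.any(np.diff(self.potential) > 1e-9):
            raise ValueError("solution potential must be non-increasing")
        for fr in (self.frac_red_enzyme, self.frac_red_dye):
            if np.any((fr < 0) | (fr > 1)):
                raise ValueError("fractions reduced must lie in [0, 1]")

    @property
    def n_steps(self) -> int:
        return int(self.delivered.size)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame({
            "step": np.arange(self.n_steps),
            "delivered_M": self.delivered,
            "potential_mV": self.potential,
            "frac_red_enzyme": self.frac_red_enzyme,
            "frac_red_dye": self.frac_red_dye,
            "abs_enzyme_au": self.abs_enzyme,
            "abs_dye_au": self.abs_dye,
        }).to_csv(path, index=False)
        if sidecar:
            meta = {
                "enzyme_total_M": self.enzyme_total,
                "dye_total_M": self.dye_total,
                "em_dye_mV": self.em_dye,
                "n_dye": self.n_dye,
                "temperature_K": self.temperature,
                "metadata": self.metadata,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationSeries":
        path = Path(path)
        df = pd.read_csv(path)
        side = path.with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(
            df["delivered_M"].to_numpy(), df["potential_mV"].to_numpy(),
            df["frac_red_enzyme"].to_numpy(), df["frac_red_dye"].to_numpy(),
            df["abs_enzyme_au"].to_numpy(), df["abs_dye_au"].to_numpy(),
            enzyme_total=float(meta.get("enzyme_total_M", np.nan)),
            dye_total=float(meta.get("dye_total_M", np.nan)),
            em_dye=float(meta.get("em_dye_mV", -139.0)),
            n_dye=int(meta.get("n_dye", 2)),
            temperature=float(meta.get("temperature_K", T_POTENTIOMETRY)),
            metadata=meta.get("metadata", {}))


@dataclass
class NernstFitResult:
    em_enz: float       # mV
    slope: float        # estimates n_enz/n_dye
    intercept: float
    em_se: float
    slope_se: float
    n_enz_estimate: float
    n_points: int

    def to_dict(self) -> dict:
        return {"Em_enz_mV": self.em_enz, "slope": self.slope,
                "intercept": self.intercept, "Em_se_mV": self.em_se,
                "slope_se": self.slope_se,
                "n_enz_estimate": self.n_enz_estimate,
                "n_points": self.n_points}


def fraction_reduced(potential_mv: float, em_mv: float, n: int,
                     temperature: float = T_POTENTIOMETRY) -> float:
    """Nernst fraction reduced of a couple at a given solution potential."""
    vt = thermal_voltage_mv(temperature)
    ratio = math.exp(n * (em_mv - potential_mv) / vt)
    return ratio / (1.0 + ratio)


def equilibrium_partition(delivered: float, params: RateParameterSet,
                          enzyme_total: float, dye_total: float,
                          temperature: float = T_POTENTIOMETRY,
                          xtol_mv: float = 1e-3) -> tuple[float, float, float]:
    """Solution potential and fractions reduced at a given electron dose.

    Solves the electron balance for the unique potential E (monotone in E,
    found by bracketed root search to ``xtol_mv``).  The boundary doses 0 and
    full capacity correspond to E = +/- infinity and return exact fractions
    0 and 1.
    """
    capacity = params.n_enz * enzyme_total + params.n_dye * dye_total
    if delivered < -1e-15 or delivered > capacity * (1 + 1e-12):
        raise PotentiometryError(
            f"delivered electrons {delivered} outside [0, capacity={capacity}]")

    def total_reduced(e_mv: float) -> float:
        fe = fraction_reduced(e_mv, params.Em_enz, params.n_enz, temperature)
        fd = fraction_reduced(e_mv, params.Em_dye, params.n_dye, temperature)
        return params.n_enz * enzyme_total * fe + params.n_dye * dye_total * fd

    if delivered <= 0:
        return math.inf, 0.0, 0.0
    if delivered >= capacity:
        return -math.inf, 1.0, 1.0

    lo = min(params.Em_enz, params.Em_dye) - 2000.0
    hi = max(params.Em_enz, params.Em_dye) + 2000.0
    e = brentq(lambda x: total_reduced(x) - delivered, lo, hi, xtol=xtol_mv)
    fe = fraction_reduced(e, params.Em_enz, params.n_enz, temperature)
    fd = fraction_reduced(e, params.Em_dye, params.n_dye, temperature)
    return float(e), float(fe), float(fd)


def nernst_fit(series: TitrationSeries,
               window: tuple[float, float] = (0.1, 0.9)) -> NernstFitResult:
    """Linearized Nernst-plot regression recovering the enzyme midpoint.

    Uses only steps where both couples' fractions reduced lie inside
    ``window``.  slope = n_enz/n_dye; the electron count of the enzyme couple
    is taken as the rounded slope*n_dye, and
    E_m,enz = E_m,dye + intercept * (RT/F) / n_enz.
    """
    lo, hi = window
    fe = series.frac_red_enzyme
    fd = series.frac_red_dye
    keep = (fe >= lo) & (fe <= hi) & (fd >= lo) & (fd <= hi)
    if keep.sum() < 5:
        raise PotentiometryError(
            f"only {int(keep.sum())} steps inside window {window}; need >= 5")
    y = np.log(fe[keep] / (1.0 - fe[keep]))
    x = np.log(fd[keep] / (1.0 - fd[keep]))
    reg = stats.linregress(x, y)
    vt = thermal_voltage_mv(series.temperature)
    n_est = reg.slope * series.n_dye
    n_enz = int(min(2, max(1, round(n_est))))
    em = series.em_dye + reg.intercept * vt / n_enz
    em_se = (reg.intercept_stderr or np.nan) * vt / n_enz
    return NernstFitResult(float(em), float(reg.slope), float(reg.intercept),
                           float(em_se), float(reg.stderr), float(n_est),
                           int(keep.sum()))
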