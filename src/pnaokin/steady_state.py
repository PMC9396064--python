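"""Steady-state turnover: velocity extraction, Michaelis-Menten fitting and
the rate-limiting-step consistency analysis.

Turnover reduces two CycN per catalytic cycle, so per-enzyme velocities are
the 550 nm CycN-reduction rate divided by two.  The consistency analysis
compares the fitted k_cat with the microscopic constants from transient
kinetics: the predicted cycle k_cat is the harmonic combination
(1/k_red + 1/k_rel)^-1 of the two first-order steps, and the verdict is
"product-release-limited" when product release is much slower than hydride
transfer and the fitted k_cat does not exceed it by more than 20%.  The
oxidant-preference ratios k_cyc1/k_ox_o2 and k_cyc2/k_ox_o2 quantify how
much better CycN is than O2 as an electron acceptor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .observables import DELTA_EPS_CYCN_550, Trace
from .params import RateParameterSet

VERDICTS = ("product-release-limited", "reduction-limited", "mixed",
            "inconsistent")


class SteadyStateError(ValueError):
    pass


@dataclass
class MMFitResult:
    k_cat: float           # s^-1
    K_M: float             # mol/L
    k_cat_se: float
    K_M_se: float
    residual_sd: float
    unidentifiable: bool = False

    def __post_init__(self) -> None:
        if self.k_cat <= 0 or self.K_M <= 0:
            raise ValueError("k_cat and K_M must be positive")

    def to_dict(self) -> dict:
        return {"k_cat_per_s": self.k_cat, "K_M_M": self.K_M,
                "k_cat_se": self.k_cat_se, "K_M_se": self.K_M_se,
                "residual_sd": self.residual_sd,
                "unidentifiable": self.unidentifiable}


@dataclass
class ConsistencyReport:
    fitted_k_cat: float
    k_rel: float
    k_red: float
    predicted_k_cat: float      # (1/k_red + 1/k_rel)^-1
    predicted_K_M: float        # predicted_k_cat*(1/k_cyc1 + 1/k_cyc2)
    verdict: str
    ratio_cyc1_o2: float        # k_cyc1/k_ox_o2, 2 significant figures
    ratio_cyc2_o2: float        # k_cyc2/k_ox_o2, 2 significant figures

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}")
        if self.ratio_cyc1_o2 <= 0 or self.ratio_cyc2_o2 <= 0:
            raise ValueError("oxidant-preference ratios must be positive")

    def to_dict(self) -> dict:
        return {"fitted_k_cat_per_s": self.fitted_k_cat,
                "k_rel_per_s": self.k_rel, "k_red_per_s": self.k_red,
                "predicted_k_cat_per_s": self.predicted_k_cat,
                "predicted_K_M_M": self.predicted_K_M,
                "verdict": self.verdict,
                "ratio_k_cyc1_over_k_ox_o2": self.ratio_cyc1_o2,
                "ratio_k_cyc2_over_k_ox_o2": self.ratio_cyc2_o2}


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def extract_velocity(trace: Trace, enzyme_conc: float,
                     window_fraction: float = 0.1,
                     delta_eps: float = DELTA_EPS_CYCN_550,
                     path_length: float = 1.0,
                     min_points: int = 10) -> float:
    """Per-enzyme initial velocity (s^-1) from a 550 nm progress trace.

    A line is fit over the initial window spanning the first
    ``window_fraction`` of the total amplitude (amplitude-based, so the
    window adapts to concentration-dependent time scales); the slope is
    converted by v = (dA/dt) / (delta_eps * path * [E]) / 2, the factor of
    two accounting for the two CycN reduced per turnover.
    """
    if enzyme_conc <= 0:
        raise SteadyStateError("enzyme concentration must be positive")
    t, a = trace.unsaturated()
    if t.size < min_points:
        raise SteadyStateError("too few unsaturated points in trace")
    total = a[-1] - a[0]
    if total == 0:
        return 0.0
    keep = np.abs(a - a[0]) <= window_fraction * abs(total)
    # the window is contiguous from the start; cut at the first excursion
    stop = np.argmin(keep) if not keep.all() else keep.size
    stop = max(stop, min_points)
    if stop > t.size:
        raise SteadyStateError(
            f"initial window has fewer than {min_points} unsaturated points")
    tw, aw = t[:stop], a[:stop]
    slope = np.polyfit(tw, aw, 1)[0]
    if slope < 0 and total > 0:
        warnings.warn("negative initial slope on a rising trace",
                      stacklevel=2)
    return float(slope / (delta_eps * path_length * enzyme_conc) / 2.0)


def fit_mm(dataset) -> MMFitResult:
    """Least-squares Michaelis-Menten fit v = k_cat*[C]/(K_M + [C])."""
    conc = np.asarray(dataset.cycn_concs, dtype=float)
    v = np.asarray(dataset.velocities, dtype=float)
    if np.unique(conc).size < 5:
        raise SteadyStateError("need >= 5 distinct concentrations")

    def mm(c, kcat, km):
        return kcat * c / (km + c)

    p0 = (float(v.max()) * 1.2, float(np.median(conc)))
    popt, pcov = curve_fit(mm, conc, v, p0=p0, maxfev=20000,
                           bounds=((0, 0), (np.inf, np.inf)))
    perr = np.sqrt(np.diag(pcov))
    resid = v - mm(conc, *popt)
    dof = max(conc.size - 2, 1)
    unident = bool(popt[1] > 10.0 * conc.max())
    if unident:
        warnings.warn("K_M estimate exceeds 10x the largest concentration; "
                      "fit is unidentifiable", stacklevel=2)
    return MMFitResult(float(popt[0]), float(popt[1]), float(perr[0]),
                       float(perr[1]), float(np.sqrt(resid @ resid / dof)),
                       unident)


def consistency_analysis(mm: MMFitResult,
                         params: RateParameterSet) -> ConsistencyReport:
    """Compare fitted steady-state k_cat with the microscopic constants."""
    k_red, k_rel = params.k_red, params.k_rel
    pred_kcat = 1.0 / (1.0 / k_red + 1.0 / k_rel)
    pred_km = pred_kcat * (1.0 / params.k_cyc1 + 1.0 / params.k_cyc2)
    kcat = mm.k_cat
    if kcat > 1.2 * pred_kcat:
        verdict = "inconsistent"
    elif k_rel < 0.5 * k_red and kcat <= 1.2 * k_rel:
        verdict = "product-release-limited"
    elif k_red < 0.5 * k_rel and kcat <= 1.2 * k_red:
        verdict = "reduction-limited"
    else:
        verdict = "mixed"
    return ConsistencyReport(
        fitted_k_cat=kcat, k_rel=k_rel, k_red=k_red,
        predicted_k_cat=pred_kcat, predicted_K_M=pred_km, verdict=verdict,
        ratio_cyc1_o2=round_sig(params.k_cyc1 / params.k_ox_o2, 2),
        ratio_cyc2_o2=round_sig(params.k_cyc2 / params.k_ox_o2, 2))
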