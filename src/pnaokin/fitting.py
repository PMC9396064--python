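"""Multi-exponential trace fitting and secondary (concentration-level) fits.

Trace models: Y(t) = sum_i dA_i * exp(-k_obs_i * t) + A_inf with 1-3 phases.
Rates are fit in log space (positivity by construction); initial guesses come
from a log-spaced rate grid with amplitudes obtained by linear projection,
and up to eight starts are polished with Levenberg-Marquardt (lmfit).
Phase-count selection minimizes the Bayesian information criterion, ties
broken toward fewer phases.

Secondary models for k_obs versus concentration:
``linear``      k_obs = slope*[X] + intercept (unweighted least squares)
``hyperbolic``  k_obs = k_red*[S]/(K_d+[S])
``constant``    inverse-variance-weighted mean
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .observables import Trace


class FitError(RuntimeError):
    """A fit could not be performed or failed to converge."""


@dataclass
class ExponentialFitResult:
    """Per-trace phase parameters; phases sorted by descending rate."""

    amplitudes: np.ndarray          # dA_i, AU
    rates: np.ndarray               # k_obs_i, s^-1, descending
    a_inf: float                    # AU
    amplitude_se: np.ndarray
    rate_se: np.ndarray
    a_inf_se: float
    residual_sd: float
    n_phases: int
    converged: bool
    n_points: int
    message: str = ""

    def __post_init__(self) -> None:
        order = np.argsort(self.rates)[::-1]
        self.rates = np.asarray(self.rates, dtype=float)[order]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)[order]
        self.rate_se = np.asarray(self.rate_se, dtype=float)[order]
        self.amplitude_se = np.asarray(self.amplitude_se, dtype=float)[order]

    @property
    def total_amplitude(self) -> float:
        return float(np.sum(np.abs(self.amplitudes)))

    def significant_phases(self, max_rel_rate_se: float = 0.5,
                           min_amp_sigma: float = 2.0) -> list[int]:
        """Indices (rate-descending) of phases that are actually determined.

        A phase is significant when its rate has a finite standard error
        below ``max_rel_rate_se`` of the rate and its amplitude exceeds
        ``min_amp_sigma`` standard errors.  Ill-determined phases (a noise
        spike absorbed as a very fast exponential, or a near-zero-rate
        baseline drift) fail these tests and are excluded from secondary
        analyses.  Fits without error estimates keep all phases.
        """
        if not (np.all(np.isfinite(self.rate_se))
                and np.all(np.isfinite(self.amplitude_se))):
            return list(range(self.n_phases))
        out = []
        for i in range(self.n_phases):
            if self.rate_se[i] > max_rel_rate_se * self.rates[i]:
                continue
            if abs(self.amplitudes[i]) < min_amp_sigma * self.amplitude_se[i]:
                continue
            out.append(i)
        return out

    def bic(self) -> float:
        n = self.n_points
        ssr = self.residual_sd ** 2 * max(n - (2 * self.n_phases + 1), 1)
        p = 2 * self.n_phases + 1
        return n * math.log(max(ssr / n, 1e-300)) + p * math.log(n)

    def to_dict(self) -> dict:
        return {
            "n_phases": self.n_phases,
            "rates_per_s": self.rates.tolist(),
            "amplitudes_au": self.amplitudes.tolist(),
            "a_inf_au": self.a_inf,
            "rate_se": self.rate_se.tolist(),
            "amplitude_se": self.amplitude_se.tolist(),
            "a_inf_se": self.a_inf_se,
            "residual_sd": self.residual_sd,
            "converged": self.converged,
            "n_points": self.n_points,
        }


@dataclass
class SecondaryFitResult:
    """Concentration-dependence fit of observed rates."""

    model: str                      # linear | hyperbolic | constant
    params: dict
    stderr: dict
    points: list = field(default_factory=list)
    unidentifiable: bool = False

    def to_dict(self) -> dict:
        return {"model": self.model, "params": self.params,
                "stderr": self.stderr, "unidentifiable": self.unidentifiable}


def _model_eval(t: np.ndarray, amps: Sequence[float], rates: Sequence[float],
                a_inf: float) -> np.ndarray:
    y = np.full(t.shape, float(a_inf))
    for a, k in zip(amps, rates):
        y = y + a * np.exp(-k * t)
    return y


def _linear_amplitudes(t: np.ndarray, y: np.ndarray,
                       rates: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Best amplitudes + offset for fixed rates (variable projection)."""
    cols = [np.exp(-k * t) for k in rates] + [np.ones_like(t)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef[:-1], float(coef[-1]), float(resid @ resid)


def _candidate_starts(t: np.ndarray, y: np.ndarray, phases: int,
                      n_grid: int = 12) -> list[tuple[np.ndarray, float, float]]:
    """Rank rate combinations from a log-spaced grid by linear-projection SSR."""
    t1 = max(t[0], 1e-9)
    t_end = t[-1]
    lo, hi = 0.1 / t_end, 10.0 / t1
    grid = np.geomspace(lo, hi, n_grid)
    ranked = []
    for combo in itertools.combinations(range(n_grid), phases):
        rates = grid[list(combo)]
        amps, a_inf, ssr = _linear_amplitudes(t, y, rates)
        ranked.append((ssr, rates, amps, a_inf))
    ranked.sort(key=lambda r: r[0])
    return [(r[1], r[2], r[3]) for r in ranked]


def fit_exponentials(trace: Trace, phases: int,
                     initial_guesses: dict | None = None,
                     max_starts: int = 8) -> ExponentialFitResult:
    """Nonlinear least-squares fit of a 1-3 phase exponential model.

    Saturated points are excluded.  The convergence flag is honest: a result
    with ``converged=False`` carries the best attempt plus a diagnostic
    message and should not be used silently.
    """
    if phases not in (1, 2, 3):
        raise ValueError("phases must be 1, 2 or 3")
    t, y = trace.unsaturated()
    if t.size < 10 * phases:
        raise FitError(
            f"need >= {10 * phases} unsaturated points for {phases} phases, "
            f"got {t.size}")

    starts: list[tuple[np.ndarray, float, float]] = []
    if initial_guesses is not None:
        rates0 = np.asarray(initial_guesses["rates"], dtype=float)
        if "amplitudes" in initial_guesses:
            amps0 = np.asarray(initial_guesses["amplitudes"], dtype=float)
            ainf0 = float(initial_guesses.get("a_inf", y[-1]))
        else:
            amps0, ainf0, _ = _linear_amplitudes(t, y, rates0)
        starts.append((rates0, amps0, ainf0))
    starts.extend(_candidate_starts(t, y, phases))

    scale = max(np.ptp(y), 1e-6)

    def residual(p):
        amps = [p[f"amp{i}"].value for i in range(phases)]
        rates = [math.exp(p[f"lnk{i}"].value) for i in range(phases)]
        return _model_eval(t, amps, rates, p["a_inf"].value) - y

    best = None
    for rates0, amps0, ainf0 in starts[:max_starts]:
        params = lmfit.Parameters()
        for i in range(phases):
            params.add(f"lnk{i}", value=float(np.log(max(rates0[i], 1e-12))),
                       min=-30.0, max=30.0)
            params.add(f"amp{i}", value=float(amps0[i]),
                       min=-100 * scale, max=100 * scale)
        params.add("a_inf", value=ainf0, min=y.min() - 10 * scale,
                   max=y.max() + 10 * scale)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # singular steps etc.; try next start
            continue
        ssr = float(np.sum(res.residual ** 2))
        if best is None or ssr < best[0] * (1 - 1e-9):
            best = (ssr, res)
        if res.success and res.errorbars:
            if best[1] is res:
                break

    if best is None:
        raise FitError("all multi-start exponential fits failed")

    ssr, res = best
    p = res.params
    rates = np.array([math.exp(p[f"lnk{i}"].value) for i in range(phases)])
    amps = np.array([p[f"amp{i}"].value for i in range(phases)])
    rate_se = np.array([
        rates[i] * (p[f"lnk{i}"].stderr or np.nan) for i in range(phases)])
    amp_se = np.array([p[f"amp{i}"].stderr or np.nan for i in range(phases)])
    dof = max(t.size - (2 * phases + 1), 1)
    converged = bool(res.success) and bool(res.errorbars)
    return ExponentialFitResult(
        amplitudes=amps, rates=rates, a_inf=float(p["a_inf"].value),
        amplitude_se=amp_se, rate_se=rate_se,
        a_inf_se=float(p["a_inf"].stderr or np.nan),
        residual_sd=math.sqrt(ssr / dof), n_phases=phases,
        converged=converged, n_points=int(t.size),
        message="" if converged else str(res.message))


def select_phase_count(trace: Trace, max_phases: int = 3) -> int:
    """Phase count (1..max_phases) minimizing BIC; ties go to fewer phases."""
    if not 1 <= max_phases <= 3:
        raise ValueError("max_phases must be 1..3")
    bics: dict[int, float] = {}
    for n in range(1, max_phases + 1):
        try:
            fit = fit_exponentials(trace, n)
        except FitError:
            continue
        if fit.converged or n == 1:
            bics[n] = fit.bic()
    if not bics:
        raise FitError("no candidate phase count could be fit")
    best = min(bics.values())
    for n in sorted(bics):  # ascending: ties broken toward fewer phases
        if bics[n] <= best + 1e-9:
            return n
    return max(bics)  # unreachable


def fit_secondary(points: Iterable[tuple], model: str) -> SecondaryFitResult:
    """Fit the concentration dependence of observed rates.

    ``points`` is an iterable of (concentration mol/L, k_obs s^-1[, se]).
    """
    pts = [tuple(p) for p in points]
    conc = np.array([p[0] for p in pts], dtype=float)
    kobs = np.array([p[1] for p in pts], dtype=float)
    se = np.array([p[2] if len(p) > 2 and p[2] is not None and p[2] > 0
                   else np.nan for p in pts], dtype=float)
    n_distinct = np.unique(conc).size

    if model == "linear":
        if n_distinct < 3:
            raise FitError("linear secondary fit needs >= 3 distinct concentrations")
        reg = stats.linregress(conc, kobs)
        return SecondaryFitResult(
            "linear",
            {"slope": float(reg.slope), "intercept": float(reg.intercept)},
            {"slope": float(reg.stderr), "intercept": float(reg.intercept_stderr)},
            points=pts)

    if model == "hyperbolic":
        if n_distinct < 4:
            raise FitError("hyperbolic secondary fit needs >= 4 distinct concentrations")

        def hyp(s, k_red, kd):
            return k_red * s / (kd + s)

        p0 = (float(kobs.max()) * 1.2, float(np.median(conc)))
        popt, pcov = curve_fit(hyp, conc, kobs, p0=p0, maxfev=20000,
                               bounds=((0, 0), (np.inf, np.inf)))
        perr = np.sqrt(np.diag(pcov))
        unident = popt[1] > 10.0 * conc.max()
        return SecondaryFitResult(
            "hyperbolic",
            {"k_red": float(popt[0]), "K_d": float(popt[1])},
            {"k_red": float(perr[0]), "K_d": float(perr[1])},
            points=pts, unidentifiable=bool(unident))

    if model == "constant":
        if len(pts) < 3:
            raise FitError("constant secondary fit needs >= 3 points")
        if np.all(np.isfinite(se)):
            w = 1.0 / se ** 2
            mean = float(np.sum(w * kobs) / np.sum(w))
            mean_se = float(np.sqrt(1.0 / np.sum(w)))
        else:
            mean = float(np.mean(kobs))
            mean_se = float(np.std(kobs, ddof=1) / np.sqrt(len(kobs))) \
                if len(kobs) > 1 else float("nan")
        return SecondaryFitResult("constant", {"mean": mean},
                                  {"mean": mean_se}, points=pts)

    raise ValueError(f"unknown secondary model {model!r}")
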