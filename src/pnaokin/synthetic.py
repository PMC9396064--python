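"""Seeded synthetic datasets for the three experiment classes.

Generators emulate the statistical structure the analysis assumes:
mass-action dynamics of the catalytic cycle, Gaussian instrument noise,
stopped-flow dead time (which truncates the log-spaced time grid; t = 0 is
flow stop) and CCD saturation above 1.5 AU.  Concentrations are always
labeled *after* 1:1 mixing; published "before mixing" values are halved.

All randomness flows from one root seed through named integer substreams, so
identical seeds yield bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .observables import (SATURATION_LIMIT_AU, ExtinctionTable, Trace,
                          default_extinction_table, project_absorbance)
from .params import RateParameterSet, T_POTENTIOMETRY
from .potentiometry import TitrationSeries, equilibrium_partition
from .scheme import build_pnao_scheme, eigenrates, integrate

UM = 1e-6  # mol/L per micromolar

# default concentration panels, mol/L after mixing
PON_PANEL = tuple(c * UM for c in (25, 50, 100, 150, 250, 375, 500))
O2_PANEL = tuple(c * UM for c in (75, 150, 300, 600, 1200))
CYCN_TRANSIENT_PANEL = tuple(c * UM for c in (10, 20, 40, 80, 160, 320))
CYCN_STEADY_PANEL = tuple(np.geomspace(2.5 * UM, 80 * UM, 8))

ENZYME_AFTER_MIXING = 17.5 * UM      # "~35 uM before mixing"
ENZYME_CYCN_TRANSIENT = 5.0 * UM     # keeps the whole panel >= 2*[E]
ENZYME_STEADY_STATE = 0.1 * UM       # 200 nM before mixing
PON_STEADY_STATE = 1e-3              # saturating, 2 mM before mixing

# substream tags
_STREAM = {"reductive": 1, "oxidation_o2": 2, "oxidation_cycn": 3,
           "steady_state": 4, "titration": 5}


@dataclass
class InstrumentModel:
    """Stopped-flow instrument description used by the trace generators."""

    dead_time: float = 0.0015        # s
    noise_sd: float = 0.002          # AU
    n_points: int = 300              # log-spaced samples per trace
    t_end: float | None = None       # s; None = auto (7 / slowest eigenrate)
    saturation_limit: float = SATURATION_LIMIT_AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dead_time < 0 or self.noise_sd < 0:
            raise ValueError("dead_time and noise_sd must be >= 0")
        if self.n_points < 50:
            raise ValueError("need at least 50 points per trace")


@dataclass
class SteadyStateDataset:
    """Initial-velocity dataset of CycN reduction at varying [CycN]."""

    cycn_concs: np.ndarray        # mol/L after mixing, one entry per velocity
    velocities: np.ndarray        # s^-1 per-enzyme turnover (already /2)
    enzyme_conc: float
    pon_conc: float
    replicates: int
    seed: int
    mode: str = "empirical"

    def __post_init__(self) -> None:
        self.cycn_concs = np.asarray(self.cycn_concs, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if np.any(self.cycn_concs <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(self.velocities < 0):
            raise ValueError("velocities must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"cycn_M": self.cycn_concs,
                      "velocity_per_s": self.velocities}).to_csv(path, index=False)
        meta = {"enzyme_conc_M": self.enzyme_conc, "pon_conc_M": self.pon_conc,
                "replicates": self.replicates, "seed": self.seed,
                "mode": self.mode}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SteadyStateDataset":
        path = Path(path)
        df = pd.read_csv(path)
        side = path.with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(df["cycn_M"].to_numpy(), df["velocity_per_s"].to_numpy(),
                   enzyme_conc=float(meta.get("enzyme_conc_M", np.nan)),
                   pon_conc=float(meta.get("pon_conc_M", np.nan)),
                   replicates=int(meta.get("replicates", 1)),
                   seed=int(meta.get("seed", 0)),
                   mode=meta.get("mode", "empirical"))


def _rng(seed: int, experiment: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAM[experiment], int(index)]))


def _grid(instrument: InstrumentModel, slowest_rate: float) -> np.ndarray:
    t_end = instrument.t_end
    if t_end is None:
        t_end = 7.0 / max(slowest_rate, 1e-6)
    t0 = max(instrument.dead_time, t_end * 1e-4, 1e-5)
    return np.geomspace(t0, t_end, instrument.n_points)


def _noisy(trace: Trace, rng: np.random.Generator, sd: float) -> Trace:
    noise = rng.normal(0.0, sd, size=trace.n_points) if sd > 0 \
        else np.zeros(trace.n_points)
    return Trace(trace.time, trace.absorbance + noise, trace.wavelength,
                 trace.saturated, trace.metadata)


def generate_reductive(params: RateParameterSet,
                       pon_concs: Sequence[float] = PON_PANEL,
                       instrument: InstrumentModel | None = None,
                       enzyme_conc: float = ENZYME_AFTER_MIXING,
                       table: ExtinctionTable | None = None) -> list[Trace]:
    """450 nm flavin-reduction traces, one per Pon concentration."""
    pon_concs = list(pon_concs)
    if not pon_concs:
        raise ValueError("empty Pon concentration list")
    if any(c <= 0 or c > 1e-3 for c in pon_concs):
        raise ValueError("Pon concentrations must lie in (0, 1 mM] after mixing")
    instrument = instrument or InstrumentModel()
    table = table or default_extinction_table()
    scheme = build_pnao_scheme(params, "reductive")
    traces = []
    for i, c in enumerate(pon_concs):
        rates = eigenrates(scheme, {"S": c})
        slowest = rates.min() if rates.size else params.k_rel
        grid = _grid(instrument, slowest)
        series = integrate(scheme, {"E_ox": enzyme_conc, "S": c}, grid)
        meta = {"experiment": "reductive", "wavelength_nm": 450.0,
                "pon_M": c, "enzyme_M": enzyme_conc,
                "temperature_K": params.temperature,
                "dead_time_s": instrument.dead_time,
                "noise_sd_au": instrument.noise_sd,
                "seed": instrument.seed, "trace_index": i}
        trace = project_absorbance(series, table, 450.0, meta)
        traces.append(_noisy(trace, _rng(instrument.seed, "reductive", i),
                             instrument.noise_sd))
    return traces


def generate_oxidation_o2(params: RateParameterSet,
                          o2_concs: Sequence[float] = O2_PANEL,
                          instrument: InstrumentModel | None = None,
                          enzyme_conc: float = ENZYME_AFTER_MIXING,
                          table: ExtinctionTable | None = None) -> list[Trace]:
    """450 nm flavin-reoxidation traces; single-exponential, rate k_ox_o2*[O2]."""
    o2_concs = list(o2_concs)
    if not o2_concs:
        raise ValueError("empty O2 concentration list")
    if any(c <= 0 or c > 1.3e-3 for c in o2_concs):
        raise ValueError("O2 concentrations must lie in (0, 1.3 mM]")
    instrument = instrument or InstrumentModel()
    table = table or default_extinction_table()
    scheme = build_pnao_scheme(params, "oxidation_o2")
    traces = []
    for i, c in enumerate(o2_concs):
        kobs = max(params.k_ox_o2 * c, 1e-9)
        grid = _grid(instrument, kobs)
        series = integrate(scheme, {"E_red": enzyme_conc, "O2": c}, grid)
        meta = {"experiment": "oxidation_o2", "wavelength_nm": 450.0,
                "o2_M": c, "enzyme_M": enzyme_conc,
                "temperature_K": params.temperature,
                "dead_time_s": instrument.dead_time,
                "noise_sd_au": instrument.noise_sd,
                "seed": instrument.seed, "trace_index": i}
        trace = project_absorbance(series, table, 450.0, meta)
        traces.append(_noisy(trace, _rng(instrument.seed, "oxidation_o2", i),
                             instrument.noise_sd))
    return traces


def generate_oxidation_cycn(params: RateParameterSet,
                            cycn_concs: Sequence[float] = CYCN_TRANSIENT_PANEL,
                            instrument: InstrumentModel | None = None,
                            enzyme_conc: float = ENZYME_CYCN_TRANSIENT,
                            table: ExtinctionTable | None = None) -> list[Trace]:
    """550 nm CycN-reduction traces from the two sequential electron transfers.

    CycN is clamped in excess (pseudo-first-order).  A minor empirical phase
    of rate ``k_art`` and relative amplitude ``frac_art`` is added on top of
    the mechanistic signal; with the default 0.05 the two electron-transfer
    phases carry ~95% of the total amplitude.
    """
    cycn_concs = list(cycn_concs)
    if not cycn_concs:
        raise ValueError("empty CycN concentration list")
    bad = [c for c in cycn_concs if c < 2.0 * enzyme_conc]
    if bad:
        raise ValueError(
            f"CycN concentrations {bad} below 2*[E]={2 * enzyme_conc}; "
            "sub-stoichiometric regime unsupported")
    instrument = instrument or InstrumentModel()
    table = table or default_extinction_table()
    scheme = build_pnao_scheme(params, "oxidation_cycn")
    traces = []
    for i, c in enumerate(cycn_concs):
        rates = eigenrates(scheme, {"CycN_ox": c})
        slowest = min(rates.min(), params.k_art) if params.frac_art > 0 \
            else rates.min()
        grid = _grid(instrument, slowest)
        series = integrate(scheme, {"E_red": enzyme_conc, "CycN_ox": c}, grid)
        meta = {"experiment": "oxidation_cycn", "wavelength_nm": 550.0,
                "cycn_M": c, "enzyme_M": enzyme_conc,
                "temperature_K": params.temperature,
                "dead_time_s": instrument.dead_time,
                "noise_sd_au": instrument.noise_sd,
                "seed": instrument.seed, "trace_index": i}
        trace = project_absorbance(series, table, 550.0, meta)
        if params.frac_art > 0:
            main_amp = 2.0 * enzyme_conc * table.path_length * (
                table.entries.get(("CycN_red", 550.0), 0.0)
                - table.entries.get(("CycN_ox", 550.0), 0.0))
            art = params.frac_art * main_amp * (1.0 - np.exp(-params.k_art * grid))
            a = trace.absorbance + art
            trace = Trace(grid, a, 550.0, a > instrument.saturation_limit, meta)
        traces.append(_noisy(trace, _rng(instrument.seed, "oxidation_cycn", i),
                             instrument.noise_sd))
    return traces


def cycle_flux(params: RateParameterSet, cycn_conc: float,
               pon_conc: float = PON_STEADY_STATE) -> float:
    """Closed-form steady-state turnover (cycles/s): sum of reciprocal waits.

    1/v = 1/k_red_eff + 1/k_rel + 1/(k_cyc1*[C]) + 1/(k_cyc2*[C]), where
    k_red_eff = k_red*[S]/(Kd+[S]).
    """
    k_red_eff = params.k_red * pon_conc / (params.Kd_pon + pon_conc)
    tau = (1.0 / k_red_eff + 1.0 / params.k_rel
           + 1.0 / (params.k_cyc1 * cycn_conc)
           + 1.0 / (params.k_cyc2 * cycn_conc))
    return 1.0 / tau


def generate_steady_state(params: RateParameterSet,
                          cycn_concs: Sequence[float] = CYCN_STEADY_PANEL,
                          mode: str = "empirical",
                          replicates: int = 1,
                          seed: int = 0,
                          cv: float = 0.05,
                          enzyme_conc: float = ENZYME_STEADY_STATE,
                          pon_conc: float = PON_STEADY_STATE) -> SteadyStateDataset:
    """Initial-velocity dataset of CycN reduction.

    ``empirical`` draws from the Michaelis-Menten law at (kcat_emp,
    Km_cyc_emp) with multiplicative Gaussian noise of the given CV.
    ``mechanistic`` integrates full-cycle progress curves with CycN clamped
    at its initial concentration (the initial-velocity idealization) and
    takes the per-enzyme turnover from the linear late region; it is
    deterministic.  Velocities are per-enzyme turnovers, i.e. the CycN
    reduction rate already divided by two.
    """
    cycn_concs = np.asarray(list(cycn_concs), dtype=float)
    if cycn_concs.size == 0 or np.any(cycn_concs <= 0):
        raise ValueError("CycN concentrations must be strictly positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mode not in ("empirical", "mechanistic"):
        raise ValueError(f"unknown steady-state mode {mode!r}")

    if mode == "empirical":
        rng = _rng(seed, "steady_state", 0)
        conc = np.repeat(cycn_concs, replicates)
        v0 = params.kcat_emp * conc / (params.Km_cyc_emp + conc)
        v = v0 * (1.0 + rng.normal(0.0, cv, size=conc.size))
        v = np.clip(v, 0.0, None)
        return SteadyStateDataset(conc, v, enzyme_conc, pon_conc,
                                  replicates, seed, mode)

    scheme = build_pnao_scheme(params, "full_cycle").with_excess("CycN_ox")
    velocities = []
    for c in cycn_concs:
        tau = 1.0 / cycle_flux(params, c, pon_conc)
        grid = np.linspace(0.0, 12.0 * tau, 400)[1:]
        series = integrate(scheme, {"E_red": enzyme_conc, "S": pon_conc,
                                    "CycN_ox": c}, grid)
        cred = series["CycN_red"]
        half = grid.size // 2
        slope = np.polyfit(grid[half:], cred[half:], 1)[0]
        velocities.append(slope / (2.0 * enzyme_conc))
    conc = np.repeat(cycn_concs, replicates)
    v = np.repeat(np.asarray(velocities), replicates)
    return SteadyStateDataset(conc, np.clip(v, 0.0, None), enzyme_conc,
                              pon_conc, replicates, seed, "mechanistic")


def generate_titration(params: RateParameterSet, steps: int = 40,
                       noise_sd: float = 0.0, seed: int = 0,
                       enzyme_total: float = 35 * UM,
                       dye_total: float = 20 * UM,
                       table: ExtinctionTable | None = None) -> TitrationSeries:
    """Simulated slow reductive titration of the enzyme couple plus dye.

    The xanthine/xanthine-oxidase electron source is abstracted as a monotone
    electron-delivery schedule spanning 1-99% of the total capacity; at every
    step both couples are equilibrated at a common solution potential.
    Absorbance noise (if any) is applied to the projected bands and the
    recorded fractions are recomputed from the noisy absorbances, as in a
    real experiment.
    """
    if steps < 10:
        raise ValueError("need at least 10 titration steps")
    table = table or default_extinction_table()
    temperature = T_POTENTIOMETRY
    capacity = params.n_enz * enzyme_total + params.n_dye * dye_total
    delivered = capacity * np.linspace(0.01, 0.99, steps)
    pot = np.empty(steps)
    fe = np.empty(steps)
    fd = np.empty(steps)
    for i, d in enumerate(delivered):
        pot[i], fe[i], fd[i] = equilibrium_partition(
            d, params, enzyme_total, dye_total, temperature)

    eps_eox = table.entries.get(("E_ox", 450.0), 0.0)
    eps_esq = table.entries.get(("E_sq", 450.0), 0.0)
    eps_dox = table.entries.get(("Dye_ox", 600.0), 0.0)
    eps_dred = table.entries.get(("Dye_red", 600.0), 0.0)
    ae = table.path_length * enzyme_total * (eps_eox * (1 - fe) + eps_esq * fe)
    ad = table.path_length * dye_total * (eps_dox * (1 - fd) + eps_dred * fd)

    fe_obs, fd_obs = fe, fd
    if noise_sd > 0:
        rng = _rng(seed, "titration", 0)
        ae = ae + rng.normal(0.0, noise_sd, steps)
        ad = ad + rng.normal(0.0, noise_sd, steps)
        span_e = table.path_length * enzyme_total * (eps_eox - eps_esq)
        span_d = table.path_length * dye_total * (eps_dox - eps_dred)
        a_e_ox = table.path_length * enzyme_total * eps_eox
        a_d_ox = table.path_length * dye_total * eps_dox
        fe_obs = np.clip((a_e_ox - ae) / span_e, 1e-9, 1 - 1e-9)
        fd_obs = np.clip((a_d_ox - ad) / span_d, 1e-9, 1 - 1e-9)

    meta = {"seed": seed, "noise_sd_au": noise_sd, "steps": steps,
            "Em_enz_true_mV": params.Em_enz, "n_enz_true": params.n_enz}
    return TitrationSeries(delivered, pot, fe_obs, fd_obs, ae, ad,
                           enzyme_total, dye_total, params.Em_dye,
                           params.n_dye, temperature, meta)
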