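"""Mass-action representation and integration of the Pnao catalytic cycle.

The cycle is modeled as a small reaction network over enzyme flavin states
(E_ox, substrate-reduced complex E_redP, free hydroquinone E_red, semiquinone
E_sq) plus co-substrates (Pon "S", O2, CycN_ox/CycN_red, product P).
Substrate binding is lumped by rapid equilibrium: the reduction step carries
an effective first-order rate k_red*[S]/(Kd+[S]).  All steps are treated as
irreversible.  Species held in large excess can be clamped (pseudo-first-order
approximation), in which case the network is linear in the enzyme states and
its noiseless observables are exact sums of exponentials whose rates are the
nonzero eigenvalues of the first-order rate matrix (:func:`eigenrates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm


class SchemeError(ValueError):
    """Invalid scheme construction or use."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed to produce a valid trajectory."""


EXPERIMENTS = ("reductive", "oxidation_o2", "oxidation_cycn", "full_cycle")


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action step.

    ``saturating=(species, K_half)`` marks a rapid-equilibrium lumped step:
    the rate is ``k*[species]/(K_half+[species])*[reactants[0]]`` and the
    modifier species is not consumed.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    saturating: tuple[str, float] | None = None
    label: str = ""

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise SchemeError(f"rate constant of {self.label or self} negative")
        if not 1 <= len(self.reactants) <= 2:
            raise SchemeError("reactions must have one or two reactants")
        if self.saturating is not None and len(self.reactants) != 1:
            raise SchemeError("saturating steps must be unimolecular")


@dataclass
class KineticScheme:
    """Species, reactions and excess-species declaration of one experiment."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    enzyme_states: tuple[str, ...]
    excess_species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        self.enzyme_states = tuple(self.enzyme_states)
        self.excess_species = frozenset(self.excess_species)
        known = set(self.species)
        if not set(self.enzyme_states) <= known:
            raise SchemeError("enzyme states must be listed in species")
        estates = set(self.enzyme_states)
        for rxn in self.reactions:
            names = set(rxn.reactants) | set(rxn.products)
            if rxn.saturating is not None:
                names.add(rxn.saturating[0])
            if not names <= known:
                raise SchemeError(f"unknown species in reaction {rxn}")
            # flavin conservation: exactly one enzyme-state in, one out
            if sum(r in estates for r in rxn.reactants) != 1 or \
               sum(p in estates for p in rxn.products) != 1:
                raise SchemeError(
                    f"reaction {rxn.label or rxn} must map exactly one enzyme "
                    "state to exactly one enzyme state")
            if rxn.order == 2 and len(rxn.reactants) != 2:
                raise SchemeError("bimolecular reaction needs two reactants")

    def with_excess(self, *names: str) -> "KineticScheme":
        """Copy of the scheme with additional clamped (excess) species."""
        return KineticScheme(self.species, self.reactions, self.enzyme_states,
                             self.excess_species | set(names))


@dataclass
class ConcentrationSeries:
    """Time-resolved species concentrations (mol/L) on a strictly increasing grid."""

    time: np.ndarray
    species: tuple[str, ...]
    concentrations: np.ndarray  # shape (n_time, n_species)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (self.time.size, len(self.species)):
            raise ValueError("concentration array shape mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.concentrations, columns=list(self.species),
                            index=pd.Index(self.time, name="time_s"))


def build_pnao_scheme(params, experiment: str,
                      explicit_binding: bool = False,
                      k_on: float = 1e7) -> KineticScheme:
    """Build the reaction scheme for one of the four experiment classes.

    ``reductive``       E_ox --k_red*[S]/(Kd+[S])--> E_redP --k_rel--> E_red + P
    ``oxidation_o2``    E_red + O2 --k_ox_o2--> E_ox  (the semiquinone is
                        unreactive toward O2 and does not appear)
    ``oxidation_cycn``  E_red + CycN_ox --k_cyc1--> E_sq + CycN_red;
                        E_sq + CycN_ox --k_cyc2--> E_ox + CycN_red
    ``full_cycle``      reductive followed by CycN oxidation, closing the cycle.

    With ``explicit_binding=True`` the rapid-equilibrium lumped reduction step
    is replaced by explicit association/dissociation with ``k_on`` (default
    1e7 M^-1 s^-1) and ``k_off = k_on*Kd_pon``, for sensitivity checks.
    """
    params.validate()
    if experiment not in EXPERIMENTS:
        raise SchemeError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")

    def reductive_parts():
        if explicit_binding:
            species = ["E_ox", "E_oxS", "E_redP", "E_red", "S", "P"]
            states = ["E_ox", "E_oxS", "E_redP", "E_red"]
            rxns = [
                Reaction(("E_ox", "S"), ("E_oxS",), k_on, label="bind"),
                Reaction(("E_oxS",), ("E_ox", "S"), k_on * params.Kd_pon,
                         label="unbind"),
                Reaction(("E_oxS",), ("E_redP",), params.k_red, label="hydride"),
                Reaction(("E_redP",), ("E_red", "P"), params.k_rel,
                         label="release"),
            ]
        else:
            species = ["E_ox", "E_redP", "E_red", "S", "P"]
            states = ["E_ox", "E_redP", "E_red"]
            rxns = [
                Reaction(("E_ox",), ("E_redP",), params.k_red,
                         saturating=("S", params.Kd_pon), label="hydride"),
                Reaction(("E_redP",), ("E_red", "P"), params.k_rel,
                         label="release"),
            ]
        return species, states, rxns

    def cycn_parts():
        species = ["E_red", "E_sq", "E_ox", "CycN_ox", "CycN_red"]
        states = ["E_red", "E_sq", "E_ox"]
        rxns = [
            Reaction(("E_red", "CycN_ox"), ("E_sq", "CycN_red"),
                     params.k_cyc1, label="et1"),
            Reaction(("E_sq", "CycN_ox"), ("E_ox", "CycN_red"),
                     params.k_cyc2, label="et2"),
        ]
        return species, states, rxns

    if experiment == "reductive":
        species, states, rxns = reductive_parts()
        return KineticScheme(tuple(species), tuple(rxns), tuple(states),
                             frozenset({"S"}))
    if experiment == "oxidation_o2":
        rxns = (Reaction(("E_red", "O2"), ("E_ox",), params.k_ox_o2,
                         label="reox_o2"),)
        return KineticScheme(("E_red", "E_ox", "O2"), rxns,
                             ("E_red", "E_ox"), frozenset({"O2"}))
    if experiment == "oxidation_cycn":
        species, states, rxns = cycn_parts()
        return KineticScheme(tuple(species), tuple(rxns), tuple(states),
                             frozenset({"CycN_ox"}))
    # full cycle
    rspecies, rstates, rrxns = reductive_parts()
    cspecies, cstates, crxns = cycn_parts()
    species = list(dict.fromkeys(rspecies + cspecies))
    states = list(dict.fromkeys(rstates + cstates))
    return KineticScheme(tuple(species), tuple(rrxns + crxns), tuple(states),
                         frozenset({"S"}))


def _effective_rate(rxn: Reaction, scheme: KineticScheme,
                    excess: Mapping[str, float]) -> float:
    """Pseudo-first-order effective rate of a reaction, s^-1."""
    if rxn.saturating is not None:
        name, khalf = rxn.saturating
        s = float(excess.get(name, 0.0))
        return rxn.k * s / (khalf + s)
    if rxn.order == 2:
        estates = set(scheme.enzyme_states)
        partner = [r for r in rxn.reactants if r not in estates]
        if not partner:
            raise SchemeError("bimolecular step between two enzyme states")
        name = partner[0]
        if name not in scheme.excess_species:
            raise SchemeError(
                f"scheme is nonlinear: {name} is not an excess species")
        if name not in excess:
            raise SchemeError(f"missing excess concentration for {name}")
        return rxn.k * float(excess[name])
    return rxn.k


def rate_matrix(scheme: KineticScheme,
                excess_concentrations: Mapping[str, float]) -> np.ndarray:
    """First-order rate matrix over enzyme states under the pseudo-first-order
    approximation; d(c_states)/dt = M @ c_states."""
    states = scheme.enzyme_states
    idx = {s: i for i, s in enumerate(states)}
    m = np.zeros((len(states), len(states)))
    estates = set(states)
    for rxn in scheme.reactions:
        keff = _effective_rate(rxn, scheme, excess_concentrations)
        src = next(r for r in rxn.reactants if r in estates)
        dst = next(p for p in rxn.products if p in estates)
        m[idx[src], idx[src]] -= keff
        m[idx[dst], idx[src]] += keff
    return m


def eigenrates(scheme: KineticScheme,
               excess_concentrations: Mapping[str, float]) -> np.ndarray:
    """Magnitudes of the nonzero eigenvalues of the rate matrix, descending.

    These are the exact observed exponential rates (k_obs) of any noiseless
    absorbance trace projected from this scheme.
    """
    m = rate_matrix(scheme, excess_concentrations)
    mags = np.abs(np.linalg.eigvals(m))
    tol = 1e-10 * max(1.0, mags.max(initial=0.0))
    rates = np.sort(mags[mags > tol])[::-1]
    return rates


def linear_solution(scheme: KineticScheme, initial: Mapping[str, float],
                    excess_concentrations: Mapping[str, float],
                    time_grid: Sequence[float]) -> ConcentrationSeries:
    """Matrix-exponential solution for the enzyme states of a linear scheme.

    Serves as the analytic oracle against which the general ODE integrator is
    checked.  Only enzyme-state trajectories are returned.
    """
    t = np.asarray(time_grid, dtype=float)
    m = rate_matrix(scheme, excess_concentrations)
    c0 = np.array([float(initial.get(s, 0.0)) for s in scheme.enzyme_states])
    out = np.empty((t.size, c0.size))
    for i, ti in enumerate(t):
        out[i] = expm(m * ti) @ c0
    return ConcentrationSeries(t, scheme.enzyme_states, out)


def integrate(scheme: KineticScheme, initial: Mapping[str, float],
              time_grid: Sequence[float], rtol: float = 1e-8,
              atol: float = 1e-12, method: str = "LSODA") -> ConcentrationSeries:
    """Integrate the mass-action ODEs of ``scheme`` on ``time_grid``.

    Species in ``scheme.excess_species`` are clamped at their initial value.
    Raises :class:`IntegrationError` on solver failure (never returns NaN).
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    if grid[0] < 0:
        raise ValueError("time grid must start at t >= 0")
    unknown = set(initial) - set(scheme.species)
    if unknown:
        raise ValueError(f"initial concentrations for unknown species {unknown}")
    for name, c in initial.items():
        if c < 0:
            raise ValueError(f"negative initial concentration for {name}")

    idx = {s: i for i, s in enumerate(scheme.species)}
    y0 = np.array([float(initial.get(s, 0.0)) for s in scheme.species])
    clamped = np.array([s in scheme.excess_species for s in scheme.species])

    # precompute index arrays per reaction
    compiled = []
    for rxn in scheme.reactions:
        i0 = idx[rxn.reactants[0]]
        i1 = idx[rxn.reactants[1]] if rxn.order == 2 else -1
        mod = (idx[rxn.saturating[0]], rxn.saturating[1]) \
            if rxn.saturating is not None else None
        sinks = [idx[r] for r in rxn.reactants if not clamped[idx[r]]]
        sources = [idx[p] for p in rxn.products if not clamped[idx[p]]]
        compiled.append((rxn.k, i0, i1, mod, sinks, sources))

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for k, i0, i1, mod, sinks, sources in compiled:
            if mod is not None:
                jmod, khalf = mod
                rate = k * y[jmod] / (khalf + y[jmod]) * y[i0]
            elif i1 >= 0:
                rate = k * y[i0] * y[i1]
            else:
                rate = k * y[i0]
            for j in sinks:
                dy[j] -= rate
            for j in sources:
                dy[j] += rate
        return dy

    t0, t1 = 0.0, float(grid[-1])
    sol = solve_ivp(rhs, (t0, t1), y0, method=method, t_eval=grid,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise IntegrationError("ODE integration produced non-finite values")
    return ConcentrationSeries(grid, scheme.species, y)
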