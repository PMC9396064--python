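"""Kinetic and thermodynamic constants of the Pnao catalytic cycle.

Pnao (pseudooxynicotine amine oxidase, in fact a dehydrogenase) oxidizes
pseudooxynicotine (Pon) by hydride transfer to its FAD cofactor and hands
the two electrons, one at a time, to the cytochrome *c* protein CycN.
:class:`RateParameterSet` collects every microscopic and empirical constant
of that cycle; the shipped defaults are the fitted values obtained from
stopped-flow, steady-state and potentiometric experiments:

========== ============================ =====================
field      meaning                      default
========== ============================ =====================
k_red      hydride transfer (sat.)      74 s^-1
Kd_pon     apparent K_d for Pon         64 uM
k_rel      imine product release        6.3 s^-1
k_ox_o2    Fl_red + O2                  600 M^-1 s^-1
k_cyc1     Fl_red + CycN_ox (1st e-)    1.4e5 M^-1 s^-1
k_cyc2     Fl_sq + CycN_ox (2nd e-)     3.2e4 M^-1 s^-1
k_art      minor 550 nm phase           0.5 s^-1
kcat_emp   empirical turnover number    4.4 s^-1
Km_cyc_emp empirical K_M for CycN       34 uM
Em_enz     Fl_ox/Fl_sq midpoint         -111 mV
Em_dye     indigo disulfonate midpoint  -139 mV (pH 7.5)
========== ============================ =====================

Internal units are SI (mol/L, s, K, and mV for potentials).  Stopped-flow
work was done at 4 C (277.15 K), potentiometry at 25 C (298.15 K).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

FARADAY = 96485.0  # C mol^-1
GAS_CONSTANT = 8.314  # J mol^-1 K^-1
T_STOPPED_FLOW = 277.15  # K (4 C)
T_POTENTIOMETRY = 298.15  # K (25 C)


def thermal_voltage_mv(temperature: float = T_POTENTIOMETRY) -> float:
    """RT/F in millivolts (25.69 mV at 25 C)."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY


@dataclass
class RateParameterSet:
    """All rate/thermodynamic constants of the cycle (defaults: fitted values)."""

    k_red: float = 74.0          # s^-1, hydride transfer at saturating Pon
    Kd_pon: float = 64e-6        # mol/L, apparent dissociation constant for Pon
    k_rel: float = 6.3           # s^-1, imine product release
    k_ox_o2: float = 600.0       # M^-1 s^-1, reduced flavin + O2
    k_cyc1: float = 1.4e5        # M^-1 s^-1, hydroquinone + CycN_ox
    k_cyc2: float = 3.2e4        # M^-1 s^-1, semiquinone + CycN_ox
    k_art: float = 0.5           # s^-1, minor third 550 nm phase
    frac_art: float = 0.05       # amplitude fraction of the minor phase
    kcat_emp: float = 4.4        # s^-1, empirical turnover number
    Km_cyc_emp: float = 34e-6    # mol/L, empirical Michaelis constant for CycN
    Em_enz: float = -111.0       # mV, oxidized/semiquinone midpoint
    n_enz: int = 1               # electrons in the enzyme couple
    Em_dye: float = -139.0       # mV, indigo disulfonate at pH 7.5
    n_dye: int = 2               # electrons in the dye couple
    temperature: float = T_STOPPED_FLOW  # K

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("k_red", "k_rel", "k_ox_o2", "k_cyc1", "k_cyc2",
                     "k_art", "kcat_emp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Kd_pon <= 0:
            raise ValueError("Kd_pon must be > 0")
        if self.Km_cyc_emp <= 0:
            raise ValueError("Km_cyc_emp must be > 0")
        if self.n_enz not in (1, 2) or self.n_dye not in (1, 2):
            raise ValueError("n_enz and n_dye must be 1 or 2")
        if not 0.0 <= self.frac_art <= 0.1:
            raise ValueError("frac_art must lie in [0, 0.1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def replace(self, **changes) -> "RateParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameterSet":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"rate_parameters": self.to_dict()},
                                         indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RateParameterSet":
        data = json.loads(Path(path).read_text())
        if "rate_parameters" in data:
            data = data["rate_parameters"]
        return cls.from_dict(data)
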