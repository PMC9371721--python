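"""Electrochemical rate laws for the oxygen reduction reaction (ORR).

The microwire-array electrode consumes dissolved O2 at its surface and, on
H2O2-selective catalysts, releases H2O2.  Surface kinetics follow
concentration-dependent Tafel laws: each reaction channel carries a current
density

    i = -i0 * ([O2]/C_bulk) * exp(-alpha_c * F * eta * n_rds / (R*T))

with eta = E_appl - E0(O2/H2O) the overpotential, i0 the exchange current
density and n_rds the electron-transfer number before the rate-determining
step.  Currents are converted to species fluxes by Faradaic stoichiometry:
4e- channels consume O2 only, 2e- channels consume O2 and release H2O2.

Because every channel is linear in the local O2 concentration, the whole
surface boundary condition collapses to a pair of effective rate constants
(m/s), which is what the steady-state diffusion solver consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from scipy import constants as _const

__all__ = [
    "PhysicalConstants",
    "ORRChannel",
    "CatalystKinetics",
    "overpotential",
    "channel_current_density",
    "surface_fluxes",
    "effective_rate_constants",
    "load_catalyst",
    "DEFAULT_POTENTIAL_WINDOW",
]

#: ORR operating window for the applied potential, V vs RHE.
DEFAULT_POTENTIAL_WINDOW = (0.2, 0.6)


@dataclass(frozen=True)
class PhysicalConstants:
    """Transport and thermodynamic constants of the aerated aqueous medium.

    Concentrations are kept in mol/m^3, which is numerically identical to mM.
    """

    F: float = _const.physical_constants["Faraday constant"][0]  # C/mol
    R: float = _const.R  # J/(mol K)
    T: float = 298.15  # K (room-temperature PBS)
    D_O2: float = 2.2e-9  # m^2/s
    D_H2O2: float = 1.5e-9  # m^2/s
    C_O2_bulk: float = 0.246  # mol/m^3 = mM, air-saturated water
    E0_O2_H2O: float = 1.23  # V vs RHE

    def __post_init__(self) -> None:
        for name in ("F", "R", "T", "D_O2", "D_H2O2", "C_O2_bulk", "E0_O2_H2O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhysicalConstants.{name} must be strictly positive")


@dataclass(frozen=True)
class ORRChannel:
    """One Tafel reaction channel at the electrode surface.

    Parameters
    ----------
    i0 : exchange current density, A/m^2.
    n_rds : electron-transfer number before the rate-determining step.
    n_stoich : total electrons transferred per O2 (4 for O2->H2O, 2 for O2->H2O2).
    alpha_c : cathodic transfer coefficient.
    """

    i0: float
    n_rds: float
    n_stoich: int
    alpha_c: float = 0.5

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise ValueError("exchange current density i0 must be >= 0")
        if self.n_stoich not in (2, 4):
            raise ValueError("n_stoich must be 2 or 4")
        if self.n_rds <= 0:
            raise ValueError("n_rds must be > 0")
        if not 0 < self.alpha_c <= 1:
            raise ValueError("alpha_c must lie in (0, 1]")


@dataclass(frozen=True)
class CatalystKinetics:
    """Per-catalyst ORR channel set plus its diffusion-boundary-layer distance.

    ``dD`` (um) is the distance above the wire tops at which the flowing medium
    pins concentrations to their bulk values.
    """

    name: str
    channels: tuple[ORRChannel, ...]
    dD: float  # um

    def __post_init__(self) -> None:
        if self.dD <= 0:
            raise ValueError("boundary-layer distance dD must be > 0")
        if not self.channels:
            raise ValueError("at least one ORR channel is required")

    @property
    def has_peroxide_channel(self) -> bool:
        return any(ch.n_stoich == 2 for ch in self.channels)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "dD_um": self.dD,
            "channels": [
                {
                    "i0_A_per_m2": ch.i0,
                    "n_rds": ch.n_rds,
                    "n_stoich": ch.n_stoich,
                    "alpha_c": ch.alpha_c,
                }
                for ch in self.channels
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CatalystKinetics":
        channels = tuple(
            ORRChannel(
                i0=ch["i0_A_per_m2"],
                n_rds=ch["n_rds"],
                n_stoich=ch["n_stoich"],
                alpha_c=ch.get("alpha_c", 0.5),
            )
            for ch in obj["channels"]
        )
        return cls(name=obj["name"], channels=channels, dD=obj["dD_um"])


def load_catalyst(name_or_path: str) -> CatalystKinetics:
    """Load catalyst kinetics from a shipped preset (``"pt"``, ``"au"``) or a JSON file."""
    key = name_or_path.lower()
    if key in ("pt", "au"):
        text = resources.files("gradientforge.data").joinpath(f"{key}.json").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return CatalystKinetics.from_json(json.loads(text))


def overpotential(
    E_appl: float,
    constants: PhysicalConstants | None = None,
    window: tuple[float, float] | None = DEFAULT_POTENTIAL_WINDOW,
) -> float:
    """Cathodic overpotential eta = E_appl - E0(O2/H2O), in V.

    ``window`` bounds the applied potential (V vs RHE); pass ``None`` to skip
    the check (e.g. when evaluating the zero-overpotential reference point).
    """
    constants = constants or PhysicalConstants()
    if window is not None and not (window[0] <= E_appl <= window[1]):
        raise ValueError(
            f"E_appl = {E_appl} V vs RHE outside the operating window "
            f"[{window[0]}, {window[1]}] V"
        )
    return E_appl - constants.E0_O2_H2O


def channel_current_density(
    ch: ORRChannel,
    eta: float,
    c_O2: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """Signed Tafel current density of one channel, A/m^2 (cathodic negative).

    Linear in the local O2 concentration; zero current at zero reactant.
    """
    constants = constants or PhysicalConstants()
    if c_O2 < 0:
        raise ValueError("negative O2 concentration is non-physical")
    if not math.isfinite(eta):
        raise ValueError("overpotential must be finite")
    exponent = -ch.alpha_c * constants.F * eta * ch.n_rds / (constants.R * constants.T)
    return -ch.i0 * (c_O2 / constants.C_O2_bulk) * math.exp(exponent)


def surface_fluxes(
    kin: CatalystKinetics,
    eta: float,
    c_O2: float,
    constants: PhysicalConstants | None = None,
) -> tuple[float, float]:
    """Species fluxes (J_O2, J_H2O2) in mol/(m^2 s); positive = into the electrolyte.

    Each 4e- channel consumes O2 at i/(4F); each 2e- channel consumes O2 at
    i/(2F) and releases H2O2 at -i/(2F).  O2 is always consumed (J_O2 <= 0)
    and H2O2 only produced (J_H2O2 >= 0).
    """
    constants = constants or PhysicalConstants()
    F = constants.F
    j_o2 = 0.0
    j_h2o2 = 0.0
    for ch in kin.channels:
        i = channel_current_density(ch, eta, c_O2, constants)
        j_o2 += i / (ch.n_stoich * F)
        if ch.n_stoich == 2:
            j_h2o2 += -i / (2.0 * F)
    return j_o2, j_h2o2


def effective_rate_constants(
    kin: CatalystKinetics,
    eta: float,
    constants: PhysicalConstants | None = None,
) -> tuple[float, float]:
    """Linearized surface rate constants (k_O2, k_gen), both in m/s and >= 0.

    The Tafel fluxes are exactly linear in the local O2 concentration, so
    J_O2 = -k_O2 * c_O2 and J_H2O2 = +k_gen * c_O2.  These constants fold the
    whole surface chemistry into Robin boundary terms of the linear solver.
    """
    constants = constants or PhysicalConstants()
    k_o2 = 0.0
    k_gen = 0.0
    for ch in kin.channels:
        rate = (
            ch.i0
            * math.exp(-ch.alpha_c * constants.F * eta * ch.n_rds / (constants.R * constants.T))
            / (ch.n_stoich * constants.F * constants.C_O2_bulk)
        )
        k_o2 += rate
        if ch.n_stoich == 2:
            k_gen += rate
    return k_o2, k_gen
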