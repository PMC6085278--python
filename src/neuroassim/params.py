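"""Parameter containers and regime presets for the Morris–Lecar models.

The spiking model has two states (membrane voltage ``V`` and the potassium
activation gate ``n``); the bursting variant adds a slow intracellular
calcium concentration ``Ca`` that gates an extra K(Ca) current.  The eight
parameters routinely estimated from voltage data are the rate scale ``phi``,
the maximal conductances ``gCa``/``gK``/``gL``, and the gating-curve shape
parameters ``V1``–``V4``; the bursting model adds the K(Ca) conductance
``gKCa``.  Capacitance, reversal potentials, the applied current, and the
slow-timescale constants ``ca_eps``/``mu`` are treated as known.

Units: time in ms, voltage in mV, capacitance in nF-scale units consistent
with nA currents, conductances in mS/cm^2-scale units consistent with the
voltage equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

# Estimated-parameter ordering, shared by every estimator in the package.
SPIKING_THETA_NAMES = ("phi", "gCa", "V3", "V4", "gK", "gL", "V1", "V2")
BURSTING_THETA_NAMES = SPIKING_THETA_NAMES + ("gKCa",)


@dataclass(frozen=True)
class SpikingParams:
    """Parameters of the two-dimensional Morris–Lecar spiking model."""

    phi: float
    gCa: float
    V3: float
    V4: float
    gK: float = 8.0
    gL: float = 2.0
    V1: float = -1.2
    V2: float = 18.0
    Cm: float = 20.0
    ECa: float = 120.0
    EK: float = -84.0
    EL: float = -60.0
    Iapp: float = 100.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.as_array())):
            raise ValueError("non-finite parameter value")
        if min(self.gCa, self.gK, self.gL) < 0:
            raise ValueError("maximal conductances must be non-negative")
        if self.V2 <= 0 or self.V4 <= 0:
            raise ValueError("activation slopes V2, V4 must be positive")
        if self.Cm <= 0 or self.phi <= 0:
            raise ValueError("Cm and phi must be positive")

    @property
    def n_states(self) -> int:
        return 2

    def theta(self) -> np.ndarray:
        """Estimated-parameter vector in the canonical ordering."""
        return np.array([getattr(self, k) for k in self.theta_names()])

    def theta_names(self) -> tuple[str, ...]:
        return SPIKING_THETA_NAMES

    def with_theta(self, theta: np.ndarray) -> "SpikingParams":
        """Copy with the estimated parameters replaced by ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.theta_names()),):
            raise ValueError("theta has wrong length")
        return replace(self, **dict(zip(self.theta_names(), theta)))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    def consts(self) -> np.ndarray:
        """Fixed (non-estimated) constants: Cm, ECa, EK, EL, Iapp."""
        return np.array([self.Cm, self.ECa, self.EK, self.EL, self.Iapp])

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


@dataclass(frozen=True)
class BurstingParams(SpikingParams):
    """Morris–Lecar bursting model: spiking model plus a slow Ca variable.

    ``gKCa`` scales the calcium-gated potassium current
    ``gKCa * z * (V - EK)`` with ``z = Ca / (Ca + 1)``; ``ca_eps`` is the
    slow rate of the Ca dynamics and ``mu`` converts calcium current into
    concentration change.
    """

    gKCa: float = 0.25
    ca_eps: float = 0.005
    mu: float = 0.02

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.gKCa < 0:
            raise ValueError("gKCa must be non-negative")
        if self.ca_eps <= 0 or self.mu <= 0:
            raise ValueError("ca_eps and mu must be positive")

    @property
    def n_states(self) -> int:
        return 3

    def theta_names(self) -> tuple[str, ...]:
        return BURSTING_THETA_NAMES

    def consts(self) -> np.ndarray:
        """Fixed constants: Cm, ECa, EK, EL, Iapp, ca_eps, mu."""
        return np.array(
            [self.Cm, self.ECa, self.EK, self.EL, self.Iapp, self.ca_eps, self.mu]
        )


# --- Regime presets -------------------------------------------------------
#
# Three spiking excitability regimes (named for the bifurcation through which
# repetitive firing arises as the applied current is increased) and two
# bursting regimes (named for the fast-subsystem bifurcations that start and
# end the active phase).

HOPF = SpikingParams(phi=0.04, gCa=4.0, V3=2.0, V4=30.0, Iapp=100.0)
SNIC = SpikingParams(phi=0.067, gCa=4.0, V3=12.0, V4=17.4, Iapp=100.0)
HOMOCLINIC = SpikingParams(phi=0.23, gCa=4.0, V3=12.0, V4=17.4, Iapp=36.0)

SQUARE_WAVE = BurstingParams(
    phi=0.23, gCa=4.0, V3=12.0, V4=17.4, gKCa=0.25, Iapp=45.0
)
ELLIPTIC = BurstingParams(
    phi=0.04, gCa=4.4, V3=2.0, V4=30.0, gKCa=0.75, Iapp=120.0
)

SPIKING_REGIMES: dict[str, SpikingParams] = {
    "hopf": HOPF,
    "snic": SNIC,
    "homoclinic": HOMOCLINIC,
}
BURSTING_REGIMES: dict[str, BurstingParams] = {
    "square-wave": SQUARE_WAVE,
    "elliptic": ELLIPTIC,
}

_ALIASES = {
    "homo": "homoclinic",
    "square": "square-wave",
    "square_wave": "square-wave",
    "squarewave": "square-wave",
}


def get_regime(name: str) -> SpikingParams:
    """Look up a preset parameter regime by (case-insensitive) name."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key in SPIKING_REGIMES:
        return SPIKING_REGIMES[key]
    if key in BURSTING_REGIMES:
        return BURSTING_REGIMES[key]
    raise KeyError(
        f"unknown regime {name!r}; expected one of "
        f"{sorted(SPIKING_REGIMES) + sorted(BURSTING_REGIMES)}"
    )
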