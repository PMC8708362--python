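"""Physical constants and the thermal environment of the nanoparticle ensemble."""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Vacuum magnetic permeability, T·m/A (exact in the pre-2019 SI convention used here).
MU0 = 4e-7 * math.pi

#: Boltzmann constant, J/K (exact, 2019 SI).
KB = 1.380649e-23

#: Default absolute temperature, K — room temperature, at which the
#: material anchor values were measured.
T_ROOM = 300.0


@dataclass(frozen=True)
class Environment:
    """Thermal environment shared by all statistical-mechanics expressions.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin. Default 300 K (room temperature;
        the material property anchors are room-temperature values).
    mu0 : float
        Vacuum permeability, T·m/A.
    kB : float
        Boltzmann constant, J/K.
    """

    T: float = T_ROOM
    mu0: float = MU0
    kB: float = KB

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"temperature must be positive, got T={self.T} K")
        if self.mu0 <= 0 or self.kB <= 0:
            raise ValueError("physical constants mu0 and kB must be positive")


DEFAULT_ENV = Environment()
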