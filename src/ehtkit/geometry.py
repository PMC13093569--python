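"""Cantilever-beam model of the EHT pillar.

An engineered heart tissue (EHT) is suspended between two elastic PDMS
pillars.  Tissue contraction pulls the pillar head sideways; for small
deflections the pillar behaves as a cantilever beam with a concentrated
load ``P`` at its free end, so the tip deflection is

    delta = P * L**3 / (3 * E * I),        I = pi/64 * d**4

for a circular cross-section of diameter ``d``, beam length ``L`` and
Young's modulus ``E``.  Inverting the relation gives the force per unit
deflection, the bending stiffness ``k = 3*E*I / L**3`` (N/m), which is
all the force reconstruction needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PillarGeometry", "bending_stiffness"]


@dataclass(frozen=True)
class PillarGeometry:
    """Geometric and material constants of one PDMS pillar.

    Defaults are the fabricated pillar: length 12 mm, PDMS Young's
    modulus 1.7 MPa, diameter 1.2 mm.

    Attributes
    ----------
    length_m : float
        Pillar length ``L`` in metres.
    youngs_modulus_pa : float
        Young's modulus ``E`` of the pillar material in pascals.
    diameter_m : float
        Pillar diameter ``d`` in metres (circular cross-section).
    """

    length_m: float = 12e-3
    youngs_modulus_pa: float = 1.7e6
    diameter_m: float = 1.2e-3

    def __post_init__(self) -> None:
        for name in ("length_m", "youngs_modulus_pa", "diameter_m"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    @property
    def area_moment_m4(self) -> float:
        """Second moment of area ``I = pi/64 * d**4`` (m^4)."""
        return math.pi / 64.0 * self.diameter_m**4

    @property
    def stiffness_n_per_m(self) -> float:
        """Bending stiffness ``k = 3*E*I / L**3`` (N/m)."""
        return 3.0 * self.youngs_modulus_pa * self.area_moment_m4 / self.length_m**3

    def deflection_for_force(self, force_n):
        """Tip deflection (m) under end load ``force_n`` (N); elementwise."""
        return force_n / self.stiffness_n_per_m

    def force_for_deflection(self, deflection_m):
        """End load (N) producing tip deflection ``deflection_m`` (m)."""
        return deflection_m * self.stiffness_n_per_m


def bending_stiffness(geometry: PillarGeometry) -> float:
    """Force per unit tip deflection, ``3*E*I/L**3`` in N/m."""
    return geometry.stiffness_n_per_m
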