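"""Closed-form electromechanical quantities for stretchable thin-film electrode arrays.

These are the routine engineering formulas used when sizing an elastomer
(PDMS) multi-layer electrode for implantation on a small nerve:

* **bending strain** in a thin metal film, ε = d_N / BR, where d_N is the
  film's distance from the neutral plane of the bent sheet and BR the
  bending radius;
* the **neutral-plane position** of a uniform-modulus layer stack (the
  microcracked-gold films are treated as zero-thickness markers, so the
  neutral plane sits at half the total polymer thickness);
* **Poisson compression**: first-order thickness reduction of a stretched
  elastomer, t = t0 (1 − ν ε_axial), exploited to clamp the electrode in a
  3D-printed clamp;
* **electrode disc area**, **current/charge density** (bounding
  electrochemically safe stimulation), impedance **fold change** from
  electroplating, and the **Ohmic compliance voltage** V = I·Z a stimulator
  must deliver.

All functions are pure; units are stated per argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class LayerStack:
    """Ordered polymer layers (name, thickness in µm) with embedded metal films.

    The default stack is a bi-layer array: 45 µm substrate, metal layer L1,
    30 µm encapsulation, metal layer L2, 30 µm encapsulation. Metal film
    positions are measured from the stack bottom.
    """

    layers: list[tuple[str, float]] = field(
        default_factory=lambda: [("substrate", 45.0), ("encap1", 30.0), ("encap2", 30.0)]
    )
    metal_positions: dict[str, float] = field(
        default_factory=lambda: {"L1": 45.0, "L2": 75.0}
    )

    def __post_init__(self) -> None:
        for name, t in self.layers:
            if t <= 0:
                raise ValueError(f"layer {name!r} must have positive thickness")

    @property
    def total_thickness(self) -> float:
        return sum(t for _, t in self.layers)


@dataclass
class ElectrodeGeom:
    """Circular recording/stimulation site."""

    diameter: float = 80.0  # µm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("electrode diameter must be positive")


def bending_strain(d_n: float, br: float) -> float:
    """Strain ε = d_N / BR in a film at distance ``d_n`` (µm) from the
    neutral plane of a sheet bent to radius ``br`` (µm).

    Signed: a negative ``d_n`` (film inside the bend) gives compressive
    (negative) strain.
    """
    if br <= 0:
        raise ValueError("bending radius must be positive")
    return d_n / br


def neutral_plane_offsets(stack: LayerStack) -> dict[str, float]:
    """Distance |d_N| of each metal film from the stack's neutral plane (µm).

    Uniform-modulus assumption: with the metal films treated as
    zero-thickness markers in a homogeneous elastomer, the neutral plane is
    at half the total thickness.
    """
    neutral = stack.total_thickness / 2.0
    return {name: abs(pos - neutral) for name, pos in stack.metal_positions.items()}


def poisson_thickness(t0: float, axial_strain: float, nu: float = 0.5) -> float:
    """Thickness (µm) of an elastomer of rest thickness ``t0`` under uniaxial
    axial strain, t = t0 (1 − ν ε); ν defaults to 0.5 (incompressible)."""
    if not 0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5]")
    if axial_strain < 0:
        raise ValueError("axial strain must be non-negative")
    t = t0 * (1.0 - nu * axial_strain)
    if t <= 0:
        raise ValueError("strain would produce non-positive thickness")
    return t


def disc_area(geom: ElectrodeGeom) -> float:
    """Area of the circular site in µm²; an 80 µm disc is ≈5000 µm²."""
    return math.pi * (geom.diameter / 2.0) ** 2


def current_density(current_ua: float, geom: ElectrodeGeom) -> float:
    """Current density in mA mm⁻² for ``current_ua`` µA through the site.

    1 µA µm⁻² = 1000 mA mm⁻², so 110 µA on an 80 µm disc is ≈22 mA mm⁻².
    """
    return current_ua / disc_area(geom) * 1000.0


def charge_per_phase(current_ua: float, phase_us: float) -> float:
    """Charge delivered in one stimulation phase, in nC (µA × µs / 1000)."""
    return current_ua * phase_us / 1000.0


def fold_change(pre_mean: float, post_mean: float) -> float:
    """Impedance reduction factor pre/post (e.g., electroplating 465 → 20 kΩ
    is a 23× reduction, 'larger than tenfold')."""
    if post_mean <= 0:
        raise ValueError("post-treatment impedance must be positive")
    return pre_mean / post_mean


def ohmic_voltage(current_ua: float, impedance_kohm: float) -> float:
    """Ohmic voltage V = I·Z in volts (µA × kΩ / 1000); compare against the
    stimulator compliance limit (typically 10 V)."""
    if impedance_kohm < 0:
        raise ValueError("impedance must be non-negative")
    return current_ua * impedance_kohm / 1000.0
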