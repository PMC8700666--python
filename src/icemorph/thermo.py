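"""Closed-form thermophysical characterization of the porous product.

Four desk calculations accompany the image analysis:

* water content from wet/dry masses, ``Xw = (m0 - mf)/m0 * 100``;
* freezable water from the DSC ice-melting enthalpy,
  ``Fw = dHw / (dHi * Tw) * 100`` with the latent heat of fusion of ice
  dHi = 334 J/g and Tw the total water content as a mass *fraction*
  (entering Tw as a percent would make the printed values dimensionally
  inconsistent, so a fraction is enforced);
* theoretical (air-free) mixture density from the formulation by harmonic
  mass-fraction mixing, ``rho = sum(w_i) / sum(w_i / rho_i)``, with
  components of unknown density (stabilizers) excluded from both sums;
* porosity from the apparent (with air) and theoretical (air-free)
  densities, ``phi = (1 - rho_apparent / rho_theoretical) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Component",
    "Formulation",
    "DSCMeasurement",
    "MoistureWeights",
    "LATENT_HEAT_ICE",
    "water_content",
    "freezable_water",
    "mixture_density",
    "porosity_from_densities",
]

#: Specific latent heat of fusion of ice, J/g.
LATENT_HEAT_ICE = 334.0


@dataclass(frozen=True)
class Component:
    """One formulation ingredient: mass fraction in % w/w, density in kg/m³.

    ``density=None`` marks an ingredient of unknown density (it can only be
    excluded from the density calculation).
    """

    name: str
    mass_fraction: float
    density: float | None = None
    exclude_from_density: bool = False

    def __post_init__(self) -> None:
        if self.mass_fraction <= 0:
            raise ValueError(f"{self.name}: mass fraction must be > 0")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")


@dataclass(frozen=True)
class Formulation:
    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("formulation needs at least one component")


def model_sponge_cake_formulation() -> Formulation:
    """The model sponge-cake batter: water and starch with known densities,
    two cellulose-ether stabilizers of unknown density (neglected)."""
    return Formulation((
        Component("HPMC", 0.35, None, exclude_from_density=True),
        Component("MC", 0.46, None, exclude_from_density=True),
        Component("water", 62.64, 1000.0),
        Component("starch", 36.55, 766.0),
    ))


@dataclass(frozen=True)
class MoistureWeights:
    """Wet and oven-dried sample masses, kg."""

    m0: float
    mf: float

    def __post_init__(self) -> None:
        if not self.mf > 0:
            raise ValueError("dried mass must be > 0")
        if self.mf > self.m0:
            raise ValueError("dried mass cannot exceed wet mass")


@dataclass(frozen=True)
class DSCMeasurement:
    """Ice-melting enthalpy (J/g), latent heat of ice (J/g), water content (fraction)."""

    dHw: float
    Tw: float
    dHi: float = LATENT_HEAT_ICE

    def __post_init__(self) -> None:
        if self.dHw <= 0 or self.dHi <= 0:
            raise ValueError("enthalpies must be > 0")
        if not 0 < self.Tw <= 1:
            raise ValueError(
                "Tw is the total water content as a mass FRACTION in (0, 1]; "
                f"got {self.Tw}"
            )


def water_content(w: MoistureWeights) -> float:
    """Water content Xw = (m0 - mf)/m0 * 100, in % w/w."""
    return (w.m0 - w.mf) / w.m0 * 100.0


def freezable_water(d: DSCMeasurement) -> float:
    """Freezable water Fw = dHw / (dHi * Tw) * 100, in % of total water.

    Values above 100% would mean more ice melted than water present and are
    rejected as physically impossible.
    """
    fw = d.dHw / (d.dHi * d.Tw) * 100.0
    if fw > 100.0:
        raise ValueError(
            f"freezable water {fw:.1f}% exceeds 100%: enthalpy, latent heat and "
            "water content are inconsistent"
        )
    return fw


def mixture_density(f: Formulation) -> float:
    """Air-free mixture density by harmonic mass-fraction mixing, kg/m³.

    ``rho = sum(w_i) / sum(w_i / rho_i)`` over the included components;
    excluded or density-less components are dropped from both sums.
    """
    included = [
        c for c in f.components if c.density is not None and not c.exclude_from_density
    ]
    if not included:
        raise ValueError("no component with a density is included")
    w_sum = sum(c.mass_fraction for c in included)
    v_sum = sum(c.mass_fraction / c.density for c in included)
    return w_sum / v_sum


def porosity_from_densities(rho_apparent: float, rho_theoretical: float) -> float:
    """Porosity (% v/v) from apparent (with air) vs theoretical (air-free) density."""
    if not 0 < rho_apparent <= rho_theoretical:
        raise ValueError(
            f"need 0 < rho_apparent <= rho_theoretical, got {rho_apparent} vs {rho_theoretical}"
        )
    return (1.0 - rho_apparent / rho_theoretical) * 100.0
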