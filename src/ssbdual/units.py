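"""Unit system and calibration arithmetic for the anti-AFP reagent.

The reagent is characterised magnetically, by its AC-susceptibility response
under the reference excitation field, rather than chemically.  The working
quantities are therefore CGS-derived, as conventional for biosusceptometry:

* magnetic concentration ``c`` in emu/g — moment per gram of reagent under
  the reference excitation;
* reagent mass ``w`` in g;
* sample magnetism ``c * w`` in emu — the total moment a sample exhibits;
* Fe mass concentration in mg/g, related to magnetic concentration by a
  fixed factor (default 6.5 mg/g per emu/g, calibrated from the
  0.3 emu/g <-> 1.95 mg/g endpoint of the reagent batch).

No hidden SI conversion happens at this layer; the forward model converts
emu to A*m^2 where it needs to.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReagentSpec",
    "DoseSpec",
    "fe_concentration",
    "sample_magnetism",
    "dose_fraction",
    "fe_mass",
    "tube_to_reagent_distance",
    "DEFAULT_FE_FACTOR",
    "TUBE_HEADSPACE_MM",
]

#: Fe mass concentration per unit magnetic concentration, mg/g per emu/g.
#: Calibrated from the single endpoint 0.3 emu/g <-> 1.95 mg/g; the low end
#: (0.005 emu/g <-> 32.5 ug/g) is then an internal consistency check.
DEFAULT_FE_FACTOR = 1.95 / 0.3

#: Axial gap between the reagent surface and the top of the microtest tube, mm.
TUBE_HEADSPACE_MM = 29.0


@dataclass(frozen=True)
class ReagentSpec:
    """A batch of antibody-coated magnetic-nanoparticle reagent.

    The hydrodynamic-diameter fields are metadata carried for provenance;
    nothing downstream consumes them.
    """

    concentration: float  # emu/g
    weight: float  # g
    fe_factor: float = DEFAULT_FE_FACTOR  # mg/g per emu/g
    hydrodynamic_diameter_mean: float = 57.3  # nm, metadata
    hydrodynamic_diameter_sd: float = 15.2  # nm, metadata

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 emu/g")
        if self.weight < 0:
            raise ValueError("weight must be >= 0 g")
        if self.fe_factor <= 0:
            raise ValueError("fe_factor must be > 0")

    @property
    def magnetism(self) -> float:
        """Total sample magnetism in emu."""
        return sample_magnetism(self.concentration, self.weight)


@dataclass(frozen=True)
class DoseSpec:
    """The injected reagent dose (tail-vein bolus) an animal received."""

    dose_weight: float = 0.9  # g
    dose_concentration: float = 0.3  # emu/g

    def __post_init__(self) -> None:
        if self.dose_weight <= 0:
            raise ValueError("dose_weight must be > 0 g")
        if self.dose_concentration <= 0:
            raise ValueError("dose_concentration must be > 0 emu/g")

    @property
    def magnetism(self) -> float:
        return sample_magnetism(self.dose_concentration, self.dose_weight)


def fe_concentration(c: float, fe_factor: float = DEFAULT_FE_FACTOR) -> float:
    """Fe mass concentration (mg/g) for a magnetic concentration ``c`` (emu/g)."""
    if c < 0:
        raise ValueError("magnetic concentration must be >= 0")
    if fe_factor <= 0:
        raise ValueError("fe_factor must be > 0")
    return c * fe_factor


def sample_magnetism(c: float, w: float) -> float:
    """Sample magnetism (emu): product of concentration (emu/g) and weight (g)."""
    if c < 0 or w < 0:
        raise ValueError("concentration and weight must be >= 0")
    return c * w


def dose_fraction(sample_w: float, dose: DoseSpec | float = DoseSpec()) -> float:
    """Sample weight as a percentage of the injected dose weight.

    Returns the unrounded percentage; report layers round to whole percent.
    """
    dose_weight = dose.dose_weight if isinstance(dose, DoseSpec) else float(dose)
    if dose_weight <= 0:
        raise ValueError("dose weight must be > 0 g")
    if sample_w < 0:
        raise ValueError("sample weight must be >= 0 g")
    return 100.0 * sample_w / dose_weight


def fe_mass(c: float, w: float, fe_factor: float = DEFAULT_FE_FACTOR) -> float:
    """Fe mass (ug) in a sample of concentration ``c`` (emu/g) and weight ``w`` (g).

    ``c * w * fe_factor`` is mg of Fe; the factor 1000 converts to ug.
    """
    if c < 0 or w < 0:
        raise ValueError("concentration and weight must be >= 0")
    return fe_concentration(c, fe_factor) * w * 1000.0


def tube_to_reagent_distance(
    probe_to_tube_top: float, headspace: float = TUBE_HEADSPACE_MM
) -> float:
    """Probe-to-reagent-surface distance (mm) from the probe-to-tube-top distance.

    The reagent sits ``headspace`` mm below the tube's top rim, so a 2-36 mm
    mechanical standoff corresponds to 31-65 mm of source depth.
    """
    if probe_to_tube_top < 0:
        raise ValueError("probe_to_tube_top must be >= 0 mm")
    return probe_to_tube_top + headspace
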