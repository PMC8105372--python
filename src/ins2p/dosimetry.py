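"""Geometry and energetics of the infrared exposure.

This module computes everything about the light delivery that can be derived
from the fiber and the optical path: the elliptical footprint of the oblique,
divergent beam on the brain surface, the exposed area, the conversion between
radiant exposure (J cm^-2) and pulse energy (uJ), the water absorption
coefficient and the corresponding penetration depth, and a 3-D fluence model
(elliptical Gaussian at the surface, Beer-Lambert in depth) that the
synthetic generator uses to decide which cells are recruited.

Unit conventions: lengths in micrometres, areas in cm^2, radiant exposure in
J cm^-2, pulse energy in uJ, absorption coefficients in cm^-1, angles in
degrees at the API surface (radians internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "FiberSpec",
    "Medium",
    "OpticalPathSpec",
    "AbsorptionTable",
    "BeamFootprint",
    "StimulusProtocol",
    "FluenceField",
    "load_water_table",
    "interpolate_absorption",
    "penetration_depth",
    "project_footprint",
    "ellipse_area",
    "pulse_energy",
    "pulse_count",
    "build_fluence_field",
    "dosimetry_report",
]

#: uJ/um^2 -> J/cm^2  (1e-6 J over 1e-8 cm^2)
_UJ_PER_UM2_TO_J_PER_CM2 = 100.0
#: um^2 -> cm^2
_UM2_TO_CM2 = 1e-8


class GeometryError(ValueError):
    """Raised when the optical path cannot transmit the beam (total internal
    reflection) or produces a degenerate footprint."""


@dataclass(frozen=True)
class FiberSpec:
    """Multimode fiber output: core diameter (um), NA, wavelength (nm)."""

    core_diameter_um: float = 105.0
    numerical_aperture: float = 0.15
    wavelength_nm: float = 1470.0

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0:
            raise ValueError("core_diameter_um must be > 0")
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")


@dataclass(frozen=True)
class Medium:
    refractive_index: float
    thickness_um: float = 0.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.thickness_um < 0:
            raise ValueError("thickness must be >= 0")


def _default_media() -> tuple[Medium, ...]:
    # immersion gel, cranial window, brain tissue; indices/thicknesses are
    # package defaults, the publication-grade values are not fully known
    return (Medium(1.34, 0.0), Medium(1.51, 100.0), Medium(1.36, 0.0))


@dataclass(frozen=True)
class OpticalPathSpec:
    """Path from fiber tip to the brain surface.

    ``incidence_angle_deg`` is measured between the fiber axis and the
    brain-surface *plane* (90 deg = normal incidence).  ``media`` lists the
    traversed media in order; the beam propagates through all but the last
    entry (the receiving tissue) and the footprint is evaluated on the upper
    face of that last medium.  ``tip_to_surface_um`` is an additional axial
    path through the first medium.
    """

    incidence_angle_deg: float = 35.0
    tip_to_surface_um: float = 150.0
    media: Sequence[Medium] = field(default_factory=_default_media)

    def __post_init__(self) -> None:
        if not 0 < self.incidence_angle_deg <= 90:
            raise ValueError("incidence angle must be in (0, 90] degrees")
        if self.tip_to_surface_um < 0:
            raise ValueError("tip_to_surface_um must be >= 0")
        if len(self.media) == 0:
            raise ValueError("at least one medium is required")


@dataclass(frozen=True)
class AbsorptionTable:
    """Tabulated water extinction coefficient k(lambda).

    ``wavelengths_nm`` strictly ascending, ``k_values`` dimensionless and
    positive.  The Lambert absorption coefficient follows as
    ``alpha = 4 pi k / lambda``.
    """

    wavelengths_nm: np.ndarray
    k_values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        if wl.ndim != 1 or wl.shape != k.shape or wl.size < 1:
            raise ValueError("wavelengths and k must be 1-D arrays of equal length")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(k > 0):
            raise ValueError("extinction coefficients must be > 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "k_values", k)

    @classmethod
    def from_csv(cls, path, source_label: str = "") -> "AbsorptionTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(np.atleast_1d(data["wavelength_nm"]),
                   np.atleast_1d(data["k"]), source_label)


def load_water_table() -> AbsorptionTable:
    """Packaged water extinction table (1300-2000 nm).

    The table is a synthetic coarse digitization of the published water
    extinction spectrum, assembled for this package from widely tabulated
    absorption-coefficient values; it is accurate to a few percent around
    1470 nm and 1875 nm.
    """
    ref = resources.files("ins2p.data") / "water_extinction_synthetic.csv"
    with resources.as_file(ref) as path:
        return AbsorptionTable.from_csv(
            path, source_label="synthetic digitization of the water extinction spectrum")


def interpolate_absorption(table: AbsorptionTable, wavelength_nm: float) -> float:
    """Lambert absorption coefficient alpha(lambda) in cm^-1.

    k is interpolated log-linearly between the bracketing tabulated
    wavelengths, then converted with ``alpha = 4 pi k / lambda``.
    """
    wl = table.wavelengths_nm
    if not wl[0] <= wavelength_nm <= wl[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside table range "
            f"[{wl[0]}, {wl[-1]}] nm")
    log_k = float(np.interp(wavelength_nm, wl, np.log(table.k_values)))
    lambda_cm = wavelength_nm * 1e-7
    return 4.0 * math.pi * math.exp(log_k) / lambda_cm


def penetration_depth(alpha_per_cm: float) -> float:
    """Depth (um) at which intensity falls to 1/e (~37%) of its surface value."""
    if alpha_per_cm <= 0:
        raise ValueError("alpha must be > 0")
    return 1e4 / alpha_per_cm


@dataclass(frozen=True)
class BeamFootprint:
    """Elliptical beam footprint; axes are full diameters in um."""

    major_axis_um: float
    minor_axis_um: float
    center_um: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.major_axis_um >= self.minor_axis_um > 0:
            raise ValueError("require major >= minor > 0")

    @property
    def area_cm2(self) -> float:
        return ellipse_area(self.major_axis_um, self.minor_axis_um)


def ellipse_area(major_um: float, minor_um: float) -> float:
    """Ellipse area in cm^2 from full axes in um."""
    if major_um <= 0 or minor_um <= 0:
        raise ValueError("axes must be > 0")
    if major_um < minor_um:
        raise ValueError("major axis must be >= minor axis")
    return math.pi * major_um * minor_um / 4.0 * _UM2_TO_CM2


def pulse_energy(energy_density_j_cm2: float, area_cm2: float) -> float:
    """Single-pulse energy in uJ delivered over ``area_cm2`` at the given
    radiant exposure."""
    if energy_density_j_cm2 < 0 or area_cm2 < 0:
        raise ValueError("inputs must be non-negative")
    return energy_density_j_cm2 * area_cm2 * 1e6


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse-train description: 250 us pulses at 200 Hz for 500 ms by default."""

    pulse_width_us: float = 250.0
    rep_rate_hz: float = 200.0
    train_duration_ms: float = 500.0
    energy_densities_j_cm2: tuple[float, ...] = (0.35, 0.47, 0.58, 0.70)

    def __post_init__(self) -> None:
        if self.pulse_width_us <= 0 or self.rep_rate_hz <= 0 or self.train_duration_ms <= 0:
            raise ValueError("pulse width, rate and duration must be > 0")
        if self.pulse_width_us * 1e-6 * self.rep_rate_hz > 1.0:
            raise ValueError("duty cycle exceeds 100%")
        if any(e <= 0 for e in self.energy_densities_j_cm2):
            raise ValueError("energy densities must be > 0")

    @property
    def n_pulses(self) -> int:
        return pulse_count(self.rep_rate_hz, self.train_duration_ms)


def pulse_count(rep_rate_hz: float, train_duration_ms: float) -> int:
    """Number of pulses in a train: floor(rate x duration)."""
    if rep_rate_hz <= 0 or train_duration_ms <= 0:
        raise ValueError("rate and duration must be > 0")
    return int(math.floor(rep_rate_hz * train_duration_ms * 1e-3))


def _snell_chain(n_list: Sequence[float], phi0_rad: float) -> list[float]:
    """Propagation angles from the surface normal through successive media."""
    phis = [phi0_rad]
    for i in range(len(n_list) - 1):
        s = n_list[i] * math.sin(phis[-1]) / n_list[i + 1]
        if s > 1.0:
            raise GeometryError(
                f"total internal reflection at interface {i}->{i + 1}")
        phis.append(math.asin(s))
    return phis


def project_footprint(fiber: FiberSpec, path: OpticalPathSpec) -> BeamFootprint:
    """Project the divergent fiber output onto the obliquely oriented brain
    surface.

    The beam is modelled as a cone of half-angle ``asin(NA / n)`` in each
    medium, refracted at flat interfaces parallel to the surface (Snell,
    no Fresnel losses).  The beam diameter where it meets the surface is the
    ellipse minor axis; obliquity stretches the footprint along the fiber's
    projected axis, so the major axis is minor / sin(final incidence angle),
    with the final angle taken in the medium just above the surface.
    """
    media = list(path.media)
    phi0 = math.radians(90.0 - path.incidence_angle_deg)
    phis = _snell_chain([m.refractive_index for m in media], phi0)

    # media traversed before the surface (all but the receiving tissue,
    # unless only a single medium is given)
    prop = media[:-1] if len(media) > 1 else media
    diameter = fiber.core_diameter_um
    for i, medium in enumerate(prop):
        axial = medium.thickness_um / math.cos(phis[i])
        if i == 0:
            axial += path.tip_to_surface_um
        divergence = math.asin(fiber.numerical_aperture / medium.refractive_index)
        diameter += 2.0 * axial * math.tan(divergence)

    phi_surface = phis[len(prop) - 1]
    incidence = math.pi / 2.0 - phi_surface  # angle to the surface plane
    n_surface = prop[-1].refractive_index
    divergence_surface = math.asin(fiber.numerical_aperture / n_surface)
    if incidence <= divergence_surface:
        raise GeometryError(
            "incidence angle at the surface does not exceed the beam "
            "divergence; footprint is degenerate")

    minor = diameter
    major = diameter / math.sin(incidence)
    return BeamFootprint(major_axis_um=major, minor_axis_um=minor,
                         orientation_deg=0.0)


@dataclass(frozen=True)
class FluenceField:
    """3-D radiant-exposure model of one pulse train's energy delivery.

    At the surface the fluence is an elliptical Gaussian whose 1/e^2
    diameters equal the footprint axes, normalized so the plane integral
    equals ``surface_pulse_energy_uj``; in depth it decays as
    ``exp(-alpha z)`` (Beer-Lambert).
    """

    footprint: BeamFootprint
    surface_pulse_energy_uj: float
    alpha_per_cm: float

    def __post_init__(self) -> None:
        if self.surface_pulse_energy_uj <= 0:
            raise ValueError("pulse energy must be > 0")
        if self.alpha_per_cm <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def radius_x_um(self) -> float:
        """1/e^2 radius along the footprint major axis."""
        return self.footprint.major_axis_um / 2.0

    @property
    def radius_y_um(self) -> float:
        """1/e^2 radius along the footprint minor axis."""
        return self.footprint.minor_axis_um / 2.0

    @property
    def peak_fluence_j_cm2(self) -> float:
        """Surface fluence at the beam center: 2E / (pi wx wy)."""
        wx, wy = self.radius_x_um, self.radius_y_um
        peak_uj_um2 = 2.0 * self.surface_pulse_energy_uj / (math.pi * wx * wy)
        return peak_uj_um2 * _UJ_PER_UM2_TO_J_PER_CM2

    def fluence(self, x_um, y_um, z_um=0.0):
        """Radiant exposure (J cm^-2) at FoV coordinates (x, y) and depth z >= 0.

        Accepts scalars or arrays (broadcast)."""
        x = np.asarray(x_um, dtype=float) - self.footprint.center_um[0]
        y = np.asarray(y_um, dtype=float) - self.footprint.center_um[1]
        z = np.asarray(z_um, dtype=float)
        if np.any(z < 0):
            raise ValueError("depth z must be >= 0")
        theta = math.radians(self.footprint.orientation_deg)
        xr = x * math.cos(theta) + y * math.sin(theta)
        yr = -x * math.sin(theta) + y * math.cos(theta)
        q = (xr / self.radius_x_um) ** 2 + (yr / self.radius_y_um) ** 2
        out = self.peak_fluence_j_cm2 * np.exp(-2.0 * q) * np.exp(
            -self.alpha_per_cm * z * 1e-4)
        return out if out.ndim else float(out)

    __call__ = fluence


def build_fluence_field(footprint: BeamFootprint, pulse_energy_uj: float,
                        alpha_per_cm: float) -> FluenceField:
    """Compose footprint, pulse energy and absorption into a fluence field."""
    return FluenceField(footprint=footprint,
                        surface_pulse_energy_uj=pulse_energy_uj,
                        alpha_per_cm=alpha_per_cm)


def dosimetry_report(fiber: FiberSpec, path: OpticalPathSpec,
                     protocol: StimulusProtocol,
                     table: AbsorptionTable | None = None) -> dict:
    """Full dosimetry summary as a JSON-serializable dict: footprint axes
    and area, per-energy-density pulse energies, absorption coefficient and
    penetration depth, and the pulse count."""
    if table is None:
        table = load_water_table()
    footprint = project_footprint(fiber, path)
    alpha = interpolate_absorption(table, fiber.wavelength_nm)
    area = footprint.area_cm2
    return {
        "fiber": {
            "core_diameter_um": fiber.core_diameter_um,
            "numerical_aperture": fiber.numerical_aperture,
            "wavelength_nm": fiber.wavelength_nm,
        },
        "footprint": {
            "major_axis_um": footprint.major_axis_um,
            "minor_axis_um": footprint.minor_axis_um,
            "area_cm2": area,
        },
        "pulse_train": {
            "pulse_width_us": protocol.pulse_width_us,
            "rep_rate_hz": protocol.rep_rate_hz,
            "train_duration_ms": protocol.train_duration_ms,
            "n_pulses": protocol.n_pulses,
        },
        "pulse_energies_uj": {
            f"{e:g}": pulse_energy(e, area)
            for e in protocol.energy_densities_j_cm2
        },
        "absorption": {
            "alpha_per_cm": alpha,
            "penetration_depth_um": penetration_depth(alpha),
            "table_source": table.source_label,
        },
    }
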