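"""Acoustofluidic physics of SAW-actuated particle sorting.

Implements the force laws governing lateral displacement of a particle in
a microchannel under surface acoustic wave excitation:

* the interdigitated-transducer (IDT) resonance ``f = v / lambda``;
* the dimensionless size parameter ``kappa = 2 pi d_p f / C_f`` that
  separates the radiation-force (ARF) regime from the streaming-drag
  (ASF) regime;
* the acoustic contrast factor
  ``phi = (5 rho_p - 2 rho_f) / (2 rho_p + rho_f) - beta_p / beta_f``;
* the one-dimensional standing-wave radiation force
  ``F = -(pi P0^2 V_p beta_f / 2 lambda) phi sin(2 k x)``;
* the time-averaged travelling-wave radiation force
  ``<F_ARF> = Y_T pi d_p^2 <E> / 4``;
* Stokes drag ``F_D = 3 pi eta d v`` and the quasi-steady lateral
  displacement ``dy = F tau / (3 pi eta d)`` over a pulse of duration tau.

All quantities are SI.  The particle Reynolds number in these devices is
far below one, so inertia is neglected throughout: a particle reaches its
terminal velocity instantaneously on the pulse time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleSpec",
    "FluidSpec",
    "AcousticField",
    "IDTSpec",
    "resonance_frequency",
    "kappa_factor",
    "dominant_regime",
    "contrast_factor",
    "ssaw_radiation_force",
    "tsaw_radiation_force",
    "stokes_drag",
    "lateral_displacement",
    "energy_density_from_power",
    "KAPPA_THRESHOLD_EXPERIMENTAL",
    "KAPPA_THRESHOLD_THEORETICAL",
]

#: empirically suggested regime boundary (anisotropic scattering onset)
KAPPA_THRESHOLD_EXPERIMENTAL = 1.28
#: theoretical boundary (kappa = 1)
KAPPA_THRESHOLD_THEORETICAL = 1.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ParticleSpec:
    """Acoustic material properties of a particle or cell.

    Parameters are SI: diameter in m, density in kg/m^3, compressibility
    in 1/Pa.  ``radiation_factor`` is the dimensionless travelling-wave
    scattering coefficient Y_T; it depends on particle mechanics and size
    and is supplied by the user (default 1.0) rather than computed from
    scattering theory.
    """

    diameter: float
    density: float = 1050.0
    compressibility: float = 4.0e-10
    radiation_factor: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            diameter=self.diameter,
            density=self.density,
            compressibility=self.compressibility,
        )
        if self.radiation_factor < 0:
            raise ValueError("radiation_factor must be >= 0")

    @property
    def volume(self) -> float:
        """Particle volume pi d^3 / 6 (m^3)."""
        return math.pi * self.diameter**3 / 6.0


@dataclass(frozen=True)
class FluidSpec:
    """Host-medium properties (SI).

    Defaults describe the viscous methylcellulose/PBS measurement buffer
    used in deformability cytometry: sound speed 1487 m/s and an effective
    in-channel viscosity of ~10 mPa s (shear-thinned from the ~25 mPa s
    bulk value).
    """

    density: float = 998.0
    compressibility: float = 4.58e-10
    sound_speed: float = 1487.0
    viscosity: float = 10e-3

    def __post_init__(self) -> None:
        _require_positive(
            density=self.density,
            compressibility=self.compressibility,
            sound_speed=self.sound_speed,
            viscosity=self.viscosity,
        )


# canonical water for quick experiments
WATER = FluidSpec(density=998.0, compressibility=4.58e-10,
                  sound_speed=1481.0, viscosity=1.0e-3)


@dataclass(frozen=True)
class AcousticField:
    """SSAW or TSAW excitation.

    mode='ssaw' requires ``pressure_amplitude`` (Pa) and ``wavelength``;
    mode='tsaw' requires ``energy_density`` (J/m^3).  ``pulse_duration``
    is the actuation pulse length in seconds.
    """

    mode: str
    frequency: float
    wavelength: float | None = None
    pressure_amplitude: float | None = None
    energy_density: float | None = None
    pulse_duration: float = 1e-3

    def __post_init__(self) -> None:
        mode = self.mode.lower()
        object.__setattr__(self, "mode", mode)
        if mode not in ("ssaw", "tsaw"):
            raise ValueError(f"mode must be 'ssaw' or 'tsaw', got {self.mode!r}")
        _require_positive(frequency=self.frequency, pulse_duration=self.pulse_duration)
        if mode == "ssaw":
            if self.pressure_amplitude is None or self.wavelength is None:
                raise ValueError("SSAW field requires pressure_amplitude and wavelength")
            _require_positive(pressure_amplitude=self.pressure_amplitude,
                              wavelength=self.wavelength)
        else:
            if self.energy_density is None:
                raise ValueError("TSAW field requires energy_density")
            if self.energy_density < 0:
                raise ValueError("energy_density must be >= 0")

    @property
    def wavenumber(self) -> float:
        """Acoustic wavenumber 2 pi / lambda (1/m)."""
        if self.wavelength is None:
            raise ValueError("wavelength not set for this field")
        return 2.0 * math.pi / self.wavelength


@dataclass(frozen=True)
class IDTSpec:
    """Interdigitated-transducer geometry on the piezoelectric substrate.

    ``substrate_sound_speed`` defaults to 3978 m/s (128 deg Y-cut lithium
    niobate); ``finger_periodicity`` is the acoustic wavelength set by the
    electrode pitch.
    """

    finger_periodicity: float
    substrate_sound_speed: float = 3978.0
    aperture: float = 100e-6
    focal_length: float = 170e-6
    design: str = "focused"

    def __post_init__(self) -> None:
        _require_positive(
            finger_periodicity=self.finger_periodicity,
            substrate_sound_speed=self.substrate_sound_speed,
            aperture=self.aperture,
            focal_length=self.focal_length,
        )
        if self.design not in ("straight", "focused"):
            raise ValueError("design must be 'straight' or 'focused'")


def resonance_frequency(idt: IDTSpec) -> float:
    """Design resonance f = v / lambda of the transducer (Hz).

    Fabricated devices can resonate a few percent below the design value;
    a measured frequency should be supplied as a config override where
    available.
    """
    return idt.substrate_sound_speed / idt.finger_periodicity


def kappa_factor(diameter: float, frequency: float, sound_speed: float) -> float:
    """Dimensionless size parameter kappa = 2 pi d_p f / C_f.

    kappa compares the particle circumference to the acoustic wavelength
    in the fluid; it decides whether direct radiation force (large kappa)
    or streaming-induced drag (small kappa) dominates lateral motion.
    ``diameter`` may be 0 (returns 0) but not negative.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    _require_positive(frequency=frequency, sound_speed=sound_speed)
    return 2.0 * math.pi * diameter * frequency / sound_speed


def dominant_regime(kappa: float, threshold: float = KAPPA_THRESHOLD_EXPERIMENTAL) -> str:
    """Classify the scattering regime: 'ARF' iff kappa > threshold else 'ASF'.

    The theoretical boundary is kappa = 1 (onset of anisotropic
    scattering); experiments place it at 1.28 +/- 0.2, which is the
    default.  The boundary itself is classified as ASF (strict
    inequality).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not (KAPPA_THRESHOLD_THEORETICAL <= threshold <= KAPPA_THRESHOLD_EXPERIMENTAL + 0.5):
        raise ValueError("threshold should lie near the 1.0-1.28 regime boundary")
    return "ARF" if kappa > threshold else "ASF"


def contrast_factor(particle: ParticleSpec, fluid: FluidSpec) -> float:
    """Acoustic contrast factor phi.

    phi = (5 rho_p - 2 rho_f) / (2 rho_p + rho_f) - beta_p / beta_f.
    Positive phi drives the particle to the pressure node, negative to
    the antinode.  Zero for a particle acoustically matched to the fluid.
    """
    rho_p, rho_f = particle.density, fluid.density
    density_term = (5.0 * rho_p - 2.0 * rho_f) / (2.0 * rho_p + rho_f)
    return density_term - particle.compressibility / fluid.compressibility


def ssaw_radiation_force(
    field: AcousticField, particle: ParticleSpec, fluid: FluidSpec, x: float
) -> float:
    """Standing-wave acoustic radiation force at distance x from the node (N).

    F = -(pi P0^2 V_p beta_f / 2 lambda) * phi * sin(2 k x).

    For phi > 0 the force restores the particle toward the pressure node:
    it vanishes at x = 0 and every lambda/4, and is lambda/2-periodic.
    """
    if field.mode != "ssaw":
        raise ValueError("ssaw_radiation_force requires a field with mode='ssaw'")
    phi = contrast_factor(particle, fluid)
    amplitude = (
        math.pi
        * field.pressure_amplitude**2
        * particle.volume
        * fluid.compressibility
        / (2.0 * field.wavelength)
    )
    return -amplitude * phi * math.sin(2.0 * field.wavenumber * x)


def tsaw_radiation_force(field: AcousticField, particle: ParticleSpec) -> float:
    """Time-averaged travelling-wave radiation force (N).

    <F_ARF> = Y_T pi d_p^2 <E> / 4, directed away from the transducer
    (toward the target outlet in the sorter geometry).  Scales with the
    particle cross-section d_p^2, which is why small cells (platelets)
    are hard to deflect.
    """
    if field.mode != "tsaw":
        raise ValueError("tsaw_radiation_force requires a field with mode='tsaw'")
    if field.energy_density is None:
        raise ValueError("TSAW field has no energy_density configured")
    return (
        particle.radiation_factor
        * math.pi
        * particle.diameter**2
        * field.energy_density
        / 4.0
    )


def stokes_drag(fluid: FluidSpec, diameter: float, relative_velocity: float) -> float:
    """Stokes drag F_D = 3 pi eta d v on a sphere (N), opposing motion.

    Returned with the sign of ``relative_velocity``; the drag force on
    the particle is minus this value.
    """
    _require_positive(diameter=diameter)
    return 3.0 * math.pi * fluid.viscosity * diameter * relative_velocity


def lateral_displacement(
    force: float, fluid: FluidSpec, diameter: float, pulse_duration: float
) -> float:
    """Quasi-steady lateral travel under a constant force pulse (m).

    dy = F tau / (3 pi eta d): the particle moves at the terminal
    velocity F / (3 pi eta d) for the whole pulse.  Valid at Re << 1
    where the viscous relaxation time (~us) is far below the pulse
    length (~ms).  ``force`` may be a numpy array (vectorised over
    events); ``diameter`` broadcasts likewise.
    """
    _require_positive(pulse_duration=pulse_duration)
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter <= 0):
        raise ValueError("diameter must be positive")
    out = np.asarray(force, dtype=float) * pulse_duration / (
        3.0 * math.pi * fluid.viscosity * diameter
    )
    return float(out) if out.ndim == 0 else out


def energy_density_from_power(
    electrical_power: float,
    conversion_efficiency: float,
    beam_cross_section: float,
    sound_speed: float,
) -> float:
    """Calibration helper mapping RF drive power to <E> (J/m^3).

    <E> = eta_conv * P / (A_beam * C_f): the acoustic power delivered
    into the fluid divided by the energy flux area.  The electro-acoustic
    conversion efficiency is a single user-supplied number; no substrate
    propagation model is implied.
    """
    _require_positive(
        electrical_power=electrical_power,
        beam_cross_section=beam_cross_section,
        sound_speed=sound_speed,
    )
    if not 0 < conversion_efficiency <= 1:
        raise ValueError("conversion_efficiency must be in (0, 1]")
    return conversion_efficiency * electrical_power / (beam_cross_section * sound_speed)
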