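"""Scalar-diffraction building blocks for in-line digital holography.

The simulation chain is: a thin object multiplies an incident plane wave
(:func:`transmit`), the exit wave travels to the sensor under the paraxial
Fresnel approximation (:func:`fresnel_propagate`), and the sensor records
the interference of that wave with an on-axis plane reference
(:func:`interfere`).  Propagation uses the single-FFT transfer-function
method, whose kernel has unit modulus -- total power is conserved exactly
and propagating by ``-z`` undoes propagating by ``+z``, which is what the
reconstruction stage relies on.

Sign convention: phases enter fields as ``exp(+i*phase)`` everywhere.
The complex exponential prefactor ``exp(ikz)`` of the Fresnel kernel is
retained; it is a global phase and cancels in every intensity image.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "TransmissionObject",
    "ComplexField",
    "PlaneReference",
    "PlaneTag",
    "SamplingWarning",
    "SamplingError",
    "plane_wave",
    "transmit",
    "transfer_function",
    "fresnel_propagate",
    "interfere",
    "wrap_phase",
]


class SamplingWarning(UserWarning):
    """The requested propagation distance violates the aliasing criterion."""


class SamplingError(ValueError):
    """Raised instead of :class:`SamplingWarning` in strict mode."""


class PlaneTag(enum.Enum):
    OBJECT = "object_plane"
    RECORDING = "recording_plane"


def wrap_phase(phi: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    out = -((-phi + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out)


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the recording setup.

    Parameters
    ----------
    wavelength : float
        Laser wavelength in metres.
    distance_z : float
        Object-to-sensor distance in metres.
    pixel_pitch : float
        Square pixel size in metres.
    grid_shape : tuple of int
        Sensor dimensions ``(rows, cols)``; each must be even and >= 8.
    strict_sampling : bool
        If True, a violated sampling criterion raises :class:`SamplingError`
        instead of emitting a :class:`SamplingWarning`.
    """

    wavelength: float
    distance_z: float
    pixel_pitch: float
    grid_shape: tuple[int, int] = (512, 512)
    strict_sampling: bool = False

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if self.distance_z <= 0:
            raise ValueError(f"distance_z must be positive, got {self.distance_z}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        rows, cols = self.grid_shape
        if rows < 8 or cols < 8 or rows % 2 or cols % 2:
            raise ValueError(
                f"grid dims must be even and >= 8, got {self.grid_shape}"
            )

    @property
    def wave_number(self) -> float:
        """k = 2*pi / wavelength; derived, never stored."""
        return 2.0 * np.pi / self.wavelength

    @property
    def critical_distance(self) -> float:
        """Largest |z| for which the transfer-function kernel is alias-free.

        ``z_c = N * pitch^2 / wavelength`` with N the smaller grid dimension:
        beyond this distance the sampled quadratic-phase kernel wraps.
        """
        n = min(self.grid_shape)
        return n * self.pixel_pitch**2 / self.wavelength


@dataclass
class TransmissionObject:
    """Thin object described by ``t = exp(-absorption) * exp(i*phase)``.

    Pure amplitude objects have ``phase == 0``; immersion in clear water is
    modelled as zero absorption (transmission 1).
    """

    absorption: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorption = np.asarray(self.absorption, dtype=float)
        if self.phase is None:
            self.phase = np.zeros_like(self.absorption)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != self.absorption.shape:
            raise ValueError(
                f"phase shape {self.phase.shape} != absorption shape "
                f"{self.absorption.shape}"
            )
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.absorption.shape

    def transmission(self) -> np.ndarray:
        """Complex transmission ``exp(-a) * exp(i*phi)``; magnitude in [0, 1]."""
        return np.exp(-self.absorption) * np.exp(1j * self.phase)


@dataclass
class ComplexField:
    """A sampled complex wavefront on a uniform grid."""

    values: np.ndarray
    plane_tag: PlaneTag = PlaneTag.OBJECT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass(frozen=True)
class PlaneReference:
    """On-axis plane reference wave ``A_r * exp(i*delta)``."""

    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"reference amplitude must be >= 0, got {self.amplitude}")
        object.__setattr__(self, "phase", wrap_phase(self.phase))

    @property
    def value(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase)


def plane_wave(grid_shape: tuple[int, int], amplitude: float = 1.0,
               plane_tag: PlaneTag = PlaneTag.OBJECT) -> ComplexField:
    """Uniform unit-phase plane wave, the default incident illumination."""
    return ComplexField(np.full(grid_shape, amplitude, dtype=complex), plane_tag)


def transmit(obj: TransmissionObject, incident: ComplexField) -> ComplexField:
    """Exit wave behind a thin object: pointwise product with its transmission."""
    if obj.shape != incident.shape:
        raise ValueError(
            f"object shape {obj.shape} does not match incident field shape "
            f"{incident.shape}"
        )
    return ComplexField(obj.transmission() * incident.values, incident.plane_tag)


def transfer_function(config: OpticalConfig, z_signed: float) -> np.ndarray:
    """Sampled Fresnel transfer function ``exp(ikz) exp(-i pi lambda z f^2)``.

    Unit modulus everywhere, hence exactly power-conserving and invertible
    by conjugation (equivalently by flipping the sign of z).
    """
    rows, cols = config.grid_shape
    fy = np.fft.fftfreq(rows, d=config.pixel_pitch)
    fx = np.fft.fftfreq(cols, d=config.pixel_pitch)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(1j * config.wave_number * z_signed) * np.exp(
        -1j * np.pi * config.wavelength * z_signed * f2
    )


def _check_sampling(config: OpticalConfig, z_signed: float) -> None:
    zc = config.critical_distance
    if abs(z_signed) > zc * (1.0 + 1e-12):
        msg = (
            f"|z| = {abs(z_signed):.4g} m exceeds the alias-free limit "
            f"z_c = N*pitch^2/lambda = {zc:.4g} m for this grid; the "
            "transfer-function kernel is undersampled"
        )
        if config.strict_sampling:
            raise SamplingError(msg)
        warnings.warn(msg, SamplingWarning, stacklevel=3)


def fresnel_propagate(field: ComplexField, z_signed: float,
                      config: OpticalConfig) -> ComplexField:
    """Fresnel-propagate a field by a signed distance (negative = inverse).

    Implemented as ``IFFT( FFT(U) * H(z) )`` with the analytic kernel of
    :func:`transfer_function`.  ``z_signed == 0`` returns the input
    unchanged (no FFT round-off is introduced).
    """
    if field.shape != tuple(config.grid_shape):
        raise ValueError(
            f"field shape {field.shape} does not match config grid "
            f"{config.grid_shape}"
        )
    if z_signed == 0:
        return ComplexField(field.values.copy(), field.plane_tag)
    _check_sampling(config, z_signed)
    spectrum = np.fft.fft2(field.values)
    out = np.fft.ifft2(spectrum * transfer_function(config, z_signed))
    tag = PlaneTag.RECORDING if z_signed > 0 else PlaneTag.OBJECT
    return ComplexField(out, tag)


def interfere(object_field: ComplexField, reference: PlaneReference) -> np.ndarray:
    """Recorded intensity ``|U_z + A_r exp(i delta)|^2``; real and >= 0."""
    total = object_field.values + reference.value
    return (total * np.conj(total)).real
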