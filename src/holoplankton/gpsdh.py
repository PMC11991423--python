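"""Two-step generalized phase-shifting reconstruction.

Two interferograms recorded with an unknown reference phase step, plus the
individual object and reference intensities, determine the complex object
wave on the recording plane in closed form:

    Re(U_o) = (I1 - Io - Ir) / (2 A_r)
    Im(U_o) = (I2 - I1 cos d - (1 - cos d)(Io + Ir)) / (2 A_r sin d)

The step ``d`` itself can be estimated from the data when the object-wave
phase is broadly distributed over the frame (the generic situation after
Fresnel diffraction of a diffuse object).  Refocusing the recovered wave
to the object plane is a single inverse Fresnel propagation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .optics import (
    ComplexField,
    OpticalConfig,
    PlaneTag,
    fresnel_propagate,
)

__all__ = [
    "EPS_DELTA",
    "HologramSet",
    "Provenance",
    "PhaseStepError",
    "ar_from_reference",
    "estimate_phase_shift",
    "reconstruct_object_wave",
    "two_step_reconstruct",
]

#: Degeneracy guard for the 1/sin(delta) division.
EPS_DELTA = 1e-3

#: Fraction of the object-intensity maximum below which a pixel is
#: excluded from phase-step estimation.
SUPPORT_FRACTION = 1e-3


class Provenance(enum.Enum):
    SIMULATED = "simulated"
    EXPERIMENTAL = "experimental"


class PhaseStepError(ValueError):
    """Degenerate or unestimable reference phase step."""


@dataclass
class HologramSet:
    """The four intensity frames consumed by the two-step algorithm.

    ``I1`` and ``I2`` are the interferograms at reference phases 0 and
    ``delta``; ``Io`` is the object-wave intensity and ``Ir`` the (nominally
    uniform) reference intensity.  ``background`` is an optional flat-field
    frame that only occurs with experimental data.
    """

    I1: np.ndarray
    I2: np.ndarray
    Io: np.ndarray
    Ir: np.ndarray
    delta: float | None = None
    provenance: Provenance = Provenance.SIMULATED
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        maps = {"I1": self.I1, "I2": self.I2, "Io": self.Io, "Ir": self.Ir}
        for name, m in maps.items():
            arr = np.asarray(m, dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.I1.shape:
                raise ValueError(f"{name} shape {arr.shape} != I1 shape {self.I1.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.delta is not None and abs(np.sin(self.delta)) <= EPS_DELTA:
            raise PhaseStepError(
                f"phase step delta = {self.delta} has |sin(delta)| <= {EPS_DELTA}; "
                "the two-step inversion is degenerate"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.I1.shape


def ar_from_reference(Ir: np.ndarray) -> float:
    """Reference amplitude from its intensity frame: sqrt(spatial mean)."""
    Ir = np.asarray(Ir, dtype=float)
    if np.any(Ir < 0):
        raise ValueError("reference intensity must be nonnegative")
    mean = Ir.mean()
    if mean == 0:
        raise ValueError("reference intensity frame is identically zero")
    return float(np.sqrt(mean))


def estimate_phase_shift(holoset: HologramSet) -> float:
    """Estimate the reference phase step from the four frames.

    Over pixels with appreciable object intensity, the normalized
    interference terms ``c1 = (I1-Io-Ir)/(2 sqrt(Io Ir)) = cos(phi)`` and
    ``c2 = (I2-Io-Ir)/(2 sqrt(Io Ir)) = cos(phi - d)`` correlate as
    ``<c1 c2>/sqrt(<c1^2><c2^2>) -> cos(d)`` when the object phase ``phi``
    is broadly distributed.  Returns the step in (0, pi); the two-frame
    problem cannot distinguish +d from -d.

    Raises
    ------
    PhaseStepError
        If ``I1 == I2`` within tolerance (a zero step), or if fewer than 1%
        of pixels carry object intensity.
    """
    I1, I2, Io, Ir = holoset.I1, holoset.I2, holoset.Io, holoset.Ir
    scale = max(I1.max(), I2.max(), 1e-300)
    if np.allclose(I1, I2, rtol=0.0, atol=1e-9 * scale):
        raise PhaseStepError(
            "I1 and I2 are identical: the phase step is zero (or a multiple "
            "of 2*pi) and cannot be used for two-step reconstruction"
        )
    support = Io > SUPPORT_FRACTION * Io.max()
    if support.mean() < 0.01:
        raise PhaseStepError(
            "object intensity has support on less than 1% of pixels; "
            "the phase step cannot be estimated reliably"
        )
    den = 2.0 * np.sqrt(Io[support] * Ir[support])
    valid = den > 0
    c1 = (I1[support] - Io[support] - Ir[support])[valid] / den[valid]
    c2 = (I2[support] - Io[support] - Ir[support])[valid] / den[valid]
    norm = np.sqrt(np.mean(c1 * c1) * np.mean(c2 * c2))
    if norm == 0:
        raise PhaseStepError("interference terms vanish; cannot estimate the step")
    ratio = np.mean(c1 * c2) / norm
    delta_hat = float(np.arccos(np.clip(ratio, -1.0, 1.0)))
    if abs(np.sin(delta_hat)) <= EPS_DELTA:
        raise PhaseStepError(
            f"estimated phase step {delta_hat:.4g} rad is degenerate "
            f"(|sin| <= {EPS_DELTA})"
        )
    return delta_hat


def reconstruct_object_wave(holoset: HologramSet, delta: float,
                            A_r: float) -> ComplexField:
    """Closed-form object wave on the recording plane from the four frames."""
    if A_r <= 0:
        raise ValueError(f"reference amplitude must be positive, got {A_r}")
    sin_d = np.sin(delta)
    if abs(sin_d) <= EPS_DELTA:
        raise PhaseStepError(
            f"phase step delta = {delta} rad is degenerate: |sin(delta)| = "
            f"{abs(sin_d):.3g} <= {EPS_DELTA}"
        )
    cos_d = np.cos(delta)
    I1, I2, Io, Ir = holoset.I1, holoset.I2, holoset.Io, holoset.Ir
    real = (I1 - Io - Ir) / (2.0 * A_r)
    imag = (I2 - I1 * cos_d - (1.0 - cos_d) * (Io + Ir)) / (2.0 * A_r * sin_d)
    return ComplexField(real + 1j * imag, PlaneTag.RECORDING)


def two_step_reconstruct(holoset: HologramSet, config: OpticalConfig,
                         delta: float | None = None,
                         flat_field: bool = False) -> np.ndarray:
    """Full pipeline: recover the object wave, refocus, return |amplitude|.

    The phase step is taken from ``delta``, else from ``holoset.delta``,
    else estimated from the frames.  The recovered recording-plane wave is
    back-propagated by ``-config.distance_z`` and the amplitude image is
    normalized to [0, 1] by its maximum.

    ``flat_field=True`` divides all frames by the optional background frame
    first (experimental data only; off by default).
    """
    hs = holoset
    if flat_field:
        if hs.background is None:
            raise ValueError("flat_field requested but the set has no background frame")
        bg = np.where(hs.background > 0, hs.background, np.nan)
        scale = np.nanmean(bg)
        flat = np.where(np.isfinite(bg), bg, scale) / scale
        hs = HologramSet(hs.I1 / flat, hs.I2 / flat, hs.Io / flat, hs.Ir / flat,
                         delta=hs.delta, provenance=hs.provenance)
    if delta is None:
        delta = hs.delta
    if delta is None:
        delta = estimate_phase_shift(hs)
    A_r = ar_from_reference(hs.Ir)
    wave = reconstruct_object_wave(hs, delta, A_r)
    refocused = fresnel_propagate(wave, -config.distance_z, config)
    amp = refocused.amplitude
    peak = amp.max()
    return amp / peak if peak > 0 else amp
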