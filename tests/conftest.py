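"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the library code paths they check:
propagation is re-done with explicit O(N^4) summations, and dataset
statistics are recomputed by direct enumeration.
"""

import numpy as np
import pytest

from holoplankton.gpsdh import HologramSet
from holoplankton.optics import (
    ComplexField,
    OpticalConfig,
    PlaneTag,
    TransmissionObject,
)
from holoplankton.scenegen import (
    compose_scene,
    make_shape_bank,
    profile_config,
    synthesize_hologram_set,
)


@pytest.fixture
def desk_config() -> OpticalConfig:
    return profile_config("desk")


@pytest.fixture
def tiny_config() -> OpticalConfig:
    """32x32 grid with z at 60% of the alias-free limit."""
    pitch, wl, n = 5e-6, 530e-9, 32
    return OpticalConfig(wavelength=wl, distance_z=0.6 * n * pitch**2 / wl,
                         pixel_pitch=pitch, grid_shape=(n, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_field(rng, shape, tag=PlaneTag.OBJECT) -> ComplexField:
    values = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return ComplexField(values, tag)


# ---------------------------------------------------------------------------
# propagation oracles (no FFT anywhere)
# ---------------------------------------------------------------------------

def naive_dft_propagate(u: np.ndarray, config: OpticalConfig,
                        z: float) -> np.ndarray:
    """Direct-summation spectral propagation: explicit DFT matrices, the
    sampled Fresnel transfer function, explicit inverse DFT.  O(N^4)."""
    n = u.shape[0]
    k = 2 * np.pi / config.wavelength
    f = np.fft.fftfreq(n, d=config.pixel_pitch)
    H = np.exp(1j * k * z) * np.exp(
        -1j * np.pi * config.wavelength * z * (f[:, None] ** 2 + f[None, :] ** 2))
    m = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(m, m) / n)      # forward DFT matrix
    Wi = np.conj(W) / n                                # inverse DFT matrix
    return Wi @ ((W @ u @ W.T) * H) @ Wi.T


def chirp_convolution_propagate(u: np.ndarray, config: OpticalConfig,
                                z: float) -> np.ndarray:
    """O(N^4) circular convolution with the spatially sampled Fresnel chirp
    h = exp(ikz)/(i lambda z) exp(ik r^2 / 2z) * pitch^2.  Coincides with
    the transfer-function operator exactly at the critical distance."""
    n = u.shape[0]
    wl, pitch = config.wavelength, config.pixel_pitch
    k = 2 * np.pi / wl
    idx = np.arange(n)
    d = ((idx + n // 2) % n - n // 2) * pitch  # periodic displacements
    DX, DY = np.meshgrid(d, d, indexing="ij")
    h = np.exp(1j * k * z) / (1j * wl * z) * np.exp(
        1j * k * (DX**2 + DY**2) / (2 * z)) * pitch**2
    out = np.zeros_like(u, dtype=complex)
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sum(u * h[(i - idx)[:, None] % n, (j - idx)[None, :] % n])
    return out


# ---------------------------------------------------------------------------
# simulated hologram sets
# ---------------------------------------------------------------------------

def amplitude_scene_set(seed: int, config: OpticalConfig, delta: float,
                        count_range=(2, 4)):
    """Compose a silhouette scene and synthesize its four frames.

    Returns (holoset, transmission object, true recording-plane wave)."""
    from holoplankton.optics import fresnel_propagate, plane_wave, transmit

    gen = np.random.default_rng(seed)
    bank = make_shape_bank(gen, size=max(12, min(config.grid_shape) // 4))
    obj, _ = compose_scene(bank, gen, config.grid_shape, count_range)
    holoset = synthesize_hologram_set(obj, config, delta=delta)
    true_wave = fresnel_propagate(transmit(obj, plane_wave(config.grid_shape)),
                                  config.distance_z, config)
    return holoset, obj, true_wave


def diffuse_scene_set(seed: int, config: OpticalConfig, delta: float,
                      A_r: float = 1.0) -> HologramSet:
    """Hologram set of a weak random-phase object: after propagation the
    object-wave phase is broadly distributed, the regime the phase-step
    estimator is specified for."""
    from holoplankton.optics import fresnel_propagate, plane_wave, transmit

    gen = np.random.default_rng(seed)
    shape = config.grid_shape
    obj = TransmissionObject(absorption=0.3 * gen.random(shape),
                             phase=gen.uniform(-np.pi, np.pi, shape))
    wave = fresnel_propagate(transmit(obj, plane_wave(shape)),
                             config.distance_z, config)
    return synthesize_hologram_set(obj, config, delta=delta, A_r=A_r)
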