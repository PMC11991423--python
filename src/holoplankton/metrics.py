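"""Image-quality measures: SSIM, mean squared error, log-magnitude spectra.

Two SSIM modes are exposed.  ``gaussian_11x11`` is the conventional
mean-of-local-windows form (11x11 Gaussian weights, sigma = 1.5) and is
the default; ``global`` evaluates the same formula once on whole-image
statistics.  Inputs are jointly min-max rescaled to [0, L] (L = 255 for
the 8-bit convention) so the stabilizing constants c1 = (k1 L)^2 and
c2 = (k2 L)^2 act on a fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SSIMParams", "ssim", "mse", "log_spectrum"]

_WINDOW_MODES = ("global", "gaussian_11x11")


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0
    window: str = "gaussian_11x11"

    def __post_init__(self) -> None:
        if self.window not in _WINDOW_MODES:
            raise ValueError(f"window must be one of {_WINDOW_MODES}, got {self.window!r}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("derived constants c1, c2 must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


def _rescale_pair(x: np.ndarray, y: np.ndarray, L: float):
    """Jointly min-max rescale both images to [0, L].

    A joint (not per-image) rescale keeps SSIM sensitive to brightness
    differences between the two inputs.  Already-constant pairs are
    passed through unchanged.
    """
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:
        return x - lo, y - lo
    s = L / (hi - lo)
    return (x - lo) * s, (y - lo) * s


def _ssim_formula(mu_x, mu_y, var_x, var_y, cov_xy, c1, c2):
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov_xy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return num / den


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity between two images of equal shape.

    Returns 1.0 exactly when ``x`` and ``y`` are identical, and is
    symmetric in its arguments in both window modes.
    """
    if params is None:
        params = SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    if np.array_equal(x, y):
        return 1.0
    x, y = _rescale_pair(x, y, params.L)
    c1, c2 = params.c1, params.c2

    if params.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x = np.mean((x - mu_x) ** 2)
        var_y = np.mean((y - mu_y) ** 2)
        cov = np.mean((x - mu_x) * (y - mu_y))
        return float(min(_ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2), 1.0))

    # 11x11 Gaussian window, sigma 1.5; truncate chosen so the filter
    # footprint is exactly 11 pixels.  The border where the window hangs
    # off the image is cropped before averaging.
    sigma = 1.5
    win = 11
    truncate = (win - 1) / 2 / sigma
    blur = lambda im: ndimage.gaussian_filter(im, sigma, mode="nearest",
                                              truncate=truncate)
    mu_x, mu_y = blur(x), blur(y)
    mu_xx, mu_yy, mu_xy = blur(x * x), blur(y * y), blur(x * y)
    var_x = np.maximum(mu_xx - mu_x**2, 0.0)  # guard float-negative variances
    var_y = np.maximum(mu_yy - mu_y**2, 0.0)
    cov = mu_xy - mu_x * mu_y
    smap = _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2)
    pad = (win - 1) // 2
    core = smap[pad:smap.shape[0] - pad, pad:smap.shape[1] - pad]
    if core.size == 0:  # image smaller than the window: use the full map
        core = smap
    # per-window SSIM is <= 1 mathematically; float noise may poke above
    return float(min(core.mean(), 1.0))


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean of squared pixel differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def log_spectrum(x: np.ndarray) -> np.ndarray:
    """Centered ``log(1 + |FFT|)`` magnitude spectrum of an image."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("image must be finite")
    return np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(x))))
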