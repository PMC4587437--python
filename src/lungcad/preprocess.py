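"""Adaptive Wiener denoising of CT slices.

Pixel-wise linear filtering from local statistics: within a sliding window
the local mean mu and variance sigma^2 are estimated, and the output is

    F = mu + max(sigma^2 - v^2, 0) / sigma^2 * (I - mu)

where v^2 is the noise variance.  Where the local signal variance is below
the noise floor the filter returns the local mean; where the signal
dominates it passes the detail through.  Borders use reflect padding so no
spurious HU values appear at the thorax edge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import CTImage

_EPS = 1e-12


@dataclasses.dataclass
class WienerConfig:
    """Window size (odd, default 3x3) and noise variance (HU^2 or "estimate")."""

    window: tuple[int, int] = (3, 3)
    noise_variance: float | str = "estimate"

    def __post_init__(self) -> None:
        w = tuple(int(x) for x in self.window)
        if len(w) != 2 or any(x < 1 or x % 2 == 0 for x in w):
            raise ValueError(f"window dims must be odd and >= 1, got {w}")
        self.window = w
        if isinstance(self.noise_variance, str):
            if self.noise_variance != "estimate":
                raise ValueError("noise_variance must be a number or 'estimate'")
        elif self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


def local_mean_variance(
    pixels: np.ndarray, window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and variance with reflect padding."""
    mu = ndimage.uniform_filter(pixels, size=window, mode="reflect")
    mu2 = ndimage.uniform_filter(pixels * pixels, size=window, mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    return mu, var


def wiener_filter(image: CTImage, config: WienerConfig | None = None) -> CTImage:
    """Apply the adaptive Wiener filter to a CT slice.

    With ``noise_variance="estimate"`` the noise floor v^2 is taken as the
    mean of all local variances.  The gain (sigma^2 - v^2)/sigma^2 is
    clamped at zero so noise-dominated pixels collapse to the local mean.
    """
    config = config or WienerConfig()
    pixels = image.pixels
    if config.window[0] > pixels.shape[0] or config.window[1] > pixels.shape[1]:
        raise ValueError(
            f"window {config.window} larger than image {pixels.shape}"
        )
    mu, var = local_mean_variance(pixels, config.window)
    if config.noise_variance == "estimate":
        noise = float(var.mean())
    else:
        noise = float(config.noise_variance)
    gain = np.maximum(var - noise, 0.0) / np.maximum(var, _EPS)
    filtered = mu + gain * (pixels - mu)
    return CTImage(pixels=filtered, source_id=image.source_id)
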