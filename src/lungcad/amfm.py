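"""Multiscale AM-FM demodulation.

An image region is modelled as a sum of components a_n(k) cos(phi_n(k))
with slowly varying instantaneous amplitude (IA) a_n, instantaneous phase
(IP) phi_n, and instantaneous frequency (IF) grad phi_n.  Demodulation:

1. Extend the real image to an analytic image by adding j times its 2D
   Hilbert transform, realized in the frequency domain by zeroing one
   frequency half-plane and doubling the other.
2. Pass the analytic image through a four-scale, 25-filter bank: one
   low-pass disc plus four radial annuli (H, M, L, VL) whose bandwidths
   halve per scale, each annulus cut into six 30-degree orientation
   wedges over the half-plane.
3. Per channel, IA = |response|, IP = arg(response), and IF components via
   variable-spacing phase differences (spacing adapted to the channel's
   radial center frequency).
4. Dominant component analysis: per pixel, over the channels of a scale
   combination, keep the estimates of the channel with the largest IA.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

MIN_FILTER_SHAPE = 32

# Nominal radial band edges, rad/pixel.  The outermost band's support
# additionally absorbs the rectangular grid's corner bins (|omega| > pi)
# so that the 25 supports partition the half-plane exactly.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "LPF": (0.0, np.pi / 16),
    "VL": (np.pi / 16, np.pi / 8),
    "L": (np.pi / 8, np.pi / 4),
    "M": (np.pi / 4, np.pi / 2),
    "H": (np.pi / 2, np.pi),
}
SCALE_ORDER = ("LPF", "H", "M", "L", "VL")  # filter 1 = LPF, 2-7 = H, ...
N_WEDGES = 6

# amplitude gate below which phase (hence IF) is meaningless
IA_GATE_FRAC = 1e-3

_IF_SPACING_MIN, _IF_SPACING_MAX = 1, 4


@dataclasses.dataclass
class AMFMEstimates:
    """Per-pixel IA, IP, and IF for one channel or one dominant composite."""

    ia: np.ndarray
    ip: np.ndarray
    if_k1: np.ndarray
    if_k2: np.ndarray

    @property
    def if_mag(self) -> np.ndarray:
        return np.hypot(self.if_k1, self.if_k2)


@dataclasses.dataclass(frozen=True)
class ScaleCombination:
    """One of the 11 scale subsets used for dominant component analysis."""

    id: int
    scales: frozenset[str]


SCALE_COMBINATIONS: tuple[ScaleCombination, ...] = tuple(
    ScaleCombination(i + 1, frozenset(s))
    for i, s in enumerate(
        [
            {"VL", "L", "M", "H"},
            {"LPF"},
            {"VL"},
            {"L"},
            {"M"},
            {"LPF", "VL", "L", "M", "H"},
            {"LPF", "VL"},
            {"VL", "L"},
            {"L", "M"},
            {"M", "H"},
            {"H"},
        ]
    )
)


@dataclasses.dataclass
class Filterbank:
    """Frequency-domain realization of the 25-filter four-scale bank.

    ``filters[i]`` is a {0,1} transfer function on the FFT grid of
    ``shape``; ``scale_of[i]`` names its scale; ``center_freq[i]`` is the
    nominal radial center (rad/pixel) used by the IF spacing rule.
    """

    shape: tuple[int, int]
    filters: list[np.ndarray]
    scale_of: list[str]
    center_freq: list[float]

    def __len__(self) -> int:
        return len(self.filters)

    def indices_for(self, scales: frozenset[str] | set[str]) -> list[int]:
        return [i for i, s in enumerate(self.scale_of) if s in scales]


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    w1 = 2 * np.pi * np.fft.fftfreq(shape[0])
    w2 = 2 * np.pi * np.fft.fftfreq(shape[1])
    return np.meshgrid(w1, w2, indexing="ij")


def halfplane_mask(shape: tuple[int, int]) -> np.ndarray:
    """FFT-grid bins forming the analytic half-plane: w1 > 0, or w1 = 0 and w2 > 0."""
    w1g, w2g = _freq_grids(shape)
    return (w1g > 0) | ((w1g == 0) & (w2g > 0))


def analytic_image(image: np.ndarray) -> np.ndarray:
    """Analytic extension: zero the negative-w1 half-plane, double the positive.

    DC and Nyquist boundary rows keep unit gain, so the real part of the
    result equals the input to machine precision (the standard discrete
    analytic-signal construction, applied along the row-frequency axis).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("analytic_image requires a 2D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("analytic_image requires finite values")
    m = image.shape[0]
    spectrum = np.fft.fft2(image)
    gain = np.zeros(m)
    if m % 2 == 0:
        gain[0] = gain[m // 2] = 1.0
        gain[1 : m // 2] = 2.0
    else:
        gain[0] = 1.0
        gain[1 : (m + 1) // 2] = 2.0
    return np.fft.ifft2(spectrum * gain[:, None])


def build_filterbank(shape: tuple[int, int]) -> Filterbank:
    """Construct the 25-filter bank on the FFT grid of ``shape``.

    Ideal (brick-wall) supports: LPF = open disc |omega| < pi/16 within the
    half-plane; each scale annulus is cut into six equal orientation wedges.
    The supports are disjoint and their union is exactly the half-plane.
    """
    if shape[0] < MIN_FILTER_SHAPE or shape[1] < MIN_FILTER_SHAPE:
        raise ValueError(f"shape {shape} too small for the filterbank (min {MIN_FILTER_SHAPE})")
    w1g, w2g = _freq_grids(shape)
    half = halfplane_mask(shape)
    radius = np.hypot(w1g, w2g)
    theta = np.arctan2(w2g, w1g)  # in [-pi/2, pi/2] on the half-plane
    wedge = np.clip(np.floor((theta + np.pi / 2) / (np.pi / N_WEDGES)), 0, N_WEDGES - 1)

    filters: list[np.ndarray] = []
    scale_of: list[str] = []
    center_freq: list[float] = []
    for scale in SCALE_ORDER:
        lo, hi = BAND_EDGES[scale]
        if scale == "LPF":
            in_band = half & (radius < hi)
        elif scale == "H":
            in_band = half & (radius >= lo)  # unbounded outer edge: covers corners
        else:
            in_band = half & (radius >= lo) & (radius < hi)
        if scale == "LPF":
            filters.append(in_band.astype(np.float64))
            scale_of.append(scale)
            center_freq.append((lo + hi) / 2)
            continue
        for w in range(N_WEDGES):
            filters.append((in_band & (wedge == w)).astype(np.float64))
            scale_of.append(scale)
            center_freq.append((lo + hi) / 2)
    return Filterbank(shape=tuple(shape), filters=filters, scale_of=scale_of, center_freq=center_freq)


def if_spacing(center_freq: float) -> int:
    """Variable phase-difference spacing: s = clamp(round(pi / (2 w_c)), 1, 4).

    Low-frequency channels use a wider spacing so the phase increment is
    well above the phase-difference noise floor; high-frequency channels
    use s = 1 to avoid phase wrapping.
    """
    if center_freq <= 0:
        return _IF_SPACING_MAX
    return int(np.clip(round(np.pi / (2 * center_freq)), _IF_SPACING_MIN, _IF_SPACING_MAX))


def _phase_diff_axis(channel: np.ndarray, spacing: int, axis: int) -> np.ndarray:
    """IF component along ``axis`` from spaced phase differences.

    arg(z(k + s e) conj(z(k))) / s at each valid pixel; the trailing border
    replicates the nearest interior estimate.
    """
    n = channel.shape[axis]
    s = min(spacing, n - 1)
    lead = np.take(channel, np.arange(s, n), axis=axis)
    lag = np.take(channel, np.arange(0, n - s), axis=axis)
    est = np.angle(lead * np.conj(lag)) / s
    pad = [(0, 0), (0, 0)]
    pad[axis] = (0, s)
    return np.pad(est, pad, mode="edge")


def demodulate_channel(
    analytic: np.ndarray,
    transfer: np.ndarray,
    spacing: int | None = None,
    center_freq: float | None = None,
) -> AMFMEstimates:
    """Demodulate one filterbank channel of an analytic image.

    The channel response is the inverse FFT of (transfer x spectrum);
    IA = |response|, IP = arg(response); IF components come from spaced
    phase differences (``spacing``, or derived from ``center_freq`` via the
    variable-spacing rule).  Pixels whose IA falls below a small fraction
    of the channel maximum get IF = 0: phase is meaningless there.
    """
    analytic = np.asarray(analytic, dtype=np.complex128)
    if analytic.shape != transfer.shape:
        raise ValueError("transfer function shape must match image shape")
    if spacing is None:
        spacing = if_spacing(center_freq) if center_freq is not None else 1
    channel = np.fft.ifft2(np.fft.fft2(analytic) * transfer)
    ia = np.abs(channel)
    ip = np.angle(channel)
    if_k1 = _phase_diff_axis(channel, spacing, axis=0)
    if_k2 = _phase_diff_axis(channel, spacing, axis=1)
    gate = ia < IA_GATE_FRAC * ia.max() if ia.max() > 0 else np.ones_like(ia, dtype=bool)
    if_k1 = np.where(gate, 0.0, if_k1)
    if_k2 = np.where(gate, 0.0, if_k2)
    return AMFMEstimates(ia=ia, ip=ip, if_k1=if_k1, if_k2=if_k2)


def demodulate_all(image: np.ndarray, filterbank: Filterbank) -> list[AMFMEstimates]:
    """Demodulate every filterbank channel (spectrum computed once)."""
    z = analytic_image(image)
    spectrum = np.fft.fft2(z)
    out = []
    for transfer, wc in zip(filterbank.filters, filterbank.center_freq):
        channel = np.fft.ifft2(spectrum * transfer)
        s = if_spacing(wc)
        ia = np.abs(channel)
        ip = np.angle(channel)
        if_k1 = _phase_diff_axis(channel, s, axis=0)
        if_k2 = _phase_diff_axis(channel, s, axis=1)
        gate = ia < IA_GATE_FRAC * ia.max() if ia.max() > 0 else np.ones_like(ia, dtype=bool)
        out.append(
            AMFMEstimates(
                ia=ia,
                ip=ip,
                if_k1=np.where(gate, 0.0, if_k1),
                if_k2=np.where(gate, 0.0, if_k2),
            )
        )
    return out


def dominant_component(
    channel_estimates: Sequence[AMFMEstimates],
    filterbank: Filterbank | None = None,
    combo: ScaleCombination | None = None,
) -> AMFMEstimates:
    """Per-pixel selection of the channel with maximal IA.

    With ``filterbank`` and ``combo`` given, ``channel_estimates`` must be
    the full per-filter list and only channels whose scale belongs to the
    combination compete; otherwise all supplied channels compete.
    """
    if filterbank is not None and combo is not None:
        idx = filterbank.indices_for(combo.scales)
        channel_estimates = [channel_estimates[i] for i in idx]
    if not channel_estimates:
        raise ValueError("no channels to select the dominant component from")
    ia = np.stack([e.ia for e in channel_estimates])
    winner = np.argmax(ia, axis=0)[None, ...]

    def pick(field: str) -> np.ndarray:
        stack = np.stack([getattr(e, field) for e in channel_estimates])
        return np.take_along_axis(stack, winner, axis=0)[0]

    return AMFMEstimates(
        ia=np.take_along_axis(ia, winner, axis=0)[0],
        ip=pick("ip"),
        if_k1=pick("if_k1"),
        if_k2=pick("if_k2"),
    )
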