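"""Synthetic chest-CT phantoms and closed-form AM-FM test images.

The phantom emulates the HU structure the segmentation stage relies on: a
scanner-padding background near -3024 HU, an elliptical thorax of
fat/muscle tissue around -50 HU, two elliptical lung cavities of textured
parenchyma around -700 HU, and (optionally) a bright nodule disc above
-500 HU with a mildly roughened surround, so that texture -- not just mean
HU -- separates the cancer class.  Ground-truth masks and per-side labels
ride along, which makes every downstream stage testable without any
external dataset.

AM-FM test images are built from closed forms a(k) cos(phi(k)) with the
true IA, phase, and IF returned alongside the pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import BinaryMask, CTImage

DEFAULT_IMAGE_SIZE = 512

# Default HU levels: centers of the bands the segmenter expects
# (background spike -3024; lung parenchyma -910..-500; tissue above -500).
HU_BACKGROUND = -3024.0
HU_FAT_MUSCLE = -50.0
HU_LUNG = -700.0
HU_NODULE = 20.0
LUNG_TEXTURE_SD = 60.0
NOISE_SD = 5.0

# texture correlation length (pixels) for the smoothed-noise parenchyma
_TEXTURE_SMOOTH_SIGMA = 1.5
# roughened ring around a nodule, in units of nodule radius
_NODULE_HALO_FACTOR = 2.5
_NODULE_HALO_EXTRA_SD_FRAC = 0.5


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and semi-axes (row, col), pixels."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (
            ((rr - self.center[0]) / self.axes[0]) ** 2
            + ((cc - self.center[1]) / self.axes[1]) ** 2
        ) <= 1.0

    def contains(self, other: "Ellipse", margin: float = 0.0) -> bool:
        # conservative check on the other ellipse's bounding extremes
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r = other.center[0] + dr * other.axes[0]
            c = other.center[1] + dc * other.axes[1]
            v = ((r - self.center[0]) / self.axes[0]) ** 2 + (
                (c - self.center[1]) / self.axes[1]
            ) ** 2
            if v > (1.0 - margin) ** 2:
                return False
        return True


@dataclasses.dataclass(frozen=True)
class NoduleSpec:
    """Bright disc: center (row, col), radius in pixels, and lung side."""

    center: tuple[float, float]
    radius: float
    side: str  # "left" or "right" (radiological display)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nodule radius must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("nodule side must be 'left' or 'right'")


def _default_thorax(size: int) -> Ellipse:
    return Ellipse(center=(0.51 * size, 0.50 * size), axes=(0.31 * size, 0.39 * size))


def _default_lungs(size: int) -> dict[str, Ellipse]:
    # radiological display: patient-left lung sits at larger columns
    return {
        "right": Ellipse(center=(0.51 * size, 0.30 * size), axes=(0.19 * size, 0.125 * size)),
        "left": Ellipse(center=(0.51 * size, 0.70 * size), axes=(0.19 * size, 0.125 * size)),
    }


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, HU levels, texture, and noise of one synthetic slice."""

    image_size: int = DEFAULT_IMAGE_SIZE
    thorax_ellipse: Ellipse | None = None
    lung_ellipses: dict[str, Ellipse] | None = None
    hu_background: float = HU_BACKGROUND
    hu_fat_muscle: float = HU_FAT_MUSCLE
    hu_lung: float = HU_LUNG
    hu_nodule: float = HU_NODULE
    lung_texture_sd: float = LUNG_TEXTURE_SD
    nodule: NoduleSpec | None = None
    noise_sd: float = NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thorax_ellipse is None:
            self.thorax_ellipse = _default_thorax(self.image_size)
        if self.lung_ellipses is None:
            self.lung_ellipses = _default_lungs(self.image_size)
        if set(self.lung_ellipses) != {"left", "right"}:
            raise ValueError("lung_ellipses must have exactly the keys 'left' and 'right'")
        if not (self.hu_background < self.hu_lung < self.hu_fat_muscle):
            raise ValueError("HU ordering violated: background < lung < fat/muscle required")
        for side, lung in self.lung_ellipses.items():
            if not self.thorax_ellipse.contains(lung, margin=0.02):
                raise ValueError(f"{side} lung ellipse not strictly inside the thorax")


@dataclasses.dataclass
class PhantomTruth:
    """A phantom image with its ground-truth masks and per-side labels."""

    image: CTImage
    thorax_mask: BinaryMask
    lung_mask: BinaryMask
    left_mask: BinaryMask
    right_mask: BinaryMask
    labels: dict[str, int]
    spec: PhantomSpec

    def __post_init__(self) -> None:
        left = self.left_mask.as_bool()
        right = self.right_mask.as_bool()
        if (left & right).any():
            raise ValueError("left and right lung masks overlap")
        if not np.array_equal(left | right, self.lung_mask.as_bool()):
            raise ValueError("left | right must equal the lung mask")


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Band-limited texture: smoothed white noise rescaled to the target sd."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, _TEXTURE_SMOOTH_SIGMA)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom slice with ground truth; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)

    thorax = spec.thorax_ellipse.mask(shape)
    left = spec.lung_ellipses["left"].mask(shape)
    right = spec.lung_ellipses["right"].mask(shape)
    lungs = left | right

    image = np.full(shape, spec.hu_background)
    image[thorax] = spec.hu_fat_muscle
    texture = _correlated_noise(rng, shape, spec.lung_texture_sd)
    image[lungs] = spec.hu_lung + texture[lungs]

    labels = {"left": 0, "right": 0}
    if spec.nodule is not None:
        nod = spec.nodule
        side_mask = left if nod.side == "left" else right
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dist2 = (rr - nod.center[0]) ** 2 + (cc - nod.center[1]) ** 2
        disc = dist2 <= nod.radius**2
        if not (disc & side_mask).any():
            raise ValueError("nodule disc lies outside its lung")
        halo = (dist2 <= (_NODULE_HALO_FACTOR * nod.radius) ** 2) & side_mask & ~disc
        image[disc & side_mask] = spec.hu_nodule
        image[halo] += rng.standard_normal(int(halo.sum())) * (
            _NODULE_HALO_EXTRA_SD_FRAC * spec.lung_texture_sd
        )
        labels[nod.side] = 1

    if spec.noise_sd > 0:
        image = image + rng.standard_normal(shape) * spec.noise_sd

    return PhantomTruth(
        image=CTImage(image, source_id=f"phantom_seed{spec.seed}"),
        thorax_mask=BinaryMask(thorax),
        lung_mask=BinaryMask(lungs),
        left_mask=BinaryMask(left),
        right_mask=BinaryMask(right),
        labels=labels,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# AM-FM test images
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AMFMTestImage:
    """pixels = ia_true * cos(phase_true), with the analytic IF alongside."""

    pixels: np.ndarray
    ia_true: np.ndarray
    phase_true: np.ndarray
    if_true: tuple[np.ndarray, np.ndarray]
    description: str


def make_amfm_image(kind: str, **params) -> AMFMTestImage:
    """Closed-form single-component AM-FM images.

    kinds
    -----
    sinusoid : ``omega=(w1, w2)``, optional ``phase0`` -- constant IF.
    gaussian_am_sinusoid : sinusoid with a Gaussian IA envelope
        (``am_center``, ``am_sigma``).
    radial_chirp : quadratic phase ``alpha * r^2 / 2`` around ``center``;
        |IF| = alpha * r grows linearly with radius.  ``alpha`` defaults to
        keeping max |IF| at 0.8 pi.

    All requested spatial frequencies must lie in (0, pi) rad/pixel.
    """
    size = int(params.get("size", 128))
    k1, k2 = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    k1 = k1.astype(float)
    k2 = k2.astype(float)

    if kind in ("sinusoid", "gaussian_am_sinusoid"):
        w1, w2 = params.get("omega", (np.pi / 4, 0.0))
        if not (0 <= abs(w1) < np.pi and 0 <= abs(w2) < np.pi) or (w1 == 0 and w2 == 0):
            raise ValueError("sinusoid frequencies must lie in (0, pi) rad/pixel")
        phase = w1 * k1 + w2 * k2 + params.get("phase0", 0.0)
        if kind == "sinusoid":
            ia = np.ones_like(phase)
            desc = f"sinusoid omega=({w1:.4f},{w2:.4f})"
        else:
            c1, c2 = params.get("am_center", (size / 2, size / 2))
            sigma = params.get("am_sigma", size / 4)
            ia = np.exp(-(((k1 - c1) ** 2 + (k2 - c2) ** 2) / (2 * sigma**2)))
            desc = f"gaussian AM sinusoid omega=({w1:.4f},{w2:.4f}) sigma={sigma:.1f}"
        if_true = (np.full_like(phase, w1), np.full_like(phase, w2))
    elif kind == "radial_chirp":
        c1, c2 = params.get("center", (size / 2, size / 2))
        r_max = np.hypot(max(c1, size - 1 - c1), max(c2, size - 1 - c2))
        alpha = params.get("alpha", 0.8 * np.pi / r_max)
        if alpha <= 0 or alpha * r_max >= np.pi:
            raise ValueError("radial chirp |IF| must stay inside (0, pi) rad/pixel")
        phase = alpha * ((k1 - c1) ** 2 + (k2 - c2) ** 2) / 2
        ia = np.ones_like(phase)
        if_true = (alpha * (k1 - c1), alpha * (k2 - c2))
        desc = f"radial chirp alpha={alpha:.5f}"
    else:
        raise ValueError(f"unknown AM-FM test image kind: {kind!r}")

    return AMFMTestImage(
        pixels=ia * np.cos(phase),
        ia_true=ia,
        phase_true=phase,
        if_true=if_true,
        description=desc,
    )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def make_dataset(
    n_per_class: int,
    base_spec: PhantomSpec | None = None,
    jitter: float = 0.05,
    seed: int = 0,
) -> list[PhantomTruth]:
    """Generate ``n_per_class`` phantoms, each bearing one nodule.

    Every phantom carries a nodule in one lung (sides alternate), so ROI
    splitting yields exactly ``n_per_class`` cancer lungs and
    ``n_per_class`` normal lungs.  Geometry and texture are jittered per
    image (fractional ``jitter`` on axes/levels, a few pixels on centers);
    deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    size = base.image_size
    phantoms = []
    for i in range(n_per_class):
        def jit(x: float) -> float:
            return float(x * (1 + rng.uniform(-jitter, jitter)))

        def shift(c: tuple[float, float], amount: float) -> tuple[float, float]:
            return (
                float(c[0] + rng.uniform(-amount, amount)),
                float(c[1] + rng.uniform(-amount, amount)),
            )

        thorax = Ellipse(
            center=shift(base.thorax_ellipse.center, 0.01 * size),
            axes=(jit(base.thorax_ellipse.axes[0]), jit(base.thorax_ellipse.axes[1])),
        )
        lungs = {
            side: Ellipse(
                center=shift(e.center, 0.01 * size),
                axes=(jit(e.axes[0]), jit(e.axes[1])),
            )
            for side, e in base.lung_ellipses.items()
        }
        side = "left" if i % 2 == 0 else "right"
        lung = lungs[side]
        # place the nodule well inside the lung ellipse
        radius = float(rng.uniform(0.018, 0.03) * size)
        angle = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.5)
        center = (
            lung.center[0] + rho * (lung.axes[0] - radius) * np.sin(angle),
            lung.center[1] + rho * (lung.axes[1] - radius) * np.cos(angle),
        )
        spec = PhantomSpec(
            image_size=size,
            thorax_ellipse=thorax,
            lung_ellipses=lungs,
            hu_background=base.hu_background,
            hu_fat_muscle=base.hu_fat_muscle,
            hu_lung=base.hu_lung,
            hu_nodule=base.hu_nodule,
            lung_texture_sd=jit(base.lung_texture_sd),
            nodule=NoduleSpec(center=center, radius=radius, side=side),
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = make_phantom(spec)
        truth.image.source_id = f"phantom_{i:03d}"
        phantoms.append(truth)
    return phantoms
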