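"""Synthetic brain-slice phantoms with ground-truth tissue labels.

A phantom is a 2D grayscale slice built from concentric discs: dark
background, an optional dark skull ring, a thin CSF rim, a gray-matter
annulus and a white-matter core, plus an optional bright tumor disc
surrounded by an edema halo.  Each tissue has a distinct mean intensity;
i.i.d. Gaussian noise is added and the result is clipped to [0, 255].
Phantoms give every downstream stage (skull stripping, segmentation,
feature extraction, classification) a reproducible input with exact
ground truth, which clinical scans cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# Integer label codes.  Order matters nowhere except readability.
BACKGROUND = 0
SKULL = 1
CSF = 2
GM = 3
WM = 4
TUMOR = 5
EDEMA = 6

LABEL_NAMES = {
    BACKGROUND: "background",
    SKULL: "skull",
    CSF: "CSF",
    GM: "GM",
    WM: "WM",
    TUMOR: "tumor",
    EDEMA: "edema",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Fixed class order used for classification and tie-breaking.
TISSUE_CLASSES = ("WM", "GM", "CSF", "tumor", "edema")

#: Default per-tissue mean intensities (8-bit scale).  Gaps are wide
#: enough that tissues stay separable up to noise_sd ~ 8.
DEFAULT_TISSUE_MEANS = {
    "background": 0.0,
    "skull": 25.0,
    "CSF": 50.0,
    "GM": 110.0,
    "WM": 200.0,
    "edema": 150.0,
    "tumor": 245.0,
}

# Layer geometry as fractions of the brain radius (itself 0.40 of the
# smaller image dimension): skull ring width in pixels, CSF rim inner
# fraction, GM annulus inner fraction.
_BRAIN_RADIUS_FRAC = 0.40
_SKULL_WIDTH_PX = 4.0
_CSF_INNER_FRAC = 0.87
_GM_INNER_FRAC = 0.58


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice.

    The same spec (including ``seed``) always generates bit-identical
    output.  ``tumor`` is an optional ``((row, col), radius)`` pair in
    pixel coordinates; the tumor disc plus its edema halo must fit
    inside the white-matter core.
    """

    width: int = 192
    height: int = 192
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sd: float = 4.0
    skull_ring: bool = True
    tumor: Optional[tuple] = None  # ((row, col), radius_px)
    edema_halo_width: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ValueError("phantom must be at least 16x16 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        means = sorted(self.tissue_means.values())
        min_gap = min(b - a for a, b in zip(means, means[1:]))
        if min_gap < max(3.0 * self.noise_sd, 1e-9):
            raise ValueError(
                "tissue means must be pairwise distinct by at least 3*noise_sd "
                f"(min gap {min_gap:.1f} < {3.0 * self.noise_sd:.1f})"
            )
        r_brain = self.brain_radius
        if self.skull_ring and r_brain + _SKULL_WIDTH_PX > 0.5 * min(self.width, self.height):
            raise ValueError("skull ring does not fit inside the image")
        if self.tumor is not None:
            (tr, tc), radius = self.tumor
            if radius <= 0:
                raise ValueError("tumor radius must be positive")
            cr, cc = (self.height - 1) / 2.0, (self.width - 1) / 2.0
            off = float(np.hypot(tr - cr, tc - cc))
            if off + radius + self.edema_halo_width > self.wm_radius:
                raise ValueError(
                    "tumor disc plus edema halo does not fit inside the WM core"
                )

    @property
    def brain_radius(self) -> float:
        return _BRAIN_RADIUS_FRAC * min(self.width, self.height)

    @property
    def wm_radius(self) -> float:
        return _GM_INNER_FRAC * self.brain_radius


@dataclass
class LabeledImage:
    """A 2D intensity array with a per-pixel tissue label map.

    ``intensity`` is float64 in [0, 255]; ``labels`` is an int array over
    the codes in :data:`LABEL_NAMES`.  Coordinates are 0-based
    ``(row, col)``.  Every pixel carries exactly one label.
    """

    intensity: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must have the same shape")
        if self.intensity.ndim != 2:
            raise ValueError("expected 2D arrays")

    @property
    def shape(self):
        return self.intensity.shape

    def mask(self, tissue) -> np.ndarray:
        """Binary ground-truth mask for one tissue (name or label code)."""
        code = NAME_TO_LABEL[tissue] if isinstance(tissue, str) else int(tissue)
        return self.labels == code

    def copy(self) -> "LabeledImage":
        return LabeledImage(self.intensity.copy(), self.labels.copy())


def _label_map(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(rows - cr, cols - cc)

    r_brain = spec.brain_radius
    labels = np.full((h, w), BACKGROUND, dtype=np.int64)
    if spec.skull_ring:
        labels[(dist > r_brain) & (dist <= r_brain + _SKULL_WIDTH_PX)] = SKULL
    labels[dist <= r_brain] = CSF
    labels[dist <= _CSF_INNER_FRAC * r_brain] = GM
    labels[dist <= _GM_INNER_FRAC * r_brain] = WM

    if spec.tumor is not None:
        (tr, tc), radius = spec.tumor
        tdist = np.hypot(rows - tr, cols - tc)
        labels[(tdist > radius) & (tdist <= radius + spec.edema_halo_width)] = EDEMA
        labels[tdist <= radius] = TUMOR
    return labels


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Generate a phantom slice and its ground-truth label map.

    Intensity of each pixel is its tissue mean plus N(0, noise_sd^2)
    noise (seeded), clipped to [0, 255].  A pure function of ``spec``.
    """
    labels = _label_map(spec)
    intensity = np.empty(labels.shape, dtype=np.float64)
    for code, name in LABEL_NAMES.items():
        sel = labels == code
        if sel.any():
            intensity[sel] = spec.tissue_means.get(name, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity += rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    np.clip(intensity, 0.0, 255.0, out=intensity)
    return LabeledImage(intensity, labels)


def corrupt(img: LabeledImage, noise_sd: float, seed: int = 0) -> LabeledImage:
    """Add seeded Gaussian noise to the intensities; labels are untouched."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    out = img.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.intensity += rng.normal(0.0, noise_sd, size=out.intensity.shape)
        np.clip(out.intensity, 0.0, 255.0, out=out.intensity)
    return out


def random_tumor_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Vary tumor center/radius and halo width within the WM core.

    Used by the pipeline to build image cohorts whose lesions differ
    between slices while every geometry constraint still holds.
    """
    h, w = base.height, base.width
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = float(rng.uniform(10.0, 14.0))
    halo = float(rng.uniform(5.0, 7.0))
    max_off = base.wm_radius - radius - halo - 1.0
    ang = rng.uniform(0.0, 2.0 * np.pi)
    off = rng.uniform(0.0, max(max_off, 0.0))
    center = (cr + off * np.sin(ang), cc + off * np.cos(ang))
    return replace(base, tumor=(center, radius), edema_halo_width=halo)
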