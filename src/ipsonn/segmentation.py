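"""Tissue segmentation operators.

Five operators turn a skull-stripped slice into binary masks:

* ``gradient_map`` — Gaussian smoothing followed by a central-difference
  gradient magnitude; its edge map separates tissue interfaces.
* ``segment_wm_gm`` — a white/gray-matter dichotomy: non-edge brain
  pixels are binarized by an intensity cut (bright -> WM, dark -> GM).
* ``segment_csf`` — a sine-based pixel transform ("orthogonal polynomial
  transform"): I_cf = sin(3*I/100)^2 + 0.05*rand with the intensity
  rescaled to [0, 100]; CSF responds low, so the mask is the brain
  pixels below a fraction of the maximum response.
* ``segment_tumor`` — seeded region growing: a 4-neighbor joins the
  region iff its intensity is within a tolerance of the running region
  mean.  The seed is auto-placed at the brightest blob after histogram
  equalization.
* ``segment_edema`` — histogram equalization, a multilevel intensity
  band (t4 <= p <= t3, tumor core above t5 excluded), a per-pixel
  distance-from-tumor-centroid test (keep distance >= t6), then
  morphological dilation and closing.

``segment_tissues`` runs them in dependency order and resolves overlaps
so the masks partition the pathological tissue away from the healthy
ones.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .preprocess import hist_equalize


@dataclass
class SegmentationParams:
    """Tunable thresholds; ``None`` means derive automatically per image.

    gauss_sigma : px, smoothing before the gradient.
    edge_threshold : gradient-magnitude cut for the edge map (auto: Otsu
        on the gradient magnitude inside the brain).
    wm_gm_intensity_cut : intensity separating WM from GM (auto: Otsu on
        brain intensities).
    csf_threshold : fraction of max CSF-transform response kept.
    csf_smooth_sigma : px, smoothing applied before the CSF transform.
    t3, t4, t5 : multilevel intensity thresholds for the edema band
        (auto: percentile bounds of the equalized intensities in a thin
        ring just outside the tumor core).
    t6 : px, minimum distance from the tumor centroid (auto: tumor
        equivalent radius sqrt(area/pi)).
    rg_tolerance : intensity, region-growing homogeneity tolerance.
    rg_seed : (row, col) seed for region growing, or "auto".
    morph_radius : px, structuring-element radius for the edema
        dilation/closing (0 disables morphology).
    trim_mad : after the morphology, drop pixels whose raw intensity
        deviates from the mask median by more than this many MADs —
        the dilation sweeps in a ring of neighboring tissue that would
        otherwise contaminate the region's statistics (0 disables).
    max_tumor_fraction : if the grown region exceeds this fraction of
        the brain area, the image is treated as having no focal tumor.
    """

    gauss_sigma: float = 0.5
    edge_threshold: Optional[float] = None
    wm_gm_intensity_cut: Optional[float] = None
    csf_threshold: float = 0.45
    csf_smooth_sigma: float = 1.0
    t3: Optional[float] = None
    t4: Optional[float] = None
    t5: Optional[float] = None
    t6: Optional[float] = None
    rg_tolerance: float = 25.0
    rg_seed: object = "auto"
    morph_radius: int = 1
    trim_mad: float = 4.0
    max_tumor_fraction: float = 0.25

    def __post_init__(self):
        if self.gauss_sigma < 0:
            raise ValueError("gauss_sigma must be nonnegative")
        if self.rg_tolerance < 0:
            raise ValueError("rg_tolerance must be nonnegative")
        if self.t3 is not None and self.t4 is not None and self.t4 > self.t3:
            raise ValueError("t4 must not exceed t3")
        if not 0 < self.csf_threshold <= 1:
            raise ValueError("csf_threshold must be a fraction in (0, 1]")


@dataclass
class TissueMasks:
    """Binary masks per tissue, same shape as the input slice."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    tumor: np.ndarray
    edema: np.ndarray
    tumor_centroid: Optional[tuple] = None
    params_used: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "WM": self.wm,
            "GM": self.gm,
            "CSF": self.csf,
            "tumor": self.tumor,
            "edema": self.edema,
        }


# ---------------------------------------------------------------------------
# gradient


def gradient_map(I_s: np.ndarray, gauss_sigma: float = 0.5):
    """Smooth with a Gaussian, then take the central-difference gradient.

    Returns ``(I_G, grad_mag)`` where ``I_G`` is the smoothed image and
    ``grad_mag = sqrt((dI/dx)^2 + (dI/dy)^2)``.
    """
    if gauss_sigma < 0:
        raise ValueError("gauss_sigma must be nonnegative")
    I_s = np.asarray(I_s, dtype=np.float64)
    I_G = ndimage.gaussian_filter(I_s, gauss_sigma) if gauss_sigma > 0 else I_s.copy()
    gy, gx = np.gradient(I_G)
    grad_mag = np.hypot(gx, gy)
    return I_G, grad_mag


# ---------------------------------------------------------------------------
# WM / GM


def _exact_otsu_cut(vals: np.ndarray) -> float:
    """Between-class-variance-optimal cut over the exact value set.

    Binned Otsu implementations return a bin *center*, which on a
    noise-free image can fall a hair below an intensity mode and flip
    that whole tissue across the cut.  Scanning the distinct values
    directly and returning the midpoint of the optimal gap avoids the
    quantization artifact.
    """
    u, counts = np.unique(vals, return_counts=True)
    if u.size < 2:
        return float(u[0])
    w = counts / counts.sum()
    cw = np.cumsum(w)
    cm = np.cumsum(w * u)
    mu = cm[-1]
    w0, w1 = cw[:-1], 1.0 - cw[:-1]
    m0 = cm[:-1] / w0
    m1 = (mu - cm[:-1]) / w1
    var = w0 * w1 * (m0 - m1) ** 2
    k = int(np.argmax(var))
    return float(0.5 * (u[k] + u[k + 1]))


def segment_wm_gm(I_s: np.ndarray, grad_mag: np.ndarray, params: SegmentationParams):
    """Dichotomize non-edge brain pixels into WM (bright) and GM (dark).

    The edge map is ``grad_mag > edge_threshold``; edge pixels (tissue
    interfaces) are assigned to neither mask.  Returns
    ``(wm_mask, gm_mask)``, disjoint by construction.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    brain = I_s > 0
    if not brain.any():
        raise ValueError("empty brain support")

    thr_e = params.edge_threshold
    if thr_e is None:
        vals = grad_mag[brain]
        thr_e = filters.threshold_otsu(vals) if np.ptp(vals) > 0 else np.inf
    edges = grad_mag > thr_e

    cut = params.wm_gm_intensity_cut
    if cut is None:
        cut = _exact_otsu_cut(I_s[brain])
    elif not 0 <= cut <= 255:
        raise ValueError("wm_gm_intensity_cut outside the intensity range [0, 255]")

    keep = brain & ~edges
    wm = keep & (I_s >= cut)
    gm = keep & (I_s < cut)
    return wm, gm


# ---------------------------------------------------------------------------
# CSF


def csf_response(
    I_s: np.ndarray,
    smooth_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """The sine pixel transform: sin(3*u/100)^2 + 0.05*rand, u in [0,100].

    ``u`` is the (optionally smoothed) intensity rescaled from the 8-bit
    range to [0, 100].  With ``rng=None`` the random term is zero, which
    gives the deterministic closed form.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    if smooth_sigma > 0:
        I_s = ndimage.gaussian_filter(I_s, smooth_sigma)
    u = I_s * (100.0 / 255.0)
    icf = np.sin(u * 3.0 / 100.0) ** 2
    if rng is not None:
        icf = icf + 0.05 * rng.random(I_s.shape)
    return icf


def segment_csf(I_s: np.ndarray, params: SegmentationParams, rng) -> np.ndarray:
    """CSF mask: brain pixels whose transform response is in the low band.

    ``rng`` may be a seeded ``numpy.random.Generator`` or an int seed;
    the same seed always yields the same mask.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    I_s = np.asarray(I_s, dtype=np.float64)
    brain = I_s > 0
    if not brain.any():
        return brain
    icf = csf_response(I_s, smooth_sigma=params.csf_smooth_sigma, rng=rng)
    cutoff = params.csf_threshold * icf[brain].max()
    return brain & (icf <= cutoff)


# ---------------------------------------------------------------------------
# tumor (region growing)


def _auto_seed(I_s: np.ndarray, brain: np.ndarray) -> tuple:
    """Brightest-blob centroid after histogram equalization."""
    eq = hist_equalize(I_s)
    thr = np.percentile(eq[brain], 99.0)
    blob = brain & (eq >= thr)
    lab, n = ndimage.label(blob)
    if n == 0:
        raise ValueError("no candidate tumor blob found")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    biggest = lab == counts.argmax()
    rows, cols = np.nonzero(biggest)
    cr, cc = rows.mean(), cols.mean()
    # snap the centroid to the blob pixel nearest to it
    k = np.argmin((rows - cr) ** 2 + (cols - cc) ** 2)
    return int(rows[k]), int(cols[k])


def region_grow(
    I_s: np.ndarray,
    seed: tuple,
    tolerance: float,
    support: Optional[np.ndarray] = None,
    max_pixels: Optional[int] = None,
) -> np.ndarray:
    """Grow a 4-connected region from ``seed`` by running-mean homogeneity.

    A neighbor joins iff ``|intensity - region mean| <= tolerance`` with
    the mean updated as the region grows (breadth-first, fixed neighbor
    order, hence deterministic).  ``max_pixels`` aborts runaway growth.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    h, w = I_s.shape
    if support is None:
        support = np.ones_like(I_s, dtype=bool)
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < h and 0 <= c0 < w) or not support[r0, c0]:
        raise ValueError("seed outside the brain support")

    mask = np.zeros((h, w), dtype=bool)
    mask[r0, c0] = True
    total = I_s[r0, c0]
    count = 1
    queue = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            if mask[rr, cc] or not support[rr, cc]:
                continue
            if abs(I_s[rr, cc] - total / count) <= tolerance:
                mask[rr, cc] = True
                total += I_s[rr, cc]
                count += 1
                queue.append((rr, cc))
                if max_pixels is not None and count > max_pixels:
                    return mask
    return mask


def segment_tumor(I_s: np.ndarray, params: SegmentationParams):
    """Region-grow the tumor core; returns ``(tumor_mask, centroid)``.

    The centroid (center of mass of the grown region) feeds the edema
    distance test.  If the grown region exceeds ``max_tumor_fraction``
    of the brain area — i.e. the "tumor" is just bright normal tissue —
    the image is treated as having no focal tumor and
    ``(empty mask, None)`` is returned.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    brain = I_s > 0
    if not brain.any():
        raise ValueError("empty brain support")
    if params.rg_seed == "auto":
        seed = _auto_seed(I_s, brain)
    else:
        seed = tuple(params.rg_seed)
        if not brain[int(seed[0]), int(seed[1])]:
            raise ValueError("seed outside the brain support")
    cap = int(params.max_tumor_fraction * brain.sum())
    mask = region_grow(I_s, seed, params.rg_tolerance, support=brain, max_pixels=cap)
    if mask.sum() > cap:
        return np.zeros_like(brain), None
    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()), float(cols.mean()))
    return mask, centroid


# ---------------------------------------------------------------------------
# edema


def _auto_band(eq: np.ndarray, brain: np.ndarray, tumor_mask: np.ndarray,
               centroid: tuple, t6: float):
    """Derive (t3, t4, t5) from a thin ring just outside the tumor core.

    The ring (distance in (t6, t6 + 3] from the centroid) is dominated
    by peritumoral tissue, so percentile bounds of its equalized
    intensities bracket the edema band; t5 is the lower edge of the
    tumor-core intensities, which caps the band from above.
    """
    h, w = eq.shape
    rows, cols = np.mgrid[0:h, 0:w]
    d = np.hypot(rows - centroid[0], cols - centroid[1])
    ring = brain & ~tumor_mask & (d > t6) & (d <= t6 + 3.0)
    if not ring.any():
        raise ValueError("no ring pixels outside the tumor core; set t3/t4 explicitly")
    vals = eq[ring]
    t4, t3 = np.percentile(vals, [2.0, 98.0])
    t5 = float(np.percentile(eq[tumor_mask], 2.0)) if tumor_mask.any() else None
    if t5 is not None and t5 <= t3:
        # keep the band strictly below the tumor-core intensities
        t3 = min(t3, t5 - 1e-9)
    return float(t3), float(t4), t5


def segment_edema(
    I_s: np.ndarray,
    tumor_centroid: Optional[tuple],
    params: SegmentationParams,
    tumor_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Edema mask via band thresholding plus a centroid-distance test.

    Steps: equalize; keep pixels in the intensity band
    ``t4 <= p <= t3`` (and below the tumor-core floor ``t5``); keep only
    candidates at distance >= ``t6`` from the tumor centroid; dilate and
    close with ``morph_radius``.  Auto thresholds need ``tumor_mask``.
    """
    if tumor_centroid is None:
        raise ValueError("tumor centroid unavailable: run tumor segmentation first")
    I_s = np.asarray(I_s, dtype=np.float64)
    brain = I_s > 0
    eq = hist_equalize(I_s)

    t6 = params.t6
    if t6 is None:
        if tumor_mask is None or not tumor_mask.any():
            raise ValueError("t6 is auto-derived from the tumor mask; provide one")
        t6 = float(np.sqrt(tumor_mask.sum() / np.pi))

    t3, t4, t5 = params.t3, params.t4, params.t5
    if t3 is None or t4 is None:
        if tumor_mask is None or not tumor_mask.any():
            raise ValueError("auto band thresholds need the tumor mask")
        a3, a4, a5 = _auto_band(eq, brain, tumor_mask, tumor_centroid, t6)
        t3 = a3 if t3 is None else t3
        t4 = a4 if t4 is None else t4
        t5 = a5 if t5 is None else t5

    band = brain & (eq >= t4) & (eq <= t3)
    if t5 is not None:
        band &= eq < t5

    h, w = I_s.shape
    rows, cols = np.mgrid[0:h, 0:w]
    d = np.hypot(rows - tumor_centroid[0], cols - tumor_centroid[1])
    mask = band & (d >= t6)

    if params.morph_radius > 0:
        selem = morphology.disk(params.morph_radius)
        mask = morphology.dilation(mask, selem)
        mask = morphology.closing(mask, selem)
        mask &= brain
    if params.trim_mad > 0 and mask.any():
        vals = I_s[mask]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        mask &= np.abs(I_s - med) <= params.trim_mad * mad
    return mask


# ---------------------------------------------------------------------------
# orchestration


def segment_tissues(
    I_s: np.ndarray,
    params: SegmentationParams,
    seed: int = 0,
) -> TissueMasks:
    """Run all five operators in dependency order on a stripped slice.

    Tumor first (its centroid and area parameterize edema), then edema,
    CSF and the WM/GM dichotomy.  Pathological masks are subtracted
    from the healthy ones so each pixel ends up in at most one tissue.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    tumor, centroid = segment_tumor(I_s, params)
    if centroid is not None:
        edema = segment_edema(I_s, centroid, params, tumor_mask=tumor)
        edema &= ~tumor
    else:
        edema = np.zeros_like(tumor)

    csf = segment_csf(I_s, params, np.random.default_rng(seed))
    csf &= ~(tumor | edema)

    I_G, grad = gradient_map(I_s, params.gauss_sigma)
    wm, gm = segment_wm_gm(I_s, grad, params)
    abnormal = tumor | edema | csf
    wm &= ~abnormal
    gm &= ~abnormal

    return TissueMasks(
        wm=wm, gm=gm, csf=csf, tumor=tumor, edema=edema,
        tumor_centroid=centroid,
        params_used={"gauss_sigma": params.gauss_sigma,
                     "csf_threshold": params.csf_threshold,
                     "rg_tolerance": params.rg_tolerance},
    )
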