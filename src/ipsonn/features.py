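"""Seven-feature block descriptors of a segmented tissue.

The masked tissue image is tiled into non-overlapping square blocks;
blocks with enough nonzero pixels qualify, and each contributes a
7-vector: two histogram features (modal-bin fraction I and the
least-squares slope S of the histogram envelope), two statistical
features (mean M and population variance E of the nonzero pixels), and
the mean absolute coefficients of the three level-1 Haar wavelet detail
subbands (horizontal H, vertical V, diagonal D).  The tissue's feature
vector is the mean over its qualifying blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

logger = logging.getLogger(__name__)

#: Column order of the feature vector everywhere (tables, particles, nets).
FEATURE_NAMES = ("I", "S", "M", "E", "H", "V", "D")

_HIST_BINS = 32
_HIST_RANGE = (0.0, 255.0)


@dataclass(frozen=True)
class FeatureVector:
    I: float
    S: float
    M: float
    E: float
    H: float
    V: float
    D: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValueError("expected a 7-vector")
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class BlockSpec:
    """Tiling rule: square ``block_size`` (even, so the level-1 wavelet
    halves cleanly) and the minimum nonzero fraction for a block to
    qualify."""

    block_size: int = 8
    nonzero_rule: float = 0.5

    def __post_init__(self):
        if self.block_size < 2 or self.block_size % 2:
            raise ValueError("block_size must be even and >= 2")
        if not 0 < self.nonzero_rule <= 1:
            raise ValueError("nonzero_rule must be in (0, 1]")


def extract_blocks(masked_img: np.ndarray, spec: BlockSpec = BlockSpec()):
    """Tile the masked image and keep sufficiently nonzero blocks.

    Partial blocks at the right/bottom edges are dropped.  Raises if no
    block qualifies ("tissue region too small").
    """
    masked_img = np.asarray(masked_img, dtype=np.float64)
    bs = spec.block_size
    h, w = masked_img.shape
    blocks = []
    for r in range(0, h - bs + 1, bs):
        for c in range(0, w - bs + 1, bs):
            blk = masked_img[r : r + bs, c : c + bs]
            if np.count_nonzero(blk) >= spec.nonzero_rule * bs * bs:
                blocks.append(blk.copy())
    if not blocks:
        raise ValueError("tissue region too small: no block passes the nonzero rule")
    return blocks


def block_features(block: np.ndarray) -> FeatureVector:
    """Compute the 7-vector for one block.

    I, S are from a 32-bin histogram of the nonzero pixels over [0,255];
    M, E from the nonzero pixels; H, V, D from the Haar level-1 detail
    subbands of the full block (zeros included — the spatial layout
    matters for the wavelet).
    """
    block = np.asarray(block, dtype=np.float64)
    nz = block[block != 0]
    if nz.size == 0:
        raise ValueError("block has no nonzero pixels")

    M = float(nz.mean())
    E = float(nz.var())

    counts, edges = np.histogram(nz, bins=_HIST_BINS, range=_HIST_RANGE)
    I = float(counts.max() / nz.size)
    occupied = counts > 0
    if occupied.sum() >= 2:
        centers = 0.5 * (edges[:-1] + edges[1:])
        S = float(np.polyfit(centers[occupied], counts[occupied], 1)[0])
    else:
        S = 0.0

    _, (cH, cV, cD) = pywt.dwt2(block, "haar")
    H = float(np.abs(cH).mean())
    V = float(np.abs(cV).mean())
    D = float(np.abs(cD).mean())
    return FeatureVector(I=I, S=S, M=M, E=E, H=H, V=V, D=D)


def image_features(I_s: np.ndarray, masks: dict, spec: BlockSpec = BlockSpec()) -> dict:
    """Per-tissue feature vectors: mean of block vectors over kept blocks.

    ``masks`` maps tissue name -> binary mask.  A tissue whose masked
    region yields no qualifying block is omitted with a warning rather
    than failing the whole image.
    """
    I_s = np.asarray(I_s, dtype=np.float64)
    if not any(np.any(m) for m in masks.values()):
        raise ValueError("all tissue masks are empty")
    out = {}
    for tissue, mask in masks.items():
        masked = np.where(mask, I_s, 0.0)
        try:
            blocks = extract_blocks(masked, spec)
        except ValueError as exc:
            logger.warning("tissue %s skipped: %s", tissue, exc)
            continue
        vecs = np.stack([block_features(b).as_array() for b in blocks])
        out[tissue] = FeatureVector.from_array(vecs.mean(axis=0))
    return out
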