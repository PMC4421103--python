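"""Reading and writing slices, masks and label maps.

Intensities travel as 8-bit PNG/TIFF or float NIfTI; label maps as a
paletted PNG plus a JSON legend mapping palette index -> tissue name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import LABEL_NAMES

# distinct palette colors per label code
_PALETTE = {
    0: (0, 0, 0),
    1: (120, 120, 120),
    2: (0, 90, 200),
    3: (90, 200, 90),
    4: (240, 240, 240),
    5: (220, 40, 40),
    6: (240, 180, 40),
}


def save_intensity(path, img: np.ndarray) -> None:
    """Write an intensity image; format chosen by suffix (.png/.tif/.nii[.gz])."""
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.clip(img, 0, 255).astype(np.uint8))
    else:
        Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).save(path)


def load_intensity(path) -> np.ndarray:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.asarray(np.squeeze(data), dtype=np.float64)
    if name.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64)


def save_labels(path_png, labels: np.ndarray) -> None:
    """Paletted PNG plus a sidecar JSON legend (palette index -> tissue)."""
    path_png = Path(path_png)
    labels = np.asarray(labels, dtype=np.uint8)
    im = Image.fromarray(labels, mode="P")
    palette = []
    for i in range(256):
        palette.extend(_PALETTE.get(i, (0, 0, 0)))
    im.putpalette(palette)
    im.save(path_png)
    legend = {str(code): name for code, name in LABEL_NAMES.items()}
    path_png.with_suffix(".json").write_text(json.dumps(legend, indent=1, sort_keys=True))


def load_labels(path_png) -> np.ndarray:
    return np.asarray(Image.open(path_png), dtype=np.int64)


def save_mask(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127
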