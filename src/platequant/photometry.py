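"""Per-well RGB extraction and the photometric analytical signal.

The analytical signal of the assay is a linear function of the mean RGB
channels over a circular region of interest centred on each well; the
default is S = 255 − B, the blue-channel attenuation of the orange complex.
ROI membership uses the exact lattice-disc rule (x−cx)² + (y−cy)² ≤ r²,
which contains 317 pixels at r = 10 with an integer center (≈ π r² = 314).
Channel means are plain floating-point averages of the raw 8-bit values;
no gamma or white-balance correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate import PlateLayout, Role

__all__ = [
    "RGBSummary",
    "SignalDefinition",
    "disc_mask",
    "extract_well",
    "signal",
    "extract_plate",
    "read_image",
]

EXTRACTION_COLUMNS = [
    "row",
    "col",
    "role",
    "conc_pct_wv",
    "mean_R",
    "mean_G",
    "mean_B",
    "signal",
]


@dataclass(frozen=True)
class RGBSummary:
    mean_R: float
    mean_G: float
    mean_B: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("RGBSummary needs at least one pixel")
        for name in ("mean_R", "mean_G", "mean_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")


@dataclass(frozen=True)
class SignalDefinition:
    """S = constant + cR·mean_R + cG·mean_G + cB·mean_B."""

    constant: float = 255.0
    coefficients: tuple[float, float, float] = (0.0, 0.0, -1.0)

    @classmethod
    def from_name(cls, name: str) -> "SignalDefinition":
        """Parse the common named signals; default is '255-B'."""
        table = {
            "255-B": cls(255.0, (0.0, 0.0, -1.0)),
            "255-G": cls(255.0, (0.0, -1.0, 0.0)),
            "255-R": cls(255.0, (-1.0, 0.0, 0.0)),
            "B": cls(0.0, (0.0, 0.0, 1.0)),
        }
        if name not in table:
            raise ValueError(f"unknown signal {name!r}; known: {sorted(table)}")
        return table[name]


def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) uint8 RGB array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def disc_mask(
    center: tuple[float, float], radius: float, image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixels with (x−cx)² + (y−cy)² ≤ r², clipped to the image.

    ``center`` is (x, y) in pixel coordinates (origin top-left, y down);
    returns (rows, cols) index arrays in deterministic row-major order.
    """
    cx, cy = center
    h, w = image_shape[:2]
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center ({cx},{cy}) outside {h}x{w} image")
    y0 = max(0, int(np.floor(cy - radius)))
    y1 = min(h - 1, int(np.ceil(cy + radius)))
    x0 = max(0, int(np.floor(cx - radius)))
    x1 = min(w - 1, int(np.ceil(cx + radius)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return yy[inside], xx[inside]


def extract_well(image: np.ndarray, roi: tuple[np.ndarray, np.ndarray]) -> RGBSummary:
    """Channel means over exactly the ROI pixels."""
    rows, cols = roi
    if len(rows) == 0:
        raise ValueError("empty ROI")
    pixels = image[rows, cols].astype(np.float64)
    means = pixels.mean(axis=0)
    return RGBSummary(float(means[0]), float(means[1]), float(means[2]), len(rows))


def signal(summary: RGBSummary, defn: SignalDefinition = SignalDefinition()) -> float:
    """Evaluate the analytical signal on a well's RGB summary."""
    cr, cg, cb = defn.coefficients
    return (
        defn.constant
        + cr * summary.mean_R
        + cg * summary.mean_G
        + cb * summary.mean_B
    )


def extract_plate(
    image: np.ndarray,
    layout: PlateLayout,
    defn: SignalDefinition = SignalDefinition(),
) -> pd.DataFrame:
    """Extract every non-empty well of a plate image into a tidy table.

    Returns one row per well in row-major order with columns
    (row, col, role, conc_pct_wv, mean_R, mean_G, mean_B, signal).
    Geometry errors carry the offending well's identity.
    """
    records = []
    for well in layout.active_wells():
        center = layout.center_of(well.row, well.col)
        try:
            roi = disc_mask(center, layout.roi_radius, image.shape[:2])
            summ = extract_well(image, roi)
        except ValueError as exc:
            raise ValueError(f"well ({well.row},{well.col}): {exc}") from exc
        records.append(
            {
                "row": well.row,
                "col": well.col,
                "role": well.role.value,
                "conc_pct_wv": well.conc,
                "mean_R": summ.mean_R,
                "mean_G": summ.mean_G,
                "mean_B": summ.mean_B,
                "signal": signal(summ, defn),
            }
        )
    return pd.DataFrame(records, columns=EXTRACTION_COLUMNS)
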