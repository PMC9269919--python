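"""Trichrome histology fibrosis quantification.

Masson's trichrome renders collagen (fibrosis) blue and myocytes red.  The
quantifier converts an RGB slide to hue/saturation/value, excludes the
near-white background (low saturation or very high value), and classifies
the remaining tissue pixels by hue interval: blue/green collagen versus
red/magenta tissue.  Percent fibrosis is the blue share of tissue pixels.

The hue and background thresholds are fixed, configurable defaults pinned by
ground-truth tests on synthetic slides; no per-sample threshold optimisation
is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv

from .core import ValidationError
from .fibrosis import GroupSummary, group_summary

#: Hue interval (degrees) classified as blue/green collagen.
DEFAULT_HUE_BLUE = (90.0, 270.0)
DEFAULT_BACKGROUND_SATURATION = 0.15
DEFAULT_BACKGROUND_VALUE = 0.95


@dataclass
class TrichromeClassification:
    n_fibrotic: int
    n_nonfibrotic: int
    n_background: int

    @property
    def n_tissue(self) -> int:
        return self.n_fibrotic + self.n_nonfibrotic

    @property
    def percent_fibrosis(self) -> float:
        return 100.0 * self.n_fibrotic / self.n_tissue


def percent_fibrosis_trichrome(
    image: np.ndarray,
    hue_blue: tuple[float, float] = DEFAULT_HUE_BLUE,
    background_saturation: float = DEFAULT_BACKGROUND_SATURATION,
    background_value: float = DEFAULT_BACKGROUND_VALUE,
) -> TrichromeClassification:
    """Classify an RGB trichrome slide into fibrotic / tissue / background.

    ``image`` is (H, W, 3) uint8 or float in [0, 1].  A pixel is background
    when saturation < ``background_saturation`` or value >
    ``background_value``; remaining pixels are fibrotic when their hue (in
    degrees) falls in the half-open ``hue_blue`` interval, non-fibrotic
    otherwise.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) RGB image")
    lo, hi = hue_blue
    if not (0.0 <= lo < hi <= 360.0):
        raise ValidationError(f"invalid hue interval {hue_blue}")
    hsv = rgb2hsv(image)
    hue_deg = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]
    background = (sat < background_saturation) | (val > background_value)
    tissue = ~background
    if not tissue.any():
        raise ValidationError("no tissue pixels after background exclusion")
    blue = tissue & (hue_deg >= lo) & (hue_deg < hi)
    n_blue = int(blue.sum())
    n_tissue = int(tissue.sum())
    return TrichromeClassification(
        n_fibrotic=n_blue,
        n_nonfibrotic=n_tissue - n_blue,
        n_background=int(background.sum()),
    )


def load_slide(path) -> np.ndarray:
    """Load a TIFF/PNG slide as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def histology_summaries(
    per_slice: pd.DataFrame,
) -> tuple[pd.DataFrame, GroupSummary]:
    """Per-animal averages and a group summary of slice-wise %fibrosis.

    ``per_slice`` needs columns ``animal`` and ``percent_fibrosis``; missing
    slices are simply absent rows.  Returns a per-animal table (columns
    ``animal``, ``n_slices``, ``mean_percent_fibrosis``) and the
    mean/SD/median/IQR group summary over the per-animal averages.
    """
    if len(per_slice) == 0:
        raise ValidationError("empty histology table")
    for col in ("animal", "percent_fibrosis"):
        if col not in per_slice.columns:
            raise ValidationError(f"missing column {col!r}")
    values = pd.to_numeric(per_slice["percent_fibrosis"])
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValidationError("percent_fibrosis values must be finite")
    grouped = (
        per_slice.assign(percent_fibrosis=values)
        .groupby("animal", sort=True)["percent_fibrosis"]
        .agg(n_slices="count", mean_percent_fibrosis="mean")
        .reset_index()
    )
    return grouped, group_summary(grouped["mean_percent_fibrosis"])
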