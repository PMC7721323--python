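"""Per-class color channel means and chroma indices.

Channel means are arithmetic means of the red, green and blue intensities of
the original image over exactly the pixels of one mask class.  The five
chroma indices are then computed from these per-region means (not averaged
per-pixel indices):

.. math::

    \\text{chroma\\_base} = (N_b + N_r) / N_g \\\\
    \\text{chroma\\_difference} = (N_b + N_r)/2 - N_g \\\\
    \\text{chroma\\_ratio} = N_g / ((N_b + N_r)/2) \\\\
    \\text{blue\\_green\\_ratio} = N_b / N_g \\\\
    \\text{green\\_strength} = N_g / (N_r + N_g + N_b)

The chroma ratio falls as red/blue pigmentation (anthocyanin) rises, and
green strength is the normalized weight of the green channel.  Wherever a
denominator is zero — or the region is empty — the index is emitted as
missing (NaN) rather than infinity, keeping downstream tables finite.
Note the algebraic identity chroma_ratio * chroma_base = 2 whenever both
are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .schemes import PLANT_REGION, SegmentationMask

CHANNEL_TRAITS: tuple[str, ...] = ("n_red", "n_green", "n_blue")
CHROMA_TRAITS: tuple[str, ...] = (
    "chroma_base",
    "chroma_difference",
    "chroma_ratio",
    "blue_green_ratio",
    "green_strength",
)


@dataclass(frozen=True)
class ChannelMeans:
    n_red: float
    n_green: float
    n_blue: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ChromaIndices:
    chroma_base: float
    chroma_difference: float
    chroma_ratio: float
    blue_green_ratio: float
    green_strength: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def channel_means(
    image: np.ndarray, mask: SegmentationMask, class_name: str
) -> ChannelMeans:
    """Mean R, G, B intensities over the pixels of one class.

    ``image`` is an 8-bit RGB array of shape (H, W, 3) sharing the mask's
    grid.  An empty class yields NaN means.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image grid {image.shape[:2]} does not match mask grid {mask.shape}"
        )
    if class_name != PLANT_REGION:
        mask.scheme.label_of(class_name)
    pixels = mask.class_pixels(class_name)
    if not pixels.any():
        return ChannelMeans(math.nan, math.nan, math.nan)
    region = image[pixels].astype(np.float64)
    r, g, b = region.mean(axis=0)
    return ChannelMeans(n_red=float(r), n_green=float(g), n_blue=float(b))


def _ratio(num: float, den: float) -> float:
    """num/den with zero or missing denominators mapped to NaN."""
    if math.isnan(num) or math.isnan(den) or den == 0:
        return math.nan
    return num / den


def chroma_indices(means: ChannelMeans) -> ChromaIndices:
    """The five chroma indices from per-region channel means."""
    r, g, b = means.n_red, means.n_green, means.n_blue
    if any(math.isnan(v) for v in (r, g, b)):
        return ChromaIndices(*([math.nan] * 5))
    return ChromaIndices(
        chroma_base=_ratio(b + r, g),
        chroma_difference=(b + r) / 2.0 - g,
        chroma_ratio=_ratio(g, (b + r) / 2.0),
        blue_green_ratio=_ratio(b, g),
        green_strength=_ratio(g, r + g + b),
    )
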