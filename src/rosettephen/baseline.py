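"""Classical color-based segmentation baseline and multi-scale inference.

The baseline segments plant from background by thresholding in CIELAB space:
a pixel is plant iff its a* (green-magenta axis) is at most ``a_max`` and its
L* (lightness) at least ``l_min``.  Green tissue sits far down the negative
a* axis, so this works well for healthy rosettes and fails — by design of the
color model, not by accident — on anthocyanin-rich (magenta, positive a*)
plants.  The raw threshold mask is cleaned by keeping the largest 8-connected
foreground component and filling its holes.

``multiscale_predict`` wraps any pluggable pixel classifier (a callable
mapping an RGB image to a per-class :class:`ScoreMap`): the image is resized
to each scale factor, classified, the score maps are resized back to native
resolution, averaged per pixel, and the argmax over classes yields the mask.
Neural-network inference is deliberately not implemented; the classifier
callable is the extension point for external models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab
from skimage.measure import label as cc_label
from skimage.transform import resize

from .schemes import SCHEME_A, ClassScheme, SegmentationMask

#: Conventional multi-scale factor set for encoder-decoder segmentation models.
DEFAULT_SCALES: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75)

#: Default CIELAB thresholds separating green tissue from soil-like
#: backgrounds.  a_max is placed just below the achromatic axis: green leaf
#: pixels sit far down the negative a* axis (their distribution's upper tail
#: reaches about -5), while soil, gray and blue-mesh backgrounds stay near or
#: above 0.  A stricter cut loses whole yellowish-green leaves, which costs
#: far more IoU than the scattered soil speckles this setting admits (those
#: are removed by the largest-component cleanup).
DEFAULT_A_MAX = -3.0
DEFAULT_L_MIN = 15.0


@dataclass
class ScoreMap:
    """Per-class scores on an image grid; nonnegative, summing to 1 per pixel."""

    scores: np.ndarray  # (H, W, n_classes)
    scheme: ClassScheme

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.ndim != 3 or scores.shape[2] != self.scheme.n_classes:
            raise ValueError(
                f"expected (H, W, {self.scheme.n_classes}) scores, "
                f"got shape {scores.shape}"
            )
        if (scores < 0).any():
            raise ValueError("scores must be nonnegative")
        if not np.allclose(scores.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("scores must sum to 1 per pixel")
        self.scores = scores

    def argmax_mask(self) -> SegmentationMask:
        return SegmentationMask(
            np.argmax(self.scores, axis=2).astype(np.int64), self.scheme
        )


PixelClassifier = Callable[[np.ndarray], ScoreMap]


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Standard sRGB (D65) to CIELAB conversion.

    Returns an (H, W, 3) float array with channels L* in [0, 100], a*
    (negative green / positive magenta) and b*.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return rgb2lab(image.astype(np.uint8))


def threshold_segment(
    image: np.ndarray,
    a_max: float = DEFAULT_A_MAX,
    l_min: float = DEFAULT_L_MIN,
    clean: bool = True,
) -> SegmentationMask:
    """Lab-threshold plant/background segmentation (scheme A).

    Plant iff a* <= ``a_max`` and L* >= ``l_min``.  With ``clean`` (default)
    only the largest 8-connected foreground component is kept and its holes
    are filled — the usual cleanup of color-pipeline output.  Deterministic.
    """
    lab = rgb_to_lab(image)
    fg = (lab[..., 1] <= a_max) & (lab[..., 0] >= l_min)
    if clean and fg.any():
        comps, n = cc_label(fg, connectivity=2, return_num=True)
        if n > 1:
            sizes = np.bincount(comps.ravel())
            sizes[0] = 0
            fg = comps == sizes.argmax()
        fg = ndi.binary_fill_holes(fg)
    return SegmentationMask(fg.astype(np.int64), SCHEME_A)


def lab_threshold_classifier(
    a_max: float = DEFAULT_A_MAX, l_min: float = DEFAULT_L_MIN
) -> PixelClassifier:
    """The thresholding rule as a hard-scored pixel classifier (scheme A)."""

    def classify(image: np.ndarray) -> ScoreMap:
        fg = threshold_segment(image, a_max=a_max, l_min=l_min, clean=False)
        plant = fg.labels.astype(np.float64)
        return ScoreMap(np.stack([1.0 - plant, plant], axis=2), SCHEME_A)

    return classify


def multiscale_predict(
    classifier: PixelClassifier,
    image: np.ndarray,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> SegmentationMask:
    """Average classifier scores over rescaled copies of the image.

    The image is bilinearly resized to each scale factor, classified, and
    the per-class scores are bilinearly resized back to the native grid;
    the per-pixel mean score over scales is renormalized and its argmax
    taken as the predicted label.
    """
    if len(scales) == 0:
        raise ValueError("scales must be nonempty")
    if any(s <= 0 for s in scales):
        raise ValueError("scale factors must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    total: np.ndarray | None = None
    scheme: ClassScheme | None = None
    for s in scales:
        hs, ws = max(1, round(h * s)), max(1, round(w * s))
        if (hs, ws) == (h, w):
            scaled = image
        else:
            scaled = resize(
                image.astype(np.float64),
                (hs, ws),
                order=1,
                anti_aliasing=s < 1.0,
                preserve_range=True,
            )
            scaled = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
        smap = classifier(scaled)
        scheme = smap.scheme
        scores = smap.scores
        if scores.shape[:2] != (h, w):
            scores = resize(scores, (h, w), order=1, preserve_range=True)
        total = scores if total is None else total + scores
    assert total is not None and scheme is not None
    mean = total / len(scales)
    # bilinear resampling of a simplex-valued field preserves the per-pixel
    # sum up to float error; renormalize to keep the ScoreMap contract exact
    mean = mean / mean.sum(axis=2, keepdims=True)
    return ScoreMap(mean, scheme).argmax_mask()
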