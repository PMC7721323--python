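"""Per-class region morphometrics.

All pixels carrying a given class label are treated as one region, even when
disconnected: a rosette's leaves may separate in the mask, but traits such as
the convex hull or the bounding-box extent are meaningful only for the whole
plant.  Eleven traits are computed per class:

``area``, ``filled_area``, ``convex_area``, ``equivalent_diameter``,
``major_axis_length``, ``minor_axis_length``, ``perimeter``, ``eccentricity``,
``extent``, ``solidity``, ``aspect_ratio``.

Definitions follow the scikit-image ``regionprops`` conventions: the ellipse
axes are those of the ellipse with the same normalized second central moments
as the pixel set (major = 4*sqrt(lambda1), minor = 4*sqrt(lambda2));
``equivalent_diameter`` is the diameter of the circle with the same pixel
area; ``solidity`` = area / convex hull area; ``extent`` = area /
bounding-box area.  The convex hull is taken over pixel centers and
``convex_area`` counts pixel centers on or inside it.  An absent class yields
area 0 with every other field missing (NaN), which keeps "class not present"
distinguishable from degenerate geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image

from .schemes import PLANT_REGION, SegmentationMask

MORPHOMETRIC_TRAITS: tuple[str, ...] = (
    "area",
    "filled_area",
    "convex_area",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "eccentricity",
    "extent",
    "solidity",
    "aspect_ratio",
)


@dataclass(frozen=True)
class MorphometricTraits:
    area: float
    filled_area: float
    convex_area: float
    equivalent_diameter: float
    major_axis_length: float
    minor_axis_length: float
    perimeter: float
    eccentricity: float
    extent: float
    solidity: float
    aspect_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_EMPTY = MorphometricTraits(0.0, *([math.nan] * 10))


def compute_morphometrics(
    mask: SegmentationMask, class_name: str
) -> MorphometricTraits:
    """Morphometric traits of one class (or ``plant_region``) of a mask.

    Raises ``KeyError`` for a class name unknown to the mask's scheme.
    """
    if class_name != PLANT_REGION:
        mask.scheme.label_of(class_name)  # validate early
    pixels = mask.class_pixels(class_name)
    area = int(pixels.sum())
    if area == 0:
        return _EMPTY

    props = regionprops(pixels.astype(np.uint8))[0]
    filled_area = int(ndi.binary_fill_holes(pixels).sum())
    with warnings.catch_warnings():
        # qhull cannot build a 2-D hull from collinear pixel centers; their
        # hull is a segment holding exactly the pixel centers, so the count
        # falls back to the area
        warnings.simplefilter("ignore")
        hull = convex_hull_image(pixels, offset_coordinates=False)
    convex_area = max(int(hull.sum()), area)

    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    aspect_ratio = major / minor if minor > 0 else math.nan
    return MorphometricTraits(
        area=float(area),
        filled_area=float(filled_area),
        convex_area=float(convex_area),
        equivalent_diameter=math.sqrt(4.0 * area / math.pi),
        major_axis_length=major,
        minor_axis_length=minor,
        perimeter=float(props.perimeter),
        eccentricity=float(props.eccentricity),
        extent=float(props.extent),
        solidity=area / convex_area,
        aspect_ratio=aspect_ratio,
    )
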