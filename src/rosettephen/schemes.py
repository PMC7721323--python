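"""Class schemes and segmentation masks.

Three segmentation vocabularies are supported, mirroring the one-, two- and
three-class leaf-state models used in top-view rosette phenotyping:

* scheme ``A`` — background vs. plant (``class_norm``)
* scheme ``B`` — background, non-senescent (``class_norm``), senescent
  (``class_senesc``)
* scheme ``C`` — background, green (``class_norm``), anthocyanin-rich
  (``class_antho``), senescent (``class_senesc``)

Integer labels are consecutive from 0 (background) in the listed class order,
so scheme C encodes background=0, class_norm=1, class_antho=2, class_senesc=3.
``plant_region`` is the compound "living plant" class: the union of
``class_norm`` and ``class_antho`` (for schemes A and B it coincides with
``class_norm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

BACKGROUND = "background"
CLASS_NORM = "class_norm"
CLASS_ANTHO = "class_antho"
CLASS_SENESC = "class_senesc"
PLANT_REGION = "plant_region"


class MaskValidationError(ValueError):
    """Raised when a label image does not conform to its class scheme."""


@dataclass(frozen=True)
class ClassScheme:
    """An ordered segmentation vocabulary with fixed integer encoding."""

    name: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.classes[0] != BACKGROUND:
            raise ValueError("background must be the first class (label 0)")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def labels(self) -> range:
        return range(len(self.classes))

    @property
    def foreground_classes(self) -> tuple[str, ...]:
        return self.classes[1:]

    @property
    def plant_region_classes(self) -> tuple[str, ...]:
        """Constituents of the compound plant_region class."""
        return tuple(
            c for c in (CLASS_NORM, CLASS_ANTHO) if c in self.classes
        )

    def label_of(self, class_name: str) -> int:
        try:
            return self.classes.index(class_name)
        except ValueError:
            raise KeyError(
                f"class {class_name!r} not in scheme {self.name}"
            ) from None

    def __contains__(self, class_name: str) -> bool:
        return class_name in self.classes


SCHEME_A = ClassScheme("A", (BACKGROUND, CLASS_NORM))
SCHEME_B = ClassScheme("B", (BACKGROUND, CLASS_NORM, CLASS_SENESC))
SCHEME_C = ClassScheme("C", (BACKGROUND, CLASS_NORM, CLASS_ANTHO, CLASS_SENESC))
SCHEMES: dict[str, ClassScheme] = {"A": SCHEME_A, "B": SCHEME_B, "C": SCHEME_C}

# Merge rules for coarsening a fine vocabulary into a coarser one.  The
# anthocyanin class folds into class_norm (both are living tissue); the
# one-class vocabulary A carries no senescence concept, so senescent pixels
# fall back to background there.
_COARSEN_RULES: dict[tuple[str, str], dict[str, str]] = {
    ("C", "B"): {CLASS_ANTHO: CLASS_NORM},
    ("C", "A"): {CLASS_ANTHO: CLASS_NORM, CLASS_SENESC: BACKGROUND},
    ("B", "A"): {CLASS_SENESC: BACKGROUND},
}


@dataclass
class SegmentationMask:
    """Per-pixel integer labels over an image grid, tied to a scheme.

    Labels are validated on construction: every value must be a label of
    ``scheme`` (classes are mutually exclusive per pixel).
    """

    labels: np.ndarray
    scheme: ClassScheme = field(default=SCHEME_C)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise MaskValidationError(
                f"mask must be a 2-D label grid, got shape {labels.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(np.int64)):
                raise MaskValidationError("mask labels must be integers")
            labels = labels.astype(np.int64)
        bad = np.setdiff1d(np.unique(labels), np.arange(self.scheme.n_classes))
        if bad.size:
            raise MaskValidationError(
                f"label {bad[0]} is not valid for scheme {self.scheme.name} "
                f"(valid labels: 0..{self.scheme.n_classes - 1})"
            )
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_pixels(self, class_name: str) -> np.ndarray:
        """Boolean membership grid for a class or for ``plant_region``."""
        if class_name == PLANT_REGION:
            out = np.zeros(self.shape, dtype=bool)
            for c in self.scheme.plant_region_classes:
                out |= self.labels == self.scheme.label_of(c)
            return out
        return self.labels == self.scheme.label_of(class_name)

    def class_counts(self) -> dict[str, int]:
        """Pixel count per scheme class (background included)."""
        tallies = np.bincount(self.labels.ravel(), minlength=self.scheme.n_classes)
        return {c: int(tallies[i]) for i, c in enumerate(self.scheme.classes)}


def load_mask(path, scheme: ClassScheme) -> SegmentationMask:
    """Read a single-channel integer PNG and validate it against ``scheme``."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise MaskValidationError(
            f"{path}: mask must be single-channel, got shape {arr.shape}"
        )
    return SegmentationMask(arr.astype(np.int64), scheme)


def save_mask(mask: SegmentationMask, path) -> None:
    """Write a mask as 8-bit single-channel PNG."""
    iio.imwrite(path, mask.labels.astype(np.uint8))


def coarsen_mask(mask: SegmentationMask, target: ClassScheme) -> SegmentationMask:
    """Merge a fine-scheme mask into a strictly coarser vocabulary.

    Supported directions: C->B, C->A, B->A.  Pixel counts are conserved:
    each source pixel maps to exactly one target label.  Coarsening to the
    mask's own scheme is the identity; refinement raises ``ValueError``.
    """
    if target.name == mask.scheme.name:
        return SegmentationMask(mask.labels.copy(), mask.scheme)
    rules = _COARSEN_RULES.get((mask.scheme.name, target.name))
    if rules is None:
        raise ValueError(
            f"unsupported coarsening direction {mask.scheme.name}->{target.name}"
        )
    lut = np.empty(mask.scheme.n_classes, dtype=np.int64)
    for i, cls in enumerate(mask.scheme.classes):
        lut[i] = target.label_of(rules.get(cls, cls))
    return SegmentationMask(lut[mask.labels], target)
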