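"""Synthetic single-rosette top-view scenes with exact ground truth.

Scenes emulate the data a top-view phenotyping camera produces for one
potted rosette: elliptical leaves placed radially around the image center,
each leaf in one of three states — green (``class_norm``), anthocyanin-rich
(``class_antho``) or senescent (``class_senesc``) — over a configurable
background (solid gray, blue plastic mesh, bare soil, or soil with green
algae speckle).  Leaves are drawn back to front and the ground-truth mask is
rasterized from the same geometry in the same order, so the mask labels
exactly the visible pixels.  Every scene is fully determined by
``(params.seed, scene index)``, independent of generation order.

The generator supports trend studies: ``generate_time_series`` produces
scenes of increasing age with leaf count and senescent-state probability
rising monotonically, mimicking the progressive senescence a long-running
growth experiment records.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse

from .schemes import (
    CLASS_ANTHO,
    CLASS_NORM,
    CLASS_SENESC,
    SCHEME_C,
    SegmentationMask,
    save_mask,
)

BACKGROUND_KINDS = ("solid", "blue_mesh", "soil", "soil_with_algae")

#: Fixture palette for the three leaf states: plausible green / purple / brown
#: separations on an 8-bit scale (convention of this package, not measurements).
STATE_COLORS: dict[str, tuple[float, float, float]] = {
    CLASS_NORM: (45.0, 110.0, 40.0),
    CLASS_ANTHO: (95.0, 40.0, 85.0),
    CLASS_SENESC: (150.0, 120.0, 60.0),
}

_STATE_ORDER = (CLASS_NORM, CLASS_ANTHO, CLASS_SENESC)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic rosette scene.

    Leaf length/width are (mean, sd) in pixels; ``state_probabilities`` is
    the per-leaf (p_norm, p_antho, p_senesc) triple; ``color_spread`` the
    per-channel sd of the leaf color around its state mean; ``illumination``
    a global intensity scale factor.  ``seed`` plus a scene index fully
    determine the scene.
    """

    size: tuple[int, int] = (256, 256)
    leaf_count: int = 8
    leaf_length: tuple[float, float] = (48.0, 10.0)
    leaf_width: tuple[float, float] = (18.0, 4.0)
    angle_jitter: float = 0.15
    state_probabilities: tuple[float, float, float] = (1.0, 0.0, 0.0)
    state_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(STATE_COLORS)
    )
    color_spread: float = 15.0
    background: str = "soil"
    illumination: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaf_count < 0:
            raise ValueError("leaf_count must be nonnegative")
        if self.leaf_length[0] <= 0 or self.leaf_width[0] <= 0:
            raise ValueError("leaf dimensions must be positive")
        p = self.state_probabilities
        if len(p) != 3 or any(v < 0 for v in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("state probabilities must be nonnegative and sum to 1")
        if self.background not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.background!r}")
        if self.illumination <= 0:
            raise ValueError("illumination must be positive")


@dataclass
class SyntheticScene:
    """A rendered scene with its exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: SegmentationMask  # scheme C
    class_counts: dict[str, int]
    true_colors: dict[str, tuple[float, float, float]]
    params: SceneParams
    index: int


def _render_background(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.size
    img = np.empty((h, w, 3), dtype=np.float64)
    if params.background == "solid":
        img[:] = (70.0, 70.0, 70.0)
    elif params.background == "blue_mesh":
        img[:] = (50.0, 50.0, 55.0)
        # periodic grid of blue plastic lines, 2 px wide every 16 px
        rows = (np.arange(h) % 16) < 2
        cols = (np.arange(w) % 16) < 2
        img[rows, :] = (40.0, 60.0, 150.0)
        img[:, cols] = (40.0, 60.0, 150.0)
    else:  # soil variants: brown base with per-pixel grain
        img[:] = (90.0, 70.0, 50.0)
        img += rng.normal(0.0, 8.0, size=(h, w, 3))
        if params.background == "soil_with_algae":
            # sparse green algae dots on the soil surface
            n_dots = max(1, int(0.001 * h * w))
            rr = rng.integers(0, h, size=n_dots)
            cc = rng.integers(0, w, size=n_dots)
            for r, c in zip(rr, cc):
                dr, dc = ellipse(r, c, 2, 2, shape=(h, w))
                img[dr, dc] = (60.0, 110.0, 50.0)
    return img


def generate_rosette(params: SceneParams, index: int = 0) -> SyntheticScene:
    """Render one rosette scene; deterministic under (params.seed, index)."""
    rng = np.random.default_rng([params.seed, index])
    h, w = params.size
    image = _render_background(params, rng)
    labels = np.zeros((h, w), dtype=np.int64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    for leaf in range(params.leaf_count):
        angle = 2.0 * math.pi * leaf / params.leaf_count + rng.normal(
            0.0, params.angle_jitter
        )
        length = max(4.0, rng.normal(*params.leaf_length))
        width = max(2.0, rng.normal(*params.leaf_width))
        state = _STATE_ORDER[rng.choice(3, p=params.state_probabilities)]
        color = np.clip(
            rng.normal(params.state_colors[state], params.color_spread), 0, 255
        )
        # leaf base at the rosette center, tip pointing outward; geometry
        # outside the frame is clipped, not an error
        r0 = cy - (length / 2.0) * math.cos(angle)
        c0 = cx + (length / 2.0) * math.sin(angle)
        rr, cc = ellipse(
            r0, c0, length / 2.0, width / 2.0, shape=(h, w), rotation=-angle
        )
        image[rr, cc] = color
        labels[rr, cc] = SCHEME_C.label_of(state)

    image = np.clip(np.rint(image * params.illumination), 0, 255).astype(np.uint8)
    truth = SegmentationMask(labels, SCHEME_C)
    return SyntheticScene(
        image=image,
        truth=truth,
        class_counts=truth.class_counts(),
        true_colors={s: params.state_colors[s] for s in _STATE_ORDER},
        params=params,
        index=index,
    )


def generate_time_series(
    base: SceneParams,
    ages: Sequence[float],
    senescence_rate: Callable[[float], tuple[float, float, float]],
    replicate: int = 0,
) -> list[SyntheticScene]:
    """Scenes of increasing age with growing leaf count and senescence.

    ``senescence_rate`` maps an age to a (p_norm, p_antho, p_senesc) triple;
    it should be monotone in the senescent component for trend studies.  One
    leaf is added per age step on top of ``base.leaf_count``.  Scene streams
    are indexed by (replicate, age position), so replicate series are
    reproducible independently of each other.
    """
    ages = list(ages)
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("ages must be strictly increasing")
    scenes = []
    for i, age in enumerate(ages):
        probs = tuple(float(p) for p in senescence_rate(age))
        params = replace(
            base,
            leaf_count=base.leaf_count + i,
            state_probabilities=probs,  # validated by SceneParams
        )
        scenes.append(generate_rosette(params, index=replicate * 100003 + i))
    return scenes


PRESETS: dict[str, dict] = {
    "green": {"state_probabilities": (1.0, 0.0, 0.0)},
    "mixed": {"state_probabilities": (0.5, 0.3, 0.2)},
    "senescing": {"state_probabilities": (0.3, 0.2, 0.5), "leaf_count": 12},
}


def write_dataset(
    outdir,
    n: int,
    seed: int = 0,
    preset: str = "green",
    size: tuple[int, int] = (256, 256),
    background: str = "soil",
) -> Path:
    """Write ``n`` scenes as images/, masks/ and a truth.csv summary."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    if preset == "timeseries":
        scenes = generate_time_series(
            SceneParams(size=size, background=background, seed=seed, leaf_count=6),
            ages=list(range(n)),
            senescence_rate=lambda age: (
                max(0.0, 1.0 - 0.08 * age - 0.05),
                0.05,
                min(1.0, 0.08 * age),
            ),
        )
    else:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        params = SceneParams(
            size=size, background=background, seed=seed, **PRESETS[preset]
        )
        scenes = [generate_rosette(params, index=i) for i in range(n)]

    truth_path = outdir / "truth.csv"
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_id", "background_px", "norm_px", "antho_px", "senesc_px"]
        )
        for i, scene in enumerate(scenes):
            image_id = f"scene_{i:04d}"
            iio.imwrite(outdir / "images" / f"{image_id}.png", scene.image)
            save_mask(scene.truth, outdir / "masks" / f"{image_id}.png")
            c = scene.class_counts
            writer.writerow(
                [
                    image_id,
                    c["background"],
                    c[CLASS_NORM],
                    c[CLASS_ANTHO],
                    c[CLASS_SENESC],
                ]
            )
    return truth_path
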