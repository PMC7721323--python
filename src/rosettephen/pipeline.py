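"""Scatter-gather trait extraction: images + masks -> one results table.

Inputs are scattered into fixed-size batches (deterministic lexicographic
order), each image is segmented — either by pairing it with an externally
provided mask of the same file stem or by the Lab-threshold baseline — and
per-class traits are extracted.  Each image contributes one row: for every
foreground class plus the compound ``plant_region``, 11 morphometric traits,
3 channel means and 5 chroma indices (19 traits per class block), plus two
whole-image traits (``total_area``: all non-background pixels, and
``background_area``).  Scheme C therefore yields 4 x 19 + 2 = 78 trait
columns besides the image identifier.  The gather step restores the original
input order, so batch size affects scheduling only and two runs on identical
inputs produce byte-identical CSV output.

Diagnostics per image: a class-color overlay, the color-coded mask, the
background-subtracted crop of the living plant region, and a convex-hull
outline panel.
"""

from __future__ import annotations

import json
import logging
import math
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from . import evaluation
from .baseline import (
    DEFAULT_A_MAX,
    DEFAULT_L_MIN,
    DEFAULT_SCALES,
    lab_threshold_classifier,
    multiscale_predict,
    threshold_segment,
)
from .color import CHANNEL_TRAITS, CHROMA_TRAITS, channel_means, chroma_indices
from .morphometrics import MORPHOMETRIC_TRAITS, compute_morphometrics
from .schemes import (
    CLASS_ANTHO,
    CLASS_NORM,
    CLASS_SENESC,
    PLANT_REGION,
    ClassScheme,
    SegmentationMask,
    load_mask,
)

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")

#: Diagnostic palette: green / magenta / gold for the three leaf states.
CLASS_PALETTE: dict[str, tuple[int, int, int]] = {
    CLASS_NORM: (0, 170, 0),
    CLASS_ANTHO: (200, 0, 200),
    CLASS_SENESC: (218, 165, 32),
}
OVERLAY_ALPHA = 0.5

REGION_TRAITS: tuple[str, ...] = (
    MORPHOMETRIC_TRAITS + CHANNEL_TRAITS + CHROMA_TRAITS
)


class PipelineError(RuntimeError):
    """Raised when a strict run encounters per-image failures."""


def region_blocks(scheme: ClassScheme) -> tuple[str, ...]:
    """The per-class trait blocks of a results row, in column order."""
    return scheme.foreground_classes + (PLANT_REGION,)


def trait_columns(scheme: ClassScheme) -> list[str]:
    """Results-table trait columns for a scheme (identifier excluded)."""
    cols = [
        f"{block}_{trait}"
        for block in region_blocks(scheme)
        for trait in REGION_TRAITS
    ]
    return cols + ["total_area", "background_area"]


@dataclass(frozen=True)
class BatchPlan:
    """Input paths split into equally sized batches, order-preserving."""

    batches: tuple[tuple[Path, ...], ...]
    batch_size: int

    @property
    def n_images(self) -> int:
        return sum(len(b) for b in self.batches)


def scatter(paths, batch_size: int) -> BatchPlan:
    """Split inputs into ceil(N / batch_size) lexicographically ordered batches."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    ordered = sorted(Path(p) for p in paths)
    if not ordered:
        raise ValueError("no input images found")
    batches = tuple(
        tuple(ordered[i : i + batch_size])
        for i in range(0, len(ordered), batch_size)
    )
    return BatchPlan(batches=batches, batch_size=batch_size)


def process_image(
    image: np.ndarray, mask: SegmentationMask, image_id: str = ""
) -> dict:
    """One results-table row: all per-class traits plus whole-image areas."""
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image grid {image.shape[:2]} does not match mask grid {mask.shape}"
        )
    row: dict = {"image_id": image_id}
    for block in region_blocks(mask.scheme):
        morpho = compute_morphometrics(mask, block)
        means = channel_means(image, mask, block)
        chroma = chroma_indices(means)
        for trait, value in {
            **morpho.as_dict(),
            **means.as_dict(),
            **chroma.as_dict(),
        }.items():
            row[f"{block}_{trait}"] = value
    counts = mask.class_counts()
    background_area = counts["background"]
    row["total_area"] = float(mask.labels.size - background_area)
    row["background_area"] = float(background_area)
    return row


def gather(batch_results, scheme: ClassScheme) -> pd.DataFrame:
    """Merge per-batch row lists into one table in original input order."""
    rows = [row for batch in batch_results for row in batch]
    ids = [row["image_id"] for row in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate image_id(s): {', '.join(dupes)}")
    columns = ["image_id"] + trait_columns(scheme)
    return pd.DataFrame(rows, columns=columns)


def write_results(table: pd.DataFrame, path) -> None:
    """Write the results table as UTF-8 CSV; missing values become empty fields."""
    table.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def render_diagnostics(
    image: np.ndarray, mask: SegmentationMask, outdir, image_id: str
) -> dict[str, Path]:
    """Write the four diagnostic panels for one image; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask grids differ")

    overlay = image.astype(np.float64).copy()
    colored_mask = np.zeros_like(image)
    for cls in mask.scheme.foreground_classes:
        pix = mask.class_pixels(cls)
        color = np.array(CLASS_PALETTE[cls], dtype=np.float64)
        overlay[pix] = (1 - OVERLAY_ALPHA) * overlay[pix] + OVERLAY_ALPHA * color
        colored_mask[pix] = CLASS_PALETTE[cls]
    overlay = np.clip(np.rint(overlay), 0, 255).astype(np.uint8)

    plant = mask.class_pixels(PLANT_REGION)
    crop = np.zeros_like(image)
    crop[plant] = image[plant]
    if plant.any():
        rows = np.flatnonzero(plant.any(axis=1))
        cols = np.flatnonzero(plant.any(axis=0))
        crop = crop[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]

    hull_panel = image.copy()
    if plant.any():
        with warnings.catch_warnings():
            # degenerate (collinear) plant regions have no 2-D hull to draw
            warnings.simplefilter("ignore")
            hull = convex_hull_image(plant, offset_coordinates=False)
        outline = hull & ~ndi.binary_erosion(hull)
        hull_panel[outline] = (255, 0, 0)

    paths = {}
    for name, arr in (
        ("overlay", overlay),
        ("mask", colored_mask),
        ("crop", crop),
        ("hull", hull_panel),
    ):
        path = outdir / f"{image_id}_{name}.png"
        iio.imwrite(path, arr)
        paths[name] = path
    return paths


def _list_images(images_dir: Path) -> list[Path]:
    return sorted(
        p
        for p in images_dir.iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    )


def _segment(
    image: np.ndarray,
    path: Path,
    scheme: ClassScheme,
    segmenter: str,
    masks_dir: Path | None,
    multiscale: bool,
    scales,
    a_max: float,
    l_min: float,
) -> SegmentationMask:
    if segmenter == "external-mask":
        if masks_dir is None:
            raise ValueError("--masks is required with the external-mask segmenter")
        mask_path = masks_dir / f"{path.stem}.png"
        if not mask_path.exists():
            raise FileNotFoundError(
                f"no mask for image {path.name!r} (expected {mask_path})"
            )
        return load_mask(mask_path, scheme)
    if segmenter == "lab-threshold":
        if scheme.name != "A":
            raise ValueError(
                "the lab-threshold baseline produces plant/background masks "
                "only; use --scheme A"
            )
        if multiscale:
            return multiscale_predict(
                lab_threshold_classifier(a_max=a_max, l_min=l_min), image, scales
            )
        return threshold_segment(image, a_max=a_max, l_min=l_min)
    raise ValueError(f"unknown segmenter {segmenter!r}")


def run_pipeline(
    images_dir,
    outdir,
    scheme: ClassScheme,
    segmenter: str = "external-mask",
    masks_dir=None,
    batch_size: int = 10,
    multiscale: bool = False,
    scales=DEFAULT_SCALES,
    a_max: float = DEFAULT_A_MAX,
    l_min: float = DEFAULT_L_MIN,
    diagnostics: bool = False,
    evaluate_dir=None,
    strict: bool = True,
) -> dict:
    """Run the full pipeline over a folder of images.

    Writes ``results.csv`` (plus ``diagnostics/`` and ``evaluation.json`` on
    request) under ``outdir`` and returns a summary dict.  Per-image
    failures are collected and the run continues; under ``strict`` any
    failure raises :class:`PipelineError` after the table is written.
    """
    images_dir = Path(images_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    masks_dir = Path(masks_dir) if masks_dir is not None else None
    evaluate_dir = Path(evaluate_dir) if evaluate_dir is not None else None

    plan = scatter(_list_images(images_dir), batch_size)
    acc = evaluation.ConfusionAccumulator(scheme) if evaluate_dir else None
    batch_rows: list[list[dict]] = []
    failures: list[tuple[str, str]] = []

    for b, batch in enumerate(plan.batches):
        t0 = time.perf_counter()
        rows: list[dict] = []
        for path in batch:
            try:
                image = iio.imread(path)
                if image.ndim == 2:
                    image = np.stack([image] * 3, axis=2)
                image = image[..., :3]
                mask = _segment(
                    image, path, scheme, segmenter, masks_dir,
                    multiscale, scales, a_max, l_min,
                )
                rows.append(process_image(image, mask, image_id=path.stem))
                if diagnostics:
                    render_diagnostics(image, mask, outdir / "diagnostics", path.stem)
                if acc is not None:
                    truth = load_mask(evaluate_dir / f"{path.stem}.png", scheme)
                    acc.add(mask, truth)
            except Exception as exc:  # noqa: BLE001 - collected, reported at end
                failures.append((path.name, str(exc)))
                logger.warning("failed on %s: %s", path.name, exc)
        batch_rows.append(rows)
        logger.info(
            "batch %d/%d: %d image(s) in %.2fs",
            b + 1, len(plan.batches), len(batch), time.perf_counter() - t0,
        )

    table = gather(batch_rows, scheme)
    results_path = outdir / "results.csv"
    write_results(table, results_path)

    summary: dict = {
        "n_images": plan.n_images,
        "n_rows": len(table),
        "n_failures": len(failures),
        "failures": failures,
        "results": results_path,
    }
    if acc is not None and acc.n_images:
        report = {
            "per_class_iou": {
                k: (None if math.isnan(v) else v)
                for k, v in acc.per_class_iou().items()
            },
            "mean_iou": evaluation.mean_iou(acc),
            "n_images": acc.n_images,
        }
        eval_path = outdir / "evaluation.json"
        eval_path.write_text(json.dumps(report, indent=2) + "\n")
        summary["evaluation"] = report
        summary["evaluation_path"] = eval_path
    if failures and strict:
        raise PipelineError(
            f"{len(failures)} image(s) failed; results for the rest are in "
            f"{results_path}"
        )
    return summary
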