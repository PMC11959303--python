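"""Synthetic plate/nucleus rendering and image-based colony & focus counting.

The high-content readout of a clonogenic screen is an image of a
crystal-violet-stained well; colonies are counted as connected components
above a global threshold, discarding objects smaller than the pixel-area
equivalent of a 50-cell colony. A companion renderer draws anti-aliased
discs with Gaussian background noise and attaches the ground-truth object
list, so counting accuracy is testable exactly.

Focus counting (gamma-H2AX-style) operates per nucleus mask: top-hat
background subtraction followed by thresholded connected components,
reporting the mean focus count over nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops_table
from skimage.morphology import disk, white_tophat

__all__ = [
    "PlateImage",
    "FociResult",
    "render_plate",
    "count_colonies",
    "default_min_area",
    "render_nucleus_field",
    "count_foci",
]

#: Rough footprint of one adherent cell (um^2), used to translate the
#: ">= 50 cells" colony rule into a pixel-area threshold.
CELL_AREA_UM2 = 200.0
CELLS_PER_COLONY = 50


@dataclass
class PlateImage:
    """Grayscale raster in [0, 1] with calibration and optional truth."""

    image: np.ndarray
    pixel_size_um: float
    ground_truth: pd.DataFrame | None = None
    overlaps_flagged: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class FociResult:
    per_nucleus: np.ndarray
    mean_foci: float
    n_nuclei: int


def default_min_area(pixel_size_um: float,
                     cells_per_colony: int = CELLS_PER_COLONY,
                     cell_area_um2: float = CELL_AREA_UM2) -> float:
    """Pixel-area proxy for the minimum countable colony."""
    return cells_per_colony * cell_area_um2 / pixel_size_um ** 2


def render_plate(colonies, shape: tuple[int, int] = (512, 512),
                 pixel_size_um: float = 10.0, background: float = 0.05,
                 noise_sd: float = 0.01, seed: int = 0) -> PlateImage:
    """Render anti-aliased discs on a noisy background.

    ``colonies`` is a sequence of (row, col, radius_px, intensity). Disc
    edges are softened over one pixel (linear ramp on the signed distance to
    the boundary). Overlapping discs are summed, clipped to [0, 1], and
    flagged.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    rows = []
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    overlap = False
    placed: list[tuple[float, float, float]] = []
    for (r, c, rad, inten) in colonies:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"colony center ({r}, {c}) outside the well")
        dist = np.sqrt((yy - r) ** 2 + (xx - c) ** 2)
        img += inten * np.clip(rad + 0.5 - dist, 0.0, 1.0)
        for (pr, pc, prad) in placed:
            if np.hypot(pr - r, pc - c) < prad + rad:
                overlap = True
        placed.append((r, c, rad))
        area_px = np.pi * rad ** 2
        rows.append({"row": r, "col": c, "radius_px": rad,
                     "intensity": inten, "area_px": area_px,
                     "sub_threshold":
                         area_px < default_min_area(pixel_size_um)})
    img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    truth = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["row", "col", "radius_px", "intensity", "area_px",
                 "sub_threshold"])
    return PlateImage(image=img, pixel_size_um=pixel_size_um,
                      ground_truth=truth, overlaps_flagged=overlap)


def count_colonies(plate: PlateImage, min_area: float | None = None,
                   threshold: str | float = "otsu",
                   ) -> tuple[int, pd.DataFrame]:
    """Count colonies as above-threshold connected components.

    ``threshold='otsu'`` uses Otsu's global threshold (relative to the image
    histogram, hence invariant to global intensity scaling); a float is used
    as an absolute threshold. Components with area < ``min_area`` (default:
    the 50-cell pixel-area proxy for the image's pixel size) are discarded.
    A blank or saturated image yields 0 with a warning.
    """
    img = plate.image
    if min_area is None:
        min_area = default_min_area(plate.pixel_size_um)
    empty = pd.DataFrame(columns=["label", "area", "centroid-0",
                                  "centroid-1"])
    if np.ptp(img) < 1e-6:
        warnings.warn("blank or saturated image; no colonies counted")
        return 0, empty
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    mask = img > thr
    if not mask.any() or mask.all():
        warnings.warn("thresholding produced an empty/full mask")
        return 0, empty
    lab = label(mask)
    props = pd.DataFrame(regionprops_table(
        lab, properties=("label", "area", "centroid")))
    props = props[props["area"] >= min_area].reset_index(drop=True)
    return int(len(props)), props


def render_nucleus_field(n_nuclei: int, foci_per_nucleus: int,
                         nucleus_radius_px: int = 20,
                         focus_radius_px: float = 1.5,
                         focus_intensity: float = 0.8,
                         background: float = 0.05, noise_sd: float = 0.01,
                         seed: int = 0,
                         ) -> tuple[PlateImage, np.ndarray]:
    """Render a grid of circular nuclei each carrying well-separated foci.

    Returns the image and a labeled nucleus-mask array (0 = background,
    1..n = nucleus id). Foci are placed on a ring inside each nucleus so
    they never touch.
    """
    rng = np.random.default_rng(seed)
    cell = 2 * nucleus_radius_px + 8
    per_side = int(np.ceil(np.sqrt(n_nuclei)))
    shape = (per_side * cell, per_side * cell)
    img = np.full(shape, background, dtype=float)
    masks = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for i in range(n_nuclei):
        gr, gc = divmod(i, per_side)
        cy = gr * cell + cell // 2
        cx = gc * cell + cell // 2
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        masks[dist <= nucleus_radius_px] = i + 1
        img += 0.10 * np.clip(nucleus_radius_px + 0.5 - dist, 0.0, 1.0)
        if foci_per_nucleus > 0:
            ring = 0.6 * nucleus_radius_px
            phase = rng.uniform(0, 2 * np.pi)
            for k in range(foci_per_nucleus):
                ang = phase + 2 * np.pi * k / foci_per_nucleus
                fy, fx = cy + ring * np.sin(ang), cx + ring * np.cos(ang)
                fd = np.sqrt((yy - fy) ** 2 + (xx - fx) ** 2)
                img += focus_intensity * np.clip(
                    focus_radius_px + 0.5 - fd, 0.0, 1.0)
    img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    plate = PlateImage(image=img, pixel_size_um=0.5,
                       meta={"foci_per_nucleus": foci_per_nucleus})
    return plate, masks


def count_foci(field: PlateImage, nucleus_masks: np.ndarray,
               tophat_radius: int = 3, min_snr: float = 10.0,
               abs_floor: float = 0.2) -> FociResult:
    """Count foci per nucleus and report the mean over nuclei.

    Background (including the smooth nuclear stain) is removed with a white
    top-hat; within each nucleus, pixels above
    ``max(abs_floor, median + min_snr * robust_sd)`` of the top-hat image
    form candidate foci, counted as connected components. With no nucleus
    masks an error is raised.
    """
    ids = np.unique(nucleus_masks)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no nucleus masks provided")
    th = white_tophat(field.image, footprint=disk(tophat_radius))
    counts = []
    for nid in ids:
        vals = th[nucleus_masks == nid]
        med = np.median(vals)
        sigma = 1.4826 * np.median(np.abs(vals - med))
        thr = max(abs_floor, med + min_snr * sigma)
        mask = (th > thr) & (nucleus_masks == nid)
        counts.append(int(label(mask).max()))
    counts = np.asarray(counts)
    return FociResult(per_nucleus=counts, mean_foci=float(counts.mean()),
                      n_nuclei=int(ids.size))
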