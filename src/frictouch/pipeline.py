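"""End-to-end trial analysis: track -> grid -> divergence summary.

Ties the imaging stages together the way a recorded press trial is
analysed: track ridge features (onset-referenced), build the
apparent-contact mask from the contact channel, interpolate the
scattered displacements on a regular grid, and summarise the field
(median divergence, global-displacement exclusion, real contact area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import (
    DisplacementField,
    GlobalDisplacement,
    divergence_map,
    global_displacement,
    grid_interpolate,
)
from .images import (
    TrackedPoints,
    TrialRecord,
    otsu_threshold,
    real_contact_area,
    track_features,
)

__all__ = ["TrialAnalysis", "apparent_contact_mask", "analyze_trial"]


@dataclass
class TrialAnalysis:
    """Summary of one analysed press trial."""

    field: DisplacementField
    tracked: TrackedPoints
    median_divergence: float
    mean_divergence: float
    global_disp: GlobalDisplacement
    real_area_mm2: np.ndarray  # per frame
    excluded: bool
    exclusion_reason: str


def apparent_contact_mask(
    contact_image: np.ndarray,
    closing_px: int = 9,
) -> np.ndarray:
    """Gross contact footprint from a contact-channel image.

    The bright microjunction speckle is thresholded (Otsu), closed
    with a disk to bridge the gaps between asperities, and hole-filled;
    the largest connected component is kept.
    """
    img = np.asarray(contact_image, dtype=float)
    thr = otsu_threshold(img)
    dots = img > thr
    r = np.arange(-closing_px, closing_px + 1)
    dx, dy = np.meshgrid(r, r)
    selem = dx**2 + dy**2 <= closing_px**2
    closed = ndimage.binary_closing(dots, structure=selem)
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n == 0:
        return filled
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def analyze_trial(
    trial: TrialRecord,
    tracked: TrackedPoints | None = None,
    grid_n: int = 48,
    **track_kwargs,
) -> TrialAnalysis:
    """Full displacement-field analysis of one press trial.

    Tracks features (unless pre-tracked ones are supplied), grids the
    onset-referenced displacements over the apparent-contact footprint
    of the final frame, and reports the median and mean divergence, the
    global-displacement exclusion flag and the per-frame real contact
    area.
    """
    if tracked is None:
        tracked = track_features(trial, **track_kwargs)
    res = trial.pixel_resolution
    final = trial.frames[tracked.final_index]
    mask_img = apparent_contact_mask(final.contact_image)

    pts_mm = tracked.positions[tracked.final_index] * res
    x_lo, y_lo = pts_mm.min(axis=0)
    x_hi, y_hi = pts_mm.max(axis=0)
    grid_x = np.linspace(x_lo, x_hi, grid_n)
    grid_y = np.linspace(y_lo, y_hi, grid_n)
    gx, gy = np.meshgrid(grid_x, grid_y)
    cols = np.clip(np.round(gx / res).astype(int), 0, mask_img.shape[1] - 1)
    rows = np.clip(np.round(gy / res).astype(int), 0, mask_img.shape[0] - 1)
    contact_on_grid = mask_img[rows, cols]

    fld = grid_interpolate(
        pts_mm,
        tracked.displacement_mm,
        grid_x,
        grid_y,
        contact_mask=contact_on_grid,
        pixel_resolution=res,
        timestamp=final.timestamp,
    )
    dmap = divergence_map(fld)
    med = float(np.nanmedian(dmap))
    mean = float(np.nanmean(dmap))
    gd = global_displacement(fld)
    areas = np.array(
        [real_contact_area(f.contact_image, res) for f in trial.frames]
    )
    return TrialAnalysis(
        field=fld,
        tracked=tracked,
        median_divergence=med,
        mean_divergence=mean,
        global_disp=gd,
        real_area_mm2=areas,
        excluded=gd.excluded,
        exclusion_reason=gd.reason,
    )
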