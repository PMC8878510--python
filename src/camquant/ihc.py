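"""DAB optical-density scoring for Ki67 immunohistochemistry.

Chromogenic DAB staining is quantified as an optical-density sum: each RGB
channel contributes -log10(I/255), so pure white scores 0 and darker stain
scores higher. Cells are positive when their mean OD reaches 0.1 and
positives are binned as weak (1+), moderate (2+) or strong (3+) at the
intensity cut-points 0.2, 0.4 and 0.6.

This is a deliberately simplified scoring rule: it reuses this package's own
segmentation/region machinery and the printed thresholds, and does not
replicate any full positive-cell-detection algorithm (background radius,
smoothing sigma, cell expansion heuristics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

POSITIVE_THRESHOLD = 0.1
DEFAULT_BINS = (0.2, 0.4, 0.6)
BIN_NAMES = ("1+", "2+", "3+")


def od_sum(rgb: np.ndarray) -> np.ndarray:
    """Optical-density sum of an RGB image (or a single pixel triple).

    OD = sum over channels of -log10(max(I, 1) / 255); intensities are floored
    at 1 before the log so fully black pixels stay finite. A pure white pixel
    (255, 255, 255) has OD exactly 0.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB data with 3 trailing channels")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("RGB values outside [0, 255]")
    return -np.log10(np.maximum(arr, 1.0) / 255.0).sum(axis=-1)


@dataclass
class Ki67Score:
    """Per-cell OD scores plus slide-level bin bookkeeping."""

    per_cell: pd.DataFrame           # label, mean_od, positive, bin
    bin_counts: dict[str, int]       # "1+"/"2+"/"3+" -> count
    n_positive: int
    n_cells: int


def score_cells(
    od_raster: np.ndarray,
    cell_labels: np.ndarray,
    positive_threshold: float = POSITIVE_THRESHOLD,
    bins: tuple[float, float, float] = DEFAULT_BINS,
) -> Ki67Score:
    """Score every labeled cell by mean optical density.

    A cell is positive when its mean OD >= ``positive_threshold``. Positives
    are binned left-closed: [bins[0], bins[1]) -> 1+, [bins[1], bins[2]) ->
    2+, [bins[2], inf) -> 3+. A positive cell below the first cut-point is
    reported in the lowest bin with a logged note.
    """
    od = np.asarray(od_raster, dtype=np.float64)
    labels = np.asarray(cell_labels)
    if od.shape != labels.shape:
        raise ValueError(f"OD raster {od.shape} and cell labels {labels.shape} differ in shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        empty = pd.DataFrame(columns=["label", "mean_od", "positive", "bin"])
        return Ki67Score(empty, dict.fromkeys(BIN_NAMES, 0), 0, 0)
    mean_od = ndi.mean(od, labels, index=ids)
    positive = mean_od >= positive_threshold

    bin_col = np.full(ids.shape, "negative", dtype=object)
    low, mid, high = bins
    n_sub = int(np.logical_and(positive, mean_od < low).sum())
    if n_sub:
        logger.info("%d positive cells below the 1+ cut-point reported as 1+", n_sub)
    bin_col[positive] = BIN_NAMES[0]
    bin_col[np.logical_and(positive, mean_od >= mid)] = BIN_NAMES[1]
    bin_col[np.logical_and(positive, mean_od >= high)] = BIN_NAMES[2]

    per_cell = pd.DataFrame(
        {"label": ids.astype(int), "mean_od": mean_od, "positive": positive, "bin": bin_col}
    )
    bin_counts = {name: int((bin_col == name).sum()) for name in BIN_NAMES}
    return Ki67Score(per_cell, bin_counts, int(positive.sum()), int(ids.size))
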