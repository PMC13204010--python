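"""Microscopy readout quantification.

Four readouts common to senescence studies: Pearson colocalization of
two fluorescence channels, puncta (foci) segmentation by global
threshold + connected components, per-cell focus counts and summed
signal areas (the proximity-ligation-assay readout), and the percentage
of cells above a per-cell cutoff (the SA-βGal-style positive fraction).

Cell/nucleus segmentation is deliberately out of scope: a labelled mask
(0 = background, 1..n = cells) is an input, produced by the synthetic
generator or any external segmenter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ParameterError, ZeroVarianceError

logger = logging.getLogger(__name__)


def pearson_coloc(channel_a: np.ndarray, channel_b: np.ndarray,
                  mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over the masked pixels.

    ``mask`` may be a binary mask or a labelled cell map (any nonzero
    pixel is included); when absent the whole image is used.  A constant
    channel raises :class:`ZeroVarianceError` rather than returning 0.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("channels must share a shape")
    if mask is not None:
        m = np.asarray(mask) != 0
        if m.shape != a.shape:
            raise ParameterError("mask must share the channel shape")
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ParameterError("need at least 2 pixels to correlate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("a channel is constant within the mask; "
                                "Pearson r is undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def per_cell_coloc(channel_a: np.ndarray, channel_b: np.ndarray,
                   cells: np.ndarray) -> pd.Series:
    """Pearson r computed within each labelled cell (cells whose pixels
    are constant in either channel are skipped with a warning)."""
    cells = np.asarray(cells)
    out = {}
    for lbl in np.unique(cells[cells > 0]):
        try:
            out[int(lbl)] = pearson_coloc(channel_a, channel_b, cells == lbl)
        except ZeroVarianceError:
            logger.warning("cell %d has a constant channel; skipped", lbl)
    return pd.Series(out, name="pearson_r")


def segment_foci(channel: np.ndarray,
                 threshold: float | str = "otsu",
                 min_area: int = 1,
                 max_area: int | None = None) -> pd.DataFrame:
    """Segment bright puncta: binarize at a global threshold, label
    8-connected components, keep components within the area gates.

    Centroids are intensity-weighted.  Columns: focus_id, x (column),
    y (row), area, total_intensity.
    """
    if min_area < 1:
        raise ParameterError("min_area must be >= 1")
    img = np.asarray(channel, dtype=float)
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return pd.DataFrame(columns=["focus_id", "x", "y", "area",
                                         "total_intensity"])
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    binary = img >= thr
    labels = cc_label(binary, connectivity=2)
    hi = np.inf if max_area is None else max_area
    rows = []
    for fid, region in enumerate(regionprops(labels, intensity_image=img), 1):
        if not min_area <= region.area <= hi:
            continue
        cy, cx = region.centroid_weighted
        rows.append((fid, float(cx), float(cy), int(region.area),
                     float(region.image_intensity[region.image].sum())))
    return pd.DataFrame(rows, columns=["focus_id", "x", "y", "area",
                                       "total_intensity"])


def assign_foci_to_cells(foci: pd.DataFrame,
                         cells: np.ndarray) -> pd.DataFrame:
    """Attach a ``cell`` label to each focus by the cell map value at its
    (rounded) centroid pixel; foci landing on background get cell 0 and
    are logged."""
    cells = np.asarray(cells)
    labels = []
    for _, row in foci.iterrows():
        r = int(round(row["y"]))
        c = int(round(row["x"]))
        inside = 0 <= r < cells.shape[0] and 0 <= c < cells.shape[1]
        labels.append(int(cells[r, c]) if inside else 0)
    out = foci.copy()
    out["cell"] = labels
    dropped = int((out["cell"] == 0).sum())
    if dropped:
        logger.warning("%d foci fell on background and are unassigned",
                       dropped)
    return out


def per_cell_counts(foci: pd.DataFrame, cells: np.ndarray) -> pd.Series:
    """Focus count per cell label (cells with no foci report 0)."""
    cells = np.asarray(cells)
    assigned = assign_foci_to_cells(foci, cells)
    counts = {int(lbl): 0 for lbl in np.unique(cells[cells > 0])}
    for lbl, n in assigned[assigned["cell"] > 0]["cell"].value_counts().items():
        counts[int(lbl)] = int(n)
    return pd.Series(counts, name="focus_count").sort_index()


def pla_area_per_cell(foci: pd.DataFrame, cells: np.ndarray,
                      pixel_size_um: float | None = None) -> pd.Series:
    """Summed focus area per cell, in px (or µm² when a pixel size in
    µm/px is given)."""
    cells = np.asarray(cells)
    assigned = assign_foci_to_cells(foci, cells)
    areas = {int(lbl): 0.0 for lbl in np.unique(cells[cells > 0])}
    for _, row in assigned[assigned["cell"] > 0].iterrows():
        areas[int(row["cell"])] += float(row["area"])
    series = pd.Series(areas, name="pla_area").sort_index()
    if pixel_size_um is not None:
        series = series * pixel_size_um ** 2
        series.name = "pla_area_um2"
    return series


def positive_fraction(per_cell_metric: Mapping[int, float] | pd.Series,
                      cutoff: float) -> float:
    """Percentage of cells whose per-cell metric is >= ``cutoff``."""
    values = np.asarray(list(dict(per_cell_metric).values()), dtype=float)
    if values.size == 0:
        raise ParameterError("no cells to score")
    return float(100.0 * np.count_nonzero(values >= cutoff) / values.size)
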