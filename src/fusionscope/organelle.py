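"""Lysosome metrics, nuclear-area statistics, and the background-corrected
nuclear/cytoplasmic (N/C) reporter ratio.

The N/C ratio of a cell is

    (mean nuclear intensity - mean background intensity)
    / (mean cytoplasmic intensity - mean background intensity),

where the background region is the set of all pixels in the field below a
fixed intensity cutoff (default 200 camera counts). Cells whose cytoplasmic
mean does not exceed the background mean are flagged and excluded from well
means; if no pixel falls below the cutoff the background defaults to 0 with
a warning and the ratio reduces to nuclear/cytoplasmic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import LabelImage, find_spots, threshold_regions

__all__ = [
    "LysoFieldResult",
    "lysosome_metrics",
    "nuclear_area_stats",
    "nc_ratio",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LysoFieldResult:
    """Per-field lysosome readouts, both normalized per nucleus."""

    n_spots: int
    thresholded_area_um2: float
    n_nuclei: int
    spots_per_nucleus: float
    area_per_nucleus_um2: float
    flagged: bool = False


def lysosome_metrics(lyso_channel: np.ndarray, nuclei: LabelImage,
                     spot_radius_px: float = 2.0,
                     intensity_threshold: float | None = None,
                     spot_threshold_rel: float = 0.1) -> LysoFieldResult:
    """Count lysosomal puncta and measure thresholded lysosomal area on one
    field (a single middle plane by upstream convention), normalized by the
    number of nuclei. With zero nuclei the ratios are undefined and the field
    is flagged."""
    px = nuclei.pixel_size_um
    spots = find_spots(lyso_channel, approx_radius_px=spot_radius_px,
                       threshold_rel=spot_threshold_rel)
    # thresholded lysosomal region: absolute intensity threshold, no area
    # filter (puncta are far below the 100 um^2 region scale)
    img = np.asarray(lyso_channel, dtype=float)
    if np.ptp(img) == 0:
        area_um2 = 0.0
    else:
        mask = threshold_regions(img, px, intensity_threshold, min_area_um2=0.0)
        area_um2 = float(mask.sum()) * px ** 2
    n_nuc = nuclei.n_labels
    if n_nuc == 0:
        return LysoFieldResult(len(spots), area_um2, 0, float("nan"),
                               float("nan"), flagged=True)
    return LysoFieldResult(
        n_spots=len(spots), thresholded_area_um2=area_um2, n_nuclei=n_nuc,
        spots_per_nucleus=len(spots) / n_nuc,
        area_per_nucleus_um2=area_um2 / n_nuc)


def nuclear_area_stats(nuclei: LabelImage):
    """Mean nuclear area (um^2) over the selected nuclei of a field.

    Area/border selection is applied upstream in nucleus segmentation; an
    empty field returns ``(nan, empty array)``.
    """
    areas = nuclei.areas_um2()
    if areas.size == 0:
        return float("nan"), areas
    return float(areas.mean()), areas


def nc_ratio(reporter_channel: np.ndarray, nuclei: LabelImage,
             rings: LabelImage, bkgd_cutoff: float = 200.0,
             bkgd_mask: np.ndarray | None = None,
             min_ring_px: int = 20) -> pd.DataFrame:
    """Background-corrected N/C ratio per cell.

    ``rings`` must be disjoint from the nuclei (as produced by
    :func:`fusionscope.imaging.surrounding_region`). ``bkgd_mask`` overrides
    the cutoff-derived background region when provided. Returns one row per
    nucleus label with the measured means, the ratio, and an ``excluded``
    flag (cytoplasm at or below background, or ring clipped below
    ``min_ring_px`` pixels).
    """
    img = np.asarray(reporter_channel, dtype=float)
    if img.shape != nuclei.labels.shape or img.shape != rings.labels.shape:
        raise ValueError("reporter, nuclei, and rings must share one shape")
    if np.any((nuclei.labels > 0) & (rings.labels > 0)):
        raise ValueError("rings must be disjoint from nuclei")

    if bkgd_mask is None:
        bkgd_mask = img < bkgd_cutoff
    if bkgd_mask.any():
        bkgd = float(img[bkgd_mask].mean())
    else:
        log.warning("no pixels below background cutoff %.1f; using bkgd=0",
                    bkgd_cutoff)
        bkgd = 0.0

    rows = []
    for lab in range(1, nuclei.n_labels + 1):
        nuc_px = img[nuclei.labels == lab]
        ring_px = img[rings.labels == lab]
        if ring_px.size < min_ring_px:
            rows.append((lab, float(nuc_px.mean()), float("nan"), bkgd,
                         float("nan"), True))
            continue
        nuc_mean = float(nuc_px.mean())
        cyto_mean = float(ring_px.mean())
        if cyto_mean <= bkgd:
            rows.append((lab, nuc_mean, cyto_mean, bkgd, float("nan"), True))
            continue
        ratio = (nuc_mean - bkgd) / (cyto_mean - bkgd)
        rows.append((lab, nuc_mean, cyto_mean, bkgd, ratio, False))
    return pd.DataFrame(rows, columns=[
        "label", "nuclear_mean", "cytoplasmic_mean", "background_mean",
        "nc_ratio", "excluded"])
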