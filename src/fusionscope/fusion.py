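"""Cell-cell fusion readouts.

The two-color assay cocultures GFP-only and mCherry-only cells; fusion
produces syncytia whose shared cytoplasm carries both fluorophores over all
member nuclei. Per field the **fusion index** is

    index = #nuclei(>90% mCh overlap AND >90% GFP overlap)
            / #fluorescent nuclei(>70% mCh overlap OR >70% GFP overlap)

with strict inequalities at both thresholds. Double-positive nuclei satisfy
the 70% OR rule and are therefore part of the denominator. A field with an
empty denominator reports 0 and is flagged rather than dropped, so well
means stay defined.

The split-GFP assay instead measures the thresholded area of reconstituted
GFP normalized by plating density:

    value = (GFP area / total area) / normalized DAPI area,
    normalized DAPI area = (DAPI area / total area)
                           / replicate mean(DAPI area / total area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import (FieldImage, LabelImage, QuantConfig, erode_regions,
                      find_nuclei, gaussian, overlap_percent,
                      threshold_regions)

__all__ = [
    "NucleusRecord",
    "FusionResult",
    "WellSummary",
    "fusion_index",
    "splitgfp_normalized_area",
    "splitgfp_field_areas",
    "aggregate_well",
    "end_to_end_two_color",
]


@dataclass(frozen=True)
class NucleusRecord:
    """Per-nucleus quantities entering the fusion index."""

    label: int
    area_um2: float
    pct_overlap_mch: float
    pct_overlap_gfp: float
    border_flag: bool = False

    def __post_init__(self):
        if not (0.0 <= self.pct_overlap_mch <= 100.0
                and 0.0 <= self.pct_overlap_gfp <= 100.0):
            raise ValueError("overlap percentages must lie in [0, 100]")
        if self.area_um2 <= 0:
            raise ValueError("nucleus area must be positive")


@dataclass(frozen=True)
class FusionResult:
    index: float
    n_double_positive: int
    n_fluorescent: int
    empty_denominator: bool


@dataclass(frozen=True)
class WellSummary:
    plate: str
    well: str
    metric: str
    per_field_values: tuple
    n_fields: int

    @property
    def value(self) -> float:
        return float(np.mean(self.per_field_values))


def fusion_index(records, cfg: QuantConfig = QuantConfig()) -> FusionResult:
    """Fusion index of one field from its per-nucleus overlap table."""
    hi, lo = cfg.overlap_hi_pct, cfg.overlap_lo_pct
    num = den = 0
    for r in records:
        mch, gfp = r.pct_overlap_mch, r.pct_overlap_gfp
        if not (0.0 <= mch <= 100.0 and 0.0 <= gfp <= 100.0):
            raise ValueError("overlap percentages must lie in [0, 100]")
        if mch > lo or gfp > lo:
            den += 1
        if mch > hi and gfp > hi:
            num += 1
    if den == 0:
        return FusionResult(0.0, 0, 0, True)
    return FusionResult(num / den, num, den, False)


def splitgfp_normalized_area(gfp_area: float, dapi_area: float,
                             total_area: float,
                             replicate_mean_dapi_fraction: float) -> float:
    """Density-normalized reconstituted-GFP area of one field.

    Equals ``(gfp_area/total_area) * replicate_mean / (dapi_area/total_area)``
    and is invariant to a uniform rescaling of all areas.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if dapi_area <= 0:
        raise ValueError("zero DAPI area: field is uninterpretable")
    if replicate_mean_dapi_fraction <= 0:
        raise ValueError("replicate mean DAPI fraction must be positive")
    if gfp_area < 0:
        raise ValueError("gfp_area must be >= 0")
    gfp_frac = gfp_area / total_area
    dapi_frac = dapi_area / total_area
    return gfp_frac / (dapi_frac / replicate_mean_dapi_fraction)


def splitgfp_field_areas(img: FieldImage, cfg: QuantConfig = QuantConfig(),
                         gfp_threshold: float | None = None,
                         dapi_threshold: float | None = None):
    """Measure (gfp_area_px, dapi_area_px, total_area_px) of one field.

    The GFP channel is Gaussian-smoothed (width 2 px) before the intensity
    threshold and 100 um^2 area filter; the DAPI area is a plain intensity
    threshold of the Hoechst channel.
    """
    gfp = gaussian(np.asarray(img.channel("gfp"), dtype=float),
                   sigma=cfg.splitgfp_smooth_sigma_px, preserve_range=True)
    gfp_mask = threshold_regions(gfp, img.pixel_size_um,
                                 intensity_threshold=gfp_threshold,
                                 min_area_um2=cfg.region_min_area_um2)
    hoechst = np.asarray(img.channel("hoechst"), dtype=float)
    if np.ptp(hoechst) == 0:
        dapi_mask = np.zeros_like(hoechst, dtype=bool)
    else:
        thr = dapi_threshold
        if thr is None:
            from skimage.filters import threshold_otsu
            thr = threshold_otsu(hoechst)
        dapi_mask = hoechst > thr
    total = hoechst.size
    return int(gfp_mask.sum()), int(dapi_mask.sum()), int(total)


def aggregate_well(per_field_values, plate: str = "", well: str = "",
                   metric: str = "") -> WellSummary:
    """Well value = arithmetic mean over its per-field values; missing fields
    are tolerated and reflected in ``n_fields``."""
    vals = tuple(float(v) for v in per_field_values if v is not None
                 and np.isfinite(v))
    if len(vals) == 0:
        raise ValueError("no usable field values for well aggregation")
    return WellSummary(plate, well, metric, vals, len(vals))


def end_to_end_two_color(img: FieldImage, cfg: QuantConfig = QuantConfig(),
                         gfp_threshold: float | None = None,
                         mch_threshold: float | None = None):
    """Full two-color pipeline on one field, in the printed processing order:
    nucleus segmentation -> per-channel region threshold (100 um^2 filter) ->
    5-px erosion -> per-nucleus overlap -> fusion index.

    Returns ``(FusionResult, per-nucleus DataFrame)``. Overlap is evaluated
    against the union mask per channel.
    """
    px = img.pixel_size_um
    nuclei = find_nuclei(img.channel("hoechst"), px, cfg)
    gfp_mask = erode_regions(
        threshold_regions(img.channel("gfp"), px, gfp_threshold,
                          cfg.region_min_area_um2),
        cfg.region_erosion_px)
    mch_mask = erode_regions(
        threshold_regions(img.channel("mcherry"), px, mch_threshold,
                          cfg.region_min_area_um2),
        cfg.region_erosion_px)
    ov_gfp = overlap_percent(nuclei, gfp_mask)
    ov_mch = overlap_percent(nuclei, mch_mask)
    areas = nuclei.areas_um2()
    records = [
        NucleusRecord(label=int(lab), area_um2=float(areas[lab - 1]),
                      pct_overlap_mch=float(ov_mch[lab]),
                      pct_overlap_gfp=float(ov_gfp[lab]))
        for lab in range(1, nuclei.n_labels + 1)
    ]
    table = pd.DataFrame({
        "label": [r.label for r in records],
        "area_um2": [r.area_um2 for r in records],
        "pct_overlap_mch": [r.pct_overlap_mch for r in records],
        "pct_overlap_gfp": [r.pct_overlap_gfp for r in records],
    })
    return fusion_index(records, cfg), table
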