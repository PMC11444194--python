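"""Ground-truthed synthetic data for every assay the pipeline quantifies.

Two families of generators live here:

* **Field generators** emulate multi-channel confocal fields of plated
  trophoblast-like cells: mono- and multinucleated cells carrying one or two
  cytoplasmic fluorophores (two-color fusion assay), reconstituted split-GFP
  sheets, lysosomal puncta, and nuclear/cytoplasmic reporter partitioning.
  Every generator returns the rendered :class:`~fusionscope.imaging.FieldImage`
  together with a :class:`FieldTruth` so downstream segmentation and metrics
  can be checked against exact ground truth.

* **Trajectory generators** emulate stroboscopic single-molecule tracking:
  a static mixture of Brownian diffusive states with localization error,
  photobleaching, and defocalization out of a finite focal slab.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import FieldImage

__all__ = [
    "FieldSpec",
    "FieldTruth",
    "AcquisitionSpec",
    "DiffusionModel",
    "DIFFUSION_PRESETS",
    "generate_two_color_field",
    "generate_splitgfp_field",
    "generate_lysosome_field",
    "generate_nc_field",
    "simulate_trajectories",
    "render_movie",
]


# ---------------------------------------------------------------------------
# Specs and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic plated field.

    Cell geometry defaults emulate BeWo cells imaged with a 10x objective
    (~0.6 um/px): nuclei are ellipses of ~12 um diameter (area well above the
    50 um^2 debris filter), cell bodies are disks extending ~6 um beyond the
    nucleus. The size distributions are assumptions (not reported for BeWo)
    and are configurable.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.6
    n_cells: int = 60
    fused_fraction: float = 0.0
    syncytium_size_mean: float = 3.0
    channel_gains: dict = field(default_factory=lambda: {
        "hoechst": 3000.0, "gfp": 2500.0, "mcherry": 2500.0,
        "lyso": 3000.0, "reporter": 600.0,
    })
    background_mean: float = 100.0
    noise_sd: float = 25.0
    nucleus_radius_um: float = 6.5
    cyto_radius_um: float = 14.0
    clumped: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fused_fraction <= 1.0):
            raise ValueError("fused_fraction must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.syncytium_size_mean < 2:
            raise ValueError("syncytium_size_mean must be >= 2")
        if self.background_mean < 0 or self.noise_sd < 0:
            raise ValueError("intensities must be >= 0")
        if any(v < 0 for v in self.channel_gains.values()):
            raise ValueError("channel gains must be >= 0")


@dataclass
class FieldTruth:
    """Exact ground truth for one synthetic field (1:1 with rendered objects)."""

    nucleus_centers: np.ndarray          # (n, 2) array of (x, y) px
    nucleus_fused_flag: np.ndarray       # (n,) bool
    true_fused_area_px: int = 0
    true_dapi_area_px: int = 0
    lyso_count: int = 0
    lyso_area_px: int = 0
    per_cell_nc_ratio: np.ndarray | None = None

    def __post_init__(self):
        self.nucleus_centers = np.asarray(self.nucleus_centers, dtype=float).reshape(-1, 2)
        self.nucleus_fused_flag = np.asarray(self.nucleus_fused_flag, dtype=bool)
        if self.nucleus_fused_flag.shape[0] != self.nucleus_centers.shape[0]:
            raise ValueError("fused flags must align 1:1 with nucleus centers")
        for name in ("true_fused_area_px", "true_dapi_area_px", "lyso_count", "lyso_area_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_nuclei(self) -> int:
        return self.nucleus_centers.shape[0]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Stroboscopic SMT acquisition geometry (160 nm pixels, 7.48 ms frames,
    8000 frames over a 150x150 px ROI, 0.7 um focal slab)."""

    pixel_size_um: float = 0.16
    frame_interval_s: float = 0.00748
    n_frames: int = 8000
    roi_px: int = 150
    focal_depth_um: float = 0.7
    track_start_frame: int = 100
    infer_start_frame: int = 1000

    def __post_init__(self):
        for name in ("pixel_size_um", "frame_interval_s", "n_frames", "roi_px",
                     "focal_depth_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.track_start_frame < 0:
            raise ValueError("track_start_frame must be >= 0")
        if self.infer_start_frame < self.track_start_frame:
            raise ValueError("infer_start_frame must be >= track_start_frame")


@dataclass(frozen=True)
class DiffusionModel:
    """Static mixture of Brownian states.

    Each trajectory draws one state for its whole lifetime (the state-array
    model assumption); per-frame state switching is available behind
    ``allow_switching`` for robustness experiments only.
    """

    state_D_um2s: tuple = (0.01, 2.5)
    state_occupancy: tuple = (0.37, 0.63)
    loc_error_um: float = 0.035
    bleach_mean_frames: float = 6.0
    allow_switching: bool = False
    switch_prob: float = 0.0

    def __post_init__(self):
        D = np.asarray(self.state_D_um2s, dtype=float)
        occ = np.asarray(self.state_occupancy, dtype=float)
        if D.shape != occ.shape:
            raise ValueError("state_D_um2s and state_occupancy must align")
        if np.any(D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("state occupancies must be >= 0 and sum to 1")
        if self.loc_error_um < 0:
            raise ValueError("localization error must be >= 0")
        if self.bleach_mean_frames < 1:
            raise ValueError("bleach_mean_frames must be >= 1")


def _three_mode(immobile: float) -> DiffusionModel:
    free = 1.0 - immobile
    return DiffusionModel(state_D_um2s=(0.01, 2.5, 9.0),
                          state_occupancy=(immobile, 0.6 * free, 0.4 * free))


#: Mixtures mirroring the measured bound-fraction regimes of the TFEB SMT
#: experiments: a freely diffusing NLS control (~9% bound), undifferentiated
#: cells (~19%), 24 h and 48 h of Forskolin differentiation (42%/62%), an H2B
#: chromatin-bound control (~85%), and the nuclear-masked DMSO regime (~37%)
#: used for the subsampling control.
DIFFUSION_PRESETS: dict[str, DiffusionModel] = {
    "nls": _three_mode(0.09),
    "dmso": _three_mode(0.19),
    "fsk24": _three_mode(0.42),
    "fsk48": _three_mode(0.62),
    "h2b": _three_mode(0.85),
    "dmso_nuclear": DiffusionModel(state_D_um2s=(0.01, 2.5),
                                   state_occupancy=(0.37, 0.63)),
}


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _place_units(rng, width, height, radii, max_attempts=3000):
    """Dart-throw unit centers so disks of the given radii do not overlap and
    stay fully inside the field. Raises when the density is infeasible."""
    centers = []
    placed_r = []
    for r in radii:
        ok = False
        for _ in range(max_attempts):
            x = rng.uniform(r, width - r)
            y = rng.uniform(r, height - r)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= (r + cr) ** 2
                   for (cx, cy), cr in zip(centers, placed_r)):
                centers.append((x, y))
                placed_r.append(r)
                ok = True
                break
        if not ok:
            raise ValueError(
                "could not place all cells without overlap; reduce n_cells or "
                "cell size")
    return centers


def _paint_ellipse(mask, cx, cy, a, b, theta):
    """Set True inside a rotated ellipse (semi-axes a, b) on a boolean image."""
    h, w = mask.shape
    r = int(math.ceil(max(a, b))) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint_disk(mask, cx, cy, r):
    _paint_ellipse(mask, cx, cy, r, r, 0.0)


def _sample_cell_layout(spec: FieldSpec, rng):
    """Partition nuclei into unfused singles and syncytial groups, and place
    every nucleus. Returns (centers (n,2), fused flags, group cytoplasm specs).

    Group spec: (member center list, cyto radius). Nuclei within a syncytium
    sit on a ring so their ellipse outlines keep >=2 px separation, which lets
    segmentation correctness be tested independently of clumping.
    """
    px = spec.pixel_size_um
    r_n = spec.nucleus_radius_um / px
    r_c = spec.cyto_radius_um / px
    n = spec.n_cells
    n_fused = int(round(spec.fused_fraction * n))
    if n_fused < 2:
        n_fused = 0 if spec.fused_fraction < 1.0 or n < 2 else n

    # group sizes: >=2, Poisson-shifted around the requested mean, capped
    sizes = []
    remaining = n_fused
    while remaining >= 2:
        k = 2 + int(rng.poisson(max(spec.syncytium_size_mean - 2.0, 0.0)))
        k = min(k, remaining, 8)
        if remaining - k == 1:
            k = k + 1 if k < 8 else k - 1
        sizes.append(k)
        remaining -= k
    n_fused = sum(sizes)
    n_single = n - n_fused

    sep = 2 * 1.15 * r_n + (0.0 if spec.clumped else 4.0)
    unit_radii = []
    ring_radii = []
    for k in sizes:
        rho = sep / 2.0 if k == 2 else sep / (2.0 * math.sin(math.pi / k))
        ring_radii.append(rho)
        unit_radii.append(rho + r_c)
    unit_radii.extend([r_c] * n_single)

    order = rng.permutation(len(unit_radii))  # avoid size-ordered placement bias
    placed = _place_units(rng, spec.width_px, spec.height_px,
                          [unit_radii[i] for i in order])
    unit_centers = [None] * len(unit_radii)
    for slot, i in enumerate(order):
        unit_centers[i] = placed[slot]

    centers, flags, groups = [], [], []
    for gi, k in enumerate(sizes):
        ux, uy = unit_centers[gi]
        rho = ring_radii[gi]
        phase = rng.uniform(0, 2 * math.pi)
        members = []
        for j in range(k):
            ang = phase + 2 * math.pi * j / k
            cx, cy = ux + rho * math.cos(ang), uy + rho * math.sin(ang)
            members.append((cx, cy))
            centers.append((cx, cy))
            flags.append(True)
        groups.append((members, r_c))
    singles = unit_centers[len(sizes):]
    for (cx, cy) in singles:
        centers.append((cx, cy))
        flags.append(False)
    return (np.asarray(centers, dtype=float).reshape(-1, 2),
            np.asarray(flags, dtype=bool), groups, singles, r_n, r_c)


def _render_nuclei(shape, centers, r_n, rng):
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy) in centers:
        a = r_n * rng.uniform(0.9, 1.15)
        b = r_n * rng.uniform(0.7, 0.95)
        theta = rng.uniform(0, math.pi)
        _paint_ellipse(mask, cx, cy, a, b, theta)
    return mask


def _compose(spec, masks_by_channel, rng, extra_values=None):
    """Render channels as background + per-mask foreground + Gaussian noise."""
    shape = (spec.height_px, spec.width_px)
    channels = {}
    for name, mask in masks_by_channel.items():
        img = np.full(shape, spec.background_mean, dtype=float)
        if extra_values is not None and name in extra_values:
            img = extra_values[name].copy()
        elif mask is not None:
            img[mask] = spec.background_mean + spec.channel_gains.get(name, 1000.0)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)
    return channels


# ---------------------------------------------------------------------------
# Field generators
# ---------------------------------------------------------------------------

def generate_two_color_field(spec: FieldSpec, seed: int | None = None):
    """Two-color fusion assay field: GFP-only and mCherry-only mononucleated
    cells plus dual-labeled syncytia whose shared cytoplasm covers all member
    nuclei. Returns (FieldImage with gfp/mcherry/hoechst, FieldTruth)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.height_px, spec.width_px)
    if spec.n_cells == 0:
        img = FieldImage(channels=_compose(spec, {"gfp": None, "mcherry": None,
                                                  "hoechst": None}, rng),
                         pixel_size_um=spec.pixel_size_um)
        return img, FieldTruth(np.empty((0, 2)), np.empty(0, dtype=bool))

    centers, flags, groups, singles, r_n, r_c = _sample_cell_layout(spec, rng)
    nuc_mask = _render_nuclei(shape, centers, r_n, rng)

    gfp = np.zeros(shape, dtype=bool)
    mch = np.zeros(shape, dtype=bool)
    for members, rc in groups:            # syncytia carry both fluorophores
        for (cx, cy) in members:
            _paint_disk(gfp, cx, cy, rc)
            _paint_disk(mch, cx, cy, rc)
    color = rng.integers(0, 2, size=len(singles))
    for (cx, cy), c in zip(singles, color):
        _paint_disk(gfp if c == 0 else mch, cx, cy, r_c)

    channels = _compose(spec, {"gfp": gfp, "mcherry": mch, "hoechst": nuc_mask}, rng)
    truth = FieldTruth(centers, flags,
                       true_fused_area_px=int(np.count_nonzero(gfp & mch)),
                       true_dapi_area_px=int(np.count_nonzero(nuc_mask)))
    return FieldImage(channels=channels, pixel_size_um=spec.pixel_size_um), truth


def generate_splitgfp_field(spec: FieldSpec, seed: int | None = None):
    """Split-GFP assay field: GFP fluorescence is reconstituted only over
    fused sheets; unfused cells show Hoechst only."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.height_px, spec.width_px)
    if spec.n_cells == 0:
        img = FieldImage(channels=_compose(spec, {"gfp": None, "hoechst": None}, rng),
                         pixel_size_um=spec.pixel_size_um)
        return img, FieldTruth(np.empty((0, 2)), np.empty(0, dtype=bool))

    centers, flags, groups, _singles, r_n, _r_c = _sample_cell_layout(spec, rng)
    nuc_mask = _render_nuclei(shape, centers, r_n, rng)
    sheet = np.zeros(shape, dtype=bool)
    for members, rc in groups:
        for (cx, cy) in members:
            _paint_disk(sheet, cx, cy, rc)

    channels = _compose(spec, {"gfp": sheet, "hoechst": nuc_mask}, rng)
    truth = FieldTruth(centers, flags,
                       true_fused_area_px=int(np.count_nonzero(sheet)),
                       true_dapi_area_px=int(np.count_nonzero(nuc_mask)))
    return FieldImage(channels=channels, pixel_size_um=spec.pixel_size_um), truth


def generate_lysosome_field(spec: FieldSpec, puncta_per_cell: int = 10,
                            puncta_radius_px: float = 2.0,
                            seed: int | None = None):
    """Lysosome assay field: per-cell non-overlapping bright puncta in the
    cytoplasmic annulus around each nucleus. Counts and areas are exact."""
    if puncta_per_cell < 0:
        raise ValueError("puncta_per_cell must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.height_px, spec.width_px)
    if spec.n_cells == 0:
        img = FieldImage(channels=_compose(spec, {"lyso": None, "hoechst": None}, rng),
                         pixel_size_um=spec.pixel_size_um)
        return img, FieldTruth(np.empty((0, 2)), np.empty(0, dtype=bool))

    base = replace(spec, fused_fraction=0.0)
    centers, flags, _groups, singles, r_n, r_c = _sample_cell_layout(base, rng)
    nuc_mask = _render_nuclei(shape, centers, r_n, rng)

    lyso = np.zeros(shape, dtype=bool)
    n_placed = 0
    pr = puncta_radius_px
    for (cx, cy) in singles:
        pts = []
        for _ in range(puncta_per_cell):
            ok = False
            for _attempt in range(2000):
                rad = rng.uniform(1.2 * r_n + pr, r_c - pr)
                ang = rng.uniform(0, 2 * math.pi)
                x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
                if all((x - qx) ** 2 + (y - qy) ** 2 >= (2 * pr + 1.0) ** 2
                       for qx, qy in pts):
                    pts.append((x, y))
                    ok = True
                    break
            if not ok:
                raise ValueError("puncta density too high to place without overlap")
        for (x, y) in pts:
            _paint_disk(lyso, x, y, pr)
        n_placed += len(pts)

    channels = _compose(spec, {"lyso": lyso, "hoechst": nuc_mask}, rng)
    truth = FieldTruth(centers, flags,
                       true_dapi_area_px=int(np.count_nonzero(nuc_mask)),
                       lyso_count=n_placed,
                       lyso_area_px=int(np.count_nonzero(lyso)))
    return FieldImage(channels=channels, pixel_size_um=spec.pixel_size_um), truth


def generate_nc_field(spec: FieldSpec, nc_ratios=(1.0,),
                      background_level: float = 120.0,
                      cyto_intensity: float = 600.0,
                      seed: int | None = None):
    """Nuclear/cytoplasmic reporter field.

    Each cell i gets requested ratio ``rho_i`` (cycled from ``nc_ratios``):
    the cytoplasm renders at ``cyto_intensity`` and the nucleus at
    ``bkgd + rho_i * (cyto_intensity - bkgd)``, so the background-corrected
    ratio of the noiseless render equals ``rho_i`` exactly.
    """
    nc_ratios = np.asarray(nc_ratios, dtype=float)
    if np.any(nc_ratios <= 0):
        raise ValueError("requested N/C ratios must be positive")
    if cyto_intensity <= background_level:
        raise ValueError("cyto_intensity must exceed background_level")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.height_px, spec.width_px)
    if spec.n_cells == 0:
        img = FieldImage(channels=_compose(spec, {"reporter": None, "hoechst": None}, rng),
                         pixel_size_um=spec.pixel_size_um)
        return img, FieldTruth(np.empty((0, 2)), np.empty(0, dtype=bool))

    base = replace(spec, fused_fraction=0.0)
    centers, flags, _groups, singles, r_n, r_c = _sample_cell_layout(base, rng)
    nuc_mask = _render_nuclei(shape, centers, r_n, rng)

    reporter = np.full(shape, background_level, dtype=float)
    ratios = np.resize(nc_ratios, len(singles))
    for (cx, cy), rho in zip(singles, ratios):
        cell = np.zeros(shape, dtype=bool)
        _paint_disk(cell, cx, cy, r_c)
        reporter[cell] = cyto_intensity
    # nuclear level painted last, with a 1 px margin beyond the rendered
    # nucleus, so segmentation-boundary pixels still sample the nuclear level
    margin = np.ones((3, 3), dtype=bool)
    for (cx, cy), rho in zip(singles, ratios):
        near = np.zeros(shape, dtype=bool)
        _paint_disk(near, cx, cy, 1.3 * r_n)
        region = near & ndi.binary_dilation(nuc_mask, structure=margin)
        reporter[region] = background_level + rho * (cyto_intensity - background_level)

    channels = _compose(spec, {"reporter": None, "hoechst": nuc_mask}, rng,
                        extra_values={"reporter": reporter})
    truth = FieldTruth(centers, flags,
                       true_dapi_area_px=int(np.count_nonzero(nuc_mask)),
                       per_cell_nc_ratio=ratios.copy())
    return FieldImage(channels=channels, pixel_size_um=spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _bridge_absorption(z0, z1, var, L, rng):
    """True where a Brownian bridge between in-slab endpoints crossed either
    absorbing boundary of the slab [0, L] during the interval."""
    out = (z1 <= 0.0) | (z1 >= L)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        p_lo = np.exp(-2.0 * z0 * z1 / var)
        p_hi = np.exp(-2.0 * (L - z0) * (L - z1) / var)
    p_lo = np.where(var > 0, p_lo, 0.0)
    p_hi = np.where(var > 0, p_hi, 0.0)
    u = rng.uniform(size=z0.shape)
    v = rng.uniform(size=z0.shape)
    return out | (u < p_lo) | (v < p_hi)


def simulate_trajectories(model: DiffusionModel, acq: AcquisitionSpec,
                          n_tracks: int, seed: int = 0):
    """Simulate a stroboscopic SMT dataset from a static diffusive mixture.

    Each track draws one state by occupancy, performs 2D Brownian steps with
    per-coordinate jump variance ``2 D dt``, and reports positions with
    independent localization noise ``sigma`` per coordinate per frame. The
    axial coordinate diffuses freely from a uniform start inside the focal
    slab and the track is truncated at its first boundary crossing
    (continuous-time crossing via Brownian-bridge probabilities), emulating
    defocalization. Visibility ends by geometric photobleaching with the
    configured mean lifetime. Returns ``(TrajectoryTable, truth)`` where
    truth is a per-track table (trajectory_id, state_index, D_um2s).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    D = np.asarray(model.state_D_um2s, dtype=float)
    occ = np.asarray(model.state_occupancy, dtype=float)
    dt = acq.frame_interval_s
    L = acq.focal_depth_um
    extent = acq.roi_px * acq.pixel_size_um

    states = rng.choice(len(D), size=n_tracks, p=occ)
    # geometric bleach lifetime in frames (support >= 1)
    life = rng.geometric(1.0 / model.bleach_mean_frames, size=n_tracks)
    start = rng.integers(acq.track_start_frame, acq.n_frames, size=n_tracks)
    life = np.minimum(life, acq.n_frames - start)
    T = int(life.max())

    Dtrack = D[states]
    if model.allow_switching and model.switch_prob > 0:
        # per-frame redraw from the mixture with probability switch_prob
        Dframes = np.empty((n_tracks, max(T - 1, 1)))
        cur = states.copy()
        for t in range(max(T - 1, 1)):
            flip = rng.uniform(size=n_tracks) < model.switch_prob
            redraw = rng.choice(len(D), size=n_tracks, p=occ)
            cur = np.where(flip, redraw, cur)
            Dframes[:, t] = D[cur]
        step_sd = np.sqrt(2.0 * Dframes * dt)
    else:
        step_sd = np.sqrt(2.0 * Dtrack * dt)[:, None]

    nsteps = max(T - 1, 1)
    dx = rng.normal(size=(n_tracks, nsteps)) * step_sd
    dy = rng.normal(size=(n_tracks, nsteps)) * step_sd
    dz = rng.normal(size=(n_tracks, nsteps)) * step_sd
    z0 = rng.uniform(0.0, L, size=n_tracks)
    z = np.concatenate([z0[:, None], z0[:, None] + np.cumsum(dz, axis=1)], axis=1)

    # increment variance 2*D*dt per step, as used by the bridge-crossing law
    var = np.broadcast_to(step_sd ** 2, (n_tracks, nsteps)).astype(float)
    absorbed = _bridge_absorption(z[:, :-1], z[:, 1:], var, L, rng)
    first = np.where(absorbed.any(axis=1), absorbed.argmax(axis=1), nsteps)
    # positions observed: capped by bleach lifetime and by slab exit
    n_pos = np.minimum(life, first + 1).astype(int)

    x0 = rng.uniform(0.0, extent, size=n_tracks)
    y0 = rng.uniform(0.0, extent, size=n_tracks)
    x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([y0[:, None], y0[:, None] + np.cumsum(dy, axis=1)], axis=1)
    if model.loc_error_um > 0:
        x = x + rng.normal(0.0, model.loc_error_um, size=x.shape)
        y = y + rng.normal(0.0, model.loc_error_um, size=y.shape)

    idx = np.repeat(np.arange(n_tracks), n_pos)
    pos = np.concatenate([np.arange(k) for k in n_pos])
    df = pd.DataFrame({
        "movie_id": 0,
        "trajectory_id": idx,
        "frame": start[idx] + pos,
        "x_um": x[idx, pos],
        "y_um": y[idx, pos],
        "cell_id": 0,
    })
    truth = pd.DataFrame({
        "trajectory_id": np.arange(n_tracks),
        "state_index": states,
        "D_um2s": Dtrack,
        "n_positions": n_pos,
    })
    return df, truth


def render_movie(localizations: pd.DataFrame, acq: AcquisitionSpec,
                 psf_sd_px: float = 1.0, intensity: float = 500.0,
                 background: float = 20.0, seed: int = 0,
                 poisson_noise: bool = True) -> np.ndarray:
    """Render localizations (frame, x_um, y_um) into a frame stack.

    Each molecule becomes a 2D Gaussian spot of total photon count
    ``intensity`` on a flat background, optionally with Poisson noise, so the
    detection and localization stages can be tested end to end against known
    positions.
    """
    rng = np.random.default_rng(seed)
    n = acq.roi_px
    if len(localizations) == 0:
        n_frames = 1
    else:
        n_frames = int(localizations["frame"].max()) + 1
    stack = np.full((n_frames, n, n), float(background))
    half = int(math.ceil(4 * psf_sd_px))
    for row in localizations.itertuples(index=False):
        f = int(row.frame)
        cx = row.x_um / acq.pixel_size_um
        cy = row.y_um / acq.pixel_size_um
        x0, x1 = int(cx) - half, int(cx) + half + 1
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0c, x1c = max(0, x0), min(n, x1)
        y0c, y1c = max(0, y0), min(n, y1)
        if x0c >= x1c or y0c >= y1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf_sd_px ** 2))
        stack[f, y0c:y1c, x0c:x1c] += intensity * g / (2 * math.pi * psf_sd_px ** 2)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return stack
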