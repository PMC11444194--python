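"""Configuration, file I/O, and pipeline orchestration.

TOML is the canonical config dialect (JSON is accepted for programmatic
round trips); unknown keys are rejected so typos fail loudly. Every output
carries the run seed and a hash of the resolved configuration, and the
structured log reports per-stage object counts (nuclei found, nuclei after
filtering, trajectories after masking, ...) so filter behavior is auditable.

Images are written as multi-page TIFF with the channel order recorded in a
JSON sidecar; tables are tidy CSV (one row per unit of analysis).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import fusion, organelle, spt, synthetic
from .imaging import FieldImage, QuantConfig, find_nuclei, surrounding_region
from .spt import LinkConfig, StateGrid
from .synthetic import AcquisitionSpec, DiffusionModel, FieldSpec

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline",
           "write_field", "read_field"]

log = logging.getLogger("fusionscope")

_ASSAYS = ("simulate-field", "two-color", "splitgfp", "lyso", "ncratio", "spt")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    assay: str = "two-color"
    seed: int = 0
    out_dir: str = "fusionscope_out"
    n_fields: int = 3
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    quant: QuantConfig = field(default_factory=QuantConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    grid: StateGrid = field(default_factory=StateGrid)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    diffusion: DiffusionModel = field(default_factory=DiffusionModel)
    n_tracks: int = 10_000
    n_subsample: int | None = None
    puncta_per_cell: int = 10
    nc_ratios: tuple = (1.0, 2.0)

    def __post_init__(self):
        if self.assay not in _ASSAYS:
            raise ValueError(f"assay must be one of {_ASSAYS}")
        if self.n_fields < 1 or self.n_tracks < 1:
            raise ValueError("n_fields and n_tracks must be >= 1")

    def to_dict(self) -> dict:
        d = {"assay": self.assay, "seed": self.seed, "out_dir": self.out_dir,
             "n_fields": self.n_fields, "n_tracks": self.n_tracks,
             "puncta_per_cell": self.puncta_per_cell,
             "nc_ratios": list(self.nc_ratios)}
        if self.n_subsample is not None:
            d["n_subsample"] = self.n_subsample
        d["field"] = dataclasses.asdict(self.field_spec)
        d["quant"] = dataclasses.asdict(self.quant)
        d["link"] = dataclasses.asdict(self.link)
        d["acquisition"] = dataclasses.asdict(self.acquisition)
        d["diffusion"] = {
            **dataclasses.asdict(self.diffusion),
            "state_D_um2s": list(self.diffusion.state_D_um2s),
            "state_occupancy": list(self.diffusion.state_occupancy)}
        g = dataclasses.asdict(self.grid)
        g.pop("d_values")
        g.update(d_min=float(self.grid.d_values[0]),
                 d_max=float(self.grid.d_values[-1]),
                 n_points=len(self.grid.d_values))
        d["grid"] = g
        return d

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _build(section: str, cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a TOML (or JSON) run configuration.

    Every key is optional (an empty file yields all defaults); unknown keys
    are rejected with a message naming the section.
    """
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text() or "{}")
    else:
        data = tomllib.loads(path.read_text())
    data = dict(data)

    kwargs = {}
    fs = dict(data.pop("field", {}))
    for name in ("state_D_um2s", "state_occupancy"):
        pass
    grid_raw = dict(data.pop("grid", {}))
    if grid_raw:
        d_min = grid_raw.pop("d_min", 1e-2)
        d_max = grid_raw.pop("d_max", 1e2)
        n_points = grid_raw.pop("n_points", 100)
        grid_raw["d_values"] = np.geomspace(d_min, d_max, int(n_points))
    diff_raw = dict(data.pop("diffusion", {}))
    for key in ("state_D_um2s", "state_occupancy"):
        if key in diff_raw:
            diff_raw[key] = tuple(diff_raw[key])
    kwargs["field_spec"] = _build("field", FieldSpec, fs)
    kwargs["quant"] = _build("quant", QuantConfig, dict(data.pop("quant", {})))
    kwargs["link"] = _build("link", LinkConfig, dict(data.pop("link", {})))
    kwargs["grid"] = _build("grid", StateGrid, grid_raw)
    kwargs["acquisition"] = _build("acquisition", AcquisitionSpec,
                                   dict(data.pop("acquisition", {})))
    kwargs["diffusion"] = _build("diffusion", DiffusionModel, diff_raw)
    top_names = {"assay", "seed", "out_dir", "n_fields", "n_tracks",
                 "n_subsample", "puncta_per_cell", "nc_ratios"}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    for key in top_names & set(data):
        kwargs[key] = tuple(data[key]) if key == "nc_ratios" else data[key]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration as JSON (loadable back via :func:`load_config`)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2))


def write_field(img: FieldImage, path) -> None:
    """Multi-page TIFF plus JSON sidecar recording channel order and pixel size."""
    path = Path(path)
    names = sorted(img.channels)
    stack = np.stack([img.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": img.pixel_size_um,
               "plate": img.plate, "well": img.well, "field": img.field}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path) -> FieldImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    return FieldImage(channels=channels, pixel_size_um=meta["pixel_size_um"],
                      plate=meta.get("plate", ""), well=meta.get("well", ""),
                      field=meta.get("field", 0))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _field_seed(cfg: RunConfig, i: int) -> int:
    return (cfg.seed * 10_007 + i) % (2 ** 31)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run one assay end to end; returns the summary dict it also writes.

    Outputs under ``cfg.out_dir``: per-unit CSV tables, a ``summary.json``
    carrying the seed and config hash, and (for simulation assays) the
    generated TIFF fields with truth CSVs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"assay": cfg.assay, "seed": cfg.seed,
               "config_hash": cfg.config_hash()}

    if cfg.assay == "simulate-field":
        for i in range(cfg.n_fields):
            img, truth = synthetic.generate_two_color_field(
                cfg.field_spec, seed=_field_seed(cfg, i))
            img.field = i
            write_field(img, out / f"field_{i:03d}.tiff")
            pd.DataFrame({
                "x_px": truth.nucleus_centers[:, 0],
                "y_px": truth.nucleus_centers[:, 1],
                "fused": truth.nucleus_fused_flag,
            }).to_csv(out / f"field_{i:03d}_truth.csv", index=False)
        summary["n_fields"] = cfg.n_fields

    elif cfg.assay == "two-color":
        rows, indices = [], []
        for i in range(cfg.n_fields):
            img, truth = synthetic.generate_two_color_field(
                cfg.field_spec, seed=_field_seed(cfg, i))
            res, table = fusion.end_to_end_two_color(img, cfg.quant)
            log.info("field %d: %d nuclei after filters, index %.4f "
                     "(truth fused share %.4f)", i, len(table), res.index,
                     truth.nucleus_fused_flag.mean() if truth.n_nuclei else 0.0)
            table.insert(0, "field", i)
            rows.append(table)
            indices.append(res.index)
        pd.concat(rows, ignore_index=True).to_csv(out / "nuclei.csv", index=False)
        well = fusion.aggregate_well(indices, metric="fusion_index")
        summary.update(metric="fusion_index", well_value=well.value,
                       per_field=indices, n_fields=well.n_fields)

    elif cfg.assay == "splitgfp":
        fracs, rows = [], []
        for i in range(cfg.n_fields):
            img, truth = synthetic.generate_splitgfp_field(
                cfg.field_spec, seed=_field_seed(cfg, i))
            gfp, dapi, total = fusion.splitgfp_field_areas(img, cfg.quant)
            rows.append((i, gfp, dapi, total))
            fracs.append(dapi / total)
        mean_dapi_frac = float(np.mean(fracs))
        values = [fusion.splitgfp_normalized_area(g, d, t, mean_dapi_frac)
                  for (_i, g, d, t) in rows]
        pd.DataFrame(rows, columns=["field", "gfp_area_px", "dapi_area_px",
                                    "total_area_px"]).assign(
            value=values).to_csv(out / "splitgfp.csv", index=False)
        summary.update(metric="splitgfp_normalized_area",
                       well_value=float(np.mean(values)), per_field=values)

    elif cfg.assay == "lyso":
        recs = []
        for i in range(cfg.n_fields):
            img, truth = synthetic.generate_lysosome_field(
                cfg.field_spec, puncta_per_cell=cfg.puncta_per_cell,
                seed=_field_seed(cfg, i))
            nuclei = find_nuclei(img.channel("hoechst"), img.pixel_size_um,
                                 cfg.quant)
            r = organelle.lysosome_metrics(img.channel("lyso"), nuclei)
            log.info("field %d: %d nuclei, %d spots (truth %d)", i,
                     r.n_nuclei, r.n_spots, truth.lyso_count)
            recs.append((i, r.n_spots, r.n_nuclei, r.spots_per_nucleus,
                         r.area_per_nucleus_um2))
        df = pd.DataFrame(recs, columns=["field", "n_spots", "n_nuclei",
                                         "spots_per_nucleus",
                                         "area_per_nucleus_um2"])
        df.to_csv(out / "lyso.csv", index=False)
        summary.update(metric="spots_per_nucleus",
                       well_value=float(df["spots_per_nucleus"].mean()))

    elif cfg.assay == "ncratio":
        per_field = []
        tables = []
        for i in range(cfg.n_fields):
            img, truth = synthetic.generate_nc_field(
                cfg.field_spec, nc_ratios=cfg.nc_ratios,
                seed=_field_seed(cfg, i))
            nuclei = find_nuclei(img.channel("hoechst"), img.pixel_size_um,
                                 cfg.quant)
            rings = surrounding_region(nuclei, width_px=7, gap_px=2)
            table = organelle.nc_ratio(img.channel("reporter"), nuclei, rings,
                                       bkgd_cutoff=cfg.quant.bkgd_intensity_cutoff)
            ok = table[~table["excluded"]]
            log.info("field %d: %d cells, %d excluded", i, len(table),
                     int(table["excluded"].sum()))
            table.insert(0, "field", i)
            tables.append(table)
            if len(ok):
                per_field.append(float(ok["nc_ratio"].mean()))
        pd.concat(tables, ignore_index=True).to_csv(out / "ncratio.csv",
                                                    index=False)
        summary.update(metric="nc_ratio",
                       well_value=float(np.mean(per_field)),
                       per_field=per_field)

    elif cfg.assay == "spt":
        tracks, truth = synthetic.simulate_trajectories(
            cfg.diffusion, cfg.acquisition, cfg.n_tracks, seed=cfg.seed)
        spec = spt.infer_spectrum(tracks, cfg.grid, seed=cfg.seed,
                                  max_sample=cfg.n_subsample)
        bf = spt.bound_fraction(spec, cfg.grid.bound_threshold_um2s)
        log.info("spt: %d tracks simulated, %d used, bound fraction %.4f",
                 cfg.n_tracks, spec.n_trajectories, bf)
        spec.to_frame().to_csv(out / "spectrum.csv", index=False)
        tracks.to_csv(out / "trajectories.csv", index=False)
        summary.update(metric="bound_fraction", bound_fraction=bf,
                       n_trajectories=spec.n_trajectories,
                       n_jumps=spec.n_jumps)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
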