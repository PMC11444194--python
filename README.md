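# fusionscope

Quantification pipelines for studies of syncytiotrophoblast biology: cell–cell
fusion and organelle readouts from high-content fluorescence images, and a
single-molecule tracking (SMT) workflow that estimates a spectrum of
diffusion coefficients and the chromatin-bound fraction of a nuclear
factor. It is aimed at groups who image trophoblast (e.g. BeWo) fusion
assays or perform fast SMT of transcription factors and want the published
quantification rules as tested, reusable, open code.

Every assay is paired with a synthetic-data generator that renders
ground-truthed fields and trajectory sets, so the whole pipeline is
verifiable end to end without any instrument data.

## What it computes

**Fusion index** (two-color coculture of GFP-only and mCherry-only cells):
per field, after nucleus segmentation (area > 50 µm²), per-channel region
thresholding (area > 100 µm²), and a 5-px region erosion,

```
index = #nuclei(>90% mCh overlap AND >90% GFP overlap)
        / #nuclei(>70% mCh overlap OR >70% GFP overlap)
```

**Split-GFP fused area**, normalized for plating density:
`(GFP area / total area) / [(DAPI area / total area) / replicate mean]`.

**Lysosome metrics** (spots/nucleus and thresholded area/nucleus),
**mean nuclear area**, and the **background-corrected N/C ratio**
`(nuc − bkgd)/(cyto − bkgd)` with the background taken below an intensity
cutoff (default 200).

**Diffusion spectra from SMT**: LLR spot detection, Gaussian subpixel
localization, conservative mutual-nearest-neighbor linking (no gap closing,
overdense frames excluded), optional nuclear masking, then a Bayesian
state-array estimate over a log-spaced grid of diffusion coefficients using
the regular-Brownian-motion-with-localization-error likelihood — for jumps
`d_1..d_n`, per coordinate, a zero-mean Gaussian with tridiagonal
covariance `diag = 2 D Δt + 2σ²`, `off-diag = −σ²` — with a defocalization
correction for molecules leaving the 0.7 µm focal slab. The **bound
fraction** is the posterior occupancy at D < 0.1 µm²/s. Defaults mirror a
stroboscopic acquisition with 160 nm pixels and 7.48 ms frames.

See `docs/methods.md` for the model details, assumptions, and limitations.

## Worked example

```python
import fusionscope as fs

# --- two-color fusion assay on a synthetic field ---------------------------
spec = fs.FieldSpec(n_cells=24, fused_fraction=0.5, noise_sd=0.0, seed=21)
img, truth = fs.generate_two_color_field(spec)
res, table = fs.end_to_end_two_color(img)
print(truth.nucleus_fused_flag.mean())          # 0.5   (generator truth)
print(res.index, res.n_double_positive, res.n_fluorescent)
# 0.5 12 24  -> 12 of 24 fluorescent nuclei are double-positive

# --- SMT: bound fraction of a mixture mirroring undifferentiated cells -----
model = fs.DIFFUSION_PRESETS["dmso"]            # 19% immobile at 0.01 um^2/s
tracks, _ = fs.simulate_trajectories(model, fs.AcquisitionSpec(),
                                     20_000, seed=101)
spectrum = fs.infer_spectrum(tracks, fs.StateGrid(), seed=7)
print(spectrum.n_trajectories, spectrum.n_jumps)   # 7652 26438
print(round(fs.bound_fraction(spectrum), 4))       # 0.2114
```

The fusion index recovers the simulated fused share exactly on this
noiseless field. The SMT example simulates 20,000 molecules (of which 7,652
yield usable post-filter trajectories after bleaching, defocalization, and
the start-frame cut) and recovers a bound fraction of 21.1% against a
simulated truth of 19%.

A CLI wraps the same pipelines
(`fusionscope two-color|splitgfp|lyso|ncratio|spt|simulate-field
--config cfg.toml --seed 1 --out outdir`), reading TOML configs whose keys
mirror the library dataclasses and writing tidy CSVs plus a `summary.json`
stamped with the seed and config hash.

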