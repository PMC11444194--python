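# Methods

`fusionscope` quantifies two experimental programs around trophoblast
syncytialization: (i) image-based readouts of cell–cell fusion, lysosomes,
nuclear area, and transcription-factor nuclear import from multi-channel
confocal fields, and (ii) a single-molecule tracking (SMT) workflow that
turns stroboscopic movies (or pre-localized trajectory tables) into a
posterior spectrum of diffusion coefficients and a chromatin-bound
fraction. A synthetic-data module generates ground-truthed inputs for every
assay, so each stage is verifiable end to end without instrument data.

## Image-based readouts

**Segmentation primitives.** The original analyses used a commercial
high-content platform whose segmentation algorithms ("find nuclei method
C", "find spots method D", "find surrounding region method A") are
unpublished. They are replaced by standard open algorithms with the same
published numeric filters:

- nuclei: Gaussian smoothing (sigma 2 px) → Otsu threshold → hole filling →
  distance-transform watershed to split touching nuclei → strict area
  filter > 50 µm² (debris removal) → optional border exclusion;
- bright regions: intensity threshold (given or Otsu) with a strict
  > 100 µm² area filter on 8-connected components;
- puncta: Laplacian-of-Gaussian blob detection with the scale range set
  from the configured punctum radius;
- cytoplasm rings: equidistant label expansion (a watershed partition of
  the background among nuclei) truncated at a fixed width, minus the
  nuclei; an optional guard gap keeps perinuclear boundary pixels out of
  cytoplasmic means. The ring width is configurable because no width was
  published.

Conventions are fixed: 4-connected structuring element for binary erosion,
8-connected component labeling, 0-based pixel indices, areas compared in
µm² after conversion by `pixel_size_um**2`. Flat-field and bright-field
correction are instrument-specific and out of scope; the generators render
flat illumination. Nuclei are area-filtered before overlap evaluation (the
processing order implied by the published description).

**Fusion index.** Per field,

    index = #nuclei(>90% mCherry overlap AND >90% GFP overlap)
            / #nuclei(>70% mCherry overlap OR >70% GFP overlap)

with strict inequalities exactly as published, overlap measured against the
per-channel union mask after a 5-pixel binary erosion of the thresholded
regions (the erosion suppresses spurious overlap at apposed cell
boundaries). Double-positive nuclei satisfy the 70% OR rule and are counted
in the denominator. A field with an empty denominator reports 0 and is
flagged rather than dropped, keeping well means defined and auditable.
Well values are arithmetic means over fields.

**Split-GFP area.** The GFP channel is smoothed (Gaussian width 2 px),
thresholded with the 100 µm² filter, and the GFP area fraction is divided
by the DAPI area fraction normalized to its biological-replicate mean;
the statistic is invariant to uniform rescaling of all areas.

**Lysosome metrics.** Spots/nuclei and thresholded-area/nuclei per field,
computed on a single middle plane (the upstream plane-selection
convention). The thresholded lysosomal region uses an absolute intensity
threshold with no area filter, since puncta are far below the 100 µm²
region scale.

**N/C ratio.** Background-corrected ratio
`(nuc − bkgd)/(cyto − bkgd)` per cell, with the background mean taken over
all pixels of the field below an intensity cutoff (default 200 camera
counts; the generators use 16-bit-like arbitrary counts so this cutoff is
meaningful on defaults). The cutoff scale is configurable because it is
instrument-specific. Fallbacks: an empty background region logs a warning
and uses bkgd = 0; cells whose cytoplasmic mean does not exceed the
background, or whose ring is clipped below 20 px, are flagged and excluded
from well means.

## Single-molecule tracking

**Detection** is a generalized log-likelihood-ratio test of a Gaussian spot
(kernel sd 1.2 px) against flat background in each 15×15 window, thresholded
at 18 and local-maximum filtered. **Localization** is a damped least-squares
fit of an integrated 2D Gaussian plus background in a 9×9 window (PSF sigma
1 px, damping 0.3, ridge 1e-3, at most 20 iterations); non-converged or
degenerate fits are flagged. **Linking** is deliberately conservative:
frames with more than 7 detections are excluded entirely, a link is made
only between unambiguous mutual nearest neighbors within a 1.0 µm search
radius, any ambiguity terminates the affected trajectories, and there is no
gap closing. The exact rule of the original tracking software is
unpublished; this rule is stated, configurable, and tested against an
exhaustive minimum-cost-assignment oracle on sparse movies. Frames before
100 are discarded before linking and trajectories starting before frame
1000 are excluded from inference, mirroring the two start parameters of the
original configuration. **Nuclear masks** come from a snapshot image:
Gaussian blur sigma 2 → minimum-method histogram threshold → hole filling →
2 binary erosions, with automatic polarity inversion when the mask covers
more than half the frame (cells with predominantly cytoplasmic signal).
Only trajectories entirely inside the mask are kept.

**Likelihood.** Regular Brownian motion with localization error (RBME): for
a trajectory with n lag-1 jumps, each coordinate's jump vector is zero-mean
Gaussian with tridiagonal covariance (diagonal `2 D dt + 2 sigma^2`,
off-diagonal `-sigma^2`), evaluated exactly via the banded Cholesky
factorization, grouped by trajectory length for speed. The localization
error is treated as known and fixed (default sigma = 0.035 µm) rather than
jointly inferred; fixing it keeps the estimator identifiable at the track
lengths produced by rapid bleaching. Motion blur is neglected: the 1 ms
excitation pulse occupies a small fraction of the 7.48 ms frame.

**State array.** Occupancies over a log-spaced grid of 100 diffusion
coefficients spanning 1e-2 to 1e2 µm²/s are estimated by the iterative
responsibility update `r_ij ∝ tau_j L_ij`,
`tau_j ← (alpha − 1 + Σ_i r_ij) / Σ_j (...)` with a uniform Dirichlet prior
(alpha = 1), run to a sup-norm occupancy change below 1e-6 or 250
iterations. At most `max_sample` trajectories (default 1e6) enter, chosen
by seeded uniform subsampling. The **bound fraction** is the cumulative
occupancy at grid points strictly below 0.1 µm²/s.

**Defocalization.** Fast molecules leave the focal slab (full depth
L = 0.7 µm) before producing a usable jump, biasing trajectory counts
toward slow states. The survival probability of Brownian z-motion started
uniformly in an absorbing slab through t = n·dt is the odd-eigenfunction
series `S = Σ_{k odd} 8/(k²π²) exp(−k²π² D t / L²)`, truncated below 1e-10.
Because the state array counts trajectories, the only state-dependent
observation loss is the probability of surviving the *first* frame
interval, so converged occupancies are divided by `S(D, 1 frame)` and
renormalized. Dividing instead by the expected survival over each observed
track's own length would over-correct: tracks observed with n jumps have
already survived those n frames by construction. The correction factor is
capped (default 20×) so numerically negligible occupancy at the extreme
fast end of the grid cannot be amplified into spurious mass; the cap only
engages above ~18 µm²/s at these acquisition settings.

## Synthetic data

**Fields** emulate plated BeWo-like cells at ~0.6 µm/px: elliptical nuclei
(~12 µm diameter, safely above the 50 µm² debris filter), disk-shaped cell
bodies, flat background plus Gaussian noise. Unfused cells carry exactly one
fluorophore; syncytia are rings of ≥2 nuclei sharing a dual-labeled (or
split-GFP-reconstituted) cytoplasm that covers all member nuclei. Nuclei
keep ≥2 px separation by default so segmentation correctness is testable
independently of clumping (a `clumped` mode removes the margin). Lysosomal
puncta are non-overlapping disks placed in the cytoplasmic annulus, with
exact counts and areas in the truth record; an infeasible density raises an
explicit error. N/C fields render each cell so that the noiseless
background-corrected ratio equals the requested value exactly, with a 1 px
nuclear-level margin outside the rendered nucleus so segmentation-boundary
pixels still sample the nuclear level. Cell and nucleus size distributions
are not published for BeWo; the defaults here are explicit, configurable
assumptions. The generators do not emulate uneven illumination, channel
bleed-through, aberrations, 3D structure, or EMCCD gain noise — passing
tests demonstrate correctness of the quantification logic, not robustness
to those instrument effects.

**Trajectories** are drawn from a static mixture (one state per track, the
state-array model assumption; per-frame switching exists behind a flag for
robustness experiments only): 2D Brownian steps with per-coordinate
variance `2 D dt`, independent localization noise per coordinate per frame,
geometric photobleaching (default mean 6 frames), and defocalization as an
absorbing slab with uniform initial z. Slab exits are detected with
Brownian-bridge crossing probabilities, i.e. in continuous time, so the
simulator's truncation law is exactly the survival series used by the
correction; a discrete-time check would systematically under-absorb fast
states. Mixture presets mirror the measured bound-fraction regimes
(immobile shares 9/19/42/62/85% with mobile modes at 2.5 and 9 µm²/s, the
free remainder split 60/40 toward the slower mode, plus a two-state 37/63%
nuclear-masked regime used by the subsampling control); the split between
the two mobile modes is an assumption, as only the mode positions were
reported.

## Problem sizes and numerical choices

The shipped tests run the subsampling control at its study scale (60,000
simulated trajectories, 20,000-trajectory subsample), mixture recovery at
20,000 trajectories per regime, and mode recovery at 5,000; image assays
use 320–512 px fields with 5–24 cells. Tolerances: likelihood oracle
equivalence to 1e-8 (1e-10 in the sigma → 0 limit); bound-fraction
recovery within 5 percentage points; subsampling stability within 1
percentage point; N/C recovery within 2% at zero noise; lysosome counts
within 10% under default noise. The responsibility update is seeded
end-to-end; ties in the fusion thresholds are resolved by the strict
inequalities exactly as published.

Known limitations: the mixture estimator at the 250-iteration cap leaves
some occupancy spread across the 2–3 grid points bracketing an off-grid
true coefficient (the posterior mode is still within one grid step, and
mass within two grid steps exceeds 90%); the bound fraction carries a
small positive bias (~1–2 points) on mixtures because soft responsibilities
misassign a little fast-state mass below threshold where it escapes the
defocalization upweighting; the LoG spot detector merges puncta closer
than ~2 radii, so generator defaults place puncta without overlap.
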