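"""Tracking and diffusion-spectrum inference: detector/localizer accuracy on
rendered ground truth, linking vs an exhaustive-assignment oracle, RBME
likelihood vs a dense-covariance oracle, the defocalization series vs an
independent PDE eigen-solution and a continuous-boundary Monte-Carlo
sampler, and posterior recovery of simulated mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal, norm

from fusionscope import (AcquisitionSpec, DiffusionModel, LinkConfig,
                         StateGrid, bound_fraction, defocalization_weights,
                         detect_spots_llr, filter_nuclear_trajectories,
                         infer_spectrum, link_conservative, localize_gaussian,
                         make_nuclear_mask, render_movie,
                         simulate_trajectories, state_array_posterior,
                         subsample_stability, track_movie,
                         trajectory_log_likelihoods)


def random_tracks(rng, n_tracks, max_len=10, scale=0.3):
    rows = []
    for tid in range(n_tracks):
        n = int(rng.integers(2, max_len + 1))
        rows.append(pd.DataFrame({
            "movie_id": 0, "trajectory_id": tid, "frame": np.arange(n),
            "x_um": rng.normal(0, scale, n).cumsum(),
            "y_um": rng.normal(0, scale, n).cumsum()}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Detection / localization
# ---------------------------------------------------------------------------

class TestDetection:
    def test_blank_noise_false_positive_rate(self):
        rng = np.random.default_rng(1)
        hits = sum(len(detect_spots_llr(rng.poisson(20, (150, 150)).astype(float)))
                   for _ in range(100))
        assert hits / 100 < 1e-3 * 150 * 150  # far below one per frame

    def test_single_and_double_spot(self, acq):
        loc = pd.DataFrame({"frame": [0, 0],
                            "x_um": np.array([40.0, 50.0]) * acq.pixel_size_um,
                            "y_um": np.array([60.0, 60.0]) * acq.pixel_size_um})
        frame = render_movie(loc, acq, intensity=2000, poisson_noise=False)[0]
        cand = detect_spots_llr(frame)
        assert len(cand) == 2
        assert {tuple(c) for c in cand} == {(60, 40), (60, 50)}

    def test_frame_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            detect_spots_llr(np.zeros((10, 10)), window=15)


class TestLocalization:
    def test_subpixel_recovery(self, acq):
        loc = pd.DataFrame({"frame": [0], "x_um": [30.3 * acq.pixel_size_um],
                            "y_um": [25.2 * acq.pixel_size_um]})
        frame = render_movie(loc, acq, intensity=2000, poisson_noise=False)[0]
        fit = localize_gaussian(frame, [(25, 30)])
        assert fit.loc[0, "converged"]
        assert fit.loc[0, "x_px"] == pytest.approx(30.3, abs=0.05)
        assert fit.loc[0, "y_px"] == pytest.approx(25.2, abs=0.05)

    def test_pixel_center_symmetry(self, acq):
        loc = pd.DataFrame({"frame": [0], "x_um": [40 * acq.pixel_size_um],
                            "y_um": [40 * acq.pixel_size_um]})
        frame = render_movie(loc, acq, intensity=2000, poisson_noise=False)[0]
        fit = localize_gaussian(frame, [(40, 40)])
        assert abs(fit.loc[0, "x_px"] - 40.0) < 1e-3
        assert abs(fit.loc[0, "y_px"] - 40.0) < 1e-3

    def test_flat_window_flagged(self):
        fit = localize_gaussian(np.full((31, 31), 100.0), [(15, 15)])
        assert not fit.loc[0, "converged"]


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def lap_link_oracle(locs: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Exhaustive min-cost assignment per frame pair, gated at the radius."""
    locs = locs.sort_values("frame")
    next_id, prev, out = 0, None, []
    for f, grp in locs.groupby("frame"):
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        ids = np.full(len(xy), -1)
        if prev is not None and f == prev[2] + 1 and len(prev[0]):
            d = np.sqrt(((prev[0][:, None, :] - xy[None, :, :]) ** 2).sum(-1))
            cost = np.where(d <= radius, d, 1e9)
            for a, b in zip(*linear_sum_assignment(cost)):
                if cost[a, b] < 1e9:
                    ids[b] = prev[1][a]
        for i in range(len(xy)):
            if ids[i] < 0:
                ids[i] = next_id
                next_id += 1
        out.append(pd.DataFrame({"trajectory_id": ids, "frame": int(f),
                                 "x_um": xy[:, 0], "y_um": xy[:, 1]}))
        prev = (xy, ids, int(f))
    return pd.concat(out, ignore_index=True)


def partition(df: pd.DataFrame):
    """Trajectory partition as comparable sets of (frame, x, y) points."""
    return sorted(frozenset(zip(g["frame"], np.round(g["x_um"], 9),
                                np.round(g["y_um"], 9)))
                  for _, g in df.groupby("trajectory_id"))


def sparse_movie(seed, n_frames=200, p_detect=0.9):
    """Three well-separated slow molecules confined to home territories."""
    rng = np.random.default_rng(seed)
    centers = np.array([[3.0, 3.0], [12.0, 3.0], [7.5, 12.0]])
    pos = centers.copy()
    rows = []
    for f in range(n_frames):
        pos = pos + rng.normal(0, 0.15, pos.shape)
        pos = centers + np.clip(pos - centers, -2.2, 2.2)
        for (x, y) in pos:
            if rng.uniform() < p_detect:
                rows.append((f, x, y))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


class TestLinking:
    CFG = LinkConfig(start_frame=0)

    def test_single_molecule_single_trajectory(self):
        locs = pd.DataFrame({"frame": np.arange(50),
                             "x_um": 0.3 * np.arange(50), "y_um": 0.0})
        out = link_conservative(locs, self.CFG)
        assert out["trajectory_id"].nunique() == 1 and len(out) == 50

    def test_ambiguity_terminates_trajectory(self):
        # two candidates within radius of one prior point -> no link
        locs = pd.DataFrame({"frame": [0, 1, 1],
                             "x_um": [0.0, 0.3, -0.3], "y_um": [0.0, 0.0, 0.0]})
        out = link_conservative(locs, self.CFG)
        assert out["trajectory_id"].nunique() == 3

    def test_overdense_frame_excluded(self):
        rows = [(0, 0.0, 0.0)]
        rows += [(1, 5.0 + 2 * i, 5.0) for i in range(8)]  # 8 > max 7
        rows += [(2, 0.05, 0.0)]
        out = link_conservative(pd.DataFrame(rows, columns=["frame", "x_um",
                                                            "y_um"]), self.CFG)
        assert 1 not in set(out["frame"])          # frame dropped entirely
        assert out["trajectory_id"].nunique() == 2  # no gap closing across it

    def test_empty_input(self):
        out = link_conservative(pd.DataFrame(columns=["frame", "x_um", "y_um"]))
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_assignment_oracle_on_sparse_movies(self, seed):
        locs = sparse_movie(seed)
        mine = link_conservative(locs, self.CFG)
        oracle = lap_link_oracle(locs, self.CFG.search_radius_um)
        assert partition(mine) == partition(oracle)


class TestTrackMovie:
    def test_end_to_end_on_rendered_movie(self):
        acq = AcquisitionSpec(roi_px=96)
        rng = np.random.default_rng(5)
        truth = []
        for tid, (cx, cy) in enumerate([(4.0, 4.0), (11.0, 11.0)]):
            x, y = cx, cy
            for f in range(40):
                truth.append((f, x, y))
                x += rng.normal(0, 0.08)
                y += rng.normal(0, 0.08)
        locs = pd.DataFrame(truth, columns=["frame", "x_um", "y_um"])
        stack = render_movie(locs, acq, intensity=3000, poisson_noise=False)
        out = track_movie(stack, LinkConfig(start_frame=0))
        assert out["trajectory_id"].nunique() == 2
        assert len(out) == 80


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

class TestNuclearMask:
    def _snapshot(self, invert=False):
        img = np.full((96, 96), 60.0)
        yy, xx = np.mgrid[:96, :96]
        circle = ((yy - 48) ** 2 + (xx - 44) ** 2) < 28 ** 2
        img[circle] = 900.0
        return (img.max() - img if invert else img), circle

    def test_mask_brackets_truth(self):
        img, circle = self._snapshot()
        mask = make_nuclear_mask(img)
        from scipy import ndimage as ndi
        eroded = ndi.binary_erosion(circle, iterations=4)
        dilated = ndi.binary_dilation(circle, iterations=2)
        assert mask[eroded].sum() >= 0.8 * eroded.sum()
        assert not mask[~dilated].any()

    def test_uniform_image_empty_mask(self):
        assert not make_nuclear_mask(np.full((64, 64), 10.0)).any()

    def test_polarity_autocorrect(self):
        up, _ = self._snapshot()
        down, _ = self._snapshot(invert=True)
        np.testing.assert_array_equal(make_nuclear_mask(up),
                                      make_nuclear_mask(down))


class TestFilterNuclearTrajectories:
    def test_excursion_drops_whole_trajectory(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:80, 20:80] = True
        px = 0.16
        inside = pd.DataFrame({"movie_id": 0, "trajectory_id": 0,
                               "frame": [0, 1, 2],
                               "x_um": np.array([30, 31, 32]) * px,
                               "y_um": np.array([30, 30, 30]) * px})
        excursion = pd.DataFrame({"movie_id": 0, "trajectory_id": 1,
                                  "frame": [0, 1, 2],
                                  "x_um": np.array([30, 31, 5]) * px,
                                  "y_um": np.array([30, 30, 30]) * px})
        tracks = pd.concat([inside, excursion], ignore_index=True)
        kept = filter_nuclear_trajectories(tracks, mask, px)
        assert set(kept["trajectory_id"]) == {0}

    def test_agrees_with_per_point_brute_force(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:50, 15:55] = True
        px = 0.16
        tracks = random_tracks(rng, 40, scale=1.0)
        tracks[["x_um", "y_um"]] += 5.0
        kept = filter_nuclear_trajectories(tracks, mask, px)
        for tid, g in tracks.groupby("trajectory_id"):
            ok = all(0 <= int(y / px) < 64 and 0 <= int(x / px) < 64
                     and mask[int(y / px), int(x / px)]
                     for x, y in zip(g["x_um"], g["y_um"]))
            assert (tid in set(kept["trajectory_id"])) == ok


# ---------------------------------------------------------------------------
# RBME likelihood
# ---------------------------------------------------------------------------

class TestLikelihood:
    def test_tridiagonal_equals_dense_covariance(self, coarse_grid):
        rng = np.random.default_rng(11)
        tracks = random_tracks(rng, 30)
        ll, ids, lengths = trajectory_log_likelihoods(tracks, coarse_grid)
        sig2 = coarse_grid.loc_error_um ** 2
        dt = coarse_grid.frame_interval_s
        for i, (mid, tid) in enumerate(ids):
            g = tracks[tracks["trajectory_id"] == tid]
            dx, dy = np.diff(g["x_um"]), np.diff(g["y_um"])
            n = len(dx)
            for j, D in enumerate(coarse_grid.d_values):
                C = (np.diag(np.full(n, 2 * D * dt + 2 * sig2))
                     + np.diag(np.full(n - 1, -sig2), 1)
                     + np.diag(np.full(n - 1, -sig2), -1))
                ref = (multivariate_normal.logpdf(dx, cov=C)
                       + multivariate_normal.logpdf(dy, cov=C))
                assert ll[i, j] == pytest.approx(ref, abs=1e-8)

    def test_sigma_zero_reduces_to_independent_jumps(self):
        grid = StateGrid(d_values=np.geomspace(1e-2, 1e2, 8),
                         loc_error_um=0.0, infer_start_frame=0)
        rng = np.random.default_rng(12)
        tracks = random_tracks(rng, 10)
        ll, ids, _ = trajectory_log_likelihoods(tracks, grid)
        dt = grid.frame_interval_s
        for i, (mid, tid) in enumerate(ids):
            g = tracks[tracks["trajectory_id"] == tid]
            dx, dy = np.diff(g["x_um"]), np.diff(g["y_um"])
            for j, D in enumerate(grid.d_values):
                s = np.sqrt(2 * D * dt)
                ref = norm.logpdf(dx, scale=s).sum() + norm.logpdf(dy, scale=s).sum()
                assert ll[i, j] == pytest.approx(ref, abs=1e-10)

    def test_single_jump_equals_independent_form(self, coarse_grid):
        tracks = pd.DataFrame({"movie_id": 0, "trajectory_id": 0,
                               "frame": [0, 1], "x_um": [0.0, 0.1],
                               "y_um": [0.0, -0.05]})
        ll, _, _ = trajectory_log_likelihoods(tracks, coarse_grid)
        dt = coarse_grid.frame_interval_s
        sig2 = coarse_grid.loc_error_um ** 2
        for j, D in enumerate(coarse_grid.d_values):
            s = np.sqrt(2 * D * dt + 2 * sig2)
            ref = norm.logpdf(0.1, scale=s) + norm.logpdf(-0.05, scale=s)
            assert ll[0, j] == pytest.approx(ref, abs=1e-10)

    def test_nonfinite_coordinates_rejected(self, coarse_grid):
        tracks = pd.DataFrame({"movie_id": 0, "trajectory_id": 0,
                               "frame": [0, 1], "x_um": [0.0, np.nan],
                               "y_um": [0.0, 0.0]})
        with pytest.raises(ValueError):
            trajectory_log_likelihoods(tracks, coarse_grid)


# ---------------------------------------------------------------------------
# Defocalization
# ---------------------------------------------------------------------------

class TestDefocalization:
    def test_zero_diffusion_weight_one(self):
        g0 = StateGrid(d_values=np.array([0.0, 0.05, 1.0]))
        for length in (1, 5, 50):
            assert defocalization_weights(g0, length)[0] == 1.0

    def test_monotone_in_d_and_length(self, grid):
        w1 = defocalization_weights(grid, 1)
        w5 = defocalization_weights(grid, 5)
        assert np.all(np.diff(w1) < 1e-12)   # decreasing in D
        assert np.all(w5 <= w1 + 1e-12)      # decreasing in track length

    def test_series_matches_pde_eigen_solution(self):
        # independent oracle: eigen-decomposition of the discrete Laplacian
        # on the absorbing slab, survival from a uniform start
        D, L, dt = 2.5, 0.7, 0.00748
        N = 4000
        h = L / (N + 1)
        lam = 4 * D / h ** 2 * np.sin(np.arange(1, N + 1) * np.pi
                                      / (2 * (N + 1))) ** 2
        S = 0.0
        for k in range(1, 200):
            a2 = (np.sqrt(2 / L) * L / (k * np.pi) * (1 - np.cos(k * np.pi))) ** 2
            S += a2 / L * np.exp(-lam[k - 1] * dt)
        g = StateGrid(d_values=np.array([1e-2, 2.5, 1e2]))
        w = defocalization_weights(g, 1)[1]
        assert w == pytest.approx(S, abs=1e-5)

    def test_series_matches_continuous_monte_carlo(self):
        # continuous-boundary z-walk sampler, written independently here
        rng = np.random.default_rng(21)
        D, L, dt, n = 2.5, 0.7, 0.00748, 200_000
        z0 = rng.uniform(0, L, n)
        z1 = z0 + rng.normal(0, np.sqrt(2 * D * dt), n)
        inside = (z1 > 0) & (z1 < L)
        p_lo = np.exp(-z0 * z1 / (D * dt))
        p_hi = np.exp(-(L - z0) * (L - z1) / (D * dt))
        survive = inside & (rng.uniform(size=n) > p_lo) \
            & (rng.uniform(size=n) > p_hi)
        s_mc = survive.mean()
        se = np.sqrt(s_mc * (1 - s_mc) / n)
        g = StateGrid(d_values=np.array([1e-2, 2.5, 1e2]))
        assert defocalization_weights(g, 1)[1] == pytest.approx(s_mc, abs=3 * se)

    def test_simulator_truncation_follows_series(self, acq):
        # observable-track fractions from the simulator factorize into the
        # slab-survival series times the geometric bleaching survival
        bleach = 30.0
        model = DiffusionModel(state_D_um2s=(2.5,), state_occupancy=(1.0,),
                               loc_error_um=0.0, bleach_mean_frames=bleach)
        n = 20_000
        _, truth = simulate_trajectories(model, acq, n, seed=22)
        g = StateGrid(d_values=np.array([1e-2, 2.5, 1e2]))
        for k in (1, 2, 3):
            frac = (truth["n_positions"] > k).mean()
            s = defocalization_weights(g, k)[1] * (1 - 1 / bleach) ** k
            se = np.sqrt(s * (1 - s) / n)
            assert frac == pytest.approx(s, abs=4 * se)


# ---------------------------------------------------------------------------
# Posterior and bound fraction
# ---------------------------------------------------------------------------

class TestPosterior:
    def test_two_equal_likelihood_states_split_evenly(self):
        grid = StateGrid(d_values=np.array([0.01, 1.0]))
        ll = np.tile(np.array([[-3.0, -3.0]]), (50, 1))
        spec = state_array_posterior(ll, grid)
        assert spec.occupancy == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_empty_input_rejected(self, grid):
        with pytest.raises(ValueError):
            state_array_posterior(np.empty((0, 5)), grid)

    def test_single_state_concentrates(self, acq, grid):
        model = DiffusionModel(state_D_um2s=(1.0,), state_occupancy=(1.0,))
        tracks, _ = simulate_trajectories(model, acq, 3000, seed=23)
        spec = infer_spectrum(tracks, grid, seed=1)
        mode_idx = int(np.argmax(spec.occupancy))
        window = spec.occupancy[max(0, mode_idx - 2):mode_idx + 3].sum()
        assert window >= 0.9
        assert abs(np.log10(spec.d_values[mode_idx])) < 2 * np.log10(
            grid.d_values[1] / grid.d_values[0])

    def test_occupancies_normalized(self, acq, grid):
        tracks, _ = simulate_trajectories(DiffusionModel(), acq, 2000, seed=24)
        spec = infer_spectrum(tracks, grid, seed=2)
        assert spec.occupancy.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.occupancy >= 0)

    def test_defocalization_correction_reduces_fast_state_bias(self, acq, grid):
        model = DiffusionModel(state_D_um2s=(0.01, 9.0),
                               state_occupancy=(0.5, 0.5))
        tracks, _ = simulate_trajectories(model, acq, 15_000, seed=25)
        corr = infer_spectrum(tracks, grid, seed=3)
        naive = infer_spectrum(tracks, grid, seed=3, apply_defocalization=False)
        fast_true = 0.5
        fast = lambda s: s.occupancy[s.d_values > 1.0].sum()
        assert abs(fast(corr) - fast_true) < abs(fast(naive) - fast_true)


class TestBoundFraction:
    def test_pure_states(self):
        grid = StateGrid(d_values=np.array([0.01, 2.5]))
        lo = state_array_posterior(np.tile([[0.0, -50.0]], (20, 1)), grid)
        hi = state_array_posterior(np.tile([[-50.0, 0.0]], (20, 1)), grid)
        assert bound_fraction(lo) == pytest.approx(1.0, abs=1e-6)
        assert bound_fraction(hi) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_threshold(self, acq, grid):
        tracks, _ = simulate_trajectories(DiffusionModel(), acq, 2000, seed=26)
        spec = infer_spectrum(tracks, grid, seed=4)
        vals = [bound_fraction(spec, t) for t in (0.03, 0.1, 0.3, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_subsample_identity_is_zero(self, acq, grid):
        tracks, _ = simulate_trajectories(DiffusionModel(), acq, 1500, seed=27)
        assert subsample_stability(tracks, grid, n_subsample=10 ** 9,
                                   seed=0) == 0.0
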