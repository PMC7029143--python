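"""Motion simulator and movie renderer against closed-form oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from memfoci import (ImagingConfig, render_movie, simulate_cell_population,
                     simulate_trajectory, wt_scenario, write_ground_truth,
                     read_ground_truth, compute_msd)
from memfoci.config import MotionModelParams
from memfoci.simulate import CellFootprint, place_cells


@pytest.mark.parametrize("model", ["directed", "random", "confined", "blended"])
def test_zero_motion_stays_at_start(model):
    params = MotionModelParams(model=model, D=0.0, v=0.0)
    xy = simulate_trajectory(params, 20, 0.1, seed=1, start=(1.0, 2.0))
    assert np.allclose(xy, [1.0, 2.0])


def test_directed_end_to_end_distance_is_v_n_dt():
    params = MotionModelParams(model="directed", v=0.4, D=0.0)
    xy = simulate_trajectory(params, 31, 0.1, seed=5)
    assert np.linalg.norm(xy[-1] - xy[0]) == pytest.approx(1.2, abs=1e-9)


def test_brownian_single_step_msd_matches_4_D_dt():
    params = MotionModelParams(model="random", D=0.02)
    xy = simulate_trajectory(params, 100_001, 0.1, seed=2)
    steps = np.diff(xy, axis=0)
    msd1 = float((steps ** 2).sum(axis=1).mean())
    assert msd1 == pytest.approx(4 * 0.02 * 0.1, rel=0.01)


def test_brownian_ensemble_msd_linear_at_every_lag():
    params = MotionModelParams(model="random", D=0.02)
    rng = np.random.default_rng(3)
    curves = [compute_msd(simulate_trajectory(params, 40, 0.1, seed=rng), 0.1)
              for _ in range(400)]
    mean_msd = np.mean([c.msd_um2 for c in curves], axis=0)
    expected = 4 * 0.02 * curves[0].lags_s
    # Monte-Carlo error grows with lag; 10 % covers it at n=400 tracks
    assert np.allclose(mean_msd, expected, rtol=0.10)


def test_confined_plateau_equals_domain_radius_squared():
    """Uniform points on a disc of radius R have E|r1-r2|^2 = R^2, so the
    long-lag MSD of non-escaping confined motion plateaus at R^2."""
    R = 0.15
    params = MotionModelParams(model="confined", D=0.05, domain_radius_um=R,
                               dwell_shape=2.0, dwell_scale_s=1e9)
    rng = np.random.default_rng(4)
    msd_long = []
    for _ in range(150):
        xy = simulate_trajectory(params, 300, 0.1, seed=rng)
        curve = compute_msd(xy, 0.1)
        msd_long.append(curve.msd_um2[100:200].mean())
    # brute-force disc oracle
    pts = rng.uniform(-R, R, (200_000, 2))
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= R][:50_000]
    oracle = float(((pts[::2][:20_000] - pts[1::2][:20_000]) ** 2).sum(1).mean())
    assert oracle == pytest.approx(R ** 2, rel=0.02)
    assert np.mean(msd_long) == pytest.approx(oracle, rel=0.10)


def test_unknown_model_and_bad_dt_rejected():
    with pytest.raises(ValueError):
        MotionModelParams(model="hovering")
    with pytest.raises(ValueError):
        simulate_trajectory(MotionModelParams(model="random", D=0.01), 10, -0.1)
    with pytest.raises(ValueError):
        simulate_trajectory(MotionModelParams(model="random", D=0.01), 1, 0.1)


def test_same_seed_gives_identical_trajectories():
    p = MotionModelParams(model="blended", D=0.02, v=0.4)
    a = simulate_trajectory(p, 50, 0.1, seed=77)
    b = simulate_trajectory(p, 50, 0.1, seed=77)
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# cell population

def test_footprint_area_matches_capsule_formula():
    cell = CellFootprint(1, (5.0, 5.0), 30.0, 4.0, 0.9)
    expected = 3.1 * 0.9 + math.pi * 0.45 ** 2
    assert cell.area_um2 == pytest.approx(expected)
    assert cell.area_um2 == pytest.approx(3.426, abs=0.01)


def test_zero_density_yields_no_foci(imaging_small):
    scen = wt_scenario(focus_density_per_um2=0.0, n_cells=2)
    truth, cells = simulate_cell_population(scen, imaging_small, seed=1)
    assert len(truth) == 0
    assert len(cells) == 2


def test_expected_foci_per_frame_matches_density_times_area(imaging_small):
    scen = wt_scenario(n_cells=1)
    per_frame = []
    for seed in range(40):
        truth, cells = simulate_cell_population(scen, imaging_small, seed=seed)
        per_frame.append(len(truth) / imaging_small.frames)
    expected = 0.3 * CellFootprint(1, (0, 0), 0, 4.0, 0.9).area_um2
    assert np.mean(per_frame) == pytest.approx(expected, rel=0.15)


def test_pure_mixture_gives_single_class(imaging_small):
    scen = wt_scenario(class_mixture={"confined": 1.0}, n_cells=2)
    truth, _ = simulate_cell_population(scen, imaging_small, seed=3)
    assert set(truth["motion_class"]) == {"confined"}


def test_class_mixture_converges_chi_square():
    """Generated class counts follow the configured mixture (alpha=0.01)."""
    scen = wt_scenario()
    rng = np.random.default_rng(9)
    mix = scen.class_mixture
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    counts = rng.multinomial(10_000, probs)  # what the generator draws from
    # and the generator's own draws on a large population
    imaging = ImagingConfig(image_shape=(512, 512), frames=40)
    big = wt_scenario(n_cells=20, focus_density_per_um2=1.5)
    truth, _ = simulate_cell_population(big, imaging, seed=10)
    per_focus = truth.drop_duplicates("focus_id")["motion_class"]
    observed = per_focus.value_counts().reindex(classes, fill_value=0).to_numpy()
    stat, p = stats.chisquare(observed, observed.sum() * probs)
    assert p > 0.01
    assert counts.sum() == 10_000


def test_positions_stay_inside_owning_cell(imaging_small):
    scen = wt_scenario(n_cells=3)
    truth, cells = simulate_cell_population(scen, imaging_small, seed=11)
    by_label = {c.label: c for c in cells}
    for label, sub in truth.groupby("cell_label"):
        cell = by_label[label]
        xy = sub[["x_um", "y_um"]].to_numpy()
        d = cell._dist_to_axis(xy)
        assert (d <= cell.width_um / 2 + 1e-9).all()


def test_cell_too_large_for_field_raises():
    scen = wt_scenario(cell_length_um=20.0, cell_width_um=0.9, n_cells=1)
    imaging = ImagingConfig(image_shape=(64, 64))
    with pytest.raises(ValueError):
        place_cells(scen, imaging, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# rendering

def test_background_is_poisson_mean_equals_variance():
    imaging = ImagingConfig(image_shape=(64, 64), frames=200,
                            background_level=100.0, read_noise_sd=0.0)
    import pandas as pd
    from memfoci.simulate import GROUND_TRUTH_COLUMNS
    empty = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    movie, _ = render_movie(empty, imaging, seed=1)
    stack = movie.astype(float)
    assert stack.mean() == pytest.approx(100.0, rel=0.01)
    assert stack.var() == pytest.approx(100.0, rel=0.05)


def test_noise_free_spot_integrates_to_gaussian_volume():
    """Summed counts above background match the Gaussian volume
    a * 2*pi*sigma^2 (averaged over frames to beat shot noise)."""
    import pandas as pd
    imaging = ImagingConfig(image_shape=(64, 64), frames=200,
                            background_level=0.0, read_noise_sd=0.0,
                            bleach_rate_per_s=0.0)
    amp = 500.0
    sigma_px = imaging.psf_sigma_um / imaging.pixel_size_um
    truth = pd.DataFrame({
        "focus_id": 1, "cell_label": 1, "motion_class": "confined",
        "D_um2_s": 0.0, "v_um_s": 0.0, "dwell_time_s": 1.0,
        "domain_radius_um": 0.15, "frame": np.arange(200),
        "x_um": 2.048, "y_um": 2.048, "amplitude": amp})
    movie, _ = render_movie(truth, imaging, seed=2)
    per_frame_total = movie.astype(float).sum() / len(movie)
    assert per_frame_total == pytest.approx(
        amp * 2 * math.pi * sigma_px ** 2, rel=0.01)


def test_photobleaching_decay_ratio():
    import pandas as pd
    imaging = ImagingConfig(image_shape=(32, 32), frames=200,
                            background_level=0.0, read_noise_sd=0.0,
                            bleach_rate_per_s=0.02)
    frames = np.arange(200)
    truth = pd.DataFrame({
        "focus_id": 1, "cell_label": 1, "motion_class": "confined",
        "D_um2_s": 0.0, "v_um_s": 0.0, "dwell_time_s": 1.0,
        "domain_radius_um": 0.15, "frame": frames,
        "x_um": 1.024, "y_um": 1.024, "amplitude": 2000.0})
    movie, _ = render_movie(truth, imaging, seed=3)
    first = movie[0].astype(float).sum()
    last = movie[-1].astype(float).sum()
    # Poisson noise on ~26k photons: ~1 % fluctuation
    assert last / first == pytest.approx(math.exp(-0.02 * 199 * 0.1), rel=0.03)


def test_same_seed_renders_identical_movie(imaging_small):
    scen = wt_scenario(n_cells=2)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        truth, cells = simulate_cell_population(scen, imaging_small, rng)
        movie, bf = render_movie(truth, imaging_small, rng, cells=cells)
        out.append((truth, movie, bf))
    assert out[0][0].equals(out[1][0])
    assert np.array_equal(out[0][1], out[1][1])
    assert np.array_equal(out[0][2], out[1][2])


# ---------------------------------------------------------------------------
# ground-truth I/O

def test_ground_truth_round_trip(tmp_path, imaging_small):
    scen = wt_scenario(n_cells=2)
    truth, _ = simulate_cell_population(scen, imaging_small, seed=8)
    path = tmp_path / "truth.csv"
    write_ground_truth(truth, path)
    back = read_ground_truth(path)
    assert len(back) == len(truth)
    assert np.allclose(back["x_um"], truth["x_um"])
    assert list(back["motion_class"]) == list(truth["motion_class"])


def test_empty_ground_truth_writes_header_only(tmp_path):
    import pandas as pd
    from memfoci.simulate import GROUND_TRUTH_COLUMNS
    path = tmp_path / "empty.csv"
    write_ground_truth(pd.DataFrame(columns=GROUND_TRUTH_COLUMNS), path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1
    assert lines[0].split(",") == GROUND_TRUTH_COLUMNS


def test_ground_truth_row_count_is_foci_times_frames(tmp_path):
    import pandas as pd
    rows = []
    for fid in range(3):
        for f in range(5):
            rows.append((fid, 1, "random", 0.02, 0.0, np.nan, np.nan,
                         f, 1.0, 1.0, 500.0))
    from memfoci.simulate import GROUND_TRUTH_COLUMNS
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    path = tmp_path / "t.csv"
    write_ground_truth(truth, path)
    assert len(path.read_text().strip().splitlines()) == 16  # header + 15
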