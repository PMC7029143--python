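"""Ground-truthed simulation of membrane-focus motion and TIRF-like imaging.

The generator produces (i) per-focus trajectories under four motion models
(directed, random/Brownian, confined-then-escape, blended two-state), (ii) a
population of rod-shaped cells carrying foci that appear and disappear with
exponential lifetimes, and (iii) rendered movies: each focus is a 2D Gaussian
of PSF width whose amplitude decays by photobleaching, on a Poisson photon
background with additive Gaussian read noise.  A matching bright-field-like
image (cells darker than the background) supports segmentation.

Motion is simulated in the 2D TIRF plane; membrane curvature is ignored
because every downstream measurement is a 2D projection.

Coordinate convention: positions are in micrometres with x along image
columns and y along rows; the centre of pixel ``(r, c)`` is at
``((c + 0.5) * pixel, (r + 0.5) * pixel)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import ImagingConfig, MotionModelParams, ScenarioConfig

GROUND_TRUTH_COLUMNS = [
    "focus_id", "cell_label", "motion_class", "D_um2_s", "v_um_s",
    "dwell_time_s", "domain_radius_um", "frame", "x_um", "y_um", "amplitude",
]


# ---------------------------------------------------------------------------
# rod-shaped cell footprints

@dataclass(frozen=True)
class CellFootprint:
    """A rod (rectangle with semicircular caps): all points within
    ``width/2`` of the central axis segment of length ``length - width``."""

    label: int
    center_um: tuple[float, float]  # (x, y)
    angle_deg: float                # axis angle to the horizontal
    length_um: float
    width_um: float

    @property
    def area_um2(self) -> float:
        w = self.width_um
        return (self.length_um - w) * w + math.pi * (w / 2.0) ** 2

    def _axis(self) -> tuple[np.ndarray, np.ndarray, float]:
        theta = math.radians(self.angle_deg)
        u = np.array([math.cos(theta), math.sin(theta)])
        c = np.asarray(self.center_um)
        half = (self.length_um - self.width_um) / 2.0
        return c, u, half

    def _dist_to_axis(self, xy: np.ndarray) -> np.ndarray:
        """Distance from points (…, 2) to the central axis segment."""
        c, u, half = self._axis()
        rel = np.atleast_2d(xy) - c
        t = np.clip(rel @ u, -half, half)
        foot = np.outer(t, u)
        return np.linalg.norm(rel - foot, axis=-1)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        return self._dist_to_axis(xy) <= self.width_um / 2.0

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Mirror a point that stepped outside back across the boundary."""
        p = np.asarray(xy, dtype=float)
        r = self.width_um / 2.0
        for _ in range(8):
            c, u, half = self._axis()
            rel = p - c
            t = float(np.clip(rel @ u, -half, half))
            foot = c + t * u
            d = float(np.linalg.norm(p - foot))
            if d <= r:
                return p
            n = (p - foot) / d
            p = foot + (2.0 * r - d) * n
        # pathological overshoot: clamp to the boundary
        return foot + r * n

    def sample_point(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform point inside the footprint (rejection in the bounding box)."""
        c, u, half = self._axis()
        r = self.width_um / 2.0
        ext = half + r
        while True:
            t = rng.uniform(-ext, ext)
            w = rng.uniform(-r, r)
            p = c + t * u + w * np.array([-u[1], u[0]])
            if self.contains(p)[0]:
                return p

    def rasterize(self, imaging: ImagingConfig) -> np.ndarray:
        """Boolean mask of pixels whose centres fall inside the footprint."""
        h, wd = imaging.image_shape
        px = imaging.pixel_size_um
        rows, cols = np.mgrid[0:h, 0:wd]
        xy = np.stack([(cols + 0.5) * px, (rows + 0.5) * px], axis=-1)
        return self.contains(xy.reshape(-1, 2)).reshape(h, wd)


def _segment_distance(p1, u1, h1, p2, u2, h2, n_samples: int = 9) -> float:
    """Approximate min distance between two segments by dense sampling."""
    t = np.linspace(-1.0, 1.0, n_samples)
    a = p1 + np.outer(t * h1, u1)
    b = p2 + np.outer(t * h2, u2)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def place_cells(scenario: ScenarioConfig, imaging: ImagingConfig,
                rng: np.random.Generator, margin_um: float = 0.5,
                max_attempts: int = 2000) -> list[CellFootprint]:
    """Random sequential placement of non-overlapping rods, fully interior.

    Raises ``ValueError`` if not even one cell fits the field.
    """
    fh, fw = imaging.field_um
    L, W = scenario.cell_length_um, scenario.cell_width_um
    half_diag = L / 2.0
    if 2 * (half_diag + margin_um) > min(fh, fw):
        raise ValueError("cell footprint cannot fit in image_shape")
    placed: list[CellFootprint] = []
    axes = []
    attempts = 0
    while len(placed) < scenario.n_cells and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(half_diag + margin_um, fw - half_diag - margin_um)
        y = rng.uniform(half_diag + margin_um, fh - half_diag - margin_um)
        ang = rng.uniform(-90.0, 90.0)
        cand = CellFootprint(len(placed) + 1, (x, y), ang, L, W)
        c, u, half = cand._axis()
        ok = all(_segment_distance(c, u, half, c2, u2, h2) > W + 0.3
                 for (c2, u2, h2) in axes)
        if ok:
            placed.append(cand)
            axes.append((c, u, half))
    return placed


# ---------------------------------------------------------------------------
# trajectory simulation

def _brownian_step(D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    if D <= 0:
        return np.zeros(2)
    return rng.normal(0.0, math.sqrt(2.0 * D * dt), size=2)


def _simulate_steps(params: MotionModelParams, n_frames: int, dt: float,
                    rng: np.random.Generator, start: np.ndarray,
                    cell: CellFootprint | None = None,
                    dwell_s: float | None = None) -> np.ndarray:
    """Core stepper shared by the standalone and in-cell simulators.

    Confined motion is reflected both at its own domain boundary (while the
    gamma-distributed dwell lasts) and, when a cell footprint is given, at
    the cell boundary.  Returns an (n_frames, 2) array of positions in um.
    """
    pos = np.empty((n_frames, 2))
    pos[0] = start

    def clamp(p: np.ndarray) -> np.ndarray:
        return cell.reflect(p) if cell is not None else p

    if params.model == "directed":
        theta = rng.uniform(0.0, 2.0 * math.pi)
        head = np.array([math.cos(theta), math.sin(theta)])
        for i in range(1, n_frames):
            step = params.v * dt * head + _brownian_step(params.D, dt, rng)
            pos[i] = clamp(pos[i - 1] + step)
    elif params.model == "random":
        for i in range(1, n_frames):
            pos[i] = clamp(pos[i - 1] + _brownian_step(params.D, dt, rng))
    elif params.model == "confined":
        dwell = rng.gamma(params.dwell_shape, params.dwell_scale_s) \
            if dwell_s is None else dwell_s
        R = params.domain_radius_um
        center = pos[0].copy()
        # reflected Brownian motion needs sub-frame steps much smaller than
        # the domain, or the sampled stationary distribution is biased
        # toward the interior and the MSD plateau undershoots R^2
        step_sd = math.sqrt(2.0 * max(params.D, 1e-300) * dt)
        n_sub = max(1, math.ceil((3.0 * step_sd / R) ** 2))
        for i in range(1, n_frames):
            if i * dt <= dwell:
                p = pos[i - 1]
                for _ in range(n_sub):
                    p = p + _brownian_step(params.D, dt / n_sub, rng)
                    d = np.linalg.norm(p - center)
                    if d > R:
                        p = center + (p - center) / d * max(2.0 * R - d, 0.0)
            else:
                p = pos[i - 1] + _brownian_step(params.D, dt, rng)
            pos[i] = clamp(p)
    elif params.model == "blended":
        p_switch = 1.0 - math.exp(-params.switch_rate_per_s * dt)
        state_directed = rng.random() < 0.5
        theta = rng.uniform(0.0, 2.0 * math.pi)
        head = np.array([math.cos(theta), math.sin(theta)])
        for i in range(1, n_frames):
            if rng.random() < p_switch:
                state_directed = not state_directed
                if state_directed:
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    head = np.array([math.cos(theta), math.sin(theta)])
            if state_directed:
                step = params.v * dt * head
            else:
                step = _brownian_step(params.D, dt, rng)
            pos[i] = clamp(pos[i - 1] + step)
    else:  # pragma: no cover - guarded by MotionModelParams
        raise ValueError(f"unknown motion model {params.model!r}")
    return pos


def simulate_trajectory(params: MotionModelParams, n_frames: int, dt: float,
                        seed: int | np.random.Generator | None = 0,
                        start: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Simulate one trajectory; returns (n_frames, 2) positions in um.

    Deterministic for a given integer ``seed``; pass a ``Generator`` to
    draw from an existing random stream.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return _simulate_steps(params, n_frames, dt, rng, np.asarray(start, float))


# ---------------------------------------------------------------------------
# cell population with appearing/disappearing foci

def simulate_cell_population(
        scenario: ScenarioConfig, imaging: ImagingConfig,
        seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[CellFootprint]]:
    """Simulate foci in a field of rod-shaped cells.

    Focus turnover is a stationary birth-death process: each cell starts
    with Poisson(density * area) foci and gains new ones at rate
    ``density * area / lifetime`` so the expected concurrent count stays at
    the scenario density; lifetimes are exponential.  Classes are drawn
    from the scenario mixture and positions stay inside the owning cell
    (reflecting boundary).

    Returns the ground-truth table (one row per focus per frame; see
    ``GROUND_TRUTH_COLUMNS``) and the list of cell footprints.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(scenario.seed if seed is None else seed)
    cells = place_cells(scenario, imaging, rng)
    dt = imaging.frame_interval_s
    T = imaging.duration_s
    tau = scenario.focus_lifetime_mean_s
    classes = sorted(scenario.class_mixture)
    probs = np.array([scenario.class_mixture[c] for c in classes])

    rows: list[tuple] = []
    focus_id = 0
    for cell in cells:
        n_expected = scenario.focus_density_per_um2 * cell.area_um2
        if n_expected <= 0:
            continue
        # birth times: initial cohort at t<=0 plus Poisson arrivals on (0, T]
        births = [0.0] * rng.poisson(n_expected)
        births += list(rng.uniform(0.0, T, rng.poisson(n_expected / tau * T)))
        for t0 in births:
            life = rng.exponential(tau)
            f_start = max(0, math.ceil(t0 / dt - 1e-9))
            f_end = min(imaging.frames - 1, math.floor((t0 + life) / dt))
            n = f_end - f_start + 1
            if n < 1:
                continue
            model = classes[rng.choice(len(classes), p=probs)]
            params = scenario.params_per_class[model]
            start = cell.sample_point(rng)
            dwell = rng.gamma(params.dwell_shape, params.dwell_scale_s) \
                if model == "confined" else np.nan
            if n == 1:
                pos = start[None, :]
            else:
                pos = _simulate_steps(params, n, dt, rng, start, cell=cell,
                                      dwell_s=dwell if model == "confined" else None)
            focus_id += 1
            amp = (scenario.amplitude_photons * scenario.intensity_multiplier
                   * rng.lognormal(0.0, 0.2))
            radius = params.domain_radius_um if model == "confined" else np.nan
            for k in range(n):
                rows.append((focus_id, cell.label, model, params.D, params.v,
                             dwell, radius, f_start + k,
                             pos[k, 0], pos[k, 1], amp))
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return truth, cells


# ---------------------------------------------------------------------------
# rendering

def _add_gaussian(frame: np.ndarray, x_px: float, y_px: float,
                  amplitude: float, sigma_px: float) -> None:
    """Accumulate a 2D Gaussian peak into ``frame`` (patch-local, in place)."""
    h, w = frame.shape
    rad = int(math.ceil(4.0 * sigma_px)) + 2
    r0 = max(0, int(y_px) - rad)
    r1 = min(h, int(y_px) + rad + 1)
    c0 = max(0, int(x_px) - rad)
    c1 = min(w, int(x_px) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (cc + 0.5 - x_px) ** 2 + (rr + 0.5 - y_px) ** 2
    frame[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * sigma_px ** 2))


def render_movie(truth: pd.DataFrame, imaging: ImagingConfig,
                 seed: int | np.random.Generator | None = 0,
                 cells: list[CellFootprint] | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render the fluorescence movie and a bright-field-like image.

    Per frame: expected photons = background + sum of focus Gaussians with
    amplitude ``A * exp(-bleach_rate * t)``; observed = Poisson(expected)
    + N(0, read_noise), clipped at zero, as uint16.  The bright-field image
    shows cells ~30 % darker than its background.  Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    h, w = imaging.image_shape
    px = imaging.pixel_size_um
    sigma_px = imaging.psf_sigma_um / px
    fh, fw = imaging.field_um
    if len(truth) and ((truth["x_um"] < 0).any() or (truth["y_um"] < 0).any()
                       or (truth["x_um"] > fw).any() or (truth["y_um"] > fh).any()):
        raise ValueError("ground-truth coordinates outside the field of view")

    movie = np.empty((imaging.frames, h, w), dtype=np.uint16)
    by_frame = dict(iter(truth.groupby("frame"))) if len(truth) else {}
    for f in range(imaging.frames):
        expected = np.full((h, w), float(imaging.background_level))
        decay = math.exp(-imaging.bleach_rate_per_s * f * imaging.frame_interval_s)
        sub = by_frame.get(f)
        if sub is not None:
            for x, y, amp in zip(sub["x_um"], sub["y_um"], sub["amplitude"]):
                _add_gaussian(expected, x / px, y / px, amp * decay, sigma_px)
        frame = rng.poisson(expected).astype(float)
        if imaging.read_noise_sd > 0:
            frame += rng.normal(0.0, imaging.read_noise_sd, size=frame.shape)
        movie[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)

    bf = np.full((h, w), 1000.0)
    if cells:
        from scipy.ndimage import gaussian_filter
        mask = np.zeros((h, w), dtype=bool)
        for cell in cells:
            mask |= cell.rasterize(imaging)
        bf[mask] = 700.0
        bf = gaussian_filter(bf, 1.0)
    bf += rng.normal(0.0, 8.0, size=bf.shape)
    bright_field = np.clip(np.round(bf), 0, 65535).astype(np.uint16)
    return movie, bright_field


# ---------------------------------------------------------------------------
# ground-truth I/O

def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the ground-truth table as CSV (one row per focus per frame)."""
    truth = truth[GROUND_TRUTH_COLUMNS] if len(truth) else \
        pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    truth.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth file misses columns {sorted(missing)}")
    return df[GROUND_TRUTH_COLUMNS]


def write_movie(movie: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, movie, photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
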