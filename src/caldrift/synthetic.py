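"""Synthetic two-environment longitudinal experiment with known ground truth.

The generator emulates days-scale representational drift on two linear
tracks: a drifting subset of active cells (a two-state Markov recruitment
chain per cell and environment), per-cell event rates that follow log-rate
random walks with a component shared between the environments and an
environment-specific component, stable place-field positions for recurring
cells, and distinct place maps per environment (remapping). Optional
forward models render dF/F traces (double-exponential calcium kernel plus
Gaussian noise) and per-session spatial footprints with centroid jitter.

Within-environment ensemble correlations decay with elapsed days through
both recruitment turnover and rate drift; across-environment correlations
decay only through the shared log-rate walk, so switching that component
off removes the cross-environment time signal while leaving each
environment's own drift intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import ENVIRONMENTS, SimConfig, InvalidConfigError, substream

EVENT_COLUMNS = ["cell_id", "env", "day", "trial", "time_s", "amplitude",
                 "position_cm", "velocity_cm_s"]


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-frame kinematics of one trial on the linearized track."""

    env: str
    day: int
    trial: int
    time: np.ndarray          # s, within trial
    position: np.ndarray      # cm in [0, track_length]
    velocity: np.ndarray      # cm/s, signed (+ rightward)
    frame_rate: float

    @property
    def speed(self) -> np.ndarray:
        return np.abs(self.velocity)

    @property
    def direction(self) -> np.ndarray:
        """'right'/'left' per frame; stationary frames keep the last heading."""
        sign = np.sign(self.velocity)
        # forward-fill zeros with the previous moving direction
        filled = sign.copy()
        last = 1.0
        for i in range(len(filled)):
            if filled[i] == 0:
                filled[i] = last
            else:
                last = filled[i]
        return np.where(filled > 0, "right", "left")


def _simulate_trial(config: SimConfig, rng: np.random.Generator,
                    env: str, day: int, trial: int) -> Trajectory:
    n = config.frames_per_trial
    dt = 1.0 / config.frame_rate
    L = config.track_length
    v = config.run_speed
    pos = np.empty(n)
    vel = np.empty(n)
    x, s = 0.0, 1.0
    pause = 0.0
    for i in range(n):
        if pause > 0:
            pause -= dt
            vel[i] = 0.0
            pos[i] = x
            continue
        x_new = x + s * v * dt
        if x_new >= L or x_new <= 0.0:
            edge = L if x_new >= L else 0.0
            if config.pause_mean > 0:
                x_new = edge
                pause = rng.exponential(config.pause_mean)
            else:
                x_new = 2 * edge - x_new  # reflect, no dwell
            s = -s
        vel[i] = (x_new - x) / dt
        pos[i] = x_new
        x = x_new
    t = np.arange(n) * dt
    return Trajectory(env, day, trial, t, pos, vel, config.frame_rate)


def simulate_trajectory(config: SimConfig, seed: Optional[int] = None
                        ) -> dict[tuple[str, int, int], Trajectory]:
    """Simulate lap-running trajectories for every (env, day, trial).

    Constant-speed back-and-forth laps with exponentially distributed dwell
    epochs at both track ends (the dwells exercise the >1 cm/s speed filter
    and the end-bin exclusion downstream).
    """
    config.validate()
    rng = substream(config.seed if seed is None else seed, "trajectory")
    out = {}
    for day in config.day_values:
        for env in ENVIRONMENTS:
            for trial in range(1, config.trials_per_session + 1):
                out[(env, day, trial)] = _simulate_trial(config, rng, env, day, trial)
    return out


# ---------------------------------------------------------------------------
# ensemble model
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Generative state of the cell population across days and environments.

    Field centers are constant across days within an environment; the
    log-rate offsets are random walks over calendar days; the active flags
    follow a two-state Markov chain per cell and environment.
    """

    config: SimConfig
    is_place_cell: np.ndarray        # (n,) bool
    field_center: np.ndarray         # (n, 2) cm per environment
    field_sigma: float               # cm (Gaussian sigma of the tuning bump)
    base_log_rate: np.ndarray        # (n,) log events/s
    active: np.ndarray               # (n_days, 2, n) bool, a_{n,d,E}
    eta_shared: np.ndarray           # (n_days, n) shared log-rate walk
    eta_env: np.ndarray              # (n_days, 2, n) env-specific walk
    gain_env: np.ndarray             # (2, n) static per-environment log gains

    def rate(self, day_index: int, env: str) -> np.ndarray:
        """Mean event rate (events/s while running) per cell for a session."""
        e = ENVIRONMENTS.index(env)
        lam = (self.base_log_rate + self.gain_env[e]
               + self.eta_shared[day_index] + self.eta_env[day_index, e])
        return self.active[day_index, e] * np.exp(lam)

    def tuning(self, env: str, positions: np.ndarray) -> np.ndarray:
        """Positional gain per cell, shape (n, len(positions)).

        Normalized so the track-average gain is 1 for every cell; flat (1)
        for untuned cells.
        """
        e = ENVIRONMENTS.index(env)
        L = self.config.track_length
        grid = np.linspace(0, L, 481)
        c = self.field_center[:, e][:, None]
        g = np.exp(-0.5 * ((positions[None, :] - c) / self.field_sigma) ** 2)
        norm = np.exp(-0.5 * ((grid[None, :] - c) / self.field_sigma) ** 2).mean(axis=1)
        g = g / norm[:, None]
        g[~self.is_place_cell] = 1.0
        return g


def build_ensemble_model(config: SimConfig, seed: Optional[int] = None) -> EnsembleModel:
    """Draw the ground-truth population: tuning, recruitment, rate drift."""
    config.validate()
    rng = substream(config.seed if seed is None else seed, "ensemble")
    n, d = config.n_cells, config.n_days

    is_place = rng.random(n) < config.place_cell_fraction
    margin = 2 * config.bin_width  # keep centers out of the excluded end bins
    lo, hi = margin, config.track_length - margin
    center_a = rng.uniform(lo, hi, n)
    center_b = rng.uniform(lo, hi, n) if config.remap_mode else center_a.copy()
    field_sigma = config.field_width / 2.3548  # FWHM -> sigma

    base = np.log(config.base_rate) + config.rate_spread * rng.standard_normal(n)
    # static rate remapping: a cell's mean rate differs persistently between
    # the two environments, independent of the day-to-day drift
    gain_env = config.env_gain_sigma * rng.standard_normal((2, n))

    # two-state recruitment chain per cell and environment
    p11 = config.recruitment_persistence
    pi = config.active_fraction
    if pi >= 1.0:
        p01 = 1.0
    else:
        p01 = pi * (1.0 - p11) / (1.0 - pi)
    if p01 > 1.0:
        raise InvalidConfigError(
            "recruitment_persistence too low for the requested active_fraction")
    active = np.zeros((d, 2, n), dtype=bool)
    active[0] = rng.random((2, n)) < pi
    for k in range(1, d):
        stay = rng.random((2, n)) < p11
        join = rng.random((2, n)) < p01
        active[k] = np.where(active[k - 1], stay, join)

    # log-rate random walks with calendar-day-scaled increments
    days = np.asarray(config.day_values, dtype=float)
    gaps = np.sqrt(np.diff(days))
    eta_shared = np.zeros((d, n))
    eta_env = np.zeros((d, 2, n))
    for k in range(1, d):
        eta_shared[k] = eta_shared[k - 1] + (
            config.shared_drift_sigma * gaps[k - 1] * rng.standard_normal(n))
        eta_env[k] = eta_env[k - 1] + (
            config.env_drift_sigma * gaps[k - 1] * rng.standard_normal((2, n)))

    return EnsembleModel(config, is_place, np.column_stack([center_a, center_b]),
                         field_sigma, base, active, eta_shared, eta_env, gain_env)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def simulate_events(model: EnsembleModel,
                    trajectories: dict[tuple[str, int, int], Trajectory],
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Draw Ca2+ events from an inhomogeneous Poisson process.

    Intensity for cell n at frame t is
    ``active(n, day, env) * exp(log-rate) * tuning(position_t)``; amplitudes
    are log-normal. Returns a tidy EventTable with one row per event.
    """
    config = model.config
    rng = substream(config.seed if seed is None else seed, "events")
    dt = 1.0 / config.frame_rate
    expected = {(env, day, trial)
                for day in config.day_values for env in ENVIRONMENTS
                for trial in range(1, config.trials_per_session + 1)}
    if set(trajectories) != expected:
        raise ValueError("trajectory set does not match the model's sessions")

    rows = []
    for k, day in enumerate(config.day_values):
        for e, env in enumerate(ENVIRONMENTS):
            rates = model.rate(k, env)  # (n,)
            for trial in range(1, config.trials_per_session + 1):
                traj = trajectories[(env, day, trial)]
                gain = model.tuning(env, traj.position)  # (n, T)
                lam = rates[:, None] * gain * dt
                counts = rng.poisson(lam)
                cell_idx, frame_idx = np.nonzero(counts)
                if len(cell_idx) == 0:
                    continue
                reps = counts[cell_idx, frame_idx]
                cell_idx = np.repeat(cell_idx, reps)
                frame_idx = np.repeat(frame_idx, reps)
                amp = np.exp(np.log(config.amp_median)
                             + config.amp_sigma * rng.standard_normal(len(cell_idx)))
                rows.append(pd.DataFrame({
                    "cell_id": cell_idx,
                    "env": env,
                    "day": day,
                    "trial": trial,
                    "time_s": traj.time[frame_idx],
                    "amplitude": amp,
                    "position_cm": traj.position[frame_idx],
                    "velocity_cm_s": traj.velocity[frame_idx],
                }))
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["env", "day", "trial", "time_s", "cell_id"],
                           kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def calcium_kernel(config: SimConfig, n_frames: Optional[int] = None) -> np.ndarray:
    """Unit-peak double-exponential kernel sampled at the frame rate."""
    tr, td = config.kernel_rise, config.kernel_decay
    if not td > tr > 0:
        raise InvalidConfigError("require kernel_decay > kernel_rise > 0")
    if n_frames is None:
        n_frames = int(np.ceil(8 * td * config.frame_rate)) + 1
    t = np.arange(n_frames) / config.frame_rate
    k = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


@dataclass
class TraceSet:
    """dF/F traces per session: (env, day) -> array (n_cells, n_frames).

    Frames concatenate the session's trials in order; ``trial_frames`` gives
    the per-trial frame count for slicing.
    """

    traces: dict[tuple[str, int], np.ndarray]
    frame_rate: float
    trial_frames: int
    n_trials: int


def render_fluorescence(events: pd.DataFrame, config: SimConfig,
                        seed: Optional[int] = None,
                        n_cells: Optional[int] = None) -> TraceSet:
    """Render dF/F traces as kernel-convolved event impulses plus noise."""
    from scipy.signal import fftconvolve

    config.validate()
    rng = substream(config.seed if seed is None else seed, "traces")
    n = config.n_cells if n_cells is None else n_cells
    tf = config.frames_per_trial
    total = tf * config.trials_per_session
    kernel = calcium_kernel(config)
    traces = {}
    for day in config.day_values:
        for env in ENVIRONMENTS:
            impulses = np.zeros((n, total))
            sub = events[(events["env"] == env) & (events["day"] == day)]
            if len(sub):
                fr = (np.round(sub["time_s"].to_numpy() * config.frame_rate).astype(int)
                      .clip(0, tf - 1))
                fr = fr + (sub["trial"].to_numpy() - 1) * tf
                np.add.at(impulses, (sub["cell_id"].to_numpy(), fr),
                          sub["amplitude"].to_numpy())
            tr = fftconvolve(impulses, kernel[None, :], mode="full")[:, :total]
            if config.noise_sigma > 0:
                tr = tr + config.noise_sigma * rng.standard_normal(tr.shape)
            traces[(env, day)] = tr
    return TraceSet(traces, config.frame_rate, tf, config.trials_per_session)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

@dataclass
class FootprintRecord:
    cell_id: int
    patch: np.ndarray        # pixel weights, cropped
    offset: tuple            # (row, col) of patch origin in the FOV image
    centroid_um: np.ndarray  # (y, x) µm in the session's own frame


@dataclass
class FootprintSet:
    """Per-session spatial footprints with ground-truth identity."""

    sessions: dict[tuple[str, int], list[FootprintRecord]]
    um_per_px: float
    fov_px: int
    true_centroids_um: np.ndarray  # (n, 2) jitter-free centroids

    def image(self, key: tuple[str, int]) -> np.ndarray:
        """Summed-footprint projection image of one session."""
        img = np.zeros((self.fov_px, self.fov_px))
        for rec in self.sessions[key]:
            r, c = rec.offset
            h, w = rec.patch.shape
            r0, c0 = max(r, 0), max(c, 0)
            r1, c1 = min(r + h, self.fov_px), min(c + w, self.fov_px)
            if r1 <= r0 or c1 <= c0:
                continue
            img[r0:r1, c0:c1] += rec.patch[r0 - r:r1 - r, c0 - c:c1 - c]
        return img


def _sample_centroids(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    margin = 3 * config.footprint_radius
    lo, hi = margin, config.fov_size - margin
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < config.n_cells:
        cand = rng.uniform(lo, hi, 2)
        if not pts or np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) >= config.min_separation:
            pts.append(cand)
        tries += 1
        if tries > 2000 * config.n_cells:
            raise InvalidConfigError(
                "cannot place n_cells centroids at min_separation in fov_size")
    return np.array(pts)


def render_footprints(model: EnsembleModel, config: SimConfig,
                      seed: Optional[int] = None) -> FootprintSet:
    """Gaussian-blob footprints per session with per-session centroid jitter.

    The blob sigma is chosen so the 50%-of-max contour sits at
    ``footprint_radius``. Only cells active in a session (in either
    environment-specific sense: active flag for that session) get a
    footprint there, mirroring extraction from real movies.
    """
    config.validate()
    rng = substream(config.seed if seed is None else seed, "footprints")
    base = _sample_centroids(config, rng)  # (n, 2) µm
    sigma = config.footprint_radius / np.sqrt(2 * np.log(2))
    half = int(np.ceil(4 * sigma / config.um_per_px))
    fov_px = int(round(config.fov_size / config.um_per_px))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")

    sessions = {}
    for k, day in enumerate(config.day_values):
        for e, env in enumerate(ENVIRONMENTS):
            recs = []
            jit = base + config.footprint_jitter * rng.standard_normal(base.shape)
            for cid in range(config.n_cells):
                if not model.active[k, e, cid]:
                    continue
                cy, cx = jit[cid] / config.um_per_px
                iy, ix = int(round(cy)), int(round(cx))
                fy, fx = cy - iy, cx - ix
                patch = np.exp(-(((yy - fy) ** 2 + (xx - fx) ** 2)
                                 * config.um_per_px ** 2) / (2 * sigma ** 2))
                recs.append(FootprintRecord(
                    cell_id=cid, patch=patch,
                    offset=(iy - half, ix - half),
                    centroid_um=jit[cid].copy()))
            sessions[(env, day)] = recs
    return FootprintSet(sessions, config.um_per_px, fov_px, base)


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    model: EnsembleModel
    trajectories: dict[tuple[str, int, int], Trajectory]
    events: pd.DataFrame
    traces: Optional[TraceSet] = None
    footprints: Optional[FootprintSet] = None

    def ground_truth(self) -> dict:
        """JSON-able record of the generative parameters actually drawn."""
        m = self.model
        return {
            "config": self.config.to_dict(),
            "is_place_cell": m.is_place_cell.astype(int).tolist(),
            "field_center_a": m.field_center[:, 0].round(3).tolist(),
            "field_center_b": m.field_center[:, 1].round(3).tolist(),
            "base_log_rate": m.base_log_rate.round(5).tolist(),
            "active": m.active.astype(int).tolist(),
        }


def generate_dataset(config: SimConfig, include_traces: bool = False,
                     include_footprints: bool = False) -> SyntheticDataset:
    """Generate a complete synthetic experiment from one root seed."""
    config.validate()
    trajectories = simulate_trajectory(config)
    model = build_ensemble_model(config)
    events = simulate_events(model, trajectories)
    traces = render_fluorescence(events, config) if include_traces else None
    footprints = render_footprints(model, config) if include_footprints else None
    return SyntheticDataset(config, model, trajectories, events, traces, footprints)
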