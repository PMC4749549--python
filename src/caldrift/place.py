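"""Place-field analysis: rate maps, spatial information, shuffle tests,
field-shift distributions, and population-vector correlations.

The track is divided into 24 bins of 4 cm; the two bins at each end
(reward zones) are excluded from all statistics. Only running epochs
(speed > 1 cm/s) contribute, separately per running direction. Occupancy
and event-count maps are smoothed with a truncated Gaussian kernel
(sigma = 1.5 bins, 5 bins wide) before division; spatial information in
bits/event is computed on the unsmoothed rate map as

    SI = sum_i p_i (r_i / rbar) log2(r_i / rbar)

where p_i is the occupancy probability of bin i, r_i the event rate in
bin i, and rbar the occupancy-weighted mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .synthetic import Trajectory

SPEED_THRESHOLD = 1.0   # cm/s
N_BINS = 24
EDGE_EXCLUDE = 2        # bins dropped at each end
SMOOTH_SIGMA = 1.5      # bins
SMOOTH_SIZE = 5         # bins
MIN_EVENTS = 5          # strict minimum for the shuffle test (> 5 required)


def smoothing_kernel(sigma: float = SMOOTH_SIGMA, size: int = SMOOTH_SIZE) -> np.ndarray:
    """Truncated Gaussian kernel, normalized to unit sum."""
    half = size // 2
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


@dataclass
class RateMap:
    """Per-cell, per-direction event-rate map over track bins."""

    rate: np.ndarray        # smoothed rate, events/s, full n_bins
    raw_rate: np.ndarray    # unsmoothed rate, events/s
    occupancy_s: np.ndarray  # raw seconds per bin
    n_events: int
    n_bins: int = N_BINS
    edge_exclude: int = EDGE_EXCLUDE

    @property
    def valid(self) -> slice:
        return slice(self.edge_exclude, self.n_bins - self.edge_exclude)

    @property
    def p(self) -> np.ndarray:
        """Occupancy probability over valid bins (sums to 1)."""
        occ = self.occupancy_s[self.valid]
        return occ / occ.sum()

    @property
    def r_bar(self) -> float:
        """Occupancy-weighted mean rate on the unsmoothed map."""
        return float(np.sum(self.p * self.raw_rate[self.valid]))

    @property
    def peak_bin(self) -> int:
        """Peak of the smoothed map within valid bins; ties -> lowest bin."""
        v = self.rate[self.valid]
        return int(np.argmax(v)) + self.edge_exclude

    def peak_position_cm(self, track_length: float) -> float:
        bw = track_length / self.n_bins
        return (self.peak_bin + 0.5) * bw

    @property
    def normalized(self) -> np.ndarray:
        m = self.rate.max()
        return self.rate / m if m > 0 else self.rate


def _running_mask(velocity: np.ndarray, direction: str) -> np.ndarray:
    speed_ok = np.abs(velocity) > SPEED_THRESHOLD
    if direction == "right":
        return speed_ok & (velocity > 0)
    if direction == "left":
        return speed_ok & (velocity < 0)
    raise ValueError("direction must be 'left' or 'right'")


def compute_rate_map(events: pd.DataFrame,
                     trajectories: Sequence[Trajectory],
                     direction: str,
                     track_length: float,
                     n_bins: int = N_BINS) -> RateMap:
    """Occupancy-normalized rate map for one cell's events in one session.

    ``events`` must carry position_cm and velocity_cm_s columns for the
    cell; ``trajectories`` are the session's trials (for occupancy). Both
    are filtered to running epochs in the requested direction.
    """
    bw = track_length / n_bins
    dt = 1.0 / trajectories[0].frame_rate
    occ = np.zeros(n_bins)
    for traj in trajectories:
        m = _running_mask(traj.velocity, direction)
        bins = np.clip((traj.position[m] / bw).astype(int), 0, n_bins - 1)
        occ += np.bincount(bins, minlength=n_bins) * dt
    if occ.sum() == 0:
        raise ValueError(f"zero running occupancy in direction {direction}")

    vel = events["velocity_cm_s"].to_numpy()
    m = _running_mask(vel, direction)
    pos = events["position_cm"].to_numpy()[m]
    bins = np.clip((pos / bw).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)

    kernel = smoothing_kernel()
    s_occ = np.convolve(occ, kernel, mode="same")
    s_cnt = np.convolve(counts, kernel, mode="same")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(s_occ > 0, s_cnt / s_occ, 0.0)
        raw = np.where(occ > 0, counts / occ, 0.0)
    return RateMap(rate, raw, occ, int(counts.sum()), n_bins)


def spatial_information_from_arrays(p: np.ndarray, r: np.ndarray) -> float:
    """SI in bits/event from occupancy probabilities and rates (0*log0 = 0)."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    r_bar = float(np.sum(p * r))
    if r_bar <= 0:
        raise ValueError("mean rate is zero; spatial information undefined")
    rel = r / r_bar
    terms = np.zeros_like(rel)
    nz = rel > 0
    terms[nz] = p[nz] * rel[nz] * np.log2(rel[nz])
    return float(terms.sum())


def spatial_information(rate_map: RateMap) -> float:
    """Spatial information of the unsmoothed rate map over valid bins."""
    return spatial_information_from_arrays(rate_map.p,
                                           rate_map.raw_rate[rate_map.valid])


@dataclass
class PlaceFieldResult:
    spatial_information: Optional[float]
    p_value: Optional[float]
    is_place_cell: bool
    field_position_cm: Optional[float]
    n_events: int
    eligible: bool


def place_field_significance(rate_map: RateMap, track_length: float,
                             n_shuffles: int = 1000,
                             seed: int = 0,
                             alpha: float = 0.05) -> PlaceFieldResult:
    """Shuffle test of spatial information against the occupancy null.

    Each shuffle redraws every event's position from the session's
    occupancy distribution (the spatial coverage statistics of that
    session and direction) and recomputes SI on the unsmoothed map. The
    p-value uses the (1 + k) / (1 + N) estimator. Cells with five or fewer
    events are ineligible and get no p-value.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    n_ev = rate_map.n_events
    if n_ev <= MIN_EVENTS:
        return PlaceFieldResult(None, None, False, None, n_ev, False)
    p = rate_map.p
    occ = rate_map.occupancy_s[rate_map.valid]
    obs = spatial_information(rate_map)
    rng = np.random.default_rng(seed)
    nb = len(p)
    # events inside valid bins only (those are what the SI sees)
    counts_valid = (rate_map.raw_rate[rate_map.valid] * occ)
    k = int(round(counts_valid.sum()))
    if k == 0:
        return PlaceFieldResult(obs, None, False, None, n_ev, False)
    draws = rng.choice(nb, size=(n_shuffles, k), p=p)
    sh_counts = np.zeros((n_shuffles, nb))
    np.add.at(sh_counts, (np.repeat(np.arange(n_shuffles), k), draws.ravel()), 1.0)
    sh_rate = sh_counts / occ
    r_bar = (p * sh_rate).sum(axis=1)
    rel = sh_rate / r_bar[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    sh_si = terms.sum(axis=1)
    p_val = (1 + int(np.sum(sh_si >= obs))) / (n_shuffles + 1)
    sig = p_val <= alpha
    pos = rate_map.peak_position_cm(track_length) if sig else None
    return PlaceFieldResult(obs, p_val, sig, pos, n_ev, True)


# ---------------------------------------------------------------------------
# field-shift distribution
# ---------------------------------------------------------------------------

@dataclass
class CentroidShiftResult:
    observed: np.ndarray     # per-cell field-position differences, cm
    null: np.ndarray         # pooled shuffle displacements, cm
    ks_statistic: float
    ks_p: float


def centroid_shift_distribution(fields_day_i: dict[int, float],
                                fields_day_j: dict[int, float],
                                n_null_pairs: int = 10000,
                                seed: int = 0) -> CentroidShiftResult:
    """Observed field-position shifts between two days and their null.

    The null shuffles cell identities on each day independently and pools
    the displacement distributions over ``n_null_pairs`` shuffle pairs.
    """
    common = sorted(set(fields_day_i) & set(fields_day_j))
    if len(common) < 2:
        raise ValueError("need at least 2 cells with fields on both days")
    a = np.array([fields_day_i[c] for c in common])
    b = np.array([fields_day_j[c] for c in common])
    observed = b - a
    rng = np.random.default_rng(seed)
    n = len(common)
    null = np.empty((n_null_pairs, n))
    for s in range(n_null_pairs):
        null[s] = b[rng.permutation(n)] - a[rng.permutation(n)]
    null = null.ravel()
    ks, ks_p = ks_2samp(observed, null)
    return CentroidShiftResult(observed, null, float(ks), float(ks_p))


# ---------------------------------------------------------------------------
# population-vector correlation
# ---------------------------------------------------------------------------

def population_vector_correlation(maps_a: np.ndarray, maps_b: np.ndarray,
                                  edge_exclude: int = EDGE_EXCLUDE,
                                  try_reversal: bool = False) -> float:
    """Mean per-bin Pearson correlation of two population rate matrices.

    ``maps_a``/``maps_b`` are (n_features, n_bins) with matching rows (the
    registered cell list, optionally stacked per direction). Bins with a
    zero-variance population vector on either side are skipped. With
    ``try_reversal`` both end-to-end alignments of the two tracks are
    evaluated and the higher mean is returned (the two linear tracks admit
    two transformations onto each other).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("population matrices must have the same shape")
    nb = a.shape[1]
    valid = slice(edge_exclude, nb - edge_exclude)

    def mean_pv(bm: np.ndarray) -> float:
        vals = []
        for i in range(valid.start, valid.stop):
            va, vb = a[:, i], bm[:, i]
            if va.std() == 0 or vb.std() == 0:
                continue  # undefined Pearson: skip the bin
            vals.append(np.corrcoef(va, vb)[0, 1])
        return float(np.mean(vals)) if vals else float("nan")

    direct = mean_pv(b)
    if not try_reversal:
        return direct
    return max(direct, mean_pv(b[:, ::-1]))


def best_track_alignment(maps_a: np.ndarray, maps_b: np.ndarray,
                         edge_exclude: int = EDGE_EXCLUDE) -> tuple[str, float]:
    """Pick the end-to-end alignment with the higher global PV correlation."""
    direct = population_vector_correlation(maps_a, maps_b, edge_exclude)
    flipped = population_vector_correlation(maps_a, maps_b[:, ::-1], edge_exclude)
    return ("identity", direct) if direct >= flipped else ("reversed", flipped)
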