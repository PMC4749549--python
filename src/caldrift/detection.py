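"""Ca2+ event detection from dF/F traces.

Detection proceeds in three stages: (1) baseline removal (20 s sliding
median) and zero-phase low-pass filtering at 2 Hz; (2) per-trace peak
detection against a threshold in multiples of the raw median absolute
deviation (MAD), with relative-peak rules that keep one event per
transient and kinetic checks on the decay time and the decay-to-rise
ratio; (3) crosstalk resolution between neighboring cells, which keeps
only the highest-amplitude event among neighbors firing within a 200 ms
window and discards the dimmer member of near-duplicate cell pairs whose
event trains correlate above 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks

from .config import DetectionParams
from .synthetic import EVENT_COLUMNS, FootprintSet, TraceSet


@dataclass
class CaEvent:
    """One detected transient, timed at its fluorescence peak."""

    cell_id: int
    time_s: float
    amplitude: float  # dF/F at the peak, on the preprocessed trace


def mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no normal-consistency scaling)."""
    return float(np.median(np.abs(x - np.median(x))))


def preprocess_trace(trace: np.ndarray, params: DetectionParams,
                     frame_rate: float) -> np.ndarray:
    """Remove the sliding-median baseline and low-pass filter the trace."""
    params.validate()
    trace = np.asarray(trace, dtype=float)
    win = int(round(params.baseline_window * frame_rate))
    if win % 2 == 0:
        win += 1
    if len(trace) <= win:
        raise ValueError("trace shorter than the baseline window")
    detrended = trace - median_filter(trace, size=win, mode="reflect")
    nyq = frame_rate / 2.0
    if params.lowpass_cutoff >= nyq:
        return detrended
    b, a = butter(2, params.lowpass_cutoff / nyq)
    return filtfilt(b, a, detrended)


def _kinetics_ok(trace: np.ndarray, peak: int, trough_before: int,
                 params: DetectionParams, frame_rate: float) -> bool:
    """Check decay time and decay-to-rise ratio of one candidate transient."""
    h = trace[peak]
    base = trace[trough_before]
    # 20%-amplitude crossing times; half-times are biased symmetric by the
    # zero-phase low-pass, 20% crossings track the true rise/decay asymmetry
    level = base + 0.2 * (h - base)
    pre = np.nonzero(trace[trough_before:peak] < level)[0]
    t_rise = (peak - (trough_before + pre[-1])) / frame_rate if len(pre) else 1.0 / frame_rate
    post = np.nonzero(trace[peak:] < level)[0]
    if len(post) == 0:
        return True  # transient truncated by the trace end: no decay evidence
    t_decay = post[0] / frame_rate
    tau = t_decay / np.log(5)  # time to fall to 20%
    lo, hi = params.decay_bounds
    if not (lo * params.indicator_decay <= tau <= hi * params.indicator_decay):
        return False
    return t_decay / max(t_rise, 1e-9) >= params.decay_rise_ratio_min


def detect_events(trace: np.ndarray, params: DetectionParams,
                  frame_rate: float, cell_id: int = 0,
                  preprocessed: bool = True) -> list[CaEvent]:
    """Detect Ca2+ events on one (preprocessed) trace.

    Candidate local maxima must exceed ``mad_threshold`` MADs. A candidate
    following an accepted event must rise at least ``peak_over_prev`` MADs
    above the intervening trough (otherwise it is a shoulder on the decay),
    and must stand at least ``peak_over_next`` MADs above a higher upcoming
    peak's intervening trough-to-come (otherwise it is a shoulder on the
    rise and the later, higher peak is kept instead).
    """
    params.validate()
    x = np.asarray(trace, dtype=float)
    if not preprocessed:
        x = preprocess_trace(x, params, frame_rate)
    scale = mad(x)
    if scale == 0:
        return []
    peaks, _ = find_peaks(x, height=params.mad_threshold * scale)
    if len(peaks) == 0:
        return []

    accepted: list[int] = []
    prev_kept = None  # index of last accepted peak
    for i, p in enumerate(peaks):
        start = prev_kept if prev_kept is not None else 0
        trough = start + int(np.argmin(x[start:p + 1])) if p > start else start
        rise = x[p] - x[trough]
        if prev_kept is not None and rise < params.peak_over_prev * scale:
            continue  # shoulder on the previous event's decay
        if i + 1 < len(peaks):
            q = peaks[i + 1]
            drop = x[p] - np.min(x[p:q + 1])
            if x[q] > x[p] - params.peak_over_next * scale and drop < params.peak_over_next * scale:
                continue  # shoulder on the next, higher peak's rise
        if not _kinetics_ok(x, p, trough, params, frame_rate):
            continue
        accepted.append(p)
        prev_kept = p
    return [CaEvent(cell_id, p / frame_rate, float(x[p])) for p in accepted]


def detect_session_events(traces: np.ndarray, params: DetectionParams,
                          frame_rate: float) -> list[list[CaEvent]]:
    """Run preprocessing + detection on every row of a (cells, frames) array."""
    out = []
    for cid in range(traces.shape[0]):
        x = preprocess_trace(traces[cid], params, frame_rate)
        out.append(detect_events(x, params, frame_rate, cell_id=cid))
    return out


# ---------------------------------------------------------------------------
# crosstalk resolution
# ---------------------------------------------------------------------------

def _event_train_correlation(t1: np.ndarray, t2: np.ndarray, bin_s: float,
                             duration: float) -> float:
    """Pearson correlation of binned event-count trains (100 ms bins)."""
    edges = np.arange(0.0, duration + bin_s, bin_s)
    c1, _ = np.histogram(t1, bins=edges)
    c2, _ = np.histogram(t2, bins=edges)
    if c1.std() == 0 or c2.std() == 0:
        return 0.0
    return float(np.corrcoef(c1, c2)[0, 1])


def resolve_crosstalk(events_per_cell: dict[int, list[CaEvent]],
                      centroids_um: dict[int, np.ndarray],
                      params: DetectionParams,
                      duration: float) -> pd.DataFrame:
    """Apply the neighbor-window and duplicate-cell rules; return an event table.

    Cells whose centroids are less than ``neighbor_radius`` µm apart are
    neighbors. Near-duplicate neighbor pairs (event-train correlation above
    ``dedup_correlation``, computed on 100 ms-binned counts of the input
    trains) lose the lower-mean-amplitude member entirely; among remaining
    neighbor events within ``crosstalk_window`` seconds of each other
    (closed interval), only the highest peak survives.
    """
    params.validate()
    cells = sorted(events_per_cell)
    for cid in cells:
        if events_per_cell[cid] and cid not in centroids_um:
            raise ValueError(f"cell {cid} has events but no footprint centroid")
    neighbors: dict[int, set[int]] = {c: set() for c in cells}
    for i, ci in enumerate(cells):
        for cj in cells[i + 1:]:
            if ci in centroids_um and cj in centroids_um:
                d = np.linalg.norm(np.asarray(centroids_um[ci], float)
                                   - np.asarray(centroids_um[cj], float))
                if d < params.neighbor_radius:
                    neighbors[ci].add(cj)
                    neighbors[cj].add(ci)

    # duplicate-component rule first, on the unpruned trains
    dropped: set[int] = set()
    for ci in cells:
        for cj in sorted(neighbors[ci]):
            if cj <= ci or ci in dropped or cj in dropped:
                continue
            ti = np.array([e.time_s for e in events_per_cell[ci]])
            tj = np.array([e.time_s for e in events_per_cell[cj]])
            if len(ti) == 0 or len(tj) == 0:
                continue
            r = _event_train_correlation(ti, tj, params.dedup_bin, duration)
            if r > params.dedup_correlation:
                mi = np.mean([e.amplitude for e in events_per_cell[ci]])
                mj = np.mean([e.amplitude for e in events_per_cell[cj]])
                dropped.add(ci if mi < mj else cj)

    # neighbor-window rule: greedy by descending amplitude
    pool = [e for c in cells if c not in dropped for e in events_per_cell[c]]
    pool.sort(key=lambda e: (-e.amplitude, e.time_s, e.cell_id))
    kept_times: dict[int, list[float]] = {c: [] for c in cells}
    kept: list[CaEvent] = []
    for ev in pool:
        clash = any(abs(t - ev.time_s) <= params.crosstalk_window
                    for nb in neighbors[ev.cell_id] if nb not in dropped
                    for t in kept_times[nb])
        if not clash:
            kept.append(ev)
            kept_times[ev.cell_id].append(ev.time_s)
    kept.sort(key=lambda e: (e.time_s, e.cell_id))
    return pd.DataFrame(
        [(e.cell_id, e.time_s, e.amplitude) for e in kept],
        columns=["cell_id", "time_s", "amplitude"],
    )


def detect_dataset_events(traces: TraceSet, footprints: FootprintSet,
                          params: DetectionParams) -> pd.DataFrame:
    """Full detection over a TraceSet; returns a tidy EventTable.

    Session traces concatenate trials; detected peak times are split back
    into (trial, within-trial time). Position/velocity columns are NaN here
    (they come from the trajectory when merging downstream).
    """
    rows = []
    fr = traces.frame_rate
    trial_s = traces.trial_frames / fr
    duration = trial_s * traces.n_trials
    for (env, day), arr in traces.traces.items():
        cents = {rec.cell_id: rec.centroid_um
                 for rec in footprints.sessions.get((env, day), [])}
        # only cells with an extracted footprint have a usable trace
        per_cell = {c: [] for c in cents}
        for cid in cents:
            x = preprocess_trace(arr[cid], params, fr)
            per_cell[cid] = detect_events(x, params, fr, cell_id=cid)
        table = resolve_crosstalk(per_cell, cents, params, duration)
        if len(table) == 0:
            continue
        trial = np.minimum(table["time_s"] // trial_s, traces.n_trials - 1).astype(int)
        rows.append(pd.DataFrame({
            "cell_id": table["cell_id"],
            "env": env,
            "day": day,
            "trial": trial + 1,
            "time_s": table["time_s"] - trial * trial_s,
            "amplitude": table["amplitude"],
            "position_cm": np.nan,
            "velocity_cm_s": np.nan,
        }))
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(rows, ignore_index=True).sort_values(
        ["env", "day", "trial", "time_s", "cell_id"], kind="stable",
        ignore_index=True)
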