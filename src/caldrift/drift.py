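"""Ensemble- and cell-level drift statistics across recording days.

Operates on event-rate tables keyed by (cell, day, trial, environment) and
on session-level activity vectors over the registered master cell list:
session-pair correlation matrices and their decay with elapsed time,
recurrence probabilities of the active subset, divergence measures
between the two environments, and single-cell monotonicity statistics
with their permutation and Poisson nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ENVIRONMENTS


# ---------------------------------------------------------------------------
# ensemble correlation structure
# ---------------------------------------------------------------------------

@dataclass
class EnsembleCorrelation:
    matrix: np.ndarray          # (n_sessions, n_sessions) Pearson
    sessions: list              # [(env, day), ...] row order
    decay: pd.DataFrame         # lag_days, kind(within/across), mean, sem, n


def ensemble_correlation_matrix(vectors: dict[tuple[str, int], np.ndarray]
                                ) -> EnsembleCorrelation:
    """Pairwise Pearson correlations between session activity vectors.

    Also returns mean-correlation decay curves versus elapsed calendar
    days, split into within-environment and across-environment session
    pairs.
    """
    sessions = sorted(vectors, key=lambda k: (k[1], k[0]))
    mat = np.vstack([np.asarray(vectors[k], dtype=float) for k in sessions])
    stds = mat.std(axis=1)
    if np.any(stds == 0):
        bad = sessions[int(np.argmax(stds == 0))]
        raise ValueError(f"zero-variance activity vector in session {bad}")
    corr = np.corrcoef(mat)
    rows = []
    for i, j in combinations(range(len(sessions)), 2):
        (ei, di), (ej, dj) = sessions[i], sessions[j]
        rows.append((abs(dj - di), "within" if ei == ej else "across",
                     corr[i, j]))
    df = pd.DataFrame(rows, columns=["lag_days", "kind", "r"])
    decay = (df.groupby(["lag_days", "kind"])["r"]
             .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                  if len(x) > 1 else 0.0, n="count")
             .reset_index())
    return EnsembleCorrelation(corr, sessions, decay)


def recurrence_probability(active: dict[tuple[str, int], np.ndarray],
                           condition_on_both: bool = False) -> pd.DataFrame:
    """P(active at day d + lag | active at day d), within and across envs.

    ``active`` maps (env, day) to a boolean vector over the master cell
    list (active = at least one event in the session). The across-
    environment curve conditions on activity in one environment on day d
    (or in both environments when ``condition_on_both``).
    """
    days = sorted({d for _, d in active})
    rows = []
    for d1 in days:
        for d2 in days:
            if d2 < d1:
                continue
            lag = d2 - d1
            for e1 in ENVIRONMENTS:
                for e2 in ENVIRONMENTS:
                    if (e1, d1) not in active or (e2, d2) not in active:
                        continue
                    cond = active[(e1, d1)]
                    if condition_on_both:
                        other = "B" if e1 == "A" else "A"
                        if (other, d1) in active:
                            cond = cond & active[(other, d1)]
                    if cond.sum() == 0:
                        continue
                    p = float(active[(e2, d2)][cond].mean())
                    kind = "within" if e1 == e2 else "across"
                    if lag == 0 and e1 == e2:
                        p = 1.0  # same session
                    rows.append((lag, kind, p))
    df = pd.DataFrame(rows, columns=["lag_days", "kind", "p"])
    return (df.groupby(["lag_days", "kind"])["p"]
            .agg(mean="mean", n="count").reset_index())


# ---------------------------------------------------------------------------
# divergence measures
# ---------------------------------------------------------------------------

def activity_divergence(rates: pd.DataFrame, day: int) -> float:
    """Across- to within-environment trial rate-difference ratio for one day.

    ``rates`` is tidy with columns cell_id, env, day, trial, rate. The
    numerator averages |r_A(t) - r_B(t')| over cells and all cross-
    environment trial pairs; the denominator averages over same-
    environment trial pairs (both environments pooled). Invariant to a
    common rescaling of all rates.
    """
    sub = rates[rates["day"] == day]
    if sub.empty:
        raise ValueError(f"no rates for day {day}")
    piv = sub.pivot_table(index="cell_id", columns=["env", "trial"],
                          values="rate", fill_value=0.0)
    envs = sorted({e for e, _ in piv.columns})
    if len(envs) != 2:
        raise ValueError("need rates from both environments")
    ra = piv[envs[0]].to_numpy()  # (cells, trials)
    rb = piv[envs[1]].to_numpy()
    if ra.shape[1] < 2 or rb.shape[1] < 2:
        raise ValueError("need >= 2 trials per environment")
    num = np.abs(ra[:, :, None] - rb[:, None, :]).mean()
    same = []
    for r in (ra, rb):
        for t, t2 in combinations(range(r.shape[1]), 2):
            same.append(np.abs(r[:, t] - r[:, t2]))
    den = float(np.mean(same))
    if den == 0:
        raise ValueError("zero within-environment rate differences: "
                         "divergence undefined")
    return float(num) / den


def peak_displacement(peaks_a: dict[int, float], peaks_b: dict[int, float],
                      track_length: float,
                      alignment: str = "identity") -> float:
    """Mean |peak position difference| between environments, in cm.

    Only cells place-coding in both environments enter. ``alignment`` is
    the end-to-end track correspondence chosen by the higher global PV
    correlation ('identity' or 'reversed').
    """
    common = sorted(set(peaks_a) & set(peaks_b))
    if not common:
        raise ValueError("no cells with fields in both environments")
    pa = np.array([peaks_a[c] for c in common])
    pb = np.array([peaks_b[c] for c in common])
    if alignment == "reversed":
        pb = track_length - pb
    elif alignment != "identity":
        raise ValueError("alignment must be 'identity' or 'reversed'")
    return float(np.mean(np.abs(pa - pb)))


# ---------------------------------------------------------------------------
# cell-level dynamics
# ---------------------------------------------------------------------------

def maximal_monotonic_sequence(rates: Sequence[float]) -> int:
    """Longest run of consecutive-day rate differences with the same sign.

    Ties (zero difference) break a run: a zero is neither an increase nor
    a decrease. A strictly monotonic series over n days scores n - 1; an
    all-constant series scores 0.
    """
    diffs = np.sign(np.diff(np.asarray(rates, dtype=float)))
    best = run = 0
    prev = 0.0
    for s in diffs:
        if s != 0 and s == prev:
            run += 1
        elif s != 0:
            run = 1
        else:
            run = 0
        prev = s
        best = max(best, run)
    return int(best)


def monotonic_sequence_null(rates: Sequence[float], n_shuffles: int = 1000,
                            seed: int = 0) -> np.ndarray:
    """Null lengths under random permutation of the day order."""
    rng = np.random.default_rng(seed)
    r = np.asarray(rates, dtype=float)
    return np.array([maximal_monotonic_sequence(rng.permutation(r))
                     for _ in range(n_shuffles)])


def monotonicity_score(rates: Sequence[float]) -> float:
    """(later-higher pairs - earlier-higher pairs) / all day pairs, in [-1, 1].

    Tied pairs count for neither side. For 8 days the denominator is 28.
    """
    r = np.asarray(rates, dtype=float)
    n = len(r)
    diff = r[None, :] - r[:, None]  # diff[i, j] = r_j - r_i
    upper = diff[np.triu_indices(n, k=1)]
    n_pairs = n * (n - 1) // 2
    return float((np.sum(upper > 0) - np.sum(upper < 0)) / n_pairs)


@dataclass
class CvNullResult:
    observed_cv: np.ndarray
    null_cv: np.ndarray
    means: np.ndarray  # per-cell mean session rates used for the null


def rate_cv_poisson_null(session_counts: np.ndarray, seed: int = 0,
                         n_null_per_cell: int = 1) -> CvNullResult:
    """CV of session event counts versus a matched stationary Poisson null.

    ``session_counts`` is (n_cells, n_sessions) for cells active in every
    session. The null simulates, for each cell, Poisson counts with that
    cell's empirical mean over the same number of sessions; for a Poisson
    cell CV approximates 1/sqrt(mean count).
    """
    counts = np.asarray(session_counts, dtype=float)
    means = counts.mean(axis=1)
    keep = means > 0
    counts, means = counts[keep], means[keep]
    obs_cv = counts.std(axis=1, ddof=1) / means
    rng = np.random.default_rng(seed)
    lam = np.repeat(means, n_null_per_cell)
    null = rng.poisson(lam[:, None], size=(len(lam), counts.shape[1])).astype(float)
    nm = null.mean(axis=1)
    ok = nm > 0
    null_cv = null[ok].std(axis=1, ddof=1) / nm[ok]
    return CvNullResult(obs_cv, null_cv, means)


def population_monotonicity(rates: np.ndarray,
                            subgroup_consecutive: Optional[int] = None,
                            shuffle: bool = False,
                            seed: int = 0) -> pd.DataFrame:
    """Normalized event rate versus lag from each cell's peak day.

    Each cell's across-day rate series is normalized by its maximum and
    aligned to its peak day (ties -> earliest), then averaged per lag; the
    value at lag 0 is 1 for every cell by construction. With
    ``subgroup_consecutive`` = k, only cells whose maximal run of
    consecutive active days (rate > 0) has length exactly k enter, and
    only that maximal segment is used. ``shuffle`` permutes each cell's
    day order first (the permutation control).
    """
    r = np.asarray(rates, dtype=float).copy()
    n_cells, n_days = r.shape
    rng = np.random.default_rng(seed)
    if shuffle:
        for i in range(n_cells):
            r[i] = r[i, rng.permutation(n_days)]
    acc: dict[int, list[float]] = {}
    for i in range(n_cells):
        row = r[i]
        lo, hi = 0, n_days
        if subgroup_consecutive is not None:
            seg = _max_active_segment(row)
            if seg is None or seg[1] - seg[0] != subgroup_consecutive:
                continue
            lo, hi = seg
        window = row[lo:hi]
        m = window.max()
        if m <= 0:
            continue
        peak = int(np.argmax(window))
        for j, v in enumerate(window):
            acc.setdefault(j - peak, []).append(v / m)
    rows = [(lag, float(np.mean(vs)),
             float(np.std(vs, ddof=1) / np.sqrt(len(vs))) if len(vs) > 1 else 0.0,
             len(vs))
            for lag, vs in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["lag", "mean", "sem", "n"])


def _max_active_segment(row: np.ndarray) -> Optional[tuple[int, int]]:
    """(start, stop) of the longest run of active (rate > 0) days; ties first."""
    best = None
    start = None
    for i, v in enumerate(np.append(row > 0, False)):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


# ---------------------------------------------------------------------------
# tidy rate tables
# ---------------------------------------------------------------------------

def event_rate_table(events: pd.DataFrame, master_ids: Sequence[int],
                     trial_duration_min: float,
                     trials_per_session: int) -> pd.DataFrame:
    """Per-trial event rates (events/min) over the master cell list.

    Cells absent from a session have rate 0 (tidy rows are emitted for
    every master cell and every observed (env, day, trial)).
    """
    keys = events[["env", "day", "trial"]].drop_duplicates()
    counts = (events.groupby(["env", "day", "trial", "cell_id"])
              .size().rename("n").reset_index())
    full = (keys.merge(pd.DataFrame({"cell_id": list(master_ids)}), how="cross")
            .merge(counts, on=["env", "day", "trial", "cell_id"], how="left")
            .fillna({"n": 0}))
    full["rate"] = full["n"] / trial_duration_min
    return full[["cell_id", "env", "day", "trial", "rate"]]


def session_rate_matrix(events: pd.DataFrame, master_ids: Sequence[int],
                        env: str, days: Sequence[int],
                        session_duration_min: float) -> np.ndarray:
    """(n_cells, n_days) session event rates (events/min) for one environment."""
    out = np.zeros((len(master_ids), len(days)))
    idx = {c: i for i, c in enumerate(master_ids)}
    sub = events[events["env"] == env]
    for j, day in enumerate(days):
        cnt = sub[sub["day"] == day].groupby("cell_id").size()
        for cid, n in cnt.items():
            if cid in idx:
                out[idx[cid], j] = n / session_duration_min
    return out
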