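"""Correlation-based time decoders over ensemble activity patterns.

An ensemble activity pattern is the vector of per-cell event counts within
an episode (a trial, ``v_{d,t}``, or a full session, ``V_d``), taken over
the registered master cell list. Three decoders infer *when* an episode
occurred from such patterns:

* :class:`OrdinalTimeDecoder` — orders eight unlabeled session patterns
  chronologically by maximizing the mean Pearson correlation between
  neighboring days over all 8!/2 = 20,160 ordering classes (an ordering
  and its reversal score identically), with an exact permutation p-value.
* :class:`WithinEnvTimeDecoder` — infers the day of a single trial from
  the session patterns of the same environment, leaving the test trial
  index out of every training session and normalizing each correlation by
  its training-pattern mean over all test days.
* :class:`AcrossEnvTimeDecoder` — infers the day of a session or trial in
  one environment from the session patterns of the other environment,
  with the same normalization.

All estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``) and expose fitted attributes with trailing underscores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import ENVIRONMENTS

RUN_SPEED_MIN = 1.0   # cm/s, running-epoch restriction
RUN_END_MARGIN = 8.0  # cm from either track end


# ---------------------------------------------------------------------------
# activity vectors
# ---------------------------------------------------------------------------

@dataclass
class ActivityVectors:
    """Trial- and session-level event-count vectors for one environment."""

    days: list                 # recording-day values, chronological
    cells: list                # master cell ids (vector coordinates)
    trials: np.ndarray         # (n_days, n_trials, n_cells) counts

    @property
    def sessions(self) -> np.ndarray:
        """(n_days, n_cells) session vectors; V_d = sum_t v_{d,t}."""
        return self.trials.sum(axis=1)


def build_activity_vectors(events: pd.DataFrame,
                           env: str,
                           days: Sequence[int],
                           n_trials: int,
                           master_cells: Sequence[int],
                           master_map: Optional[dict] = None,
                           cell_subset: Optional[Sequence[int]] = None,
                           epoch: Optional[str] = None,
                           track_length: float = 96.0,
                           time_window: Optional[tuple] = None
                           ) -> ActivityVectors:
    """Count events per (day, trial, master cell) with optional restrictions.

    ``master_map`` maps (env, day) -> {event cell_id -> master_id}; when
    omitted, event cell_ids are already master ids. Restrictions filter
    events before counting: ``epoch='run'`` keeps events at speed >=
    1 cm/s and more than 8 cm from either track end, ``epoch='stationary'``
    keeps events below 1 cm/s, and ``time_window=(start_s, duration_s)``
    keeps events inside that window of each trial. ``cell_subset``
    restricts the vector coordinates to the given master ids.
    """
    sub = events[events["env"] == env]
    if epoch == "run":
        sub = sub[(sub["velocity_cm_s"].abs() >= RUN_SPEED_MIN)
                  & (sub["position_cm"] > RUN_END_MARGIN)
                  & (sub["position_cm"] < track_length - RUN_END_MARGIN)]
    elif epoch == "stationary":
        sub = sub[sub["velocity_cm_s"].abs() < RUN_SPEED_MIN]
    elif epoch is not None:
        raise ValueError("epoch must be None, 'run' or 'stationary'")
    if time_window is not None:
        t0, dur = time_window
        sub = sub[(sub["time_s"] >= t0) & (sub["time_s"] < t0 + dur)]

    cells = list(master_cells if cell_subset is None else cell_subset)
    cidx = {c: i for i, c in enumerate(cells)}
    didx = {d: i for i, d in enumerate(days)}
    out = np.zeros((len(days), n_trials, len(cells)))
    for (day, trial), grp in sub.groupby(["day", "trial"]):
        if day not in didx or not 1 <= trial <= n_trials:
            continue
        mapping = master_map.get((env, day), {}) if master_map is not None else None
        for cid, n in grp.groupby("cell_id").size().items():
            if mapping is not None:
                if cid not in mapping:
                    raise ValueError(
                        f"event cell {cid} unregistered in session ({env}, {day})")
                cid = mapping[cid]
            if cid in cidx:
                out[didx[day], trial - 1, cidx[cid]] = n
    return ActivityVectors(list(days), cells, out)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# ordinal decoder
# ---------------------------------------------------------------------------

def ordering_classes(n_days: int) -> np.ndarray:
    """All day orderings up to reversal, shape (n!/2, n)."""
    perms = [p for p in permutations(range(n_days)) if p[0] < p[-1]]
    return np.array(perms, dtype=int)


class OrdinalTimeDecoder(BaseEstimator):
    """Recover the chronological order of unlabeled session patterns.

    The objective of an ordering <d_1..d_n> is the mean correlation
    between neighboring patterns, averaged over the supplied environments
    under a common day ordering. The permutation p-value is the fraction
    of ordering classes whose objective is >= the chronological
    ordering's.

    Attributes (after ``fit``)
    --------------------------
    ordering_ : tuple of day indices maximizing the objective
    objective_ : its mean neighbor correlation
    p_value_ : exact permutation p-value of the chronological ordering
    n_classes_ : number of ordering classes (n!/2)
    objectives_ : objective of every ordering class
    """

    def fit(self, X, y=None):
        """X: (n_days, n_cells) array, or a list of such arrays (one per
        environment) sharing the day axis in chronological order."""
        mats = [np.asarray(m, dtype=float) for m in
                (X if isinstance(X, (list, tuple)) else [X])]
        n = mats[0].shape[0]
        if any(m.shape[0] != n for m in mats):
            raise ValueError("environments must share the day axis")
        corrs = [np.corrcoef(m) for m in mats]
        perms = ordering_classes(n)
        obj = np.zeros(len(perms))
        for c in corrs:
            obj += c[perms[:, :-1], perms[:, 1:]].mean(axis=1)
        obj /= len(corrs)
        chron = np.zeros(0)
        ident = np.arange(n)
        chron_obj = float(np.mean([c[ident[:-1], ident[1:]].mean() for c in corrs]))
        best = int(np.argmax(obj))
        self.n_days_ = n
        self.n_classes_ = len(perms)
        self.objectives_ = obj
        self.ordering_ = tuple(int(i) for i in perms[best])
        self.objective_ = float(obj[best])
        self.chronological_objective_ = chron_obj
        self.p_value_ = float(np.sum(obj >= chron_obj - 1e-12) / len(perms))
        return self

    def predict(self, X=None):
        return np.array(self.ordering_)

    @property
    def recovers_order_(self) -> bool:
        ident = tuple(range(self.n_days_))
        return self.ordering_ in (ident, ident[::-1])


# ---------------------------------------------------------------------------
# within-environment decoder
# ---------------------------------------------------------------------------

@dataclass
class DecoderOutput:
    """Per-item decoding results plus summary accuracies."""

    results: pd.DataFrame      # true_day_index, inferred_day_index, error, score
    accuracy: float            # exact-day fraction
    neighbor_rate: float       # fraction with |error| == 1 recording day
    mean_abs_error: float      # recording-day steps

    @property
    def error_histogram(self) -> pd.Series:
        return self.results["error"].value_counts().sort_index()


def _summarize(rows: list[tuple]) -> DecoderOutput:
    df = pd.DataFrame(rows, columns=["true_day_index", "trial",
                                     "inferred_day_index", "error", "score"])
    ok = df.dropna(subset=["inferred_day_index"])
    acc = float((ok["error"] == 0).mean()) if len(ok) else float("nan")
    nbr = float((ok["error"].abs() == 1).mean()) if len(ok) else float("nan")
    mae = float(ok["error"].abs().mean()) if len(ok) else float("nan")
    return DecoderOutput(df, acc, nbr, mae)


class WithinEnvTimeDecoder(BaseEstimator):
    """Infer the recording day of single trials within one environment.

    For test trial (i, j), the training pattern of candidate day d is the
    session pattern minus that day's j-th trial (leave-trial-out on every
    session, not only the test session); the decoder maximizes
    ``corr(v_ij, V_d - v_dj) - mean_d' corr(v_d'j, V_d - v_dj)``.
    With ``exclude_same_day`` the test trial's own day is removed from the
    candidates (training normalization unchanged). Argmax ties break
    toward the earlier day.
    """

    def __init__(self, exclude_same_day: bool = False):
        self.exclude_same_day = exclude_same_day

    def fit(self, X, y=None):
        """X: (n_days, n_trials, n_cells) trial count tensor."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (n_days, n_trials, n_cells)")
        self.trials_ = X
        self.sessions_ = X.sum(axis=1)
        self.n_days_, self.n_trials_ = X.shape[:2]
        return self

    def _decode_one(self, test_vec: np.ndarray, i: int, j: int) -> tuple:
        if test_vec.std() == 0:
            return (np.nan, np.nan)
        n = self.n_days_
        scores = np.full(n, -np.inf)
        for d in range(n):
            train = self.sessions_[d] - self.trials_[d, j]
            c = _corr(test_vec, train)
            if np.isnan(c):
                continue
            norm = np.nanmean([_corr(self.trials_[dp, j], train)
                               for dp in range(n)])
            scores[d] = c - norm
        if self.exclude_same_day:
            scores[i] = -np.inf
        if not np.isfinite(scores).any():
            return (np.nan, np.nan)
        d_hat = int(np.argmax(scores))  # argmax -> earliest on ties
        return (d_hat, float(scores[d_hat]))

    def predict(self, X=None) -> DecoderOutput:
        """Decode every trial. ``X`` optionally supplies alternative test
        vectors with the same (day, trial) indexing (e.g. short-segment
        counts, Fig-style partial test data); training always uses the
        fitted full-trial tensor."""
        test = self.trials_ if X is None else np.asarray(X, dtype=float)
        if test.shape[:2] != (self.n_days_, self.n_trials_):
            raise ValueError("test tensor must match fitted (days, trials)")
        rows = []
        for i in range(self.n_days_):
            for j in range(self.n_trials_):
                d_hat, score = self._decode_one(test[i, j], i, j)
                err = d_hat - i if not np.isnan(d_hat) else np.nan
                rows.append((i, j + 1, d_hat, err, score))
        out = _summarize(rows)
        self.results_ = out.results
        self.accuracy_ = out.accuracy
        return out


# ---------------------------------------------------------------------------
# across-environment decoder
# ---------------------------------------------------------------------------

class AcrossEnvTimeDecoder(BaseEstimator):
    """Infer the day of episodes in one environment from the other's patterns.

    Session level: ``argmax_d corr(V_i^E1, V_d^E2) -
    mean_d' corr(V_d'^E1, V_d^E2)`` — the normalization runs over the full
    set of test-environment session patterns. Trial level mirrors the
    within-environment decoder with leave-trial-out on the training
    environment (the same trial index is subtracted).
    """

    def __init__(self, level: str = "session", exclude_same_day: bool = False):
        self.level = level
        self.exclude_same_day = exclude_same_day

    def fit(self, X, y=None):
        """X: training-environment trial tensor (n_days, n_trials, n_cells)
        or session matrix (n_days, n_cells) for level='session'."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            self.train_trials_ = X
            self.train_sessions_ = X.sum(axis=1)
        elif X.ndim == 2 and self.level == "session":
            self.train_trials_ = None
            self.train_sessions_ = X
        else:
            raise ValueError("trial-level decoding needs a 3-D training tensor")
        self.n_days_ = self.train_sessions_.shape[0]
        return self

    def predict(self, X) -> DecoderOutput:
        if self.level == "session":
            return self._predict_sessions(np.asarray(X, dtype=float))
        if self.level == "trial":
            return self._predict_trials(np.asarray(X, dtype=float))
        raise ValueError("level must be 'session' or 'trial'")

    def _predict_sessions(self, tests: np.ndarray) -> DecoderOutput:
        n = self.n_days_
        if tests.shape[0] != n:
            raise ValueError("need all test-environment session vectors")
        cmat = np.array([[_corr(tests[i], self.train_sessions_[d])
                          for d in range(n)] for i in range(n)])
        norm = np.nanmean(cmat, axis=0)  # per training day d, over test days
        rows = []
        for i in range(n):
            scores = cmat[i] - norm
            if self.exclude_same_day:
                scores[i] = -np.inf
            if not np.isfinite(scores).any() or np.all(np.isnan(scores)):
                rows.append((i, 0, np.nan, np.nan, np.nan))
                continue
            d_hat = int(np.nanargmax(np.where(np.isfinite(scores), scores, -np.inf)))
            rows.append((i, 0, d_hat, d_hat - i, float(scores[d_hat])))
        out = _summarize(rows)
        self.results_ = out.results
        self.accuracy_ = out.accuracy
        return out

    def _predict_trials(self, tests: np.ndarray) -> DecoderOutput:
        if self.train_trials_ is None:
            raise ValueError("fitted without trial-level training data")
        n, n_trials = self.train_trials_.shape[:2]
        if tests.ndim != 3 or tests.shape[0] != n or tests.shape[1] != n_trials:
            raise ValueError("test tensor must be (n_days, n_trials, n_cells)")
        rows = []
        for j in range(n_trials):
            trains = [self.train_sessions_[d] - self.train_trials_[d, j]
                      for d in range(n)]
            cmat = np.array([[_corr(tests[i, j], trains[d]) for d in range(n)]
                             for i in range(n)])
            norm = np.nanmean(cmat, axis=0)
            for i in range(n):
                if tests[i, j].std() == 0:
                    rows.append((i, j + 1, np.nan, np.nan, np.nan))
                    continue
                scores = cmat[i] - norm
                if self.exclude_same_day:
                    scores[i] = -np.inf
                finite = np.where(np.isfinite(scores), scores, -np.inf)
                if not np.isfinite(finite).any():
                    rows.append((i, j + 1, np.nan, np.nan, np.nan))
                    continue
                d_hat = int(np.argmax(finite))
                rows.append((i, j + 1, d_hat, d_hat - i, float(finite[d_hat])))
        out = _summarize(rows)
        self.results_ = out.results
        self.accuracy_ = out.accuracy
        return out


# ---------------------------------------------------------------------------
# shuffles and segments
# ---------------------------------------------------------------------------

def shuffle_day_labels(trials: np.ndarray, n_shuffles: int = 10,
                       seed: int = 0) -> list[np.ndarray]:
    """Permute each cell's across-day activity sequence independently.

    The whole (day, trial) column of a cell moves together, preserving the
    within-cell multiset of per-day patterns.
    """
    X = np.asarray(trials, dtype=float)
    n_days = X.shape[0]
    n_cells = X.shape[-1]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        sh = X.copy()
        for c in range(n_cells):
            sh[..., c] = X[rng.permutation(n_days), ..., c]
        out.append(sh)
    return out


def segment_vectors(events: pd.DataFrame, env: str, days: Sequence[int],
                    n_trials: int, master_cells: Sequence[int],
                    duration_s: float, trial_duration_s: float,
                    seed: int = 0, **kwargs) -> ActivityVectors:
    """Trial vectors restricted to one random contiguous segment per trial.

    The segment start is drawn uniformly (seeded) from the offsets that
    keep the full duration inside the trial; all trials share the offset
    grid origin at the trial start.
    """
    rng = np.random.default_rng(seed)
    max_off = max(trial_duration_s - duration_s, 0.0)
    t0 = float(rng.uniform(0.0, max_off)) if max_off > 0 else 0.0
    return build_activity_vectors(events, env, days, n_trials, master_cells,
                                  time_window=(t0, duration_s), **kwargs)
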