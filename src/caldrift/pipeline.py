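"""End-to-end orchestration: generate -> detect -> register -> analyze -> decode.

Every stage reads and writes the package's tabular formats, so stages can
be toggled and real data can enter at the event-table boundary. A single
root seed fans out to named substreams per stage; the summary JSON is
byte-reproducible from the provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .config import (DetectionParams, ENVIRONMENTS, SimConfig, session_keys,
                     substream)
from .decoders import (AcrossEnvTimeDecoder, OrdinalTimeDecoder,
                       WithinEnvTimeDecoder, build_activity_vectors,
                       segment_vectors, shuffle_day_labels)
from .detection import detect_dataset_events
from .drift import (activity_divergence, ensemble_correlation_matrix,
                    event_rate_table, maximal_monotonic_sequence,
                    monotonicity_score, peak_displacement,
                    rate_cv_poisson_null, recurrence_probability,
                    session_rate_matrix)
from .place import (best_track_alignment, compute_rate_map,
                    place_field_significance, population_vector_correlation,
                    spatial_information)
from .registration import (align_session_maps, footprint_qc,
                           identity_registration, register_cells,
                           registration_accuracy)
from .synthetic import SyntheticDataset, generate_dataset

logger = logging.getLogger("caldrift")


@dataclass
class PipelineConfig:
    out_dir: str = "caldrift_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    registration_method: str = "correlation"
    registration_threshold: Optional[float] = None
    events_path: Optional[str] = None   # skip simulation, load events
    run_simulate: bool = True
    run_detect: bool = False            # needs traces + footprints
    run_register: bool = False          # needs footprints
    run_place: bool = True
    run_drift: bool = True
    run_decode: bool = True
    n_place_shuffles: int = 1000
    n_label_shuffles: int = 10
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("sim", "detection")}
        d["sim"] = self.sim.to_dict()
        d["detection"] = self.detection.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["sim"] = SimConfig.from_dict(d.get("sim", {}))
        d["detection"] = DetectionParams.from_dict(d.get("detection", {}))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# analysis blocks reused by the CLI and the acceptance script
# ---------------------------------------------------------------------------

def place_field_table(dataset: SyntheticDataset, n_shuffles: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Spatial information + shuffle significance per cell/session/direction."""
    cfg = dataset.config
    rng = substream(seed, "place")
    rows = []
    for day in cfg.day_values:
        for env in ENVIRONMENTS:
            trajs = [dataset.trajectories[(env, day, t)]
                     for t in range(1, cfg.trials_per_session + 1)]
            sess = dataset.events[(dataset.events["env"] == env)
                                  & (dataset.events["day"] == day)]
            for cid, grp in sess.groupby("cell_id"):
                for direction in ("right", "left"):
                    rm = compute_rate_map(grp, trajs, direction,
                                          cfg.track_length, cfg.n_bins)
                    if rm.n_events == 0 or rm.r_bar == 0:
                        continue
                    res = place_field_significance(
                        rm, cfg.track_length, n_shuffles,
                        seed=int(rng.integers(2 ** 31)))
                    rows.append((cid, env, day, direction, res.n_events,
                                 res.spatial_information, res.p_value,
                                 res.is_place_cell, res.field_position_cm))
    return pd.DataFrame(rows, columns=["cell_id", "env", "day", "direction",
                                       "n_events", "si_bits", "p_value",
                                       "is_place_cell", "field_cm"])


def rate_map_matrix(dataset: SyntheticDataset, env: str, day: int,
                    cells: list, direction: str = "right") -> np.ndarray:
    """(n_cells, n_bins) smoothed rate maps for a session, zeros for silent cells."""
    cfg = dataset.config
    trajs = [dataset.trajectories[(env, day, t)]
             for t in range(1, cfg.trials_per_session + 1)]
    sess = dataset.events[(dataset.events["env"] == env)
                          & (dataset.events["day"] == day)]
    out = np.zeros((len(cells), cfg.n_bins))
    for i, cid in enumerate(cells):
        grp = sess[sess["cell_id"] == cid]
        if len(grp) == 0:
            continue
        rm = compute_rate_map(grp, trajs, direction, cfg.track_length, cfg.n_bins)
        out[i] = rm.rate
    return out


def decoder_summary_from_events(events: pd.DataFrame, days: list, cells: list,
                                trials_per_session: int,
                                trial_duration: float,
                                n_label_shuffles: int = 10, seed: int = 0,
                                segment_durations: tuple = ()) -> dict:
    """Run the three time decoders (and their controls) on an event table."""
    av = {env: build_activity_vectors(events, env, days,
                                      trials_per_session, cells)
          for env in ENVIRONMENTS}

    out: dict = {}
    # ordinal decoder, per environment and both together
    ses = {env: av[env].sessions for env in ENVIRONMENTS}
    for label, X in (("A", ses["A"]), ("B", ses["B"]),
                     ("both", [ses["A"], ses["B"]])):
        od = OrdinalTimeDecoder().fit(X)
        out[f"ordinal_{label}"] = {
            "recovered": bool(od.recovers_order_),
            "p_value": od.p_value_,
            "n_classes": od.n_classes_,
        }

    # within-environment trial decoder + label-shuffle chance
    for env in ENVIRONMENTS:
        dec = WithinEnvTimeDecoder().fit(av[env].trials)
        res = dec.predict()
        out[f"within_{env}"] = {"accuracy": res.accuracy,
                                "neighbor_rate": res.neighbor_rate,
                                "mean_abs_error": res.mean_abs_error}
        excl = WithinEnvTimeDecoder(exclude_same_day=True).fit(av[env].trials)
        r2 = excl.predict()
        out[f"within_{env}_exclude_same_day"] = {
            "accuracy": r2.accuracy, "neighbor_rate": r2.neighbor_rate}
    # chance control: decode the real test trials against training patterns
    # whose day labels were shuffled per cell (shuffling test and training
    # together would leave each cell self-aligned and decode perfectly)
    sh_acc = []
    for k, sh in enumerate(shuffle_day_labels(av["A"].trials,
                                              n_label_shuffles, seed)):
        sh_acc.append(WithinEnvTimeDecoder().fit(sh)
                      .predict(av["A"].trials).accuracy)
    out["within_A_label_shuffle"] = {"mean_accuracy": float(np.mean(sh_acc)),
                                     "n_shuffles": n_label_shuffles}

    # across-environment decoders (test A against training B)
    sdec = AcrossEnvTimeDecoder(level="session").fit(av["B"].sessions)
    sres = sdec.predict(av["A"].sessions)
    out["across_session"] = {"accuracy": sres.accuracy,
                             "neighbor_rate": sres.neighbor_rate,
                             "mean_abs_error": sres.mean_abs_error}
    tdec = AcrossEnvTimeDecoder(level="trial").fit(av["B"].trials)
    tres = tdec.predict(av["A"].trials)
    out["across_trial"] = {"accuracy": tres.accuracy,
                           "neighbor_rate": tres.neighbor_rate}

    # decoding from short trial fractions
    for tau in segment_durations:
        seg = segment_vectors(events, "A", days,
                              trials_per_session, cells, tau,
                              trial_duration, seed=seed)
        dec = WithinEnvTimeDecoder().fit(av["A"].trials)
        res = dec.predict(seg.trials)
        out[f"within_A_segment_{int(tau)}s"] = {"accuracy": res.accuracy}
    return out


def decoder_summary(dataset: SyntheticDataset, n_label_shuffles: int = 10,
                    seed: int = 0, segment_durations: tuple = ()) -> dict:
    cfg = dataset.config
    return decoder_summary_from_events(
        dataset.events, list(cfg.day_values), list(range(cfg.n_cells)),
        cfg.trials_per_session, cfg.trial_duration,
        n_label_shuffles, seed, segment_durations)


def drift_summary_from_events(events: pd.DataFrame, days: list, cells: list,
                              trials_per_session: int, trial_duration: float,
                              seed: int = 0) -> dict:
    session_min = trials_per_session * trial_duration / 60.0

    vectors = {}
    active = {}
    for env in ENVIRONMENTS:
        mat = session_rate_matrix(events, cells, env, days, session_min)
        for j, day in enumerate(days):
            vectors[(env, day)] = mat[:, j] * session_min  # counts
            active[(env, day)] = mat[:, j] > 0
    ens = ensemble_correlation_matrix(vectors)
    dec = ens.decay
    within = dec[dec["kind"] == "within"]
    across = dec[dec["kind"] == "across"]
    rec = recurrence_probability(active)

    trial_min = trial_duration / 60.0
    rates = event_rate_table(events, cells, trial_min, trials_per_session)
    div = {int(d): activity_divergence(rates, d) for d in days}

    rate_a = session_rate_matrix(events, cells, "A", days, session_min)
    always = np.all(rate_a > 0, axis=1)
    mono_scores = [monotonicity_score(rate_a[i]) for i in range(len(cells))
                   if rate_a[i].sum() > 0]
    mono_lens = [maximal_monotonic_sequence(rate_a[i])
                 for i in range(len(cells)) if rate_a[i].sum() > 0]
    counts = rate_a[always] * session_min
    cv = rate_cv_poisson_null(counts, seed=seed) if always.sum() >= 2 else None

    return {
        "within_corr_by_lag": {int(r.lag_days): float(r
                                                      ["mean"]) for _, r in within.iterrows()},
        "across_corr_by_lag": {int(r.lag_days): float(r["mean"]) for _, r in across.iterrows()},
        "recurrence_within": {int(r.lag_days): float(r["mean"])
                              for _, r in rec[rec["kind"] == "within"].iterrows()},
        "recurrence_across": {int(r.lag_days): float(r["mean"])
                              for _, r in rec[rec["kind"] == "across"].iterrows()},
        "activity_divergence_by_day": div,
        "mean_monotonicity_score": float(np.mean(mono_scores)),
        "mean_max_monotonic_len": float(np.mean(mono_lens)),
        "n_always_active_A": int(always.sum()),
        "mean_cv_observed": float(cv.observed_cv.mean()) if cv else None,
        "mean_cv_poisson_null": float(cv.null_cv.mean()) if cv else None,
    }


def drift_summary(dataset: SyntheticDataset, seed: int = 0) -> dict:
    cfg = dataset.config
    return drift_summary_from_events(
        dataset.events, list(cfg.day_values), list(range(cfg.n_cells)),
        cfg.trials_per_session, cfg.trial_duration, seed)


def run_registration_stage(dataset: SyntheticDataset,
                           method: str = "correlation",
                           threshold: Optional[float] = None) -> pd.DataFrame:
    """QC + alignment + matching on a dataset with rendered footprints."""
    if dataset.footprints is None:
        raise ValueError("dataset has no footprints; enable include_footprints")
    cfg = dataset.config
    fps = {}
    for key, recs in dataset.footprints.sessions.items():
        fps[key] = footprint_qc(recs, cfg.um_per_px)
    cents = {k: np.array([f.centroid_um for f in v]) for k, v in fps.items()}
    ref = min(fps, key=lambda k: (k[1], k[0]))
    transforms = align_session_maps(cents, ref, cfg.fov_size, cfg.um_per_px)
    return register_cells(fps, transforms, method, threshold, cfg.um_per_px)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def validate_inputs(events_path: Optional[str] = None,
                    registration_path: Optional[str] = None) -> list[str]:
    """Schema and referential-integrity checks on tabular inputs."""
    violations: list[str] = []
    events = None
    if events_path is not None:
        try:
            events = io.read_events(events_path)
        except Exception as e:  # surface schema problems as violations
            violations.append(f"events: {e}")
    if registration_path is not None:
        try:
            reg = io.read_registration(registration_path)
        except Exception as e:
            violations.append(f"registration: {e}")
        else:
            if events is not None:
                ev_sessions = set(map(tuple, events[["env", "day"]]
                                      .drop_duplicates().itertuples(index=False)))
                reg_sessions = set(map(tuple, reg[["env", "day"]]
                                       .drop_duplicates().itertuples(index=False)))
                unknown = reg_sessions - ev_sessions
                for s in sorted(unknown):
                    violations.append(f"registration cites unknown session {s}")
            dup = reg.duplicated(subset=["env", "day", "local_id"])
            if dup.any():
                violations.append("registration maps a local cell twice "
                                  "within a session")
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; write CSVs, summary and provenance."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = SimConfig.from_dict({**config.sim.to_dict(), "seed": config.seed})
    summary: dict = {}
    stage = "simulate"
    try:
        if config.events_path is not None:
            events = io.read_events(config.events_path)
            dataset = None
        elif config.run_simulate:
            dataset = generate_dataset(
                sim, include_traces=config.run_detect,
                include_footprints=config.run_detect or config.run_register)
            events = dataset.events
            io.write_events(events, out_dir / "events.csv")
            io.write_ground_truth(dataset.ground_truth(),
                                  out_dir / "ground_truth.json")
        else:
            raise ValueError("no input: enable run_simulate or set events_path")

        if config.run_detect and dataset is not None:
            stage = "detect"
            detected = detect_dataset_events(dataset.traces, dataset.footprints,
                                             config.detection)
            io.write_events(_attach_kinematics(detected, dataset),
                            out_dir / "events_detected.csv")
            summary["detection"] = {
                "n_true_events": int(len(dataset.events)),
                "n_detected_events": int(len(detected)),
            }

        if config.run_register and dataset is not None:
            stage = "register"
            table = run_registration_stage(dataset, config.registration_method,
                                           config.registration_threshold)
            io.write_registration(table, out_dir / "registration.csv")
            summary["registration"] = {
                "n_masters": int(table["master_id"].nunique()),
                "accuracy": registration_accuracy(table),
                "method": config.registration_method,
            }

        days = sorted(events["day"].unique()) if dataset is None \
            else list(sim.day_values)
        cells = sorted(events["cell_id"].unique()) if dataset is None \
            else list(range(sim.n_cells))
        n_trials = int(events["trial"].max()) if dataset is None \
            else sim.trials_per_session

        if config.run_place and dataset is None:
            logger.info("place stage skipped: needs trajectories "
                        "(events-only input)")
        if config.run_place and dataset is not None:
            stage = "place"
            pf = place_field_table(dataset, config.n_place_shuffles,
                                   seed=config.seed)
            pf.to_csv(out_dir / "place_fields.csv", index=False)
            elig = pf.dropna(subset=["p_value"])
            summary["place"] = {
                "n_tested": int(len(elig)),
                "fraction_significant": float(elig["is_place_cell"].mean())
                if len(elig) else None,
                "median_si_bits": float(elig["si_bits"].median())
                if len(elig) else None,
            }

        if config.run_drift:
            stage = "drift"
            summary["drift"] = drift_summary_from_events(
                events, days, cells, n_trials, sim.trial_duration,
                seed=config.seed)

        if config.run_decode:
            stage = "decode"
            summary["decoders"] = decoder_summary_from_events(
                events, days, cells, n_trials, sim.trial_duration,
                config.n_label_shuffles, seed=config.seed)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None

    cfg_dict = config.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True))
    (out_dir / "provenance.json").write_text(
        json.dumps(_jsonable(provenance), indent=1, sort_keys=True))
    return summary


def _attach_kinematics(events: pd.DataFrame, dataset: SyntheticDataset
                       ) -> pd.DataFrame:
    """Fill position/velocity for detected events from the trajectory."""
    ev = events.copy()
    fr = dataset.config.frame_rate
    pos = np.full(len(ev), np.nan)
    vel = np.full(len(ev), np.nan)
    for idx, row in ev.iterrows():
        key = (row["env"], int(row["day"]), int(row["trial"]))
        traj = dataset.trajectories.get(key)
        if traj is None:
            continue
        f = int(round(row["time_s"] * fr))
        f = min(max(f, 0), len(traj.position) - 1)
        pos[idx] = traj.position[f]
        vel[idx] = traj.velocity[f]
    ev["position_cm"] = pos
    ev["velocity_cm_s"] = vel
    return ev


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x
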