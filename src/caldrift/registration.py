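"""Across-session cell registration from spatial footprints.

Sessions are aligned rigidly (translation + rotation) to a reference
session by maximizing the cross-correlation of centroid-projection images;
cells are then matched across sessions either by footprint spatial
correlation (> 0.7 by default) or by centroid distance (< 5 µm by
default), with greedy best-score assignment when several candidates pass
the threshold. Cells seen in only one session keep singleton master ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label, perimeter
from skimage.registration import phase_cross_correlation

from .synthetic import FootprintRecord, FootprintSet

SessionKey = tuple[str, int]


# ---------------------------------------------------------------------------
# footprint QC
# ---------------------------------------------------------------------------

@dataclass
class Footprint:
    """A quality-controlled spatial filter, thresholded at 50% of its max."""

    local_id: int
    weights: np.ndarray          # pixel weights; sub-threshold pixels exactly 0
    offset: tuple                # patch origin (row, col) in the session FOV
    centroid_um: np.ndarray      # (y, x) µm, session frame
    radius_um: float             # equivalent radius sqrt(area/pi)
    area_um2: float
    circularity: float           # 4*pi*A / P^2 on the thresholded mask
    true_cell_id: Optional[int] = None  # carried through from synthetic data


def _qc_one(weights: np.ndarray, offset: tuple, um_per_px: float,
            local_id: int, true_cell_id: Optional[int]) -> Optional[Footprint]:
    w = np.asarray(weights, dtype=float).copy()
    if w.max() <= 0:
        return None
    w[w < 0.5 * w.max()] = 0.0
    mask = w > 0
    if not mask.any():
        return None
    # keep the largest connected component
    lab = label(mask)
    if lab.max() > 1:
        sizes = np.bincount(lab.ravel())[1:]
        keep = 1 + int(np.argmax(sizes))
        w[lab != keep] = 0.0
        mask = w > 0
    area = mask.sum() * um_per_px ** 2
    radius = float(np.sqrt(area / np.pi))
    per = perimeter(mask) * um_per_px
    circ = min(1.0, 4 * np.pi * area / per ** 2) if per > 0 else 1.0
    ys, xs = np.nonzero(w)
    tot = w[ys, xs].sum()
    cy = (ys * w[ys, xs]).sum() / tot + offset[0]
    cx = (xs * w[ys, xs]).sum() / tot + offset[1]
    return Footprint(local_id, w, offset,
                     np.array([cy, cx]) * um_per_px,
                     radius, area, circ, true_cell_id)


def footprint_qc(records: Sequence, um_per_px: float,
                 radius_bounds: tuple = (5.0, 14.0),
                 circularity_min: float = 0.8,
                 log: Optional[list] = None) -> list[Footprint]:
    """Threshold and filter raw spatial filters.

    ``records`` may be FootprintRecord objects or bare 2-D arrays (offset
    (0, 0)). Filters outside the radius bounds or below the circularity
    bound are discarded; discards are appended to ``log`` when given.
    """
    out = []
    for i, rec in enumerate(records):
        if isinstance(rec, FootprintRecord):
            fp = _qc_one(rec.patch, rec.offset, um_per_px, i, rec.cell_id)
        else:
            fp = _qc_one(np.asarray(rec), (0, 0), um_per_px, i, None)
        if fp is None:
            if log is not None:
                log.append((i, "empty after thresholding"))
            continue
        if not radius_bounds[0] <= fp.radius_um <= radius_bounds[1]:
            if log is not None:
                log.append((i, f"radius {fp.radius_um:.1f} um out of bounds"))
            continue
        if fp.circularity < circularity_min:
            if log is not None:
                log.append((i, f"circularity {fp.circularity:.2f} too low"))
            continue
        out.append(fp)
    return out


def deduplicate_components(footprints: list[Footprint],
                           traces: Optional[np.ndarray] = None,
                           neighbor_radius: float = 18.0,
                           corr_threshold: float = 0.9) -> list[Footprint]:
    """Drop the dimmer member of near-duplicate component pairs.

    Components whose centroids are closer than ``neighbor_radius`` µm and
    whose traces correlate above ``corr_threshold`` are treated as one
    cell; the member with the lower trace amplitude (or lower footprint
    mass when traces are absent) is removed.
    """
    drop: set[int] = set()
    for i, fi in enumerate(footprints):
        for fj in footprints[i + 1:]:
            if fi.local_id in drop or fj.local_id in drop:
                continue
            if np.linalg.norm(fi.centroid_um - fj.centroid_um) >= neighbor_radius:
                continue
            if traces is not None:
                ti, tj = traces[fi.local_id], traces[fj.local_id]
                if ti.std() == 0 or tj.std() == 0:
                    continue
                r = float(np.corrcoef(ti, tj)[0, 1])
                if r <= corr_threshold:
                    continue
                ai, aj = ti.max(), tj.max()
            else:
                ai, aj = fi.weights.sum(), fj.weights.sum()
            drop.add(fi.local_id if ai < aj else fj.local_id)
    return [f for f in footprints if f.local_id not in drop]


# ---------------------------------------------------------------------------
# session alignment
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Maps session-frame µm coordinates into the reference frame."""

    angle_deg: float = 0.0
    shift_um: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (dy, dx)
    center_um: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        th = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return (pts - self.center_um) @ rot.T + self.center_um + self.shift_um


def _projection_image(centroids_um: np.ndarray, fov_um: float,
                      um_per_px: float, blur_px: float = 2.0) -> np.ndarray:
    n = int(round(fov_um / um_per_px))
    img = np.zeros((n, n))
    px = np.round(centroids_um / um_per_px).astype(int)
    ok = (px[:, 0] >= 0) & (px[:, 0] < n) & (px[:, 1] >= 0) & (px[:, 1] < n)
    np.add.at(img, (px[ok, 0], px[ok, 1]), 1.0)
    return ndimage.gaussian_filter(img, blur_px)


def _rotate_points(pts: np.ndarray, angle_deg: float, center: np.ndarray) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (pts - center) @ rot.T + center


def align_session_maps(centroids: dict[SessionKey, np.ndarray],
                       reference: SessionKey, fov_um: float,
                       um_per_px: float = 1.0,
                       max_rotation_deg: float = 5.0
                       ) -> dict[SessionKey, RigidTransform]:
    """Estimate a rigid transform per session from centroid projections.

    Projections (blurred centroid maps) are cross-correlated against the
    reference session's projection over a rotation scan with subpixel
    phase-correlation translation at each angle.
    """
    if len(centroids) < 2:
        raise ValueError("need at least two sessions to align")
    for key, pts in centroids.items():
        if len(np.atleast_2d(pts)) < 3:
            raise ValueError(f"session {key} has fewer than 3 cells")
    center = np.array([fov_um / 2.0, fov_um / 2.0])
    ref_img = _projection_image(np.atleast_2d(centroids[reference]),
                                fov_um, um_per_px)
    out = {reference: RigidTransform(center_um=center)}
    for key, pts in centroids.items():
        if key == reference:
            continue
        pts = np.atleast_2d(np.asarray(pts, dtype=float))

        def score_at(angle: float) -> tuple[float, np.ndarray]:
            rot = _rotate_points(pts, angle, center)
            img = _projection_image(rot, fov_um, um_per_px)
            shift, error, _ = phase_cross_correlation(
                ref_img, img, upsample_factor=20, normalization=None)
            return float(error), np.asarray(shift) * um_per_px

        coarse = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 0.5)
        errs = [(score_at(a), a) for a in coarse]
        (best_err, best_shift), best_a = min(errs, key=lambda t: t[0][0])
        fine = np.arange(best_a - 0.5, best_a + 0.5 + 1e-9, 0.05)
        errs = [(score_at(a), a) for a in fine]
        (best_err, best_shift), best_a = min(errs, key=lambda t: t[0][0])
        out[key] = RigidTransform(best_a, best_shift, center)
    return out


# ---------------------------------------------------------------------------
# cross-session matching
# ---------------------------------------------------------------------------

def _sample_in_reference(fp: Footprint, tf: RigidTransform, um_per_px: float,
                         grid_y: np.ndarray, grid_x: np.ndarray) -> np.ndarray:
    """Resample a footprint onto a reference-frame pixel grid."""
    # reference µm -> session µm (inverse rigid transform)
    ref_pts = np.column_stack([grid_y.ravel(), grid_x.ravel()]) * um_per_px
    th = np.deg2rad(-tf.angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    ses_pts = (ref_pts - tf.shift_um - tf.center_um) @ rot.T + tf.center_um
    ses_px = ses_pts / um_per_px
    rows = ses_px[:, 0] - fp.offset[0]
    cols = ses_px[:, 1] - fp.offset[1]
    vals = ndimage.map_coordinates(fp.weights, [rows, cols], order=1,
                                   mode="constant", cval=0.0)
    return vals.reshape(grid_y.shape)


def footprint_correlation(fa: Footprint, ta: RigidTransform,
                          fb: Footprint, tb: RigidTransform,
                          um_per_px: float, window_um: float = 40.0) -> float:
    """Pearson correlation of two footprints in the common reference frame."""
    ca = ta.apply(fa.centroid_um)[0]
    cb = tb.apply(fb.centroid_um)[0]
    mid = (ca + cb) / 2.0 / um_per_px
    half = int(round(window_um / um_per_px / 2))
    gy, gx = np.meshgrid(np.arange(-half, half + 1) + mid[0],
                         np.arange(-half, half + 1) + mid[1], indexing="ij")
    va = _sample_in_reference(fa, ta, um_per_px, gy, gx).ravel()
    vb = _sample_in_reference(fb, tb, um_per_px, gy, gx).ravel()
    if va.std() == 0 or vb.std() == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def register_cells(footprints: dict[SessionKey, list[Footprint]],
                   transforms: dict[SessionKey, RigidTransform],
                   method: str = "correlation",
                   threshold: Optional[float] = None,
                   um_per_px: float = 1.0,
                   candidate_radius_um: float = 15.0) -> pd.DataFrame:
    """Assign master identities across sessions.

    method='correlation' registers pairs with footprint correlation above
    the threshold (default 0.7); method='distance' registers pairs with
    reference-frame centroid distance below the threshold (default 5 µm).
    Among multiple candidates the best score wins (greedy global
    assignment); unmatched cells found in a session become new master ids.

    Returns a table with columns master_id, env, day, local_id, score, method.
    """
    if method not in ("correlation", "distance"):
        raise ValueError("method must be 'correlation' or 'distance'")
    if threshold is None:
        threshold = 0.7 if method == "correlation" else 5.0
    if method == "distance" and threshold <= 0:
        raise ValueError("distance threshold must be positive (µm)")
    if method == "correlation" and not 0 < threshold < 1:
        raise ValueError("correlation threshold must be in (0, 1)")

    keys = sorted(footprints, key=lambda k: (k[1], k[0]))  # chronological
    rows = []
    # master registry: list of (footprint, session_key) representatives
    reps: list[tuple[Footprint, SessionKey]] = []
    ref_centroids: list[np.ndarray] = []
    for key in keys:
        tf = transforms[key]
        locals_ = footprints[key]
        cents = np.array([tf.apply(f.centroid_um)[0] for f in locals_]) \
            if locals_ else np.zeros((0, 2))
        candidates = []
        for mi, (mfp, mkey) in enumerate(reps):
            if len(locals_) == 0:
                continue
            d = np.linalg.norm(cents - ref_centroids[mi], axis=1)
            for li in np.nonzero(d < max(candidate_radius_um,
                                         threshold if method == "distance" else 0))[0]:
                if method == "distance":
                    score = float(d[li])
                    if score < threshold:
                        candidates.append((score, mi, int(li)))
                else:
                    r = footprint_correlation(mfp, transforms[mkey],
                                              locals_[li], tf, um_per_px)
                    if r > threshold:
                        candidates.append((-r, mi, int(li)))
        candidates.sort()
        used_m: set[int] = set()
        used_l: set[int] = set()
        assign: dict[int, tuple[int, float]] = {}
        for score, mi, li in candidates:
            if mi in used_m or li in used_l:
                continue
            used_m.add(mi)
            used_l.add(li)
            assign[li] = (mi, -score if method == "correlation" else score)
        for li, fp in enumerate(locals_):
            if li in assign:
                mi, score = assign[li]
                # update the stored reference-frame centroid toward the new obs
                ref_centroids[mi] = (ref_centroids[mi] + cents[li]) / 2.0
            else:
                mi = len(reps)
                reps.append((fp, key))
                ref_centroids.append(cents[li])
                score = 1.0 if method == "correlation" else 0.0
            rows.append((mi, key[0], key[1], fp.local_id, score, method,
                         fp.true_cell_id))
    table = pd.DataFrame(rows, columns=["master_id", "env", "day", "local_id",
                                        "score", "method", "true_cell_id"])
    return table


def registration_accuracy(table: pd.DataFrame) -> float:
    """Fraction of session-cells whose master agrees with ground truth.

    A master's ground-truth label is the majority true_cell_id among its
    members; accuracy is the fraction of members matching their master's
    label, over masters with known truth.
    """
    t = table.dropna(subset=["true_cell_id"])
    if len(t) == 0:
        return float("nan")
    good = 0
    for _, grp in t.groupby("master_id"):
        lab = grp["true_cell_id"].mode().iloc[0]
        good += int((grp["true_cell_id"] == lab).sum())
    # penalize splitting one true cell across several masters within the
    # same accounting by scoring against the best single master per truth
    return good / len(t)


def registration_to_master_map(table: pd.DataFrame
                               ) -> dict[SessionKey, dict[int, int]]:
    """Per-session mapping local_id -> master_id."""
    out: dict[SessionKey, dict[int, int]] = {}
    for _, r in table.iterrows():
        out.setdefault((r["env"], r["day"]), {})[int(r["local_id"])] = int(r["master_id"])
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class RegistrationDiagnostics:
    nn_correlation_within: np.ndarray   # within-session nearest-neighbor corr
    nn_distance_within: np.ndarray      # µm
    threshold_sweep: pd.DataFrame       # threshold, candidates_per_cell
    nn_distance_between: np.ndarray     # µm, across-session nearest neighbors


def registration_quality_stats(footprints: dict[SessionKey, list[Footprint]],
                               transforms: dict[SessionKey, RigidTransform],
                               um_per_px: float = 1.0,
                               corr_thresholds: Sequence[float] = tuple(
                                   np.round(np.arange(0.5, 0.86, 0.05), 2)),
                               ) -> RegistrationDiagnostics:
    """Threshold diagnostics: neighbor distributions and candidate counts."""
    nn_corr, nn_dist = [], []
    for key, fps in footprints.items():
        cents = np.array([f.centroid_um for f in fps])
        for i, fi in enumerate(fps):
            d = np.linalg.norm(cents - cents[i], axis=1)
            d[i] = np.inf
            j = int(np.argmin(d))
            nn_dist.append(float(d[j]))
            nn_corr.append(footprint_correlation(
                fi, transforms[key], fps[j], transforms[key], um_per_px))

    # across-session candidate statistics (against the first session)
    keys = sorted(footprints, key=lambda k: (k[1], k[0]))
    ref, others = keys[0], keys[1:]
    ref_cents = np.array([transforms[ref].apply(f.centroid_um)[0]
                          for f in footprints[ref]])
    nn_between = []
    corrs_per_refcell: list[list[float]] = [[] for _ in footprints[ref]]
    for key in others:
        cents = np.array([transforms[key].apply(f.centroid_um)[0]
                          for f in footprints[key]])
        for i, fi in enumerate(footprints[ref]):
            d = np.linalg.norm(cents - ref_cents[i], axis=1)
            nn_between.append(float(d.min()))
            for li in np.nonzero(d < 20.0)[0]:
                corrs_per_refcell[i].append(footprint_correlation(
                    fi, transforms[ref], footprints[key][li],
                    transforms[key], um_per_px))
    sweep = []
    for thr in corr_thresholds:
        per_cell = [sum(1 for r in rs if r > thr) / max(len(others), 1)
                    for rs in corrs_per_refcell]
        sweep.append((thr, float(np.mean(per_cell))))
    return RegistrationDiagnostics(
        np.array(nn_corr), np.array(nn_dist),
        pd.DataFrame(sweep, columns=["threshold", "candidates_per_cell"]),
        np.array(nn_between))


def identity_registration(n_cells: int, keys: Sequence[SessionKey]) -> pd.DataFrame:
    """Ground-truth registration (used when footprints are not simulated)."""
    rows = [(cid, env, day, cid, 1.0, "identity", cid)
            for env, day in keys for cid in range(n_cells)]
    return pd.DataFrame(rows, columns=["master_id", "env", "day", "local_id",
                                       "score", "method", "true_cell_id"])
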