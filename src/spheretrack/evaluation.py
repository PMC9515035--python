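"""Tracking-accuracy metrics and experiment harnesses.

Accuracy is always judged on *relative* motions, so no registration between
the tracker under test and the reference tracker is needed:

* sphere distance error ``d_e``: difference between a sphere's displacement
  (relative to its position at the reference pose) as seen by the two
  systems — a signed scalar in mm;
* relative pose error: ``T_e = (test_rel)^-1 (ref_rel)`` where each
  ``rel = pose_ref^-1 pose_p``; its translation ``t_e`` (mm) and rotation
  ``r_e`` (intrinsic Z-Y-X Euler, degrees) are reported per axis and as
  magnitudes.

Summaries follow the min / 25th / median / 75th / max / RMS scheme, with
quantiles by linear interpolation between order statistics.  ``d_e,RMS`` is
the RMS over the repeated samples of one pose (static protocol), whose
distribution over poses and spheres is then summarized.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from .bundle import read_frame_bundle
from .calibration import temporal_align
from .errors import EvaluationError, InputError
from .geometry import EulerTriple, RigidTransform, rotation_to_euler
from .kalman import KalmanParams
from .simulate import MarkerGeometry
from .tracking import TrackerConfig, TrackingResult, track_sequence

__all__ = [
    "RelativePoseError",
    "ErrorSummary",
    "sphere_distance_error",
    "relative_pose_error",
    "summarize_errors",
    "run_static_evaluation",
    "run_dynamic_evaluation",
    "StaticEvaluationReport",
    "DynamicEvaluationReport",
    "load_bundle",
]


@dataclasses.dataclass(frozen=True)
class RelativePoseError:
    """Discrepancy between relative motions measured by two tracking systems."""

    t_e: np.ndarray  # (3,) mm
    r_e: EulerTriple  # degrees

    @property
    def t_mag(self) -> float:
        return float(np.linalg.norm(self.t_e))

    @property
    def r_mag(self) -> float:
        return self.r_e.magnitude


@dataclasses.dataclass(frozen=True)
class ErrorSummary:
    """min / 25th / median / 75th / max / RMS of an error sample."""

    min: float
    p25: float
    median: float
    p75: float
    max: float
    rms: float
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def sphere_distance_error(test_p1, test_p2, ref_p1, ref_p2) -> float:
    """Signed distance error between two systems' views of the same motion.

    ``||test_p2 - test_p1|| - ||ref_p2 - ref_p1||`` for one sphere observed at
    two poses by the tracker under test and the reference system (mm).
    """
    t1, t2 = np.asarray(test_p1, float), np.asarray(test_p2, float)
    r1, r2 = np.asarray(ref_p1, float), np.asarray(ref_p2, float)
    return float(np.linalg.norm(t2 - t1) - np.linalg.norm(r2 - r1))


def relative_pose_error(
    test_p1: RigidTransform,
    test_p2: RigidTransform,
    ref_p1: RigidTransform,
    ref_p2: RigidTransform,
) -> RelativePoseError:
    """Relative pose error between two systems' views of the motion p1 -> p2.

    ``T_e = (test_p1^-1 test_p2)^-1 (ref_p1^-1 ref_p2)``; identical relative
    motions give zero.  Invariant to any rigid change of either system's base
    frame, which is what makes it usable without hand-eye registration.
    """
    rel_test = test_p1.inverse() @ test_p2
    rel_ref = ref_p1.inverse() @ ref_p2
    T_e = rel_test.inverse() @ rel_ref
    return RelativePoseError(t_e=T_e.translation.copy(), r_e=rotation_to_euler(T_e))


def summarize_errors(samples) -> ErrorSummary:
    """Order statistics (linear-interpolation quantiles) and RMS of a sample."""
    x = np.asarray(samples, float).ravel()
    if x.size == 0:
        raise InputError("cannot summarize an empty error sample")
    q = np.percentile(x, [25, 50, 75])
    return ErrorSummary(
        min=float(x.min()),
        p25=float(q[0]),
        median=float(q[1]),
        p75=float(q[2]),
        max=float(x.max()),
        rms=float(np.sqrt(np.mean(x * x))),
        n=int(x.size),
    )


# -------------------------------------------------------------------------
# bundle access helpers
# -------------------------------------------------------------------------


class load_bundle:
    """A disk frame bundle re-exposed with the synthetic-bundle interface
    (frames, lookup, truth table, marker geometry)."""

    def __init__(self, path):
        self.frames, self.lookup, self.meta = read_frame_bundle(path)
        truth_path = os.path.join(path, "truth.csv")
        self.truth = pd.read_csv(truth_path) if os.path.exists(truth_path) else None
        marker_path = os.path.join(path, "marker.txt")
        self.geometry = MarkerGeometry.load(marker_path) if os.path.exists(marker_path) else None

    def __iter__(self):
        return iter(self.frames)

    def __len__(self):
        return len(self.frames)


def _truth_pose(row) -> RigidTransform:
    _, T = RigidTransform.from_quat_row(
        [row["timestamp"], row["tx"], row["ty"], row["tz"], row["qw"], row["qx"], row["qy"], row["qz"]]
    )
    return T


def _truth_centers(row, n_spheres: int) -> np.ndarray:
    return np.array([[row[f"s{i}_x"], row[f"s{i}_y"], row[f"s{i}_z"]] for i in range(n_spheres)])


def _track_both(bundle, config: Optional[TrackerConfig]) -> dict[bool, TrackingResult]:
    config = config or TrackerConfig()
    out = {}
    for filt in (False, True):
        cfg = dataclasses.replace(config, filter_enabled=filt)
        out[filt] = track_sequence(bundle, bundle.geometry, getattr(bundle, "lookup", None), cfg)
    return out


_SUMMARY_METRICS = ("t_mag", "r_mag", "t_x", "t_y", "t_z", "r_x", "r_y", "r_z", "d_e_rms")


def _summary_table(samples_by_metric: dict, filter_on: bool) -> list[dict]:
    rows = []
    for metric, vals in samples_by_metric.items():
        if len(vals) == 0:
            continue
        s = summarize_errors(vals)
        rows.append({"metric": metric, "filter": "on" if filter_on else "off", **s.as_dict()})
    return rows


# -------------------------------------------------------------------------
# static protocol
# -------------------------------------------------------------------------


@dataclasses.dataclass
class StaticEvaluationReport:
    """Error summaries of a static multi-pose run, filter on and off."""

    table: pd.DataFrame  # metric x filter summary rows
    samples: dict  # (metric, filter_on) -> np.ndarray
    per_pose: pd.DataFrame  # pose-level d_e,RMS vs camera distance
    n_frames: int
    n_skipped: dict  # filter_on -> skipped frame count
    tracking: dict  # filter_on -> TrackingResult

    def summary(self, metric: str, filter_on: bool) -> ErrorSummary:
        return summarize_errors(self.samples[(metric, filter_on)])

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.table.to_csv(os.path.join(outdir, "static_summary.csv"), index=False)
        self.per_pose.to_csv(os.path.join(outdir, "static_per_pose.csv"), index=False)
        with open(os.path.join(outdir, "static_report.json"), "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=1)


def run_static_evaluation(
    bundle, config: Optional[TrackerConfig] = None
) -> StaticEvaluationReport:
    """Track a static multi-pose bundle (filter on and off) and score it.

    The first pose (``pose_index == 0``) is the reference; for every other
    pose, sample ``s`` is compared against sample ``s`` of the reference.
    Sphere distance errors use the same centers the pose registration used
    (raw or filtered, matching the setting being scored).
    """
    truth = bundle.truth
    if truth is None or "pose_index" not in truth.columns:
        raise EvaluationError("bundle lacks a static ground-truth table with pose_index")
    geometry = bundle.geometry
    n_s = geometry.n_spheres
    results = _track_both(bundle, config)

    pose_indices = truth["pose_index"].to_numpy()
    frames_of_pose = {p: np.flatnonzero(pose_indices == p) for p in np.unique(pose_indices)}
    ref_frames = frames_of_pose[0]
    true_pose = {p: _truth_pose(truth.iloc[frames_of_pose[p][0]]) for p in frames_of_pose}
    true_centers = {p: _truth_centers(truth.iloc[frames_of_pose[p][0]], n_s) for p in frames_of_pose}
    distance = {p: float(truth.iloc[frames_of_pose[p][0]]["distance_mm"]) for p in frames_of_pose}

    all_rows = []
    samples = {}
    per_pose_rows = []
    n_skipped = {}

    for filt, result in results.items():
        recs = result.records
        if all(recs[f].pose is None for f in ref_frames):
            raise EvaluationError("reference pose was never tracked")
        t_e_list, r_e_list = [], []
        per_pose_axis = {p: {"t": [], "r": []} for p in frames_of_pose if p != 0}
        d_e = {}  # (pose, sphere) -> list of d_e over samples
        skipped = 0
        for p, frames in frames_of_pose.items():
            if p == 0:
                continue
            for s, fp in enumerate(frames):
                fr = ref_frames[min(s, len(ref_frames) - 1)]
                rec_p, rec_r = recs[fp], recs[fr]
                if rec_p.pose is None or rec_r.pose is None:
                    skipped += 1
                    continue
                err = relative_pose_error(
                    rec_r.pose.world_from_marker,
                    rec_p.pose.world_from_marker,
                    true_pose[0],
                    true_pose[p],
                )
                t_e_list.append(err.t_e)
                r_e_list.append(err.r_e.as_array())
                per_pose_axis[p]["t"].append(err.t_e)
                per_pose_axis[p]["r"].append(err.r_e.as_array())
                centers_p = rec_p.filtered_centers if filt else rec_p.raw_centers
                centers_r = rec_r.filtered_centers if filt else rec_r.raw_centers
                for i in range(n_s):
                    if i in centers_p and i in centers_r:
                        d_e.setdefault((p, i), []).append(
                            sphere_distance_error(
                                centers_r[i], centers_p[i], true_centers[0][i], true_centers[p][i]
                            )
                        )
        n_skipped[filt] = skipped
        t_e = np.array(t_e_list)
        r_e = np.array(r_e_list)
        metric_samples = {
            "t_mag": np.linalg.norm(t_e, axis=1) if t_e.size else np.array([]),
            "r_mag": np.linalg.norm(r_e, axis=1) if r_e.size else np.array([]),
        }
        # per-axis RMS over the samples of each pose -> distribution over poses
        for ai, ax in enumerate("xyz"):
            tvals, rvals = [], []
            for p, d in per_pose_axis.items():
                if d["t"]:
                    tvals.append(np.sqrt(np.mean(np.array(d["t"])[:, ai] ** 2)))
                    rvals.append(np.sqrt(np.mean(np.array(d["r"])[:, ai] ** 2)))
            metric_samples[f"t_{ax}"] = np.array(tvals)
            metric_samples[f"r_{ax}"] = np.array(rvals)
        d_e_rms = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in d_e.items()}
        metric_samples["d_e_rms"] = np.array(list(d_e_rms.values()))
        for (p, i), v in d_e_rms.items():
            per_pose_rows.append(
                {
                    "pose_index": p,
                    "sphere": i,
                    "filter": "on" if filt else "off",
                    "distance_mm": distance[p],
                    "d_e_rms_mm": v,
                }
            )
        for metric, vals in metric_samples.items():
            samples[(metric, filt)] = vals
        all_rows.extend(_summary_table(metric_samples, filt))

    return StaticEvaluationReport(
        table=pd.DataFrame(all_rows),
        samples=samples,
        per_pose=pd.DataFrame(per_pose_rows),
        n_frames=len(truth),
        n_skipped=n_skipped,
        tracking=results,
    )


# -------------------------------------------------------------------------
# dynamic protocol
# -------------------------------------------------------------------------


@dataclasses.dataclass
class DynamicEvaluationReport:
    table: pd.DataFrame
    samples: dict
    estimated_shift_s: float
    n_frames: int
    n_skipped: dict
    tracking: dict

    def summary(self, metric: str, filter_on: bool) -> ErrorSummary:
        return summarize_errors(self.samples[(metric, filter_on)])

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.table.to_csv(os.path.join(outdir, "dynamic_summary.csv"), index=False)
        with open(os.path.join(outdir, "dynamic_report.json"), "w") as fh:
            json.dump(
                {"estimated_shift_s": self.estimated_shift_s, "summaries": self.table.to_dict(orient="records")},
                fh,
                indent=1,
            )


def run_dynamic_evaluation(
    bundle, config: Optional[TrackerConfig] = None
) -> DynamicEvaluationReport:
    """Track a dynamic bundle and score per-frame relative pose errors.

    The reference-tracker clock offset is first estimated from the leading
    sinusoidal segment by cross-correlation; each tracked frame is then
    matched to the nearest ground-truth timestamp after lag removal, and
    errors are computed against the first tracked pose as reference.
    """
    truth = bundle.truth
    if truth is None:
        raise EvaluationError("bundle lacks a ground-truth table")
    geometry = bundle.geometry
    if config is None:
        config = TrackerConfig(kalman=KalmanParams.dynamic_setting())
    results = _track_both(bundle, config)

    ot_times = truth["ot_timestamp"].to_numpy() if "ot_timestamp" in truth.columns else truth["timestamp"].to_numpy()
    true_xyz = truth[["tx", "ty", "tz"]].to_numpy()

    # estimate the clock offset from the unfiltered tracked trajectory
    raw = results[False]
    valid = [r for r in raw.records if r.pose is not None]
    if len(valid) < 10:
        raise EvaluationError("too few tracked frames for dynamic evaluation")
    trk_t = np.array([r.timestamp for r in valid])
    trk_p = np.array([r.pose.world_from_marker.translation for r in valid])
    shift = temporal_align(trk_t, trk_p, ot_times, true_xyz)

    all_rows, samples, n_skipped = [], {}, {}
    for filt, result in results.items():
        recs = [r for r in result.records if r.pose is not None]
        n_skipped[filt] = len(result.records) - len(recs)
        if not recs:
            raise EvaluationError("no tracked frames")
        t_e_list, r_e_list = [], []
        ref_rec = recs[0]
        ref_idx = int(np.argmin(np.abs(ot_times - (ref_rec.timestamp + shift))))
        ref_true = _truth_pose(truth.iloc[ref_idx])
        for rec in recs[1:]:
            idx = int(np.argmin(np.abs(ot_times - (rec.timestamp + shift))))
            err = relative_pose_error(
                ref_rec.pose.world_from_marker,
                rec.pose.world_from_marker,
                ref_true,
                _truth_pose(truth.iloc[idx]),
            )
            t_e_list.append(err.t_e)
            r_e_list.append(err.r_e.as_array())
        t_e = np.array(t_e_list)
        r_e = np.array(r_e_list)
        metric_samples = {
            "t_mag": np.linalg.norm(t_e, axis=1),
            "r_mag": np.linalg.norm(r_e, axis=1),
        }
        for ai, ax in enumerate("xyz"):
            metric_samples[f"t_{ax}"] = np.abs(t_e[:, ai])
            metric_samples[f"r_{ax}"] = np.abs(r_e[:, ai])
        for metric, vals in metric_samples.items():
            samples[(metric, filt)] = vals
        all_rows.extend(_summary_table(metric_samples, filt))

    return DynamicEvaluationReport(
        table=pd.DataFrame(all_rows),
        samples=samples,
        estimated_shift_s=float(shift),
        n_frames=len(truth),
        n_skipped=n_skipped,
        tracking=results,
    )


def plot_error_vs_distance(report: StaticEvaluationReport, path=None):
    """Mean +/- std of per-pose d_e,RMS versus camera distance (optional plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for filt, marker in (("off", "o"), ("on", "s")):
        df = report.per_pose[report.per_pose["filter"] == filt]
        g = df.groupby("pose_index").agg(d=("distance_mm", "first"), m=("d_e_rms_mm", "mean"), s=("d_e_rms_mm", "std"))
        g = g.sort_values("d")
        ax.errorbar(g["d"], g["m"], yerr=g["s"].fillna(0.0), marker=marker, capsize=3, label=f"filter {filt}")
    ax.set_xlabel("distance to depth camera [mm]")
    ax.set_ylabel("d_e,RMS [mm]")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
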