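"""Validation experiment: batch IK over simulated trials and RMS reporting.

Mirrors the published validation protocol: pseudo-random Bezier trials are
generated within the joint limits, forward kinematics produces the prototype
marker trajectories, the IK solver reconstructs the joint coordinates in one
or more precision modes, and per-trial per-coordinate RMS errors are
aggregated as mean +/- SD across trials.  An optional exclusion rule drops
trials whose worst coordinate RMS exceeds a threshold before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ik import IKSolver
from .model import COORDINATES, ModelDefinition
from .motion import MarkerTrajectory, forward_kinematics, sample_trials

__all__ = ["RMSReport", "rms_error", "apply_exclusion", "run_validation"]


def rms_error(estimated, reference) -> float:
    """Root-mean-square difference of two angle series, degrees.

    Differences are taken directly in degrees (no wrapping: all coordinates
    live well inside +/-180 degrees).
    """
    estimated = np.asarray(estimated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimated.shape != reference.shape:
        raise ValueError(
            f"series length mismatch: {estimated.shape} vs {reference.shape}"
        )
    return float(np.sqrt(np.mean((estimated - reference) ** 2)))


@dataclass(frozen=True)
class RMSReport:
    """Per-trial, per-coordinate RMS errors with mean +/- SD aggregation."""

    per_trial: pd.DataFrame  # index = trial id, columns = COORDINATES
    mode: str = "double"
    excluded: dict = field(default_factory=dict)  # trial id -> reason
    threshold: float | None = None
    mean_frame_seconds: float | None = None
    max_abs: pd.DataFrame | None = None  # per-trial max |error| per coordinate

    @property
    def included(self) -> pd.DataFrame:
        return self.per_trial.drop(index=list(self.excluded), errors="ignore")

    @property
    def mean(self) -> pd.Series:
        return self.included.mean()

    @property
    def sd(self) -> pd.Series:
        """Across-trial standard deviation (sample, n-1 denominator)."""
        return self.included.std(ddof=1)

    def to_text(self) -> str:
        """Human-readable one-row-per-mode table: cells are mean +/- SD."""
        cells = [
            f"{self.mean[c]:.4f} ± {self.sd[c]:.4f}" for c in COORDINATES
        ]
        header = "mode".ljust(12) + "".join(c.ljust(20) for c in COORDINATES)
        row = self.mode.ljust(12) + "".join(cell.ljust(20) for cell in cells)
        lines = [header, row]
        if self.excluded:
            lines.append(
                f"excluded trials ({len(self.excluded)}): "
                + ", ".join(f"{k} ({v})" for k, v in self.excluded.items())
            )
        return "\n".join(lines)


def apply_exclusion(report: RMSReport, threshold: float = 5.0) -> RMSReport:
    """Flag trials whose worst coordinate RMS exceeds ``threshold`` degrees.

    Aggregation (``mean``/``sd``) is recomputed over the remaining trials.
    Emits a warning when every trial is excluded.
    """
    excluded = dict(report.excluded)
    worst = report.per_trial.max(axis=1)
    for trial_id, w in worst.items():
        if w > threshold:
            excluded[trial_id] = f"max RMS {w:.3f} deg > {threshold} deg"
    if len(excluded) == len(report.per_trial):
        import warnings

        warnings.warn("all trials excluded; report is empty", stacklevel=2)
    return replace(report, excluded=excluded, threshold=threshold)


def run_validation(
    model: ModelDefinition,
    n_trials: int = 100,
    duration_s: float = 5.0,
    rate_hz: float = 100.0,
    seed: int = 0,
    modes=("double",),
    shoulder_axes: str = "raw",
    exclusion_threshold: float | None = None,
    timing: bool = False,
):
    """Run the full simulation -> FK -> IK -> RMS experiment.

    The same trials (and hence the same marker trajectories) are reused for
    every requested mode, so modes are directly comparable.  By default the
    forward kinematics composes the shoulder rotations about the raw oblique
    axes while the solver assumes the orthogonalized basis, reproducing the
    published model/algorithm mismatch; pass
    ``shoulder_axes="orthogonalized"`` for an exactly invertible setup.

    Returns ``{mode: RMSReport}``.  Per-trial solver failures are recorded as
    NaN RMS entries and excluded with a reason; the run continues.
    """
    trials = sample_trials(model, n_trials, duration_s, rate_hz, seed)
    marker_trajs = []
    for trial in trials:
        positions = np.empty((trial.n_samples, 12, 3))
        for i in range(trial.n_samples):
            mf, _ = forward_kinematics(
                model,
                trial.angles[i],
                shoulder_axes=shoulder_axes,
                warn_out_of_limits=False,
            )
            positions[i] = mf.positions
        marker_trajs.append(MarkerTrajectory(times=trial.times, positions=positions))

    reports = {}
    for mode in modes:
        solver = IKSolver(model, mode=mode)
        rows = np.empty((n_trials, 7))
        maxabs = np.empty((n_trials, 7))
        excluded = {}
        per_frame = []
        for k, (trial, traj) in enumerate(zip(trials, marker_trajs)):
            est, results, mean_dt = solver.solve_trajectory(
                traj, return_results=True, timing=True
            )
            per_frame.append(mean_dt)
            n_failed = sum(r.failed for r in results)
            ok = ~np.isnan(est).any(axis=1)
            if n_failed:
                excluded[k] = f"{n_failed} frame(s) failed"
            if ok.any():
                err = est[ok] - trial.angles[ok]
                rows[k] = np.sqrt(np.mean(err**2, axis=0))
                maxabs[k] = np.max(np.abs(err), axis=0)
            else:
                rows[k] = np.nan
                maxabs[k] = np.nan
        report = RMSReport(
            per_trial=pd.DataFrame(rows, columns=list(COORDINATES)),
            mode=mode,
            excluded=excluded,
            mean_frame_seconds=float(np.mean(per_frame)) if timing else None,
            max_abs=pd.DataFrame(maxabs, columns=list(COORDINATES)),
        )
        if exclusion_threshold is not None:
            report = apply_exclusion(report, exclusion_threshold)
        reports[mode] = report
    return reports
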