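"""Body-movement measures for two-path navigation trials.

All operations work on waist-tracker position series with the package's
coordinate convention: x lateral (positive = right), z forward from the
start door.  The key quantity throughout is the *last pre-guard lateral
position*: the x-position at the last sample strictly before the guard
trigger, which captures anticipatory movement toward the expected open
pathway before any visual confirmation is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TrialFlagged(Exception):
    """Raised when a trial cannot yield a valid metric and must be excluded."""


def minimum_jerk_profile(tau: np.ndarray | float) -> np.ndarray | float:
    """Minimum-jerk scalar position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.

    The unique quintic with s(0)=0, s(1)=1 and zero velocity and
    acceleration at both endpoints; it minimises integrated squared jerk
    for a point-to-point movement.  ``tau`` is clipped to [0, 1].
    """
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def last_x_before_guard(z: np.ndarray, x: np.ndarray, trigger_z: float) -> float:
    """Lateral position at the last sample strictly before the guard trigger.

    The trigger fires at the first sample with z >= trigger_z; the value
    returned is x of the sample immediately preceding it.  If the series
    never reaches ``trigger_z`` the final x is returned (the guard never
    appeared before the end of the recording).

    Raises
    ------
    TrialFlagged
        If there is no sample before the trigger.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.size == 0:
        raise TrialFlagged("empty series")
    hit = np.nonzero(z >= trigger_z)[0]
    if hit.size == 0:
        return float(x[-1])
    if hit[0] == 0:
        raise TrialFlagged("no samples before guard trigger")
    return float(x[hit[0] - 1])


def normalize_x(x: float, condition: str, guard_side: str | None = None,
                control_by_open_side: bool = True) -> float:
    """Sign-flip a lateral position so positive points toward the open side.

    In biased blocks the "likely open" side is fixed by the condition:
    left-biased blocks usually block the left, so the likely open side is
    the right and raw x (positive = right) is kept; right-biased blocks
    are flipped.  Control blocks have no likely side, so by default the
    *actual* open side of the trial is used (``guard_side`` required);
    with ``control_by_open_side=False`` control trials are left unflipped.
    """
    if condition == "left_biased":
        return float(x)
    if condition == "right_biased":
        return float(-x)
    if condition == "control":
        if not control_by_open_side:
            return float(x)
        if guard_side not in ("left", "right"):
            raise ValueError("control normalization needs guard_side")
        # open side is the complement of the blocked (guard) side
        return float(x) if guard_side == "left" else float(-x)
    raise ValueError(f"unknown condition {condition!r}")


def monotonize_z(z: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Truncate a trial at its first z-maximum and keep strictly increasing z.

    Walk-backs (the participant returning after choosing the blocked
    pathway) make z non-monotone; for forward-progress interpolation the
    series is cut at the first sample attaining its maximum z, and any
    residual non-increasing samples are dropped.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.size == 0:
        return z, x
    cut = int(np.argmax(z)) + 1
    z, x = z[:cut], x[:cut]
    keep = np.ones(z.size, dtype=bool)
    running = z[0]
    for i in range(1, z.size):
        if z[i] > running:
            running = z[i]
        else:
            keep[i] = False
    return z[keep], x[keep]


def interpolate_on_z_grid(z: np.ndarray, x: np.ndarray, z_grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear x(z) evaluated on a fixed grid of forward positions.

    The series is monotonized first (see :func:`monotonize_z`).  Grid
    points outside the observed z-range are returned as NaN.

    Raises
    ------
    TrialFlagged
        If fewer than two valid samples remain.
    """
    zm, xm = monotonize_z(z, x)
    if zm.size < 2:
        raise TrialFlagged("fewer than 2 samples for interpolation")
    grid = np.asarray(z_grid, dtype=float)
    out = np.interp(grid, zm, xm)
    out = np.where((grid < zm[0]) | (grid > zm[-1]), np.nan, out)
    return out


def walking_speed_before_guard(t: np.ndarray, x: np.ndarray, z: np.ndarray,
                               trigger_z: float) -> float:
    """Mean pre-guard walking speed: (x, z) arc length / elapsed time.

    Vertical gait oscillation is excluded; only the horizontal-plane path
    up to (excluding) the first sample with z >= trigger_z counts.

    Raises
    ------
    TrialFlagged
        With fewer than two pre-trigger samples or zero elapsed time.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    hit = np.nonzero(z >= trigger_z)[0]
    end = hit[0] if hit.size else z.size
    if end < 2:
        raise TrialFlagged("fewer than 2 pre-trigger samples")
    dt = t[end - 1] - t[0]
    if dt <= 0:
        raise TrialFlagged("zero elapsed pre-trigger time")
    seg = np.hypot(np.diff(x[:end]), np.diff(z[:end]))
    return float(seg.sum() / dt)


def classify_commitment(last_x: float, guard_side: str, threshold: float = 0.25) -> str:
    """Classify a trial's early commitment from its last pre-guard x.

    ``|last_x| < threshold`` is ``no_early_commitment``; otherwise the
    trial is an early commitment toward sign(last_x), which is correct
    iff that side is the open one (the complement of ``guard_side``).
    The boundary |last_x| == threshold counts as committed.
    """
    if not np.isfinite(last_x):
        raise ValueError("last_x must be finite")
    if guard_side not in ("left", "right"):
        raise ValueError("guard_side must be 'left' or 'right'")
    if abs(last_x) < threshold:
        return "no_early_commitment"
    committed = "right" if last_x > 0 else "left"
    return "early_correct" if committed != guard_side else "early_incorrect"


def path_length(x: np.ndarray, z: np.ndarray) -> float:
    """Total (x, z)-plane arc length of the trial path."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(z)).sum())


def min_jerk_reference(start: tuple[float, float], end: tuple[float, float],
                       n_points: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk reference path from ``start`` to ``end`` in (x, z).

    x follows the quintic profile against the normalized forward
    parameter tau = (z - z0) / (z1 - z0); returns (x_ref, z_ref) arrays
    with exact endpoints.  A degenerate start == end collapses to a
    repeated point.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x0, z0 = start
    x1, z1 = end
    z_ref = np.linspace(z0, z1, n_points)
    if z1 == z0:
        return np.full(n_points, x0, dtype=float), z_ref
    tau = (z_ref - z0) / (z1 - z0)
    x_ref = x0 + (x1 - x0) * minimum_jerk_profile(tau)
    return x_ref, z_ref


@dataclass(frozen=True)
class MinJerkDeviation:
    mean_abs_deviation: float
    start: tuple[float, float]
    end: tuple[float, float]


def min_jerk_deviation(x_obs: np.ndarray, x_ref: np.ndarray,
                       start: tuple[float, float] = (0.0, 0.0),
                       end: tuple[float, float] = (0.0, 0.0)) -> MinJerkDeviation:
    """Mean absolute lateral deviation between observed and reference paths.

    Both inputs must already be resampled on a common z-grid; NaN grid
    points (outside the observed range) are ignored.

    Raises
    ------
    TrialFlagged
        If the inputs share no finite grid points.
    """
    x_obs = np.asarray(x_obs, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x_obs.shape != x_ref.shape:
        raise ValueError("observed and reference must share a grid")
    ok = np.isfinite(x_obs) & np.isfinite(x_ref)
    if not ok.any():
        raise TrialFlagged("no overlapping finite grid points")
    return MinJerkDeviation(float(np.mean(np.abs(x_obs[ok] - x_ref[ok]))), start, end)


def trial_min_jerk_deviation(z: np.ndarray, x: np.ndarray, n_points: int = 50) -> float:
    """Convenience: deviation of one trial from its own min-jerk reference.

    The reference runs from the trial's first to last (monotonized)
    sample; both are evaluated on a shared z-grid of ``n_points``.
    """
    zm, xm = monotonize_z(z, x)
    if zm.size < 2:
        raise TrialFlagged("fewer than 2 samples")
    x_ref, z_ref = min_jerk_reference((xm[0], zm[0]), (xm[-1], zm[-1]), n_points)
    x_on = np.interp(z_ref, zm, xm)
    return min_jerk_deviation(x_on, x_ref, (xm[0], zm[0]), (xm[-1], zm[-1])).mean_abs_deviation


TRIAL_KEYS = ["participant_id", "block_index", "trial_in_block"]


def compute_trial_metrics(tracker: pd.DataFrame, trials: pd.DataFrame,
                          commitment_threshold: float = 0.25,
                          control_by_open_side: bool = True) -> pd.DataFrame:
    """Per-trial movement metrics from long-format tracker + trial tables.

    Returns one row per trial with columns ``last_x``, ``normalized_x``,
    ``speed``, ``commitment``, ``path_length`` and ``minjerk_dev``.
    Trials whose metrics cannot be computed are kept with NaN and logged.
    """
    trials = trials.set_index(TRIAL_KEYS, drop=False)
    rows = []
    for keys, g in tracker.groupby(TRIAL_KEYS, sort=True):
        try:
            trial = trials.loc[keys]
        except KeyError:
            logger.warning("tracker trial %s missing from trials table; skipped", keys)
            continue
        t = g["t"].to_numpy()
        x = g["x"].to_numpy()
        z = g["z"].to_numpy()
        trig = float(trial["trigger_z"])
        rec = dict(zip(TRIAL_KEYS, keys))
        rec["condition"] = trial["condition"]
        rec["guard_side"] = trial["guard_side"]
        try:
            lx = last_x_before_guard(z, x, trig)
            rec["last_x"] = lx
            rec["normalized_x"] = normalize_x(lx, trial["condition"], trial["guard_side"],
                                              control_by_open_side=control_by_open_side)
            rec["commitment"] = classify_commitment(lx, trial["guard_side"],
                                                    commitment_threshold)
        except TrialFlagged as exc:
            logger.warning("trial %s flagged (last_x): %s", keys, exc)
            rec.update(last_x=np.nan, normalized_x=np.nan, commitment=None)
        try:
            rec["speed"] = walking_speed_before_guard(t, x, z, trig)
        except TrialFlagged as exc:
            logger.warning("trial %s flagged (speed): %s", keys, exc)
            rec["speed"] = np.nan
        rec["path_length"] = path_length(x, z)
        try:
            rec["minjerk_dev"] = trial_min_jerk_deviation(z, x)
        except TrialFlagged as exc:
            logger.warning("trial %s flagged (minjerk): %s", keys, exc)
            rec["minjerk_dev"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
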