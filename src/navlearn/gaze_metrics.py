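"""Fixation/saccade classification and trial-level gaze metrics.

Fixations are identified with a dispersion-threshold (I-DT) algorithm in
three dimensions: consecutive gaze samples form a fixation if their
spatial spread stays within a bound (default 5 cm) for a minimum
duration (default 100 ms).  All other samples are saccadic.  Two
trial-level metrics summarise pre-guard scanning: the saccade rate
(saccades per second) and the fixation dispersion (RMS distance of
fixation centroids from their common centroid).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_metrics import TRIAL_KEYS, TrialFlagged

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdtParams:
    """I-DT parameters.

    ``metric`` selects how window spread is measured: ``"bbox_max"``
    (default) takes the maximum per-axis extent (a bounding box of side
    <= threshold); ``"bbox_sum"`` sums the per-axis extents, the
    classical 2D (dx + dy) rule extended to 3D.
    """
    dispersion_threshold: float = 0.05
    min_duration: float = 0.100
    metric: str = "bbox_max"

    def __post_init__(self) -> None:
        if self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be > 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")
        if self.metric not in ("bbox_max", "bbox_sum"):
            raise ValueError(f"unknown dispersion metric {self.metric!r}")


@dataclass(frozen=True)
class FixationEvent:
    start_t: float
    end_t: float
    centroid: tuple[float, float, float]
    n_samples: int
    start_idx: int
    end_idx: int  # inclusive

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def _dispersion(lo: np.ndarray, hi: np.ndarray, metric: str) -> float:
    ext = hi - lo
    return float(ext.max()) if metric == "bbox_max" else float(ext.sum())


def _classify_segment(t: np.ndarray, pts: np.ndarray, params: IdtParams,
                      offset: int) -> list[FixationEvent]:
    """Greedy left-to-right I-DT on one gap-free segment.

    Starting at i, the window grows while its dispersion stays within
    the threshold; if the grown window spans at least ``min_duration``
    it is emitted as a fixation and scanning restarts after it,
    otherwise the start advances by one sample.
    """
    events: list[FixationEvent] = []
    n = t.size
    i = 0
    while i < n:
        lo = pts[i].copy()
        hi = pts[i].copy()
        j = i
        while j + 1 < n:
            cand_lo = np.minimum(lo, pts[j + 1])
            cand_hi = np.maximum(hi, pts[j + 1])
            if _dispersion(cand_lo, cand_hi, params.metric) > params.dispersion_threshold:
                break
            lo, hi = cand_lo, cand_hi
            j += 1
        if t[j] - t[i] >= params.min_duration:
            window = pts[i:j + 1]
            events.append(FixationEvent(
                start_t=float(t[i]), end_t=float(t[j]),
                centroid=tuple(window.mean(axis=0)),
                n_samples=j - i + 1,
                start_idx=offset + i, end_idx=offset + j))
            i = j + 1
        else:
            i += 1
    return events


def idt_classify(t: np.ndarray, points: np.ndarray, params: IdtParams | None = None):
    """Split a gaze stream into fixations and saccade intervals.

    ``points`` is (n, 3).  Non-finite samples (blinks/dropouts) split the
    stream; no interpolation is performed across gaps.  Returns
    ``(fixations, saccades)`` where ``saccades`` are maximal runs of
    non-fixation samples as ``(start_idx, end_idx)`` inclusive index
    pairs (stream ends included).
    """
    params = params or IdtParams()
    t = np.asarray(t, dtype=float)
    pts = np.asarray(points, dtype=float)
    if t.size == 0:
        return [], []
    if pts.shape != (t.size, 3):
        raise ValueError("points must have shape (len(t), 3)")
    finite = np.isfinite(pts).all(axis=1)
    events: list[FixationEvent] = []
    # contiguous runs of finite samples
    idx = np.nonzero(finite)[0]
    if idx.size:
        splits = np.nonzero(np.diff(idx) > 1)[0] + 1
        for run in np.split(idx, splits):
            events.extend(_classify_segment(t[run], pts[run], params, int(run[0])))
    in_fix = np.zeros(t.size, dtype=bool)
    for ev in events:
        in_fix[ev.start_idx:ev.end_idx + 1] = True
    saccades = []
    start = None
    for k in range(t.size):
        if not in_fix[k]:
            if start is None:
                start = k
        elif start is not None:
            saccades.append((start, k - 1))
            start = None
    if start is not None:
        saccades.append((start, t.size - 1))
    return events, saccades


def saccade_rate(saccades, duration: float) -> float:
    """Saccades per second over the analysis window.

    Accepts the saccade-interval list (or an integer count).

    Raises
    ------
    TrialFlagged
        If duration is not positive.
    """
    if duration <= 0:
        raise TrialFlagged("non-positive gaze analysis duration")
    count = saccades if isinstance(saccades, (int, np.integer)) else len(saccades)
    return float(count) / float(duration)


def fixation_dispersion(events) -> float:
    """RMS distance of fixation centroids from their common centroid.

    ``events`` may be a list of :class:`FixationEvent` or an (n, 3)
    array of centroids.

    Raises
    ------
    TrialFlagged
        With zero fixations (the metric is undefined).
    """
    if isinstance(events, np.ndarray):
        centers = np.asarray(events, dtype=float)
    else:
        centers = np.array([ev.centroid for ev in events], dtype=float)
    if centers.size == 0:
        raise TrialFlagged("no fixations: dispersion undefined")
    centers = centers.reshape(-1, 3)
    mean = centers.mean(axis=0)
    d2 = ((centers - mean) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def compute_gaze_metrics(gaze: pd.DataFrame, tracker: pd.DataFrame,
                         trials: pd.DataFrame,
                         params: IdtParams | None = None) -> pd.DataFrame:
    """Per-trial pre-guard gaze metrics.

    The analysis window runs from trial start to the guard onset — the
    first tracker sample with z >= trigger_z.  Returns one row per trial
    with ``saccade_rate``, ``fixation_dispersion``, ``n_fixations`` and
    ``pre_guard_duration``; undefined metrics are NaN and logged.
    """
    params = params or IdtParams()
    trials_ix = trials.set_index(TRIAL_KEYS, drop=False)
    onset = {}
    for keys, g in tracker.groupby(TRIAL_KEYS, sort=True):
        try:
            trig = float(trials_ix.loc[keys, "trigger_z"])
        except KeyError:
            continue
        hit = g.loc[g["z"].to_numpy() >= trig, "t"]
        onset[keys] = float(hit.iloc[0]) if len(hit) else float(g["t"].iloc[-1])
    rows = []
    for keys, g in gaze.groupby(TRIAL_KEYS, sort=True):
        rec = dict(zip(TRIAL_KEYS, keys))
        dur = onset.get(keys)
        if dur is None:
            logger.warning("gaze trial %s has no tracker/trial entry; skipped", keys)
            continue
        pre = g[g["t"].to_numpy() < dur]
        rec["pre_guard_duration"] = dur
        try:
            events, saccades = idt_classify(
                pre["t"].to_numpy(), pre[["gx", "gy", "gz"]].to_numpy(), params)
            rec["n_fixations"] = len(events)
            rec["saccade_rate"] = saccade_rate(saccades, dur)
            rec["fixation_dispersion"] = fixation_dispersion(events)
        except TrialFlagged as exc:
            logger.warning("gaze trial %s flagged: %s", keys, exc)
            rec.setdefault("n_fixations", 0)
            rec.setdefault("saccade_rate", np.nan)
            rec["fixation_dispersion"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
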