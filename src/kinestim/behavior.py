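"""Offline behavioral pipeline.

Movement onset/offset are the edges of the contiguous above-threshold speed
run containing the peak; the main outcome per movement is the average speed
between onset and offset.  Block-level speed change is normalized to the
mean of the block's first five movements (recovery blocks to the start of
the preceding stimulation block), with outlier speeds removed, and the
direction-resolved post-stimulation speed shift compares the relative speed
change after stimulated movements with that after matched not-stimulated
movements of the same class drawn from the recovery block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closed_loop import compute_online_speed, offline_two_back_labels
from .config import SpeedThresholds, StimProtocol

__all__ = [
    "ShiftResult",
    "compute_rest_threshold",
    "rest_threshold_from_speeds",
    "first_five_baseline",
    "detect_movement_bounds",
    "movement_table",
    "block_speed_change",
    "session_speed_change",
    "poststim_speed_shift",
]


def rest_threshold_from_speeds(rest_speeds, sd_multiplier: float = 3.0) -> float:
    """mean + k*SD of pooled rest-period speed samples."""
    rest_speeds = np.asarray(rest_speeds, dtype=float)
    if rest_speeds.size == 0:
        raise ValueError("no rest-period samples")
    return float(rest_speeds.mean() + sd_multiplier * rest_speeds.std())


def compute_rest_threshold(
    traces=None,
    rest_window: float = 0.300,
    sd_multiplier: float = 3.0,
    movement_fraction: float = 0.2,
) -> float:
    """Movement threshold as mean + k*SD of pooled rest-period speeds.

    For every trial in every supplied trace the speed during the last
    ``rest_window`` seconds of the pre-movement dwell is pooled; the dwell
    end is located as the first sample whose smoothed speed exceeds
    ``movement_fraction`` of the trial's maximum.  With no cohort supplied
    the published constant is returned.
    """
    if traces is None:
        return SpeedThresholds().movement_threshold
    pooled = []
    for trace in traces:
        speeds = compute_online_speed(trace)
        times = np.asarray(trace["time_s"], dtype=float)[1:]
        trials = np.asarray(trace["trial_index"])[1:]
        for m in np.unique(trials):
            sel = trials == m
            s = speeds[sel]
            t = times[sel]
            if s.size < 3:
                continue
            above = np.flatnonzero(s > movement_fraction * s.max())
            onset = above[0] if above.size else s.size
            if onset == 0:
                continue
            t_on = t[min(onset, s.size - 1)]
            rest = s[:onset][(t[:onset] >= t_on - rest_window)]
            pooled.append(rest)
    if not pooled or sum(len(p) for p in pooled) == 0:
        raise ValueError("no rest-period samples found")
    return rest_threshold_from_speeds(np.concatenate(pooled), sd_multiplier)


def detect_movement_bounds(
    speeds: np.ndarray, peak_index: int, threshold: float
) -> tuple[int, int]:
    """Onset/offset of the contiguous above-threshold run containing the peak.

    Scanning outward from the peak, onset is the earliest and offset the
    latest sample still above ``threshold`` before the first sub-threshold
    sample on each side; a trial that never drops below the threshold is
    bounded by its edges.
    """
    speeds = np.asarray(speeds, dtype=float)
    if not 0 <= peak_index < speeds.size:
        raise ValueError("peak_index out of range")
    if speeds[peak_index] <= threshold:
        raise ValueError("no movement: speed at the peak is below the threshold")
    onset = peak_index
    while onset > 0 and speeds[onset - 1] > threshold:
        onset -= 1
    offset = peak_index
    while offset < speeds.size - 1 and speeds[offset + 1] > threshold:
        offset += 1
    return onset, offset


def movement_table(
    trace: pd.DataFrame,
    thresholds: SpeedThresholds | None = None,
    protocol: StimProtocol | None = None,
    session=None,
    truth=None,
) -> pd.DataFrame:
    """Per-movement offline kinematics for a session trace.

    Columns: movement_index, block, direction, peak_speed_px_s,
    average_speed_px_s (NaN when the trial never crosses the movement
    threshold), onset_s, offset_s, label (offline two-back), stimulated
    (False when no session is supplied).
    """
    thresholds = thresholds or SpeedThresholds()
    protocol = protocol or (session.protocol if session is not None else StimProtocol())
    speeds = compute_online_speed(trace)
    times = np.asarray(trace["time_s"], dtype=float)[1:]
    trials = np.asarray(trace["trial_index"])[1:]
    xs = np.asarray(trace["x_px"], dtype=float)

    rows = []
    for m in np.unique(trials):
        sel = np.flatnonzero(trials == m)
        s = speeds[sel]
        t = times[sel]
        peak_i = int(np.argmax(s))
        if s[peak_i] <= thresholds.movement_threshold:
            rows.append(
                {
                    "movement_index": int(m),
                    "peak_speed_px_s": float(s[peak_i]),
                    "average_speed_px_s": np.nan,
                    "onset_s": np.nan,
                    "offset_s": np.nan,
                    "direction": "unknown",
                }
            )
            continue
        on, off = detect_movement_bounds(s, peak_i, thresholds.movement_threshold)
        avg = float(np.mean(s[on : off + 1]))
        dx = xs[sel[off] + 1] - xs[sel[on]]
        rows.append(
            {
                "movement_index": int(m),
                "peak_speed_px_s": float(s[peak_i]),
                "average_speed_px_s": avg,
                "onset_s": float(t[on]),
                "offset_s": float(t[off]),
                "direction": "left_to_right" if dx >= 0 else "right_to_left",
            }
        )
    out = pd.DataFrame(rows).sort_values("movement_index").reset_index(drop=True)
    out["block"] = out["movement_index"] // protocol.block_length + 1
    out["label"] = offline_two_back_labels(
        out["peak_speed_px_s"].to_numpy(), protocol.block_length
    )
    if session is not None:
        stim = session.movements.set_index("movement_index")["stimulated"]
        out["stimulated"] = out["movement_index"].map(stim).fillna(False).astype(bool)
    elif truth is not None:
        stim = truth.movements.set_index("movement_index")["stimulated"]
        out["stimulated"] = out["movement_index"].map(stim).fillna(False).astype(bool)
    else:
        out["stimulated"] = False
    return out


def block_speed_change(
    speeds,
    thresholds: SpeedThresholds | None = None,
    baseline: float | str = "own_first_five",
) -> tuple[pd.Series, float]:
    """Percent speed change from block start, with outlier handling.

    Speeds above the outlier threshold become NaN; the baseline is the
    NaN-aware mean of the block's first five speeds (or an externally
    supplied value, used for recovery blocks); the first five trials are
    excluded from the returned series.  Returns ``(series, block_mean)``.
    """
    thresholds = thresholds or SpeedThresholds()
    v = pd.Series(np.asarray(speeds, dtype=float))
    if len(v) < 6:
        raise ValueError("block must contain at least six movements")
    v = v.mask(v > thresholds.outlier_threshold)
    if baseline == "own_first_five":
        b = v.iloc[:5].mean()
    else:
        b = float(baseline)
    if not np.isfinite(b) or b == 0:
        raise ValueError("invalid baseline: zero or all first-five speeds missing")
    change = 100.0 * (v - b) / b
    series = change.iloc[5:]
    return series, float(series.mean())


def first_five_baseline(
    speeds, thresholds: SpeedThresholds | None = None
) -> float:
    """NaN-aware mean of a block's first five (outlier-cleaned) speeds."""
    thresholds = thresholds or SpeedThresholds()
    v = pd.Series(np.asarray(speeds, dtype=float)[:5])
    v = v.mask(v > thresholds.outlier_threshold)
    return float(v.mean())


def session_speed_change(
    movements: pd.DataFrame,
    thresholds: SpeedThresholds | None = None,
    protocol: StimProtocol | None = None,
) -> pd.DataFrame:
    """Per-block percent speed-change series for a whole session.

    Stimulation blocks are normalized to their own first five movements;
    each recovery block to the first-five baseline of the preceding
    stimulation block.
    """
    thresholds = thresholds or SpeedThresholds()
    protocol = protocol or StimProtocol()
    out = []
    baselines: dict[int, float] = {}
    for block, grp in movements.groupby("block"):
        speeds = grp.sort_values("movement_index")["average_speed_px_s"].to_numpy()
        baselines[block] = first_five_baseline(speeds, thresholds)
    for block, grp in movements.groupby("block"):
        grp = grp.sort_values("movement_index")
        speeds = grp["average_speed_px_s"].to_numpy()
        if block in protocol.stim_blocks:
            series, mean = block_speed_change(speeds, thresholds, "own_first_five")
        else:
            ref = block - 1 if block - 1 in baselines else block
            series, mean = block_speed_change(speeds, thresholds, baselines[ref])
        df = pd.DataFrame(
            {
                "block": block,
                "movement_index": grp["movement_index"].to_numpy()[5:],
                "percent_change": series.to_numpy(),
            }
        )
        df["block_mean"] = mean
        out.append(df)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class ShiftResult:
    """Direction-resolved post-stimulation speed shift.

    One row per condition x relative follower direction; ``shift`` is the
    mean percent speed change after stimulated movements minus that after
    matched not-stimulated movements of the same class from the recovery
    block (NaN when a cell has no reference movements).
    """

    table: pd.DataFrame  # condition, direction, shift, n_stim, n_ref, ...


def _follower_changes(
    mv: pd.DataFrame, indices: np.ndarray, follower: int, block_length: int
) -> np.ndarray:
    """Percent change of follower ``k+follower`` relative to movement ``k``."""
    v = mv.set_index("movement_index")["average_speed_px_s"]
    changes = []
    for k in indices:
        j = k + follower
        if j not in v.index or j // block_length != k // block_length:
            continue  # follower crosses the block boundary
        vk, vj = v.loc[k], v.loc[j]
        if np.isfinite(vk) and np.isfinite(vj) and vk != 0:
            changes.append(100.0 * (vj - vk) / vk)
    return np.asarray(changes)


def poststim_speed_shift(
    movements: pd.DataFrame,
    protocol: StimProtocol | None = None,
) -> ShiftResult:
    """Stimulation-induced shift of subsequent movement speed.

    For every stimulated movement the percent change of the next two
    movements is computed; follower 1 moves in the opposite direction,
    follower 2 in the same direction (targets strictly alternate).  The
    same changes after fast/slow-classified movements of the recovery block
    (post-hoc two-back labels on offline peaks) provide the matched
    reference; the shift is the difference of the two means, per condition
    and follower direction.
    """
    protocol = protocol or StimProtocol()
    bl = protocol.block_length
    rows = []
    for stim_block in protocol.stim_blocks:
        condition = protocol.block_condition(stim_block)
        recovery_block = stim_block + 1
        stim_idx = movements.loc[
            (movements["block"] == stim_block) & (movements["stimulated"]),
            "movement_index",
        ].to_numpy()
        ref_idx = movements.loc[
            (movements["block"] == recovery_block)
            & (movements["label"] == condition),
            "movement_index",
        ].to_numpy()
        for follower, direction in ((1, "opposite"), (2, "same")):
            ch_stim = _follower_changes(movements, stim_idx, follower, bl)
            ch_ref = _follower_changes(movements, ref_idx, follower, bl)
            shift = (
                float(ch_stim.mean() - ch_ref.mean())
                if ch_stim.size and ch_ref.size
                else float("nan")
            )
            rows.append(
                {
                    "condition": condition,
                    "direction": direction,
                    "shift": shift,
                    "mean_change_stim": float(ch_stim.mean()) if ch_stim.size else float("nan"),
                    "mean_change_ref": float(ch_ref.mean()) if ch_ref.size else float("nan"),
                    "n_stim": int(ch_stim.size),
                    "n_ref": int(ch_ref.size),
                }
            )
    return ShiftResult(table=pd.DataFrame(rows))
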