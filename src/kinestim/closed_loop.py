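"""Emulation of the real-time speed-selective stimulation controller.

The controller streams 62-Hz cursor samples, computes the Euclidean
step speed smoothed over the most recent six samples, detects the peak
speed of the ongoing movement online (either by three subsequently
decreasing smoothed values, or by reading out at a calibrated
peak-latency percentile), classifies the movement as fast/slow against
the peak speeds of the previous two movements, and — in stimulation
blocks — schedules a 300-ms burst at detection time when the label
matches the block's target condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StimProtocol

__all__ = [
    "PeakEvent",
    "SessionRecord",
    "ControllerAudit",
    "compute_online_speed",
    "detect_peak_three_decreasing",
    "calibrate_peak_time_percentile",
    "classify_speed",
    "run_closed_loop_session",
    "evaluate_controller",
    "offline_two_back_labels",
    "offline_trace_peaks",
    "within_block_percentile_ranks",
]

#: smoothed-speed threshold at which the online peak detector arms; matches
#: the offline movement threshold so dwell-period noise cannot fire the rule
DEFAULT_ARM_THRESHOLD = 800.77


@dataclass(frozen=True)
class PeakEvent:
    """Online peak-speed readout for one movement."""

    movement_index: int
    online_peak_speed: float
    detection_time: float
    detection_latency: float = float("nan")  # vs. true peak time, if known


@dataclass
class SessionRecord:
    """Outcome of one closed-loop session.

    ``movements`` has one row per movement: block, movement_index, label,
    stimulated, online_peak_px_s, detection_time_s.  ``stim_events`` has one
    row per 300-ms burst.
    """

    movements: pd.DataFrame
    stim_events: pd.DataFrame
    protocol: StimProtocol
    trace: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def compute_online_speed(trace: pd.DataFrame) -> np.ndarray:
    """Smoothed cursor speed as the controller computes it.

    Instantaneous speed is the Euclidean step length between consecutive
    samples divided by the elapsed time; the returned series is the trailing
    mean over the most recent six instantaneous values (fewer at the stream
    head).  Element ``i`` corresponds to the step ending at sample ``i+1``.
    """
    t = np.asarray(trace["time_s"], dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dx = np.diff(np.asarray(trace["x_px"], dtype=float))
    dy = np.diff(np.asarray(trace["y_px"], dtype=float))
    inst = np.hypot(dx, dy) / dt
    return _trailing_mean(inst, 6)


def _trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    return (csum[idx + 1] - csum[lo]) / (idx - lo + 1)


def detect_peak_three_decreasing(
    speeds: np.ndarray,
    arm_threshold: float = 0.0,
) -> tuple[int, float] | None:
    """First index completing three consecutive strictly decreasing smoothed
    speed values after the detector is armed, with the online peak speed.

    The detector arms once the smoothed speed reaches ``arm_threshold``
    (0 arms immediately); ties and increases reset the decreasing run.  The
    online peak is the maximum of all samples seen up to the firing sample.
    Returns ``None`` if the rule never fires.
    """
    speeds = np.asarray(speeds, dtype=float)
    run = 0
    armed = arm_threshold <= 0
    for i in range(speeds.size):
        if not armed:
            if speeds[i] >= arm_threshold:
                armed = True
            continue
        if i > 0 and speeds[i] < speeds[i - 1]:
            run += 1
        else:
            run = 0
        if run >= 3:
            return i, float(np.max(speeds[: i + 1]))
    return None


def _detect_percentile_time(
    speeds: np.ndarray,
    times: np.ndarray,
    arm_threshold: float,
    peak_time_threshold: float,
) -> tuple[int, float] | None:
    """Read out the running maximum once the calibrated peak latency elapses."""
    armed_at = None
    for i in range(speeds.size):
        if armed_at is None:
            if speeds[i] >= arm_threshold or arm_threshold <= 0:
                armed_at = times[i]
            else:
                continue
        if times[i] - armed_at >= peak_time_threshold:
            return i, float(np.max(speeds[: i + 1]))
    return None


def calibrate_peak_time_percentile(latencies, q: float = 80.0) -> float:
    """Percentile (linear interpolation) of familiarization peak latencies.

    The deployed variant computed the 80th percentile of 32 familiarization
    trials; fewer trials are accepted with a warning.
    """
    latencies = np.asarray(latencies, dtype=float)
    if latencies.size < 2:
        raise ValueError("need at least two latencies")
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    if latencies.size < 32:
        warnings.warn(
            f"calibrating on {latencies.size} trials (reference procedure used 32)",
            stacklevel=2,
        )
    return float(np.percentile(latencies, q))


def classify_speed(peak: float, prev1: float, prev2: float) -> str:
    """Two-back speed classification.

    ``fast`` iff the peak strictly exceeds both previous peaks, ``slow`` iff
    it falls strictly below both, else ``intermediate``.
    """
    if peak > prev1 and peak > prev2:
        return "fast"
    if peak < prev1 and peak < prev2:
        return "slow"
    return "intermediate"


def run_closed_loop_session(
    trace: pd.DataFrame,
    protocol: StimProtocol | None = None,
    detector: str = "three_decreasing",
    arm_threshold: float = DEFAULT_ARM_THRESHOLD,
    peak_time_threshold: float | None = None,
    truth=None,
) -> SessionRecord:
    """Run the streaming controller over a full session trace.

    The two-back comparison window resets at every block boundary, so the
    first two movements of each block are never classified or stimulated.
    A stimulation burst of ``protocol.burst_duration`` starts at detection
    time for every movement whose label matches the block's target condition
    in a stimulation block; recovery blocks emit no bursts.
    """
    protocol = protocol or StimProtocol()
    if detector not in ("three_decreasing", "percentile_time"):
        raise ValueError(f"unknown detector: {detector}")
    if detector == "percentile_time" and peak_time_threshold is None:
        raise ValueError("percentile_time detector requires peak_time_threshold")

    n_needed = protocol.n_blocks * protocol.block_length
    trial_index = np.asarray(trace["trial_index"])
    n_trials = int(trial_index.max()) + 1 if trial_index.size else 0
    if n_trials < n_needed:
        raise ValueError(
            f"trace covers {n_trials} movements; protocol requires {n_needed}"
        )

    speeds = compute_online_speed(trace)  # aligned to samples 1..n-1
    times = np.asarray(trace["time_s"], dtype=float)
    speed_trial = trial_index[1:]  # trial of the sample ending each step

    truth_df = truth.movements if truth is not None else None

    rows = []
    stim_rows = []
    prev_peaks: list[float] = []
    for m in range(n_needed):
        block = m // protocol.block_length + 1
        within = m % protocol.block_length
        if within == 0:
            prev_peaks = []  # two-back window resets at block boundaries

        sel = np.flatnonzero(speed_trial == m)
        seg = speeds[sel]
        seg_t = times[sel + 1]
        if detector == "three_decreasing":
            det = detect_peak_three_decreasing(seg, arm_threshold)
        else:
            det = _detect_percentile_time(seg, seg_t, arm_threshold, peak_time_threshold)

        online_peak = np.nan
        det_time = np.nan
        latency = np.nan
        label = "unclassified"
        if det is not None:
            di, online_peak = det
            det_time = seg_t[di]
            if truth_df is not None:
                latency = det_time - truth_df["true_peak_time"].iloc[m]
            if len(prev_peaks) >= 2:
                label = classify_speed(online_peak, prev_peaks[-1], prev_peaks[-2])
            prev_peaks.append(online_peak)

        stim = False
        if label != "unclassified" and label == protocol.block_condition(block):
            stim = True
            stim_rows.append(
                {
                    "block": block,
                    "movement_index": m,
                    "start_time_s": det_time,
                    "duration_s": protocol.burst_duration,
                }
            )
        rows.append(
            {
                "block": block,
                "movement_index": m,
                "label": label,
                "stimulated": stim,
                "online_peak_px_s": online_peak,
                "detection_time_s": det_time,
                "detection_latency_s": latency,
            }
        )

    movements = pd.DataFrame(rows)
    stim_events = pd.DataFrame(
        stim_rows, columns=["block", "movement_index", "start_time_s", "duration_s"]
    )
    return SessionRecord(
        movements=movements,
        stim_events=stim_events,
        protocol=protocol,
        trace=trace,
        meta={"detector": detector, "arm_threshold": arm_threshold},
    )


def offline_two_back_labels(peaks: np.ndarray, block_length: int) -> list[str]:
    """Post-hoc two-back labels from offline peak speeds, resetting per block."""
    labels = []
    for i, p in enumerate(np.asarray(peaks, dtype=float)):
        if i % block_length < 2:
            labels.append("unclassified")
        else:
            labels.append(classify_speed(p, peaks[i - 1], peaks[i - 2]))
    return labels


def within_block_percentile_ranks(peaks) -> np.ndarray:
    """Percentile rank (0-100) of each peak within its block's distribution."""
    from scipy.stats import rankdata

    peaks = np.asarray(peaks, dtype=float)
    return 100.0 * (rankdata(peaks) - 0.5) / peaks.size


def offline_trace_peaks(trace: pd.DataFrame) -> np.ndarray:
    """Offline peak speed per trial: maximum of the smoothed speed series."""
    speeds = compute_online_speed(trace)
    trials = np.asarray(trace["trial_index"])[1:]
    n = int(trials.max()) + 1
    return np.array([speeds[trials == m].max() for m in range(n)])


@dataclass(frozen=True)
class ControllerAudit:
    """Accuracy/coverage/latency audit of a closed-loop session."""

    accuracy: float  # online vs offline-truth label agreement
    coverage: dict  # block -> stimulated fraction
    mean_latency_s: float
    total_stim_time_s: float
    n_classified: int


def evaluate_controller(
    session: SessionRecord, truth=None, reference: str = "trace"
) -> ControllerAudit:
    """Audit a closed-loop session.

    Accuracy is the fraction of online-classified movements whose label
    matches the post-hoc label obtained with the identical two-back rule
    from offline peak speeds.  With ``reference="trace"`` (the published
    accuracy metric) the offline peaks are the per-trial maxima of the
    recorded smoothed speed; ``reference="truth"`` audits against the
    generator's noise-free peak speeds instead.
    """
    mv = session.movements
    if truth is not None:
        tr = truth.movements
        if len(mv) > len(tr) or not np.array_equal(
            mv["movement_index"].to_numpy(), tr["movement_index"].to_numpy()[: len(mv)]
        ):
            raise ValueError("session and truth movement indices are misaligned")

    if reference == "truth":
        if truth is None:
            raise ValueError("reference='truth' requires ground truth")
        peaks = truth.movements["true_peak_speed"].to_numpy()[: len(mv)]
    elif reference == "trace":
        if session.trace is None:
            raise ValueError("reference='trace' requires the session trace")
        peaks = offline_trace_peaks(session.trace)[: len(mv)]
    else:
        raise ValueError(f"unknown reference: {reference}")
    offline = offline_two_back_labels(peaks, session.protocol.block_length)
    online = mv["label"].to_numpy()
    mask = (online != "unclassified") & (np.asarray(offline) != "unclassified")
    n_classified = int(mask.sum())
    accuracy = float(np.mean(online[mask] == np.asarray(offline)[mask])) if n_classified else float("nan")

    coverage = {
        int(b): float(g["stimulated"].mean()) for b, g in mv.groupby("block")
    }
    lat = mv["detection_latency_s"].to_numpy()
    mean_latency = float(np.nanmean(lat)) if np.any(np.isfinite(lat)) else float("nan")
    total_stim = float(session.protocol.burst_duration * len(session.stim_events))
    return ControllerAudit(
        accuracy=accuracy,
        coverage=coverage,
        mean_latency_s=mean_latency,
        total_stim_time_s=total_stim,
        n_classified=n_classified,
    )
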