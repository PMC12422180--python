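"""Synthetic cursor kinematics, null cohorts and synthetic sensorimotor epochs.

The generator emulates the tablet reaching task: targets alternate between
the left and right screen edge at four possible heights, movements follow
minimum-jerk bell speed profiles whose peak speed decays geometrically
across repetitions (bradykinetic decrement) with multiplicative trial noise,
and an optional reinforcement term couples a stimulated movement to the next
movement in the same direction.  A separate generator produces a synthetic
single-channel cortical recording with movement-locked beta modulation and
DBS on/offset edge artifacts at known times, for the spectral pipeline.

Every generator is fully determined by its arguments plus an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .config import EpochSpec, KinematicsModel, StimProtocol, TaskGeometry
from .closed_loop import classify_speed

__all__ = [
    "TargetSequence",
    "GroundTruth",
    "EcogEffects",
    "SynthEcog",
    "generate_target_sequence",
    "generate_kinematics",
    "generate_null_cohort",
    "generate_synthetic_ecog",
    "minimum_jerk_speed",
]


# ---------------------------------------------------------------------------
# target sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSequence:
    """Alternating left/right target positions plus the initial pen position."""

    start: tuple[float, float]
    targets: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.targets)

    def trajectory_classes(self) -> list[tuple[float, float, str]]:
        """(start_y, end_y, direction) of each movement."""
        out = []
        prev = self.start
        for tx, ty in self.targets:
            direction = "left_to_right" if tx > prev[0] else "right_to_left"
            out.append((prev[1], ty, direction))
            prev = (tx, ty)
        return out


def _euler_circuit(adjacency: dict, start) -> list:
    """Node sequence of an Eulerian circuit (Hierholzer, iterative)."""
    adj = {k: list(v) for k, v in adjacency.items()}
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if adj.get(v):
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def generate_target_sequence(
    n_movements: int,
    geometry: TaskGeometry | None = None,
    seed: int = 0,
) -> TargetSequence:
    """Pseudorandomized alternating target sequence.

    Within every 96-movement block each of the 32 trajectory classes
    (4 start heights x 4 end heights x 2 directions) occurs exactly
    96/32 = 3 times.  Because the start height of a movement is the end
    height of the previous one, a balanced block is an Eulerian circuit on
    the 8 (side, height) nodes with 3 parallel edges per directed pair of
    opposite-side nodes; a randomized Hierholzer traversal realizes one.
    """
    if n_movements < 1:
        raise ValueError("n_movements must be >= 1")
    geometry = geometry or TaskGeometry()
    rng = np.random.default_rng(seed)

    xs = {"L": float(geometry.target_x_left), "R": float(geometry.target_x_right)}
    ys = [float(y) for y in geometry.target_ys]
    block = 96
    repeats = block // (2 * len(ys) ** 2)  # 3 for the default geometry

    start_node = ("L", ys[int(rng.integers(len(ys)))])
    nodes: list[tuple[str, float]] = []
    n_blocks = -(-n_movements // block)
    for _ in range(n_blocks):
        adjacency: dict = {}
        for side, other in (("L", "R"), ("R", "L")):
            for y0 in ys:
                ends = [(other, y1) for y1 in ys for _ in range(repeats)]
                rng.shuffle(ends)
                adjacency[(side, y0)] = ends
        circuit = _euler_circuit(adjacency, start_node)
        nodes.extend(circuit[1:])  # circuit starts and ends at start_node

    targets = tuple((xs[s], y) for s, y in nodes[:n_movements])
    return TargetSequence(start=(xs[start_node[0]], start_node[1]), targets=targets)


# ---------------------------------------------------------------------------
# cursor kinematics
# ---------------------------------------------------------------------------

def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk speed bell: 16 tau^2 (1-tau)^2, peak 1 at tau=0.5."""
    tau = np.asarray(tau, dtype=float)
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def _minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Path fraction covered at normalized time tau (integral of the bell)."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


@dataclass(frozen=True)
class GroundTruth:
    """Per-movement generative truth used to audit the online controller."""

    movements: pd.DataFrame  # one row per movement

    def __len__(self) -> int:
        return len(self.movements)


def generate_kinematics(
    targets: TargetSequence,
    model: KinematicsModel | None = None,
    protocol: StimProtocol | None = None,
    seed: int = 0,
    inter_movement_interval: float = 0.350,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cursor trace for a target sequence.

    Returns ``(trace, truth)``.  ``trace`` is a DataFrame with columns
    ``time_s, x_px, y_px, trial_index``; trial ``i`` comprises the
    inter-movement dwell preceding movement ``i`` followed by the movement
    itself.  ``truth`` records, per movement, the realized (pre-position-noise)
    peak speed, the time of peak speed, direction, the two-back
    classification of the true peaks, and — when a protocol is supplied —
    which movements the generative controller stimulated and which follower
    speeds were reinforced.

    When ``protocol`` is given, movements matching the block's target
    condition (classified on true peak speeds) in stimulation blocks are
    flagged stimulated and the *next same-direction* movement (two ahead,
    within the same block) has its target peak speed multiplied by
    ``1 + reinforcement_delta`` after fast- and ``1 - reinforcement_delta``
    after slow-classified stimulated movements.
    """
    if len(targets) == 0:
        raise ValueError("targets must contain at least one movement")
    model = model or KinematicsModel()
    rng = np.random.default_rng(seed)
    n = len(targets)
    fs = model.sample_rate
    dt = 1.0 / fs

    durations = rng.normal(model.duration_mean, model.duration_sd, size=n)
    durations = np.clip(durations, 0.25, None)
    if model.noise_cv > 0:
        sigma2 = np.log1p(model.noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)
    else:
        noise = np.ones(n)
    # the bradykinetic decrement accumulates within a block and resets at
    # block boundaries (the paradigm interposes breaks between blocks); with
    # no block structure the exponent is the global movement index
    block_len = protocol.block_length if protocol is not None else n
    base = model.peak_speed_start * (1.0 - model.decrement_rate) ** (
        np.arange(n) % block_len
    )
    directions = [c[2] for c in targets.trajectory_classes()]

    # sequential pass: realized peaks, truth classification, stimulation,
    # reinforcement of the movement two ahead
    peak = np.empty(n)
    mult = np.ones(n)
    labels: list[str] = []
    stimulated = np.zeros(n, dtype=bool)
    for i in range(n):
        peak[i] = base[i] * mult[i] * noise[i]
        block = i // block_len + 1
        within = i % block_len
        if within < 2:
            label = "unclassified"
        else:
            label = classify_speed(peak[i], peak[i - 1], peak[i - 2])
        labels.append(label)
        if protocol is not None and block in protocol.stim_blocks:
            if label == protocol.block_condition(block):
                stimulated[i] = True
                j = i + 2  # next same-direction movement (targets alternate)
                if j < n and j // block_len + 1 == block:
                    sign = 1.0 if label == "fast" else -1.0
                    mult[j] *= 1.0 + model.reinforcement_delta * sign

    # assemble the sampled trace
    n_dwell = max(1, int(round(inter_movement_interval * fs)))
    times: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    trial_idx: list[np.ndarray] = []
    onset_t = np.empty(n)
    peak_t = np.empty(n)
    offset_t = np.empty(n)
    pos = np.array(targets.start, dtype=float)
    k = 0  # global sample counter
    for i, (tx, ty) in enumerate(targets.targets):
        # dwell at the current position
        t_dwell = (k + np.arange(n_dwell)) * dt
        times.append(t_dwell)
        xs.append(np.full(n_dwell, pos[0]))
        ys.append(np.full(n_dwell, pos[1]))
        trial_idx.append(np.full(n_dwell, i, dtype=int))
        k += n_dwell
        t0 = (k - 1) * dt  # movement starts at the last dwell sample

        n_i = max(4, int(round(durations[i] * fs)))
        d = n_i * dt
        length = peak[i] * d / 1.875  # path length so the profile peaks at peak[i]
        vec = np.array([tx, ty]) - pos
        dist = np.hypot(*vec)
        unit = vec / dist if dist > 0 else np.array([1.0, 0.0])
        tau = np.arange(1, n_i + 1) / n_i
        frac = _minimum_jerk_position(tau)
        seg = pos[None, :] + unit[None, :] * (length * frac)[:, None]
        t_move = (k + np.arange(n_i)) * dt
        times.append(t_move)
        xs.append(seg[:, 0])
        ys.append(seg[:, 1])
        trial_idx.append(np.full(n_i, i, dtype=int))
        k += n_i
        onset_t[i] = t0
        peak_t[i] = t0 + d / 2.0
        offset_t[i] = t0 + d
        pos = seg[-1]

    time_s = np.concatenate(times)
    if model.timing_jitter > 0:
        jit = rng.uniform(-model.timing_jitter, model.timing_jitter, size=time_s.size)
        time_s = time_s + jit * dt
        time_s = np.maximum.accumulate(time_s + 1e-9 * np.arange(time_s.size))
    x_px = np.concatenate(xs)
    y_px = np.concatenate(ys)
    if model.position_noise_sd > 0:
        x_px = x_px + rng.normal(0, model.position_noise_sd, size=x_px.size)
        y_px = y_px + rng.normal(0, model.position_noise_sd, size=y_px.size)

    trace = pd.DataFrame(
        {
            "time_s": time_s,
            "x_px": x_px,
            "y_px": y_px,
            "trial_index": np.concatenate(trial_idx),
        }
    )
    truth = GroundTruth(
        movements=pd.DataFrame(
            {
                "movement_index": np.arange(n),
                "block": np.arange(n) // block_len + 1,
                "direction": directions,
                "true_peak_speed": peak,
                "true_peak_time": peak_t,
                "onset_time": onset_t,
                "offset_time": offset_t,
                "duration_s": durations,
                "label": labels,
                "stimulated": stimulated,
                "reinforcement_factor": mult,
                "base_peak_speed": base,
            }
        )
    )
    return trace, truth


# ---------------------------------------------------------------------------
# null cohorts
# ---------------------------------------------------------------------------

def generate_null_cohort(
    n_subjects: int,
    model: KinematicsModel | None = None,
    seed: int = 0,
    block_length: int = 96,
) -> pd.DataFrame:
    """Paired condition summaries with no true condition effect.

    For each subject two blocks of per-movement average speeds are drawn from
    the *same* generative law (geometric decrement times multiplicative
    noise, reinforcement forced to zero), and each block is reduced to its
    mean percent speed change from the first-five-movement baseline.  The
    result is the type-I-error harness for the paired permutation test.

    Returns a tidy DataFrame with columns ``subject, condition, mean_change``
    where condition is ``"a"`` or ``"b"``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    model = model or KinematicsModel()
    if model.reinforcement_delta != 0:
        warnings.warn(
            "null cohort requested with reinforcement_delta != 0; forcing 0",
            stacklevel=2,
        )
        model = replace(model, reinforcement_delta=0.0)
    rng = np.random.default_rng(seed)
    m = block_length
    base = model.peak_speed_start * (1.0 - model.decrement_rate) ** np.arange(m)
    if model.noise_cv > 0:
        sigma2 = np.log1p(model.noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=(n_subjects, 2, m))
    else:
        noise = np.ones((n_subjects, 2, m))
    speeds = base[None, None, :] * noise
    baseline = speeds[:, :, :5].mean(axis=2)
    change = 100.0 * (speeds[:, :, 5:] - baseline[:, :, None]) / baseline[:, :, None]
    mean_change = change.mean(axis=2)
    rows = []
    for s in range(n_subjects):
        for ci, cond in enumerate(("a", "b")):
            rows.append({"subject": s, "condition": cond, "mean_change": mean_change[s, ci]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic cortical recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcogEffects:
    """Ground-truth effect sizes injected into the synthetic recording.

    Gains are multiplicative factors on the beta-band amplitude envelope.
    ``erd_gain``/``rebound_gain`` model movement-locked desynchronization and
    post-movement rebound common to all trials; ``peri_gain``/``post_gain``
    apply additionally to stimulated trials inside the stimulation and
    post-stimulation analysis windows.  ``artifact_amp`` scales the brief
    broadband transients added at DBS burst on/offset of stimulated trials.
    """

    peri_gain: float = 1.0
    post_gain: float = 1.0
    erd_gain: float = 0.6
    rebound_gain: float = 1.4
    beta_amp: float = 1.0
    noise_amp: float = 1.0
    artifact_amp: float = 25.0
    stim_onset: float = 0.065  # s after peak speed
    stim_duration: float = 0.300  # s
    peak_speed_mean: float = 1500.0  # px/s, trial metadata
    peak_speed_cv: float = 0.25


@dataclass(frozen=True)
class SynthEcog:
    """A synthetic continuous recording plus its event table and truth."""

    signal: np.ndarray
    sample_rate: float
    events: pd.DataFrame  # time_s, stimulated, peak_speed_px_s, stim_on_s, stim_off_s
    effects: EcogEffects = field(default_factory=EcogEffects)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def generate_synthetic_ecog(
    n_trials: int,
    spec: EpochSpec | None = None,
    seed: int = 0,
    effects: EcogEffects | None = None,
) -> SynthEcog:
    """Synthetic single-channel recording with ``n_trials`` stimulated and
    ``n_trials`` not-stimulated movement events.

    The signal is 1/f background noise plus a 20-35 Hz narrowband component
    whose amplitude envelope carries a peri-movement desynchronization and a
    post-movement rebound around every event; stimulated trials additionally
    receive the injected window gains and high-amplitude transients at burst
    on/offset.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    spec = spec or EpochSpec()
    if spec.sample_rate <= 0:
        raise ValueError("sample rate must be positive")
    effects = effects or EcogEffects()
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate

    n_events = 2 * n_trials
    spacing = 2.6  # s between peak-speed times; epochs never overlap
    event_times = 1.3 + spacing * np.arange(n_events)
    total = int(round((event_times[-1] + 1.3) * fs))
    t = np.arange(total) / fs

    stim_flags = np.zeros(n_events, dtype=bool)
    stim_flags[rng.permutation(n_events)[:n_trials]] = True
    peak_speeds = effects.peak_speed_mean * (
        1.0 + effects.peak_speed_cv * rng.standard_normal(n_events)
    )
    peak_speeds = np.clip(peak_speeds, 100.0, None)

    # narrowband beta carrier: bandpass-filtered white noise
    sos = sp_signal.butter(
        4, [spec.beta_band[0], spec.beta_band[1]], btype="bandpass", fs=fs, output="sos"
    )
    carrier = sp_signal.sosfiltfilt(sos, rng.standard_normal(total))
    carrier = carrier / carrier.std()

    envelope = np.ones(total)

    def _apply(lo: float, hi: float, gain: float) -> None:
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        envelope[max(i0, 0) : min(i1, total)] *= gain

    for ev, is_stim in zip(event_times, stim_flags):
        _apply(ev - 0.1, ev + spec.post_window[0], effects.erd_gain)
        _apply(ev + spec.post_window[0], ev + spec.post_window[1], effects.rebound_gain)
        if is_stim:
            _apply(ev + spec.stim_window[0], ev + spec.stim_window[1], effects.peri_gain)
            _apply(ev + spec.post_window[0], ev + spec.post_window[1], effects.post_gain)

    sig = effects.noise_amp * _pink_noise(total, rng)
    sig = sig + effects.beta_amp * envelope * carrier

    # DBS edge artifacts: damped 130-Hz transients at burst on/offset
    art_t = np.arange(0, 0.040, 1.0 / fs)
    art = np.exp(-art_t / 0.008) * np.cos(2 * np.pi * 130.0 * art_t)
    stim_on = np.where(stim_flags, event_times + effects.stim_onset, np.nan)
    stim_off = stim_on + effects.stim_duration
    for on, off, is_stim in zip(stim_on, stim_off, stim_flags):
        if not is_stim:
            continue
        for edge in (on, off):
            i0 = int(round(edge * fs))
            i1 = min(i0 + art.size, total)
            if i0 < total:
                sig[i0:i1] += effects.artifact_amp * art[: i1 - i0]

    events = pd.DataFrame(
        {
            "time_s": event_times,
            "stimulated": stim_flags,
            "peak_speed_px_s": peak_speeds,
            "stim_on_s": stim_on,
            "stim_off_s": stim_off,
        }
    )
    return SynthEcog(signal=sig, sample_rate=fs, events=events, effects=effects)
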