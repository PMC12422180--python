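"""Artifact-aware event-related spectral analysis.

Pipeline: common-average referencing, 2-s epochs centred on peak-speed
times, Morlet time-frequency decomposition (4 cycles), per-trial z-scoring
against the -400..-100 ms pre-peak baseline, speed-matched sampling of
not-stimulated trials, masking of DBS edge artifacts (+/-65 ms around each
burst on/offset), and beta-band (20-35 Hz) statistics in the stimulation
and post-stimulation windows plus a time-resolved cluster test.

Masked samples are NaN and tracked by an explicit boolean mask; statistics
are computed NaN-aware or on cross-epoch median-replaced values (cluster
path only, with time points excluded when >= 15% of epochs are masked).
Linear interpolation across masked spans exists solely for visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import EpochSpec
from . import perm_stats

__all__ = [
    "EpochsTFR",
    "BetaWindowResult",
    "common_average_reference",
    "epoch_around_events",
    "morlet_tfr",
    "baseline_zscore",
    "match_speed_sample",
    "mask_stim_artifacts",
    "median_fill_for_cluster",
    "interpolate_for_plot",
    "beta_window_stats",
]


@dataclass
class EpochsTFR:
    """Trials x frequencies x time power array with an explicit missing mask."""

    power: np.ndarray  # (n_trials, n_freqs, n_times); NaN where masked
    mask: np.ndarray  # bool, True where power is undefined
    times: np.ndarray  # s, relative to the epoch-locking event
    freqs: np.ndarray  # Hz
    events: pd.DataFrame | None = None  # per-trial metadata
    meta: dict = field(default_factory=dict)

    def copy(self) -> "EpochsTFR":
        return EpochsTFR(
            power=self.power.copy(),
            mask=self.mask.copy(),
            times=self.times.copy(),
            freqs=self.freqs.copy(),
            events=None if self.events is None else self.events.copy(),
            meta=dict(self.meta),
        )


def common_average_reference(channels, exclude=()) -> np.ndarray:
    """Re-reference by subtracting the mean of the included channels.

    ``channels`` is (n_channels, n_times); ``exclude`` lists channel indices
    dropped before averaging (e.g. a contact with poor signal quality).
    Excluded channels are removed from the output.
    """
    data = np.asarray(channels, dtype=float)
    if data.ndim != 2:
        raise ValueError("channels must be a 2-D (n_channels, n_times) array")
    keep = [i for i in range(data.shape[0]) if i not in set(exclude)]
    if len(keep) < 2:
        raise ValueError("need at least two included channels")
    included = data[keep]
    return included - included.mean(axis=0, keepdims=True)


def epoch_around_events(
    signal,
    sample_rate: float,
    event_times,
    spec: EpochSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut fixed windows around events.

    Returns ``(epochs, rel_times, kept)`` where ``epochs`` is
    (n_kept, n_times), ``rel_times`` the time axis relative to the event and
    ``kept`` the indices of events far enough from the recording edges
    (dropped events are counted in a warning).
    """
    spec = spec or EpochSpec()
    signal = np.asarray(signal, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    lo, hi = spec.window
    n_lo = int(round(-lo * sample_rate))
    n_hi = int(round(hi * sample_rate))
    rel_times = np.arange(-n_lo, n_hi + 1) / sample_rate
    centers = np.round(event_times * sample_rate).astype(int)
    kept = np.flatnonzero(
        (centers - n_lo >= 0) & (centers + n_hi < signal.size)
    )
    if kept.size == 0:
        raise ValueError("no events lie fully inside the recording")
    n_dropped = event_times.size - kept.size
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} event(s) too close to the recording edge")
    epochs = np.stack([signal[c - n_lo : c + n_hi + 1] for c in centers[kept]])
    return epochs, rel_times, kept


def _morlet_wavelet(freq: float, n_cycles: float, sample_rate: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at 5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    wave = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return wave / np.sqrt(np.sum(np.abs(wave) ** 2))


def morlet_tfr(
    epochs,
    sample_rate: float,
    freqs=None,
    n_cycles: float = 4.0,
    events: pd.DataFrame | None = None,
    times=None,
) -> EpochsTFR:
    """Morlet wavelet power of (n_trials, n_times) epochs.

    Power is the squared magnitude of the convolution with a complex Morlet
    wavelet of ``n_cycles`` cycles per frequency.  Samples whose wavelet
    support extends beyond the epoch are masked.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_trials, n_times = epochs.shape
    if freqs is None:
        freqs = EpochSpec().frequencies
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= sample_rate / 2) or np.any(freqs <= 0):
        raise ValueError("frequencies must lie in (0, Nyquist)")

    power = np.empty((n_trials, freqs.size, n_times))
    mask = np.zeros((n_trials, freqs.size, n_times), dtype=bool)
    for fi, f in enumerate(freqs):
        w = _morlet_wavelet(f, n_cycles, sample_rate)
        conv = fftconvolve(epochs, w[None, :], mode="same", axes=1)
        power[:, fi, :] = np.abs(conv) ** 2
        half = (w.size - 1) // 2
        edge = min(half, n_times)
        mask[:, fi, :edge] = True
        mask[:, fi, n_times - edge :] = True
    power[mask] = np.nan

    if times is None:
        # epoch assumed centred on the locking event
        times = (np.arange(n_times) - (n_times - 1) // 2) / sample_rate
    times = np.asarray(times, dtype=float)
    return EpochsTFR(
        power=power,
        mask=mask,
        times=times,
        freqs=freqs,
        events=events,
        meta={"n_cycles": n_cycles, "sample_rate": sample_rate, "normalized": False},
    )


def baseline_zscore(tfr: EpochsTFR, baseline: tuple[float, float] = (-0.400, -0.100)) -> EpochsTFR:
    """Z-score power per trial and frequency against a pre-event baseline.

    Trial-frequency rows with zero baseline variability (or a fully masked
    baseline) are masked entirely.
    """
    out = tfr.copy()
    sel = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not np.any(sel):
        raise ValueError("baseline window contains no samples")
    base = out.power[:, :, sel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(base, axis=2)
        sd = np.nanstd(base, axis=2)
    bad = ~np.isfinite(mu) | ~np.isfinite(sd) | (sd == 0)
    sd_safe = np.where(bad, 1.0, sd)
    out.power = (out.power - mu[:, :, None]) / sd_safe[:, :, None]
    out.mask = out.mask | bad[:, :, None]
    out.power[out.mask] = np.nan
    out.meta["normalized"] = True
    out.meta["baseline"] = baseline
    return out


def match_speed_sample(
    stim_speeds,
    nonstim_speeds,
    seed: int | None = None,
    alpha: float = 0.05,
    max_retries: int = 20,
    n_perm: int = 2000,
) -> np.ndarray:
    """Indices of a peak-speed-matched, equally sized not-stimulated subset.

    Greedy nearest-neighbour matching without replacement, processing
    stimulated movements in descending peak-speed order so extreme values
    claim neighbours while the pool is rich.  The match is accepted when an
    independent permutation test on peak speed is non-significant; otherwise
    the processing order is randomized and matching retried.
    """
    stim = np.asarray(stim_speeds, dtype=float)
    pool = np.asarray(nonstim_speeds, dtype=float)
    if pool.size < stim.size:
        raise ValueError("not-stimulated pool smaller than the stimulated sample")
    rng = np.random.default_rng(seed)

    def _greedy(order: np.ndarray) -> np.ndarray:
        available = list(range(pool.size))
        chosen = np.empty(stim.size, dtype=int)
        for k in order:
            j = min(available, key=lambda i: (abs(pool[i] - stim[k]), i))
            chosen[k] = j
            available.remove(j)
        return chosen

    order = np.argsort(-stim, kind="stable")
    for attempt in range(max_retries + 1):
        chosen = _greedy(order)
        res = perm_stats.independent_permutation_test(
            stim, pool[chosen], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        if res.p_value > alpha:
            return chosen
        order = rng.permutation(stim.size)
    raise RuntimeError(
        f"speed matching failed after {max_retries} retries "
        f"(last p={res.p_value:.4f}, stim mean={stim.mean():.1f}, "
        f"pool mean={pool.mean():.1f})"
    )


def mask_stim_artifacts(
    tfr: EpochsTFR,
    events: pd.DataFrame | None = None,
    halfwidth: float = 0.065,
) -> EpochsTFR:
    """NaN-mask DBS edge artifacts around burst on/offsets, per trial.

    ``events`` needs columns ``stim_on_s``/``stim_off_s`` in epoch-relative
    seconds (``time_s`` is subtracted when present) and ``stimulated``;
    samples within ``halfwidth`` of each on/offset are masked.  On/offsets
    outside the epoch are ignored with a warning.
    """
    events = events if events is not None else tfr.events
    if events is None:
        raise ValueError("no event metadata with stimulation times")
    out = tfr.copy()
    for ti, (_, ev) in enumerate(events.iterrows()):
        if not bool(ev.get("stimulated", False)):
            continue
        center = float(ev["time_s"]) if "time_s" in ev else 0.0
        for col in ("stim_on_s", "stim_off_s"):
            edge = float(ev[col]) - center
            if not np.isfinite(edge):
                continue
            if edge > out.times[-1] + halfwidth or edge < out.times[0] - halfwidth:
                warnings.warn(
                    f"stimulation edge at {edge:.3f} s outside the epoch; ignored"
                )
                continue
            sel = np.abs(out.times - edge) <= halfwidth
            out.mask[ti][:, sel] = True
    out.power[out.mask] = np.nan
    return out


def median_fill_for_cluster(
    tfr: EpochsTFR, max_fraction: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-epoch median replacement of masked values for cluster analysis.

    At each (frequency, time) point: when the fraction of masked epochs is
    below ``max_fraction`` masked entries are replaced by the median of the
    remaining epochs; otherwise the point is excluded.  Returns
    ``(filled_power, valid)`` where ``valid`` is (n_freqs, n_times), False
    at excluded points.
    """
    n_trials = tfr.power.shape[0]
    frac = tfr.mask.sum(axis=0) / n_trials  # (n_freqs, n_times)
    valid = frac < max_fraction
    filled = tfr.power.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(tfr.power, axis=0)  # (n_freqs, n_times)
    fill_at = tfr.mask & valid[None, :, :] & np.isfinite(med)[None, :, :]
    filled[fill_at] = np.broadcast_to(med[None, :, :], filled.shape)[fill_at]
    return filled, valid


def interpolate_for_plot(tfr: EpochsTFR) -> np.ndarray:
    """Linearly interpolate masked spans along time — visualization only.

    The returned array must never feed statistics.
    """
    out = tfr.power.copy()
    n_trials, n_freqs, _ = out.shape
    for ti in range(n_trials):
        for fi in range(n_freqs):
            row = out[ti, fi]
            bad = ~np.isfinite(row)
            if bad.any() and (~bad).sum() >= 2:
                row[bad] = np.interp(
                    tfr.times[bad], tfr.times[~bad], row[~bad]
                )
    return out


@dataclass(frozen=True)
class BetaWindowResult:
    """Beta-band window statistics and cluster test for stim vs no-stim."""

    per_trial: pd.DataFrame  # trial, stimulated, stim_window_beta, post_window_beta
    stim_window_test: perm_stats.PermResult
    post_window_test: perm_stats.PermResult
    cluster: perm_stats.ClusterResult
    cluster_valid: np.ndarray  # time points admitted to the cluster test
    times: np.ndarray


def _window_trial_means(
    tfr: EpochsTFR, band: tuple[float, float], window: tuple[float, float]
) -> np.ndarray:
    fsel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tsel = (tfr.times >= window[0]) & (tfr.times <= window[1])
    block = tfr.power[:, fsel][:, :, tsel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(1, 2))


def beta_window_stats(
    tfr: EpochsTFR,
    stimulated,
    spec: EpochSpec | None = None,
    n_perm: int = 5000,
    cluster_n_perm: int = 1000,
    seed: int | None = None,
) -> BetaWindowResult:
    """Beta power in the stimulation and post-stimulation windows, by group.

    Per trial the NaN-aware mean of normalized power over the beta band and
    each window is computed (trials with a fully masked window are missing
    for that window) and compared between stimulated and not-stimulated
    trials with independent permutation tests.  A cluster permutation test
    runs over the full beta-band time course on median-filled data with
    over-masked time points excluded.
    """
    spec = spec or EpochSpec()
    stimulated = np.asarray(stimulated, dtype=bool)
    if stimulated.size != tfr.power.shape[0]:
        raise ValueError("stimulated flags must match the number of trials")

    stim_beta = _window_trial_means(tfr, spec.beta_band, spec.stim_window)
    post_beta = _window_trial_means(tfr, spec.beta_band, spec.post_window)
    per_trial = pd.DataFrame(
        {
            "trial": np.arange(stimulated.size),
            "stimulated": stimulated,
            "stim_window_beta": stim_beta,
            "post_window_beta": post_beta,
        }
    )

    rng = np.random.default_rng(seed)

    def _test(values: np.ndarray) -> perm_stats.PermResult:
        a = values[stimulated & np.isfinite(values)]
        b = values[~stimulated & np.isfinite(values)]
        return perm_stats.independent_permutation_test(
            a, b, n_perm=n_perm, seed=int(rng.integers(2**31))
        )

    stim_test = _test(stim_beta)
    post_test = _test(post_beta)

    # cluster path: beta-band mean time course on median-filled power
    filled, valid_ft = median_fill_for_cluster(tfr, spec.nan_epoch_fraction)
    fsel = (tfr.freqs >= spec.beta_band[0]) & (tfr.freqs <= spec.beta_band[1])
    course = filled[:, fsel, :].mean(axis=1)  # (n_trials, n_times)
    valid = valid_ft[fsel, :].all(axis=0) & np.isfinite(course).all(axis=0)
    cluster = perm_stats.cluster_permutation_test(
        course[stimulated],
        course[~stimulated],
        n_perm=cluster_n_perm,
        alpha=0.05,
        seed=int(rng.integers(2**31)),
        valid_mask=valid,
    )
    return BetaWindowResult(
        per_trial=per_trial,
        stim_window_test=stim_test,
        post_window_test=post_test,
        cluster=cluster,
        cluster_valid=valid,
        times=tfr.times,
    )
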