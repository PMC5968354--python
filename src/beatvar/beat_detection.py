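"""Beat detection on optical and electrical traces.

The optical detector ("PointFinder" style) smooths the mean-gray trace
with a short moving average, thresholds it between the baseline noise band
and the deepest contraction dip, and takes the arg-min of each
sub-threshold run as a beat.  Beat-to-beat intervals (BBIs) are the first
differences of the beat times.  A separate branch detects beats on
extracellular voltage traces by downward threshold crossings, and a
cross-correlation alignment removes the small start asynchronism between
simultaneously recorded optical and electrical series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .trace_extraction import GrayTrace

__all__ = [
    "BeatSeries",
    "IntervalSeries",
    "moving_average",
    "estimate_threshold",
    "detect_beats",
    "compute_bbi",
    "butter_bandfilter",
    "detect_beats_electrical",
    "align_lag",
]


@dataclass
class BeatSeries:
    """Per-beat detections on one trace.

    ``indices`` are 0-based sample indices of the detected minima (strictly
    increasing), ``times`` the same in seconds, ``minima_values`` the signal
    value at each beat, ``threshold_used`` the detection threshold in the
    units of the analyzed signal.
    """

    indices: np.ndarray
    times: np.ndarray
    minima_values: np.ndarray
    threshold_used: float
    source: str = "optical"  # "optical" | "electrical"
    sample_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.minima_values = np.asarray(self.minima_values, dtype=float)
        if not (len(self.indices) == len(self.times) == len(self.minima_values)):
            raise ValueError("indices, times and minima_values must align")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("beat indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class IntervalSeries:
    """Beat-to-beat intervals in milliseconds for one experiment arm."""

    bbi: np.ndarray
    experiment_id: Optional[str] = None
    treatment: Optional[str] = None  # "Con" | "ACh"

    def __post_init__(self) -> None:
        self.bbi = np.asarray(self.bbi, dtype=float)
        if self.bbi.size and np.any(self.bbi <= 0):
            raise ValueError("all intervals must be positive")

    def __len__(self) -> int:
        return self.bbi.size


def moving_average(values: np.ndarray | GrayTrace, window: int = 25):
    """Centered moving average; the window truncates at the trace edges.

    Output length equals input length.  At index i the mean is taken over
    the available samples in [i - (window-1)//2, i + window//2], so no
    phantom excursions are introduced at the ends.  Accepts either a bare
    array or a :class:`GrayTrace` (returned as the same type).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    trace = values if isinstance(values, GrayTrace) else None
    x = np.asarray(trace.values if trace is not None else values, dtype=float)
    if window > x.size:
        raise ValueError(f"window {window} exceeds trace length {x.size}")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    if trace is not None:
        meta = dict(trace.meta)
        meta["smoothed_window"] = window
        return GrayTrace(np.clip(out, 0.0, 255.0), trace.sample_rate, meta=meta)
    return out


def estimate_threshold(values: np.ndarray | GrayTrace) -> float:
    """Place the detection threshold between baseline noise band and deepest dip.

    The admissible interval runs from (baseline - 2 * noise SD) down to the
    global minimum; the midpoint of that interval is returned.  The baseline
    level is the trace median.  The noise SD is estimated from the median
    absolute first difference (1.4826 / sqrt(2) * median|dx|): differencing
    removes the contraction waveform and drift, so the estimate reflects
    the sensor noise band of the baseline rather than signal variation
    (a plain MAD of the trace counts the dips as noise and can push the
    threshold below shallow beats).
    """
    x = np.asarray(values.values if isinstance(values, GrayTrace) else values, float)
    med = float(np.median(x))
    noise_sd = 1.4826 / np.sqrt(2.0) * float(np.median(np.abs(np.diff(x))))
    gmin = float(np.min(x))
    if noise_sd == 0.0 and gmin == med:
        raise ValueError("no contractions detectable: flat trace")
    upper = med - 2.0 * noise_sd
    return 0.5 * (upper + gmin)


def detect_beats(
    trace: GrayTrace,
    window: int = 25,
    threshold: Optional[float] = None,
) -> BeatSeries:
    """Detect contraction minima on a mean-gray trace.

    The trace is smoothed with a ``window``-point centered moving average;
    maximal runs of consecutive smoothed samples below the threshold are
    located, and within each run the arg-min of the smoothed signal is the
    beat.  When two samples tie exactly for the run minimum the second one
    is taken.  Runs touching either trace end are discarded because their
    minimum is not bracketed by a confirmed return above threshold.  Runs
    separated by fewer than ``window`` samples are merged first: on noisy
    traces the smoothed signal can pop briefly above threshold inside one
    dip, and a gap far shorter than the dip itself cannot separate two
    physiological beats.

    ``minima_values`` holds the raw (unsmoothed) trace averaged over the
    detected frame and its two neighbours, i.e. the gray value of the beat
    image with single-frame sensor noise suppressed.
    """
    raw = trace.values
    if raw.size < window:
        raise ValueError("trace shorter than smoothing window")
    smoothed = moving_average(raw, window)
    if threshold is None:
        threshold = estimate_threshold(smoothed)
    else:
        baseline = float(np.median(smoothed))
        if threshold >= baseline:
            raise ValueError(
                f"threshold {threshold} at or above baseline level {baseline:.3f}"
            )
    below = smoothed < threshold
    if not below.any():
        return BeatSeries(
            np.empty(0, int), np.empty(0), np.empty(0),
            threshold_used=float(threshold), sample_rate=trace.sample_rate,
        )
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # half-open [start, end)
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [below.size]))
    # merge runs split by brief noise pops above threshold
    if starts.size > 1:
        keep_s, keep_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - keep_e[-1] < window:
                keep_e[-1] = e
            else:
                keep_s.append(s)
                keep_e.append(e)
        starts, ends = np.asarray(keep_s), np.asarray(keep_e)
    # drop partial dips at the trace ends
    keep = ~((starts == 0) | (ends == below.size))
    starts, ends = starts[keep], ends[keep]

    indices = []
    for s, e in zip(starts, ends):
        seg = smoothed[s:e]
        # tie rule: the *second* of equal adjacent minima -> last arg-min
        idx = e - 1 - int(np.argmin(seg[::-1]))
        indices.append(idx)
    indices = np.asarray(indices, dtype=int)
    lo = np.clip(indices - 1, 0, raw.size - 1)
    hi = np.clip(indices + 1, 0, raw.size - 1)
    minima = np.array([raw[a : b + 1].mean() for a, b in zip(lo, hi)])
    return BeatSeries(
        indices=indices,
        times=indices / trace.sample_rate,
        minima_values=minima,
        threshold_used=float(threshold),
        source="optical",
        sample_rate=trace.sample_rate,
    )


def compute_bbi(
    beats: BeatSeries,
    experiment_id: Optional[str] = None,
    treatment: Optional[str] = None,
) -> IntervalSeries:
    """Beat-to-beat intervals in ms: BBI_b = t_b - t_{b-1}; length N_B - 1."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to form intervals")
    return IntervalSeries(
        np.diff(beats.times) * 1000.0, experiment_id=experiment_id, treatment=treatment
    )


def butter_bandfilter(
    values: np.ndarray,
    sample_rate: float,
    lowpass_hz: float = 1500.0,
    highpass_hz: float = 1.5,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band filtering for electrode traces."""
    x = np.asarray(values, float)
    nyq = sample_rate / 2.0
    if lowpass_hz < nyq:
        sos = sps.butter(order, lowpass_hz, "lowpass", fs=sample_rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if highpass_hz > 0:
        sos = sps.butter(order, highpass_hz, "highpass", fs=sample_rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    return x


def detect_beats_electrical(
    values: np.ndarray,
    sample_rate: float,
    threshold: float,
    mode: str = "signal",
    prefilter: bool = False,
    refractory_ms: float = 50.0,
) -> BeatSeries:
    """Time-stamp beats on an extracellular voltage trace.

    A beat is the first sample below ``threshold`` on a decreasing slope
    (downward threshold crossing).  ``mode='derivative'`` applies the same
    rule to the first temporal derivative, which helps on low-SNR signals
    where the activation downslope is the most pronounced feature.  A
    refractory window suppresses duplicate crossings on noisy downslopes.
    ``prefilter`` applies the standard Butterworth band filter first.
    """
    x = np.asarray(values, dtype=float)
    if prefilter:
        x = butter_bandfilter(x, sample_rate)
    if mode == "derivative":
        y = np.gradient(x) * sample_rate
    elif mode == "signal":
        y = x
    else:
        raise ValueError(f"unknown mode {mode!r}")
    above = y >= threshold
    crossings = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if crossings.size:
        refractory = int(round(refractory_ms * sample_rate / 1000.0))
        kept = [int(crossings[0])]
        for c in crossings[1:]:
            if c - kept[-1] > refractory:
                kept.append(int(c))
        crossings = np.asarray(kept)
    return BeatSeries(
        indices=crossings,
        times=crossings / sample_rate,
        minima_values=x[crossings] if crossings.size else np.empty(0),
        threshold_used=float(threshold),
        source="electrical",
        sample_rate=sample_rate,
    )


def align_lag(
    a: IntervalSeries, b: IntervalSeries, max_lag: int = 5
) -> tuple[int, IntervalSeries, IntervalSeries]:
    """Remove the start asynchronism between two paired interval series.

    Returns the lag (in beats, positive when ``b`` lags ``a``) maximizing
    the unbiased cross-correlation of the mean-removed series over
    |lag| <= ``max_lag``, plus both series trimmed to the overlap.  The
    bound keeps spurious distant maxima out; recordings started within a
    few beats of each other.
    """
    xa = a.bbi - a.bbi.mean()
    xb = b.bbi - b.bbi.mean()
    if min(xa.size, xb.size) < 5:
        raise ValueError("need at least 5 intervals in each series")
    if np.allclose(xa, 0) or np.allclose(xb, 0):
        raise ValueError("degenerate correlation: constant interval series")
    best_lag, best_c = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            n = min(xa.size - lag, xb.size)
            if n < 2:
                continue
            c = float(np.dot(xa[lag : lag + n], xb[:n])) / n
        else:
            n = min(xa.size, xb.size + lag)
            if n < 2:
                continue
            c = float(np.dot(xa[:n], xb[-lag : -lag + n])) / n
        if c > best_c:
            best_lag, best_c = lag, c
    lag = best_lag
    if lag >= 0:
        n = min(a.bbi.size - lag, b.bbi.size)
        ta = a.bbi[lag : lag + n]
        tb = b.bbi[:n]
    else:
        n = min(a.bbi.size, b.bbi.size + lag)
        ta = a.bbi[:n]
        tb = b.bbi[-lag : -lag + n]
    trimmed_a = IntervalSeries(ta, a.experiment_id, a.treatment)
    trimmed_b = IntervalSeries(tb, b.experiment_id, b.treatment)
    return lag, trimmed_a, trimmed_b
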