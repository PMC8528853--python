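"""Sharp-wave-ripple detection and bilateral synchrony.

Events are detected on the 90-250 Hz band (zero-phase Hamming FIR) of each
hemisphere's LFP: the band RMS power (12.5 ms sliding window) must exceed the
immobility mean by 5 SD at the peak, event edges are taken at the 2 SD
crossings, events whose peaks fall within 50 ms are merged, and events whose
peak occurs while the animal moves at >= 2 cm/s are discarded. Bilateral
synchrony is summarised by a +-100 ms cross-correlogram of event midpoints
(1 ms bins, Gaussian-smoothed with SD 4 bins, normalised to SWRs/s).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import filtfilt, firwin, hilbert
from scipy.signal.windows import dpss

from .types import PositionTrace, RippleCrossCorrelogram, RippleEvent

__all__ = [
    "bandpass_filter",
    "rms_power",
    "detect_ripples",
    "merge_close_events",
    "ripple_peak_frequency",
    "ripple_occurrence",
    "bilateral_cross_correlogram",
]


def design_bandpass(fs: float, band: Tuple[float, float] = (90.0, 250.0)) -> np.ndarray:
    """Hamming-window FIR band-pass taps; order ~3 cycles of the low edge."""
    lo, hi = band
    if fs < 2 * hi:
        hi = 0.95 * fs / 2  # keep the design valid at low sampling rates
    numtaps = int(round(3 * fs / lo))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    return firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_filter(lfp: np.ndarray, fs: float,
                    band: Tuple[float, float] = (90.0, 250.0)) -> np.ndarray:
    """Zero-phase ripple-band filtering (forward-backward FIR)."""
    taps = design_bandpass(fs, band)
    if lfp.size <= 3 * taps.size:
        raise ValueError("trace shorter than filter order")
    return filtfilt(taps, [1.0], np.asarray(lfp, dtype=float))


def rms_power(band_signal: np.ndarray, fs: float, window_ms: float = 12.5) -> np.ndarray:
    """Sliding-window root-mean-square power of the band-passed signal."""
    width = max(1, int(round(window_ms * 1e-3 * fs)))
    return np.sqrt(uniform_filter1d(band_signal ** 2, size=width, mode="nearest"))


def merge_close_events(events: List[RippleEvent], merge_ms: float = 50.0) -> List[RippleEvent]:
    """Merge events whose peaks are closer than ``merge_ms`` (union of extents).

    Idempotent and order-independent: events are time-sorted and chained
    merging is applied until no adjacent pair of peaks is closer than the
    threshold.
    """
    if not events:
        return []
    evs = sorted(events, key=lambda e: e.t_peak)
    merged: List[RippleEvent] = []
    group = [evs[0]]
    for e in evs[1:]:
        # chain on gaps between ORIGINAL peaks: transitive closure, so the
        # result does not depend on processing order and is a fixed point
        if (e.t_peak - group[-1].t_peak) * 1e3 < merge_ms:
            group.append(e)
        else:
            merged.append(_merge_group(group))
            group = [e]
    merged.append(_merge_group(group))
    return merged


def _merge_group(group: List[RippleEvent]) -> RippleEvent:
    if len(group) == 1:
        return group[0]
    amps = np.array([e.amplitude_mv for e in group])
    best = group[len(group) // 2] if np.all(np.isnan(amps)) else group[int(np.nanargmax(amps))]
    return RippleEvent(hemisphere=best.hemisphere,
                       t_start=min(e.t_start for e in group),
                       t_stop=max(e.t_stop for e in group),
                       t_peak=best.t_peak, amplitude_mv=best.amplitude_mv)


def detect_ripples(lfp: np.ndarray, fs: float, times: Optional[np.ndarray] = None,
                   position: Optional[PositionTrace] = None, *, hemisphere: str = "L",
                   band: Tuple[float, float] = (90.0, 250.0), peak_sd: float = 5.0,
                   edge_sd: float = 2.0, merge_ms: float = 50.0,
                   immobility_velocity: float = 2.0,
                   rms_window_ms: float = 12.5) -> List[RippleEvent]:
    """Detect SWR events on one hemisphere's LFP trace.

    Detection statistics are computed over immobility samples only, so
    movement artifacts cannot inflate the thresholds, and the background
    mean/SD of the RMS power are estimated robustly (median and scaled MAD):
    the events being detected are themselves part of the trace, and with a
    moment estimator their amplitude would inflate the SD and shift the
    detector's operating point with event density. If no position trace is
    supplied the whole trace is treated as immobile.
    """
    lfp = np.asarray(lfp, dtype=float)
    if times is None:
        times = np.arange(lfp.size) / fs
    band_sig = bandpass_filter(lfp, fs, band)
    power = rms_power(band_sig, fs, rms_window_ms)

    if position is not None:
        speed = np.abs(np.interp(times, position.times, position.velocity))
        immobile = speed < immobility_velocity
    else:
        speed = np.zeros_like(times)
        immobile = np.ones(lfp.size, dtype=bool)
    if not np.any(immobile):
        return []
    p_imm = power[immobile]
    mu = float(np.median(p_imm))
    sd = float(1.4826 * np.median(np.abs(p_imm - mu)))
    peak_thr = mu + peak_sd * sd
    edge_thr = mu + edge_sd * sd

    above_edge = power > edge_thr
    # contiguous supra-edge regions
    d = np.diff(above_edge.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above_edge[0]:
        starts = np.r_[0, starts]
    if above_edge[-1]:
        stops = np.r_[stops, above_edge.size]

    envelope = np.abs(hilbert(band_sig))
    events: List[RippleEvent] = []
    for a, b in zip(starts, stops):
        seg = power[a:b]
        if seg.max() <= peak_thr:
            continue
        ipk = a + int(np.argmax(seg))
        if speed[ipk] >= immobility_velocity:
            continue
        events.append(RippleEvent(hemisphere=hemisphere, t_start=float(times[a]),
                                  t_stop=float(times[b - 1]), t_peak=float(times[ipk]),
                                  amplitude_mv=float(envelope[a:b].max())))
    events = merge_close_events(events, merge_ms)
    for i, e in enumerate(events):
        e.event_id = i
    return events


def ripple_peak_frequency(event: RippleEvent, lfp: np.ndarray, fs: float,
                          times: Optional[np.ndarray] = None, *,
                          band: Tuple[float, float] = (90.0, 250.0),
                          time_bandwidth: float = 2.0, n_tapers: int = 3,
                          min_cycles: float = 3.0,
                          prominence_ratio: float = 5.0) -> Tuple[float, bool]:
    """Multitaper peak frequency of one event window.

    Returns ``(freq_hz, confident)``. Events shorter than ``min_cycles``
    cycles of the band's low edge yield ``(nan, False)``; a spectral peak
    less than ``prominence_ratio`` times the median in-band power (no clear
    oscillation) is reported but flagged low-confidence.
    """
    lfp = np.asarray(lfp, dtype=float)
    if times is None:
        times = np.arange(lfp.size) / fs
    lo, hi = band
    if (event.t_stop - event.t_start) < min_cycles / lo:
        return float("nan"), False
    i0, i1 = np.searchsorted(times, [event.t_start, event.t_stop])
    seg = lfp[i0:i1]
    seg = seg - seg.mean()
    n = seg.size
    tapers = dpss(n, time_bandwidth, Kmax=n_tapers)
    nfft = max(1024, int(2 ** np.ceil(np.log2(n))))
    spec = np.abs(np.fft.rfft(tapers * seg[None, :], n=nfft, axis=1)) ** 2
    psd = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    pk = int(np.argmax(psd[sel]))
    peak_freq = float(freqs[sel][pk])
    confident = bool(psd[sel][pk] > prominence_ratio * np.median(psd[sel]))
    return peak_freq, confident


def ripple_occurrence(events: Sequence[RippleEvent], qualified_duration: float) -> float:
    """Event count per second of immobility-qualified session time."""
    if qualified_duration <= 0:
        raise ValueError("qualified duration must be positive")
    return len(events) / qualified_duration


def bilateral_cross_correlogram(reference_events: Sequence[RippleEvent],
                                other_events: Sequence[RippleEvent], *,
                                half_window_ms: float = 100.0, bin_ms: float = 1.0,
                                smoothing_sd_bins: float = 4.0) -> RippleCrossCorrelogram:
    """Rate of other-hemisphere midpoints around reference midpoints.

    Counts are normalised to SWRs/s (counts / n_reference / bin width) and
    smoothed with a Gaussian kernel of SD ``smoothing_sd_bins`` lag bins.
    """
    if len(reference_events) == 0:
        raise ValueError("empty reference event set")
    ref = np.array([e.midpoint for e in reference_events])
    oth = np.sort(np.array([e.midpoint for e in other_events]))
    edges_ms = np.arange(-half_window_ms - bin_ms / 2, half_window_ms + bin_ms, bin_ms)
    lags_ms = 0.5 * (edges_ms[:-1] + edges_ms[1:])
    counts = np.zeros(lags_ms.size)
    for t in ref:
        rel = (oth - t) * 1e3
        rel = rel[(rel >= edges_ms[0]) & (rel <= edges_ms[-1])]
        if rel.size:
            counts += np.histogram(rel, bins=edges_ms)[0]
    rate = counts / (len(ref) * bin_ms * 1e-3)
    if smoothing_sd_bins > 0:
        rate = gaussian_filter1d(rate, smoothing_sd_bins, mode="reflect")
    return RippleCrossCorrelogram(lags_ms=lags_ms, rate=rate, n_reference=len(ref),
                                  smoothing_sd_bins=smoothing_sd_bins)
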