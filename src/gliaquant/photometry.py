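"""Isosbestic-corrected fiber-photometry analysis.

The calcium-dependent channel (465 nm) is corrected by least-squares
fitting the isosbestic control (405 nm) to it and subtracting the fitted
control: ΔF/F = signal − fitted control. Calcium transients are detected
with a two-stage robust rule inside a sliding analysis window: samples
more than k1 = 2 median absolute deviations (MAD) above the window median
are excluded when forming the reference statistics, and local maxima of
the original trace more than k2 = 3 MADs above the reference median are
events. Epoch summaries (event frequency, maximum amplitude, AUC in
10-minute bins) and zeitgeber light/dark aggregates follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


@dataclass
class PhotometryRecording:
    """Two-channel photometry trace sampled at a fixed rate."""

    time_s: np.ndarray
    signal: np.ndarray
    control: np.ndarray
    fs_hz: float
    epochs: list[tuple[float, float]] = field(default_factory=list)
    zt_start_h: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.signal) == len(self.control)):
            raise ValueError("time, signal and control must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class DffTrace:
    """ΔF/F and z-score traces derived from one recording."""

    dff: np.ndarray
    zscore: np.ndarray
    fitted_control: np.ndarray
    fs_hz: float
    window_s: float = 600.0


@dataclass
class TransientSet:
    """Detected calcium events: sorted times and peak amplitudes."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    k1: float = 2.0
    k2: float = 3.0
    window_s: float = 600.0


@dataclass
class EpochSummary:
    """Per-epoch activity statistics over the analyzed span."""

    epoch: tuple[float, float]
    analyzed_span_s: float
    n_events: int
    frequency_per_min: float
    max_amplitude: float | None
    auc_per_bin: list[float]
    zt_hour: int | None = None


def fit_control(rec: PhotometryRecording) -> tuple[np.ndarray, tuple[float, float]]:
    """Least-squares affine fit of the control channel to the signal.

    Returns the fitted control a*control + b and the coefficients (a, b).
    """
    c = np.asarray(rec.control, dtype=float)
    s = np.asarray(rec.signal, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(s))):
        raise ValueError("channels must be finite")
    if np.ptp(c) == 0:
        raise ValueError("control channel is constant; affine fit is degenerate")
    A = np.column_stack([c, np.ones_like(c)])
    (a, b), *_ = np.linalg.lstsq(A, s, rcond=None)
    return a * c + b, (float(a), float(b))


def compute_dff(
    rec: PhotometryRecording,
    fitted_control: np.ndarray,
    window_s: float = 600.0,
) -> DffTrace:
    """ΔF/F = signal − fitted control, plus its z-score.

    The z-score is (ΔF/F − mean)/sd over the supplied trace (one analysis
    window / epoch at a time is the intended use).
    """
    dff = np.asarray(rec.signal, dtype=float) - np.asarray(fitted_control, dtype=float)
    sd = float(np.std(dff))
    if sd == 0:
        if dff.size and np.allclose(dff, 0.0):
            # identically-zero ΔF/F (signal equals fitted control): keep a
            # zero z-score rather than refusing the degenerate-but-exact case
            z = np.zeros_like(dff)
            return DffTrace(dff=dff, zscore=z, fitted_control=fitted_control,
                            fs_hz=rec.fs_hz, window_s=window_s)
        raise ValueError("ΔF/F has zero variance; z-score undefined")
    z = (dff - dff.mean()) / sd
    return DffTrace(dff=dff, zscore=z, fitted_control=fitted_control,
                    fs_hz=rec.fs_hz, window_s=window_s)


def detect_transients(
    trace: DffTrace,
    window_s: float = 600.0,
    k1: float = 2.0,
    k2: float = 3.0,
    min_separation_s: float = 0.5,
    smooth_s: float = 0.25,
    use_zscore: bool = False,
) -> TransientSet:
    """Two-stage MAD-rule transient detection on ΔF/F (or z-score).

    The trace is first smoothed with a short moving average (``smooth_s``;
    the acquisition chain low-pass filters the demodulated signals, and
    peak finding follows the smoothed trace). Within each ``window_s``
    stretch of the smoothed trace: (1) samples above median + k1·MAD are
    excluded when forming the reference statistics; (2) local maxima
    above reference-median + k2·reference-MAD are events. The MAD is the
    raw median absolute deviation (no normality scaling); a zero MAD
    (flat trace) yields no events. Each event's time and amplitude are
    refined to the raw-trace maximum within the smoothing span, so on a
    noise-free trace the true peak sample is recovered exactly.
    """
    from scipy.ndimage import uniform_filter1d

    x = np.asarray(trace.zscore if use_zscore else trace.dff, dtype=float)
    n_win = int(round(window_s * trace.fs_hz))
    if n_win > len(x):
        raise ValueError(
            f"window of {n_win} samples exceeds trace length {len(x)}"
        )
    n_smooth = max(1, int(round(smooth_s * trace.fs_hz)))
    xs = uniform_filter1d(x, n_smooth) if n_smooth > 1 else x
    min_dist = max(1, int(round(min_separation_s * trace.fs_hz)))

    peak_idx: list[int] = []
    for start in range(0, len(xs), n_win):
        seg = x[start : start + n_win]       # raw window: threshold statistics
        seg_sm = xs[start : start + n_win]   # smoothed window: peak finding
        if len(seg) < 2:
            continue
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        kept = seg[seg <= med + k1 * mad]
        if kept.size == 0:
            kept = seg
        ref_med = np.median(kept)
        ref_mad = np.median(np.abs(kept - ref_med))
        threshold = ref_med + k2 * ref_mad
        # prominence must also clear k2·MAD so noise maxima riding on a
        # transient's decay shoulder are not counted as separate events
        peaks, _ = find_peaks(seg_sm, height=np.nextafter(threshold, np.inf),
                              distance=min_dist, prominence=k2 * ref_mad)
        # refine to the raw-trace maximum within the smoothing span
        for p in peaks:
            lo = max(0, start + p - n_smooth)
            hi = min(len(x), start + p + n_smooth + 1)
            peak_idx.append(lo + int(np.argmax(x[lo:hi])))

    # dedupe refined peaks and enforce the refractory separation
    times: list[float] = []
    amps: list[float] = []
    last = -np.inf
    for i in sorted(set(peak_idx)):
        t = i / trace.fs_hz
        if t - last < min_separation_s:
            if amps and x[i] > amps[-1]:
                times[-1], amps[-1] = t, float(x[i])
                last = t
            continue
        times.append(t)
        amps.append(float(x[i]))
        last = t

    return TransientSet(
        times_s=np.asarray(times),
        amplitudes=np.asarray(amps),
        k1=k1,
        k2=k2,
        window_s=window_s,
    )


def summarize_epoch(
    trace: DffTrace,
    events: TransientSet,
    epoch: tuple[float, float],
    zt_hour: int | None = None,
    analysis_span_s: float = 600.0,
    bin_s: float = 600.0,
) -> EpochSummary | None:
    """Summarize one epoch, trimming an 11-min epoch to its final 600 s.

    Epochs longer than ``analysis_span_s`` have their beginning discarded
    (the first minute of an 11-minute epoch carries tethering artifacts);
    an epoch with no analyzable span returns None.
    """
    start, end = float(epoch[0]), float(epoch[1])
    if end <= start:
        return None
    if end - start > analysis_span_s:
        start = end - analysis_span_s
    span = end - start
    if span <= 0:
        return None

    in_epoch = (events.times_s >= start) & (events.times_s < end)
    ev_amps = events.amplitudes[in_epoch]
    n = int(in_epoch.sum())

    t = np.arange(len(trace.dff)) / trace.fs_hz
    auc: list[float] = []
    b0 = start
    while b0 < end - 1e-9:
        b1 = min(b0 + bin_s, end)
        m = (t >= b0) & (t <= b1)
        if m.sum() >= 2:
            auc.append(float(np.trapezoid(trace.dff[m], t[m])))
        b0 = b1

    return EpochSummary(
        epoch=(start, end),
        analyzed_span_s=span,
        n_events=n,
        frequency_per_min=n / (span / 60.0),
        max_amplitude=float(ev_amps.max()) if n else None,
        auc_per_bin=auc,
        zt_hour=zt_hour,
    )


def phase_aggregate(summaries: list[EpochSummary]) -> dict:
    """Light/dark phase means of event frequency and max amplitude.

    ZT hours 0–11 are the light phase, 12–23 the dark phase.
    """
    out: dict = {}
    for phase, hours in (("light", range(0, 12)), ("dark", range(12, 24))):
        rows = []
        for s in summaries:
            if s.zt_hour is None:
                raise ValueError("every epoch summary needs a ZT hour")
            if not 0 <= s.zt_hour < 24:
                raise ValueError(f"ZT hour {s.zt_hour} outside [0, 24)")
            if s.zt_hour in hours:
                rows.append(s)
        amps = [s.max_amplitude for s in rows if s.max_amplitude is not None]
        out[phase] = {
            "n_epochs": len(rows),
            "mean_frequency_per_min": (
                float(np.mean([s.frequency_per_min for s in rows])) if rows else None
            ),
            "mean_max_amplitude": float(np.mean(amps)) if amps else None,
        }
    return out
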