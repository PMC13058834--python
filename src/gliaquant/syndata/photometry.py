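"""Synthetic two-channel fiber-photometry recordings.

The calcium-dependent (465 nm) and isosbestic control (405 nm) channels
share one slow drift — the control exists precisely to capture that shared
non-calcium variance — related by a fixed affine map. Calcium transients
(instant rise, exponential decay) are injected into the signal channel
only, at Poisson event times or a requested count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..photometry import PhotometryRecording
from .base import GroundTruth, object_rng


@dataclass
class PhotometrySpec:
    """Parameters of a synthetic photometry session.

    ``n_transients`` fixes the event count exactly; if None, events are
    drawn Poisson at ``transient_rate_hz``. Amplitudes are the per-event
    jumps added to the signal channel (same units as the trace).
    """

    duration_s: float = 660.0
    fs_hz: float = 100.0
    n_transients: int | None = None
    transient_rate_hz: float = 0.05
    amplitude: float = 1.0
    amplitude_jitter: float = 0.2       # lognormal-ish spread around amplitude
    decay_tau_s: float = 1.5
    drift_coeffs: tuple[float, ...] = (5.0, -0.5, 0.2)  # polynomial on t/T in [0,1]
    affine_a: float = 2.0               # signal = a * control_clean + b (+ events)
    affine_b: float = 10.0
    noise_sd: float = 0.02
    min_separation_s: float = 5.0
    zt_start_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.transient_rate_hz < 0:
            raise ValueError("rates and noise sd must be >= 0")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration and sampling rate must be > 0")


def gen_photometry(spec: PhotometrySpec) -> tuple[PhotometryRecording, GroundTruth]:
    """Generate a synthetic recording plus its transient ground truth."""
    wants_events = spec.n_transients not in (None, 0) or (
        spec.n_transients is None and spec.transient_rate_hz > 0
    )
    if spec.duration_s < 600.0 and wants_events:
        warnings.warn(
            "duration < 600 s with transients requested: the 600-s detection "
            "window rule cannot apply to this recording",
            stacklevel=2,
        )

    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz

    drift = np.polynomial.polynomial.polyval(
        t / spec.duration_s, np.asarray(spec.drift_coeffs)
    )
    control_clean = drift
    signal = spec.affine_a * control_clean + spec.affine_b

    ev_rng = object_rng(spec.seed, 0)
    if spec.n_transients is not None:
        n_events = int(spec.n_transients)
    else:
        n_events = ev_rng.poisson(spec.transient_rate_hz * spec.duration_s)
    times = _draw_event_times(ev_rng, n_events, spec)
    amps = spec.amplitude * np.exp(
        ev_rng.normal(0.0, spec.amplitude_jitter, size=n_events)
    )

    for t0, a in zip(times, amps):
        i0 = int(np.searchsorted(t, t0))
        tail = t[i0:] - t[i0]
        signal[i0:] += a * np.exp(-tail / spec.decay_tau_s)

    if spec.noise_sd > 0:
        nz = object_rng(spec.seed, 1)
        signal = signal + nz.normal(0.0, spec.noise_sd, n)
        control = control_clean + nz.normal(0.0, spec.noise_sd, n)
    else:
        control = control_clean.copy()

    rec = PhotometryRecording(
        time_s=t,
        signal=signal,
        control=control,
        fs_hz=spec.fs_hz,
        zt_start_h=spec.zt_start_h,
    )
    truth = GroundTruth(
        modality="photometry",
        values={
            "event_times_s": np.sort(times),
            "event_amplitudes": amps[np.argsort(times)],
            "fs_hz": spec.fs_hz,
            "affine": (spec.affine_a, spec.affine_b),
        },
    )
    return rec, truth


def _draw_event_times(rng, n_events: int, spec: PhotometrySpec) -> np.ndarray:
    """Uniform event times with a minimum separation (rejection sampling)."""
    if n_events == 0:
        return np.empty(0)
    lo, hi = 5.0, max(5.0 + 1e-6, spec.duration_s - 5.0 * spec.decay_tau_s)
    times: list[float] = []
    for _ in range(10000):
        cand = rng.uniform(lo, hi)
        if all(abs(cand - x) >= spec.min_separation_s for x in times):
            times.append(cand)
            if len(times) == n_events:
                break
    else:
        raise RuntimeError(
            f"could not place {n_events} transients {spec.min_separation_s} s "
            f"apart in {spec.duration_s} s"
        )
    return np.asarray(times)
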