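"""Synthetic EEG/EMG telemetry with a known per-epoch vigilance state.

A true state sequence (Wake / NREM / REM) is drawn from a Markov chain at
5-s epoch resolution. Per state, the EEG is band-limited noise with
state-specific band weights — NREM delta-heavy and high amplitude, REM
theta-heavy and low amplitude, Wake broadband and low amplitude — and the
EMG is high-frequency noise whose RMS is high only in Wake. Out-of-range
artifact segments and a high-amplitude generalized tonic-clonic (GTC)
interval can be injected on top, with their sample indices recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..eeg import EPOCH_S, EegRecording
from .base import GroundTruth, object_rng

STATES = ("Wake", "NREM", "REM")

# rows/cols ordered Wake, NREM, REM
DEFAULT_TRANSITIONS = np.array(
    [
        [0.92, 0.08, 0.00],
        [0.05, 0.90, 0.05],
        [0.15, 0.00, 0.85],
    ]
)

DEFAULT_BAND_WEIGHTS = {
    "Wake": {(0.5, 4.0): 1.0, (4.0, 12.0): 1.0, (12.0, 30.0): 1.0},
    "NREM": {(0.5, 4.0): 8.0, (4.0, 30.0): 1.0},
    "REM": {(6.0, 9.0): 8.0, (0.5, 4.0): 0.5, (9.0, 30.0): 0.5},
}

DEFAULT_EEG_RMS_MV = {"Wake": 0.05, "NREM": 0.15, "REM": 0.05}
DEFAULT_EMG_RMS_MV = {"Wake": 0.08, "NREM": 0.01, "REM": 0.01}


@dataclass
class EegSpec:
    """Parameters of a synthetic EEG/EMG recording.

    ``artifacts`` is a list of (start_s, duration_s, amplitude_mV) square
    excursions written into both channels; ``gtc`` an optional
    (onset_s, duration_s, amplitude_mV) high-amplitude seizure interval.
    ``rms_jitter`` is the lognormal sigma of per-epoch RMS variation.
    """

    n_epochs: int = 720                 # 1 h at 5-s epochs
    fs_hz: float = 500.0
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_state: str = "Wake"
    band_weights: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    eeg_rms_mv: dict = field(default_factory=lambda: dict(DEFAULT_EEG_RMS_MV))
    emg_rms_mv: dict = field(default_factory=lambda: dict(DEFAULT_EMG_RMS_MV))
    emg_band_hz: tuple[float, float] = (10.0, 100.0)
    rms_jitter: float = 0.10
    artifacts: list[tuple[float, float, float]] = field(default_factory=list)
    gtc: tuple[float, float, float] | None = None
    start_zt_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        edges = [hi for w in self.band_weights.values() for (_, hi) in w]
        edges.append(self.emg_band_hz[1])
        top = max(edges)
        if self.fs_hz < 2.0 * top:
            raise ValueError(
                f"sampling rate {self.fs_hz} Hz cannot resolve the {top} Hz "
                "band edge (need >= 2x)"
            )
        if self.rms_jitter < 0:
            raise ValueError("rms_jitter must be >= 0")


def _band_noise(rng, n: int, fs: float, weights: dict, rms: float) -> np.ndarray:
    """White noise shaped in the Fourier domain by per-band gains."""
    x = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.full(f.shape, 1e-3)
    for (lo, hi), w in weights.items():
        gain[(f >= lo) & (f < hi)] = np.sqrt(w)
    y = np.fft.irfft(spec * gain, n)
    y_rms = np.sqrt(np.mean(y**2))
    return y * (rms / y_rms) if y_rms > 0 else y


def gen_eeg(spec: EegSpec) -> tuple[EegRecording, GroundTruth]:
    """Generate a recording plus true states, artifact samples and GTC bounds."""
    rng = object_rng(spec.seed, 0)
    idx = {s: i for i, s in enumerate(STATES)}

    states = [spec.initial_state]
    for _ in range(spec.n_epochs - 1):
        p = spec.transitions[idx[states[-1]]]
        states.append(STATES[rng.choice(len(STATES), p=p / p.sum())])

    n_per = int(round(EPOCH_S * spec.fs_hz))
    eeg = np.empty(spec.n_epochs * n_per)
    emg = np.empty_like(eeg)
    for e, s in enumerate(states):
        ep_rng = object_rng(spec.seed, 1, e)
        jit_eeg = np.exp(ep_rng.normal(0.0, spec.rms_jitter))
        jit_emg = np.exp(ep_rng.normal(0.0, spec.rms_jitter))
        sl = slice(e * n_per, (e + 1) * n_per)
        eeg[sl] = _band_noise(
            ep_rng, n_per, spec.fs_hz, spec.band_weights[s],
            spec.eeg_rms_mv[s] * jit_eeg,
        )
        emg[sl] = _band_noise(
            ep_rng, n_per, spec.fs_hz, {spec.emg_band_hz: 1.0},
            spec.emg_rms_mv[s] * jit_emg,
        )

    artifact_idx: list[int] = []
    for start_s, dur_s, amp in spec.artifacts:
        i0 = int(round(start_s * spec.fs_hz))
        i1 = min(len(eeg), i0 + int(round(dur_s * spec.fs_hz)))
        sign = np.where(np.arange(i1 - i0) % 2 == 0, 1.0, -1.0)
        eeg[i0:i1] = amp * sign
        emg[i0:i1] = amp * sign
        artifact_idx.extend(range(i0, i1))

    gtc_interval = None
    if spec.gtc is not None:
        onset_s, dur_s, amp = spec.gtc
        i0 = int(round(onset_s * spec.fs_hz))
        i1 = min(len(eeg), i0 + int(round(dur_s * spec.fs_hz)))
        tt = np.arange(i1 - i0) / spec.fs_hz
        eeg[i0:i1] += amp * np.sin(2 * np.pi * 6.0 * tt)
        gtc_interval = (onset_s, onset_s + dur_s)

    rec = EegRecording(
        eeg_mv=eeg, emg_mv=emg, fs_hz=spec.fs_hz, start_zt_h=spec.start_zt_h
    )
    truth = GroundTruth(
        modality="eeg",
        values={
            "states": states,
            "artifact_sample_idx": np.asarray(artifact_idx, dtype=np.int64),
            "gtc_interval_s": gtc_interval,
            "fs_hz": spec.fs_hz,
        },
    )
    return rec, truth
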