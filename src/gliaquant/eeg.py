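"""Rule-based EEG/EMG sleep staging and seizure outcome scoring.

Biopotentials are band-pass filtered (EEG 0.3–50 Hz, EMG 10–100 Hz) and
analyzed in 5-s epochs. Per epoch, band powers (Welch periodogram), EEG
amplitude (RMS) and EMG RMS drive a rule-based stager: high EMG means
Wake; delta-dominant, high-amplitude EEG with low EMG means NREM;
theta-dominant, low-amplitude EEG with low EMG means REM. Epochs with
more than 10% of samples beyond ±0.4 mV on either channel are artifacts.
Bout statistics, microwake counts, and a low/high theta ratio during
wakefulness follow from the hypnogram. Chemoconvulsant seizure outcomes
are scored on a modified Racine scale (spikes 1, myoclonic 3,
tonic-clonic 5, death 6) with 20-min censoring of event-free animals,
and compared between groups with log-rank statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt, welch

EPOCH_S = 5.0

SLEEP_BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 9.0)}
SEIZURE_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 90.0),
}

RACINE_SCORES = {"spike": 1, "myoclonic": 3, "gtc": 5, "death": 6}


@dataclass
class EegRecording:
    """Two-channel EEG/EMG recording in millivolts."""

    eeg_mv: np.ndarray
    emg_mv: np.ndarray
    fs_hz: float
    start_zt_h: float = 0.0
    schedule: str = "LD"

    def __post_init__(self) -> None:
        if len(self.eeg_mv) != len(self.emg_mv):
            raise ValueError("EEG and EMG must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def n_epochs(self) -> int:
        return int(len(self.eeg_mv) // round(EPOCH_S * self.fs_hz))


@dataclass
class EpochFeature:
    """Spectral and amplitude features of one 5-s epoch."""

    index: int
    band_power: dict[str, float]
    band_power_rel: dict[str, float | None]
    eeg_rms: float
    emg_rms: float
    artifact: bool = False
    out_fraction: float = 0.0
    psd_freqs: np.ndarray | None = None
    psd: np.ndarray | None = None


@dataclass
class Hypnogram:
    """Per-epoch vigilance states with schedule context."""

    states: list[str]
    epoch_s: float = EPOCH_S
    start_zt_h: float = 0.0

    def zt_of_epoch(self, i: int) -> float:
        return (self.start_zt_h + i * self.epoch_s / 3600.0) % 24.0


@dataclass
class SeizureEvent:
    """One annotated seizure event interval."""

    kind: str  # "spike" | "myoclonic" | "gtc" | "death"
    onset_s: float
    offset_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in RACINE_SCORES:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.offset_s is None:
            self.offset_s = self.onset_s


@dataclass
class SeizureOutcome:
    """Per-animal seizure summary on the modified Racine scale."""

    worst_score: int
    gtc_occurred: bool
    gtc_latency_s: float
    gtc_censored: bool
    total_gtc_duration_s: float
    myoclonic_count: int
    died: bool


def bandpass(
    rec: EegRecording,
    eeg_band: tuple[float, float] = (0.3, 50.0),
    emg_band: tuple[float, float] = (10.0, 100.0),
    order: int = 4,
) -> EegRecording:
    """Zero-phase band-pass filtering of both channels."""
    for name, (lo, hi) in (("EEG", eeg_band), ("EMG", emg_band)):
        if rec.fs_hz <= 2.0 * hi:
            raise ValueError(
                f"sampling rate {rec.fs_hz} Hz too low for the {name} band "
                f"({lo}-{hi} Hz); need > {2 * hi} Hz"
            )
    sos_eeg = butter(order, eeg_band, btype="bandpass", fs=rec.fs_hz, output="sos")
    sos_emg = butter(order, emg_band, btype="bandpass", fs=rec.fs_hz, output="sos")
    return EegRecording(
        eeg_mv=sosfiltfilt(sos_eeg, np.asarray(rec.eeg_mv, dtype=float)),
        emg_mv=sosfiltfilt(sos_emg, np.asarray(rec.emg_mv, dtype=float)),
        fs_hz=rec.fs_hz,
        start_zt_h=rec.start_zt_h,
        schedule=rec.schedule,
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    m = (freqs >= lo) & (freqs < hi)
    if not m.any():
        return 0.0
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return float(psd[m].sum() * df)


def epoch_features(
    rec: EegRecording,
    band_set: str = "sleep",
    keep_psd: bool = True,
) -> list[EpochFeature]:
    """Per-5-s-epoch band powers (Welch, 1-s segments, 50% overlap) and RMS."""
    bands = {"sleep": SLEEP_BANDS, "seizure": SEIZURE_BANDS}.get(band_set)
    if bands is None:
        raise ValueError(f"band_set must be 'sleep' or 'seizure', got {band_set!r}")
    n_per = int(round(EPOCH_S * rec.fs_hz))
    if n_per == 0 or len(rec.eeg_mv) < n_per:
        raise ValueError("recording shorter than one 5-s epoch")
    nperseg = int(round(rec.fs_hz))
    out: list[EpochFeature] = []
    for e in range(rec.n_epochs):
        seg = np.asarray(rec.eeg_mv[e * n_per : (e + 1) * n_per], dtype=float)
        emg = np.asarray(rec.emg_mv[e * n_per : (e + 1) * n_per], dtype=float)
        freqs, psd = welch(seg, fs=rec.fs_hz, nperseg=nperseg,
                           noverlap=nperseg // 2)
        total = _band_power(freqs, psd, (freqs[0], freqs[-1] + 1.0))
        absolute = {name: _band_power(freqs, psd, b) for name, b in bands.items()}
        relative: dict[str, float | None] = {
            name: (p / total if total > 0 else None)
            for name, p in absolute.items()
        }
        out.append(
            EpochFeature(
                index=e,
                band_power=absolute,
                band_power_rel=relative,
                eeg_rms=float(np.sqrt(np.mean(seg**2))),
                emg_rms=float(np.sqrt(np.mean(emg**2))),
                psd_freqs=freqs if keep_psd else None,
                psd=psd if keep_psd else None,
            )
        )
    return out


def flag_artifacts(
    rec: EegRecording,
    threshold_mv: float = 0.4,
    epoch_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Artifact flags per epoch: > ``epoch_fraction`` of samples out of range.

    An epoch is artifact iff the fraction of samples with |x| exceeding
    ``threshold_mv``, on either channel, is strictly greater than
    ``epoch_fraction``. Returns (flags, worst out-of-range fraction).
    """
    n_per = int(round(EPOCH_S * rec.fs_hz))
    n_ep = rec.n_epochs
    flags = np.zeros(n_ep, dtype=bool)
    fractions = np.zeros(n_ep)
    for e in range(n_ep):
        sl = slice(e * n_per, (e + 1) * n_per)
        f_eeg = float(np.mean(np.abs(rec.eeg_mv[sl]) > threshold_mv))
        f_emg = float(np.mean(np.abs(rec.emg_mv[sl]) > threshold_mv))
        fractions[e] = max(f_eeg, f_emg)
        flags[e] = fractions[e] > epoch_fraction
    return flags, fractions


@dataclass
class StageThresholds:
    """Explicit staging thresholds; None entries derived per recording.

    The EMG "high" threshold defaults to an Otsu split of the log epoch
    EMG RMS — muscle tone is bimodal (atonia during sleep vs. active
    wake) and a fixed quantile misclassifies whenever wake occupancy
    drifts from that quantile. The EEG amplitude high/low split defaults
    to the median epoch RMS. ``emg_quantile`` switches the EMG rule back
    to a plain quantile when set.
    """

    emg_high: float | None = None
    amplitude_split: float | None = None
    emg_quantile: float | None = None
    amplitude_quantile: float = 0.50


def score_hypnogram(
    features: list[EpochFeature],
    artifact_flags: np.ndarray | None = None,
    thresholds: StageThresholds | None = None,
    start_zt_h: float = 0.0,
) -> Hypnogram:
    """Stage each non-artifact epoch as Wake / NREM / REM.

    Decision rule: high EMG RMS means Wake; otherwise delta-dominant,
    high-amplitude EEG means NREM and theta-dominant, low-amplitude EEG
    means REM; unresolved epochs inherit the previous state (first epoch
    defaults to Wake).
    """
    thr = thresholds or StageThresholds()
    if artifact_flags is None:
        artifact_flags = np.zeros(len(features), dtype=bool)
    clean = [f for f, a in zip(features, artifact_flags) if not a]
    if not clean:
        warnings.warn("all epochs are artifact; empty hypnogram", stacklevel=2)
        return Hypnogram(states=["Artifact"] * len(features),
                         start_zt_h=start_zt_h)
    emg_high = thr.emg_high
    if emg_high is None:
        emg_vals = np.array([f.emg_rms for f in clean])
        if thr.emg_quantile is not None:
            emg_high = float(np.quantile(emg_vals, thr.emg_quantile))
        elif np.ptp(emg_vals) == 0:
            emg_high = float(emg_vals[0])
        else:
            from skimage.filters import threshold_otsu

            emg_high = float(
                10 ** threshold_otsu(np.log10(np.maximum(emg_vals, 1e-12)))
            )
    amp_split = thr.amplitude_split
    if amp_split is None:
        amp_split = float(
            np.quantile([f.eeg_rms for f in clean], thr.amplitude_quantile)
        )

    states: list[str] = []
    prev = "Wake"
    for f, artifact in zip(features, artifact_flags):
        if artifact:
            states.append("Artifact")
            continue
        delta = f.band_power_rel.get("delta")
        theta = f.band_power_rel.get("theta")
        if f.emg_rms > emg_high:
            state = "Wake"
        elif (
            delta is not None and theta is not None
            and delta > theta and f.eeg_rms >= amp_split
        ):
            state = "NREM"
        elif (
            delta is not None and theta is not None
            and theta > delta and f.eeg_rms < amp_split
        ):
            state = "REM"
        else:
            state = prev
        states.append(state)
        prev = state
    return Hypnogram(states=states, start_zt_h=start_zt_h)


def bouts(hypnogram: Hypnogram) -> pd.DataFrame:
    """Maximal same-state runs as (state, start_s, duration_s) rows."""
    rows = []
    states = hypnogram.states
    i = 0
    while i < len(states):
        j = i
        while j < len(states) and states[j] == states[i]:
            j += 1
        rows.append(
            {
                "state": states[i],
                "start_s": i * hypnogram.epoch_s,
                "duration_s": (j - i) * hypnogram.epoch_s,
                "start_epoch": i,
                "n_epochs": j - i,
            }
        )
        i = j
    return pd.DataFrame(rows, columns=["state", "start_s", "duration_s",
                                       "start_epoch", "n_epochs"])


def bout_statistics(
    hypnogram: Hypnogram,
    microwake_max_epochs: int = 1,
) -> dict:
    """Bout counts, mean durations and % coverage per state and phase.

    Phases: day = ZT 0–11 (light), night = ZT 12–23 (dark), plus the
    total. Microwakes — wake bouts of at most ``microwake_max_epochs``
    epochs, the shortest wake intrusions resolvable at 5-s epoching — are
    counted separately per phase. Hourly bins of bout count, mean duration
    and coverage are included under ``"hourly"``.
    """
    bt = bouts(hypnogram)
    n = len(hypnogram.states)
    zt = np.array([hypnogram.zt_of_epoch(i) for i in range(n)])
    epoch_phase = np.where(zt < 12.0, "day", "night")
    state_arr = np.asarray(hypnogram.states)

    all_states = ["Wake", "NREM", "REM", "Artifact"]
    table_rows = []
    for phase in ("day", "night", "total"):
        in_phase = np.ones(n, dtype=bool) if phase == "total" else (
            epoch_phase == phase
        )
        n_phase = int(in_phase.sum())
        if len(bt):
            start_phase = bt["start_epoch"].map(
                lambda i: "total" if phase == "total" else epoch_phase[i]
            )
            sel = bt[(start_phase == phase)] if phase != "total" else bt
        else:
            sel = bt
        for state in all_states:
            sb = sel[sel["state"] == state] if len(sel) else sel
            coverage = (
                100.0 * float((state_arr[in_phase] == state).sum()) / n_phase
                if n_phase else 0.0
            )
            table_rows.append(
                {
                    "phase": phase,
                    "state": state,
                    "bout_count": int(len(sb)),
                    "mean_bout_duration_s": (
                        float(sb["duration_s"].mean()) if len(sb) else np.nan
                    ),
                    "coverage_pct": coverage,
                }
            )
    table = pd.DataFrame(table_rows)

    wake_bouts = bt[bt["state"] == "Wake"] if len(bt) else bt
    micro = (
        wake_bouts[wake_bouts["n_epochs"] <= microwake_max_epochs]
        if len(wake_bouts)
        else wake_bouts
    )

    epochs_per_h = int(round(3600.0 / hypnogram.epoch_s))
    hourly_rows = []
    for h0 in range(0, n, epochs_per_h):
        h1 = min(n, h0 + epochs_per_h)
        hour = h0 // epochs_per_h
        if len(bt):
            hb = bt[(bt["start_epoch"] >= h0) & (bt["start_epoch"] < h1)]
        else:
            hb = bt
        for state in all_states:
            sb = hb[hb["state"] == state] if len(hb) else hb
            hourly_rows.append(
                {
                    "hour": hour,
                    "state": state,
                    "bout_count": int(len(sb)),
                    "mean_bout_duration_s": (
                        float(sb["duration_s"].mean()) if len(sb) else np.nan
                    ),
                    "coverage_pct": 100.0
                    * float((state_arr[h0:h1] == state).sum())
                    / (h1 - h0),
                }
            )
    return {
        "table": table,
        "bouts": bt,
        "microwake_count": int(len(micro)),
        "hourly": pd.DataFrame(hourly_rows),
    }


def wake_theta_ratio(
    features: list[EpochFeature],
    hypnogram: Hypnogram,
    low_band: tuple[float, float] = (5.0, 7.0),
    high_band: tuple[float, float] = (7.0, 9.0),
) -> float | None:
    """Low-theta / high-theta power ratio over Wake epochs.

    The prevalence of low theta (5–7 Hz) relative to high theta (7–9 Hz)
    during wakefulness tracks sleep propensity. Returns None (with a
    warning) when no Wake epoch exists or high-theta power is zero.
    """
    wake = [
        f for f, s in zip(features, hypnogram.states) if s == "Wake"
        and f.psd is not None
    ]
    if not wake:
        warnings.warn("no Wake epochs with spectra; theta ratio undefined",
                      stacklevel=2)
        return None
    low = float(np.mean([_band_power(f.psd_freqs, f.psd, low_band) for f in wake]))
    high = float(np.mean([_band_power(f.psd_freqs, f.psd, high_band) for f in wake]))
    if high == 0:
        warnings.warn("zero high-theta power; theta ratio undefined", stacklevel=2)
        return None
    return low / high


def seizure_summary(
    events: list[SeizureEvent],
    observation_s: float = 1200.0,
) -> SeizureOutcome:
    """Per-animal Racine summary with censoring at the observation window.

    Event-free animals get worst score 0 and a censored latency equal to
    the 20-min observation window. Events beyond the window are clipped
    with a warning.
    """
    clipped: list[SeizureEvent] = []
    for ev in events:
        if ev.onset_s >= observation_s:
            warnings.warn(
                f"{ev.kind} event at {ev.onset_s} s is beyond the "
                f"{observation_s} s observation window; dropped",
                stacklevel=2,
            )
            continue
        off = min(float(ev.offset_s), observation_s)
        if off < ev.offset_s:
            warnings.warn(
                f"{ev.kind} event clipped at the observation window",
                stacklevel=2,
            )
        clipped.append(SeizureEvent(kind=ev.kind, onset_s=ev.onset_s, offset_s=off))

    worst = max((RACINE_SCORES[e.kind] for e in clipped), default=0)
    gtc = sorted((e for e in clipped if e.kind == "gtc"), key=lambda e: e.onset_s)
    died = any(e.kind == "death" for e in clipped)
    return SeizureOutcome(
        worst_score=worst,
        gtc_occurred=bool(gtc),
        gtc_latency_s=float(gtc[0].onset_s) if gtc else float(observation_s),
        gtc_censored=not gtc,
        total_gtc_duration_s=float(
            sum(e.offset_s - e.onset_s for e in gtc)
        ),
        myoclonic_count=sum(1 for e in clipped if e.kind == "myoclonic"),
        died=died,
    )


def group_incidence(
    outcomes: dict[str, list[SeizureOutcome]],
    event: str = "gtc",
    observation_s: float = 1200.0,
) -> dict:
    """Cumulative incidence curves per group plus a two-group log-rank test.

    ``event="gtc"`` uses GTC latency (censored at the observation window);
    ``event="death"`` builds mortality curves with death times approximated
    by GTC latency for animals that died and censoring otherwise. With a
    single group only curves are returned.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if not outcomes or any(len(v) == 0 for v in outcomes.values()):
        raise ValueError("every group needs at least one animal")

    durations: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    curves: dict[str, pd.DataFrame] = {}
    for g, outs in outcomes.items():
        if event == "gtc":
            d = np.array([o.gtc_latency_s for o in outs])
            e = np.array([o.gtc_occurred for o in outs], dtype=bool)
        elif event == "death":
            d = np.array(
                [o.gtc_latency_s if o.died else observation_s for o in outs]
            )
            e = np.array([o.died for o in outs], dtype=bool)
        else:
            raise ValueError(f"event must be 'gtc' or 'death', got {event!r}")
        durations[g], observed[g] = d, e
        km = KaplanMeierFitter()
        km.fit(d, event_observed=e)
        sf = km.survival_function_
        curves[g] = pd.DataFrame(
            {
                "time_s": sf.index.to_numpy(dtype=float),
                "incidence_pct": 100.0 * (1.0 - sf.iloc[:, 0].to_numpy()),
            }
        )

    result: dict = {"curves": curves}
    if len(outcomes) == 2:
        (g1, g2) = list(outcomes)
        lr = logrank_test(
            durations[g1], durations[g2],
            event_observed_A=observed[g1], event_observed_B=observed[g2],
        )
        result["logrank_statistic"] = float(lr.test_statistic)
        result["logrank_p"] = float(lr.p_value)
    return result


def detect_gtc_intervals(
    rec: EegRecording,
    rms_factor: float = 5.0,
    min_duration_s: float = 10.0,
) -> list[tuple[float, float]]:
    """Simple amplitude-based GTC detector (annotations are authoritative).

    Epochs whose EEG RMS exceeds ``rms_factor`` times the recording median
    epoch RMS, sustained for at least ``min_duration_s``, are returned as
    (onset_s, offset_s) intervals.
    """
    n_per = int(round(EPOCH_S * rec.fs_hz))
    rms = np.array(
        [
            np.sqrt(np.mean(np.asarray(
                rec.eeg_mv[e * n_per : (e + 1) * n_per], dtype=float) ** 2))
            for e in range(rec.n_epochs)
        ]
    )
    if rms.size == 0:
        return []
    hot = rms > rms_factor * np.median(rms)
    need = max(1, int(np.ceil(min_duration_s / EPOCH_S)))
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j < len(hot) and hot[j]:
                j += 1
            if j - i >= need:
                intervals.append((i * EPOCH_S, j * EPOCH_S))
            i = j
        else:
            i += 1
    return intervals
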