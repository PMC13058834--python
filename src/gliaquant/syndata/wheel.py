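"""Synthetic minute-binned wheel-running series with a known period.

Activity is confined to the (subjective) night of a rhythm with the stated
true period: under a 12:12 light/dark schedule the animal is entrained and
runs during the dark phase of the 24-h cycle; in constant darkness it runs
during the subjective night of its free-running period. Counts are Poisson
around a smooth raised-cosine nightly profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..circadian import WheelActivitySeries
from .base import GroundTruth, object_rng


@dataclass
class WheelSpec:
    """Parameters of a synthetic wheel-running acquisition.

    ``amplitude`` is the peak Poisson mean (rotations/min) of the nightly
    profile. Under ``schedule="LD"`` the effective period is 24.0 h
    (entrainment); ``period_h`` governs only the ``"DD"`` free-running case.
    """

    days: int = 14
    period_h: float = 24.0
    schedule: str = "LD"            # "LD" (12:12, lights-on at t=0) or "DD"
    amplitude: float = 30.0
    night_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be > 0")
        if self.schedule not in ("LD", "DD"):
            raise ValueError(f"schedule must be 'LD' or 'DD', got {self.schedule!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.night_fraction < 1:
            raise ValueError("night_fraction must be in (0, 1)")


def gen_wheel_activity(spec: WheelSpec) -> tuple[WheelActivitySeries, GroundTruth]:
    """Generate one count per minute for ``days`` days plus the true period."""
    n = spec.days * 1440
    t_h = (np.arange(n) + 0.5) / 60.0  # bin centers, hours since lights-on

    true_period = 24.0 if spec.schedule == "LD" else spec.period_h
    phase = (t_h % true_period) / true_period  # 0 = (subjective) lights-on
    night = phase >= (1.0 - spec.night_fraction)
    s = np.zeros(n)
    s[night] = (phase[night] - (1.0 - spec.night_fraction)) / spec.night_fraction
    lam = np.where(night, spec.amplitude * np.sin(np.pi * s) ** 2, 0.0)

    rng = object_rng(spec.seed, 0)
    counts = rng.poisson(lam) if spec.amplitude > 0 else np.zeros(n, dtype=np.int64)

    series = WheelActivitySeries(
        counts=counts.astype(np.int64),
        schedule=spec.schedule,
        days=spec.days,
    )
    truth = GroundTruth(
        modality="wheel",
        values={"period_h": true_period, "peak_rate_per_min": spec.amplitude},
    )
    return series, truth
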