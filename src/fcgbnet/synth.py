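"""Synthetic multichannel recordings with implanted connectivity-drop events.

The generator emulates the geometry of a 19-channel, 300 Hz dry-electrode
recording.  Every channel is a mixture of one shared band-limited source s
and an independent band-limited noise eta_i,

    c_i(t) = a(t) * s(t) + sqrt(1 - a(t)^2) * eta_i(t),

with all carriers filtered to the analysis band (18.75-37.5 Hz by default)
and normalized to unit variance, so a(t)^2 is the shared-variance fraction
and the expected pairwise correlation between channels.  At baseline
a^2 = coupling_base; inside each event window the coupling ramps down
(1 s cosine ramps) to coupling_drop, producing a transient global
decorrelation — the mechanism behind the entropy valleys that follow
fatigue-related events.  Implanted event centers are returned as an
objective-source event table, making every downstream stage testable with
exact ground truth.

An optional ``artifact_times_s`` list injects short high-amplitude bursts
to exercise the artifact-thresholding stage; bursts are additive and do not
alter the coupling schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, EventTable, TEN_TWENTY_19

__all__ = ["SynthSpec", "generate", "default_event_times"]


def default_event_times(duration_s: float, n_events: int = 6) -> List[float]:
    """Evenly spread event centers with margins at both ends."""
    return list(np.linspace(duration_s / (n_events + 1),
                            n_events * duration_s / (n_events + 1),
                            n_events).round(1))


@dataclass
class SynthSpec:
    """Parameters of the synthetic recording.

    ``coupling_base``/``coupling_drop`` are shared-variance fractions at
    baseline and inside events; ``noise_sd`` scales the overall amplitude
    (arbitrary microvolt-like units).
    """

    n_channels: int = 19
    fs: float = 300.0
    duration_s: float = 600.0
    event_times_s: Optional[List[float]] = None
    event_duration_s: float = 8.0
    coupling_base: float = 0.7
    coupling_drop: float = 0.1
    noise_sd: float = 1.0
    carrier_band_hz: Tuple[float, float] = (18.75, 37.5)
    ramp_s: float = 1.0
    artifact_times_s: List[float] = field(default_factory=list)
    artifact_amp: float = 20.0
    artifact_duration_s: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.event_times_s is None:
            self.event_times_s = default_event_times(self.duration_s)
        if not (0 < self.coupling_base <= 1):
            raise ValueError("coupling_base must lie in (0, 1]")
        if not (0 <= self.coupling_drop < self.coupling_base):
            raise ValueError("require 0 <= coupling_drop < coupling_base")
        margin = self.event_duration_s / 2 + self.ramp_s
        times = sorted(self.event_times_s)
        for t in times:
            if t - margin < 0 or t + margin > self.duration_s:
                raise ValueError(f"event at {t} s falls outside the recording")
        span = self.event_duration_s + 2 * self.ramp_s
        for t0, t1 in zip(times, times[1:]):
            if t1 - t0 < span:
                raise ValueError(f"events at {t0} s and {t1} s overlap")

    def to_dict(self) -> dict:
        return asdict(self)


def _bandlimited_noise(rng, n, fs, band, sos) -> np.ndarray:
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _coupling_profile(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    """Mixing amplitude a(t): sqrt(coupling) with cosine ramps at event edges."""
    a_hi = np.sqrt(spec.coupling_base)
    a_lo = np.sqrt(spec.coupling_drop)
    a = np.full(t.size, a_hi)
    half = spec.event_duration_s / 2.0
    r = spec.ramp_s
    for c in spec.event_times_s:
        lo, hi = c - half, c + half
        inside = (t >= lo) & (t <= hi)
        a[inside] = a_lo
        down = (t >= lo - r) & (t < lo)
        frac = (t[down] - (lo - r)) / r  # 0 -> 1 across the ramp
        a[down] = a_hi + (a_lo - a_hi) * 0.5 * (1 - np.cos(np.pi * frac))
        up = (t > hi) & (t <= hi + r)
        frac = (t[up] - hi) / r
        a[up] = a_lo + (a_hi - a_lo) * 0.5 * (1 - np.cos(np.pi * frac))
    return a


def generate(spec: SynthSpec) -> Tuple[EEGRecording, EventTable]:
    """Generate a recording and its ground-truth event table.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    sos = sps.butter(4, spec.carrier_band_hz, btype="bandpass", fs=spec.fs,
                     output="sos")
    shared = _bandlimited_noise(rng, n, spec.fs, spec.carrier_band_hz, sos)
    a = _coupling_profile(spec, t)
    b = np.sqrt(1.0 - a**2)
    data = np.empty((spec.n_channels, n))
    for i in range(spec.n_channels):
        eta = _bandlimited_noise(rng, n, spec.fs, spec.carrier_band_hz, sos)
        data[i] = spec.noise_sd * (a * shared + b * eta)

    for t_art in spec.artifact_times_s:
        i0 = int(round((t_art - spec.artifact_duration_s / 2) * spec.fs))
        i1 = i0 + int(round(spec.artifact_duration_s * spec.fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        burst = sps.windows.hann(i1 - i0) * spec.artifact_amp * spec.noise_sd
        data[:, i0:i1] += burst * rng.standard_normal((spec.n_channels, 1))

    if spec.n_channels == 19:
        labels = list(TEN_TWENTY_19)
    else:
        labels = [f"ch{i}" for i in range(spec.n_channels)]
    rec = EEGRecording(data=data, fs=spec.fs, channels=labels)
    events = EventTable.from_records(
        [(c, "coupling_drop", "objective") for c in spec.event_times_s]
    )
    return rec, events
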