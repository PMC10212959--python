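"""Sound pressure level extraction from cough recordings.

Turns a raw voltage-sampled cough recording into a per-participant session
sound pressure level (SPL): band-pass filter, 5-s peak-segment extraction,
sample-wise SPL trace, per-trial maximum, session maximum over trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "MicrophoneModel",
    "Waveform",
    "SplResult",
    "bandpass_filter",
    "extract_peak_segment",
    "spl_trace",
    "trial_max_spl",
    "session_spl",
]

#: minimum number of acceptable trials per session
MIN_TRIALS = 3


@dataclass(frozen=True)
class MicrophoneModel:
    """Microphone calibration: sensitivity ``S`` (dB re 1 V/Pa) and the
    reference pressure ``P0`` (Pa, default 20 uPa)."""

    sensitivity_db: float = -35.0
    reference_pressure: float = 20e-6

    def __post_init__(self) -> None:
        if self.reference_pressure <= 0:
            raise ValueError("reference_pressure must be > 0")

    @property
    def voltage_per_pa(self) -> float:
        """Vs = 10^(S/20), microphone output in volts per pascal."""
        return 10.0 ** (self.sensitivity_db / 20.0)

    def pressure_to_voltage(self, pressure_pa: np.ndarray) -> np.ndarray:
        return np.asarray(pressure_pa, dtype=float) * self.voltage_per_pa

    def voltage_to_pressure(self, voltage_v: np.ndarray) -> np.ndarray:
        return np.asarray(voltage_v, dtype=float) / self.voltage_per_pa


@dataclass(frozen=True)
class Waveform:
    """A voltage-sampled recording of one cough trial."""

    samples: np.ndarray
    fs: float
    participant_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.size == 0:
            raise ValueError("waveform must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class SplResult:
    """Per-trial maxima (dB), the session SPL (their max), and the sample
    bounds of the analysed segment in each trial."""

    per_trial_max_db: tuple[float, ...]
    session_spl_db: float
    segment_bounds: tuple[tuple[int, int], ...] = field(default=())


def bandpass_filter(
    w: Waveform,
    low: float = 140.0,
    high: float = 2000.0,
    order: int = 4,
) -> Waveform:
    """Zero-phase Butterworth band-pass (forward-backward, ``order`` per pass).

    The default 140-2000 Hz band removes heart-sound and muscle artifacts
    while passing the cough burst.
    """
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    nyq = w.fs / 2.0
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz >= Nyquist {nyq} Hz; resample the input "
            "or lower the cutoff"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=w.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, w.samples)
    return replace(w, samples=filtered)


def extract_peak_segment(w: Waveform, duration: float = 5.0) -> Waveform:
    """Contiguous ``duration``-second segment containing the global maximum
    of ``|samples|``, centered on it and shifted to stay inside the recording.

    Ties break to the earliest maximum. Raises if the recording is shorter
    than ``duration``.
    """
    n_seg = int(round(duration * w.fs))
    n = w.samples.size
    if n < n_seg:
        raise ValueError(
            f"recording ({n / w.fs:.2f} s) shorter than segment duration "
            f"({duration} s)"
        )
    peak = int(np.argmax(np.abs(w.samples)))  # argmax -> earliest on ties
    start = peak - n_seg // 2
    start = max(0, min(start, n - n_seg))
    return replace(w, samples=w.samples[start : start + n_seg])


def _segment_bounds(w: Waveform, duration: float) -> tuple[int, int]:
    n_seg = int(round(duration * w.fs))
    peak = int(np.argmax(np.abs(w.samples)))
    start = max(0, min(peak - n_seg // 2, w.samples.size - n_seg))
    return start, start + n_seg


def spl_trace(w: Waveform, mic: MicrophoneModel) -> np.ndarray:
    """Sample-wise sound pressure level Lp(t) = 20 log10(|Vr(t)| / (P0 Vs)).

    The rectified magnitude is used so that negative half-cycles carry the
    same level as positive ones; zero samples map to -inf (excluded from
    any subsequent maximum).
    """
    ref = mic.reference_pressure * mic.voltage_per_pa
    mag = np.abs(w.samples)
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(mag / ref)


def trial_max_spl(trace: np.ndarray) -> float:
    """Maximum finite value of an SPL trace; errors on a silent trial."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty SPL trace")
    finite = trace[np.isfinite(trace)]
    if finite.size == 0:
        raise ValueError("silent trial: no finite SPL values")
    return float(finite.max())


def session_spl(
    trials: list[Waveform],
    mic: MicrophoneModel,
    low: float = 140.0,
    high: float = 2000.0,
    order: int = 4,
    segment_duration: float = 5.0,
) -> SplResult:
    """Session SPL from >= 3 acceptable trials.

    Per trial: band-pass -> peak-segment -> SPL trace -> trial maximum; the
    session SPL is the maximum across trials.
    """
    if len(trials) < MIN_TRIALS:
        raise ValueError(
            f"session requires at least {MIN_TRIALS} acceptable trials, "
            f"got {len(trials)}"
        )
    maxima: list[float] = []
    bounds: list[tuple[int, int]] = []
    for trial in trials:
        filtered = bandpass_filter(trial, low=low, high=high, order=order)
        bounds.append(_segment_bounds(filtered, segment_duration))
        segment = extract_peak_segment(filtered, duration=segment_duration)
        maxima.append(trial_max_spl(spl_trace(segment, mic)))
    return SplResult(
        per_trial_max_db=tuple(maxima),
        session_spl_db=float(max(maxima)),
        segment_bounds=tuple(bounds),
    )
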