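"""Causal preprocessing cascade for the speller's EMG channels.

The chain mirrors the real-time system: sequential second-order IIR notch
filters at 50 and 60 Hz (Q = 30) against mains interference, a fourth-order
Butterworth bandpass (20–90 Hz) retaining the dominant surface-EMG spectrum,
full-wave rectification, then a 1.0 s sliding analysis window advanced every
5 ms.  All filters run forward-only (causal); zero-phase filtering would be
non-causal and is deliberately not used.  Filter state can persist across
streamed chunks so chunked and whole-recording processing agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigError
from .synthetic import EmgRecording


@dataclass(frozen=True)
class PipelineConfig:
    notch_freqs: tuple[float, ...] = (50.0, 60.0)
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (20.0, 90.0)
    bandpass_order: int = 4
    window_length: float = 1.0  # seconds
    window_step: float = 0.005  # seconds
    sample_rate: float = 200.0

    def __post_init__(self):
        nyq = self.sample_rate / 2.0
        if not 0 < self.bandpass[0] < self.bandpass[1] < nyq:
            raise ConfigError(
                f"bandpass {self.bandpass} must satisfy 0 < low < high < {nyq} Hz"
            )
        if any(f >= nyq for f in self.notch_freqs):
            raise ConfigError("notch frequency at or above Nyquist")
        if self.notch_q <= 0:
            raise ConfigError("notch_q must be > 0")
        if self.window_step > self.window_length:
            raise ConfigError("window_step must not exceed window_length")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length * self.sample_rate))

    @property
    def step_samples(self) -> int:
        return max(int(round(self.window_step * self.sample_rate)), 1)


@dataclass(frozen=True)
class EmgWindow:
    """One analysis window of (rectified) samples for a single channel."""

    channel: str
    samples: np.ndarray
    start_time: float  # seconds

    @property
    def n(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


def _notch_ba(freq: float, q: float, fs: float):
    return signal.iirnotch(freq, q, fs=fs)


def apply_notch(rec: EmgRecording, freq: float, q: float = 30.0) -> EmgRecording:
    """Causal second-order notch at ``freq`` Hz with quality factor ``q``."""
    if freq >= rec.sample_rate / 2:
        raise ConfigError(f"notch frequency {freq} Hz >= Nyquist")
    b, a = _notch_ba(freq, q, rec.sample_rate)
    return rec.with_samples(signal.lfilter(b, a, rec.samples, axis=1))


def apply_bandpass(rec: EmgRecording, cfg: PipelineConfig | None = None) -> EmgRecording:
    """Causal Butterworth bandpass (default 4th order, 20–90 Hz)."""
    cfg = cfg or PipelineConfig(sample_rate=rec.sample_rate)
    if cfg.sample_rate != rec.sample_rate:
        raise ConfigError("config sample_rate does not match recording")
    sos = signal.butter(
        cfg.bandpass_order, cfg.bandpass, btype="bandpass",
        fs=rec.sample_rate, output="sos",
    )
    return rec.with_samples(signal.sosfilt(sos, rec.samples, axis=1))


def rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification: the absolute-valued envelope. Idempotent."""
    return rec.with_samples(np.abs(rec.samples))


class FilterCascade:
    """Stateful notch→notch→bandpass→rectify chain for streamed chunks.

    Internal IIR state persists between ``process`` calls, so feeding a
    recording in arbitrary chunk sizes reproduces the whole-recording result
    bit for bit.
    """

    def __init__(self, cfg: PipelineConfig, n_channels: int):
        self.cfg = cfg
        self._stages: list[tuple] = []
        for f in cfg.notch_freqs:
            b, a = _notch_ba(f, cfg.notch_q, cfg.sample_rate)
            zi = np.zeros((n_channels, max(len(a), len(b)) - 1))
            self._stages.append(("ba", b, a, zi))
        sos = signal.butter(
            cfg.bandpass_order, cfg.bandpass, btype="bandpass",
            fs=cfg.sample_rate, output="sos",
        )
        zi = np.zeros((sos.shape[0], n_channels, 2))
        self._stages.append(("sos", sos, None, zi))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        """Filter + rectify one (n_channels, n_samples) chunk."""
        y = np.asarray(chunk, dtype=float)
        for i, stage in enumerate(self._stages):
            kind, p1, p2, zi = stage
            if kind == "ba":
                y, zf = signal.lfilter(p1, p2, y, axis=1, zi=zi)
            else:
                y, zf = signal.sosfilt(p1, y, axis=1, zi=zi)
            self._stages[i] = (kind, p1, p2, zf)
        return np.abs(y)


def preprocess(rec: EmgRecording, cfg: PipelineConfig | None = None) -> EmgRecording:
    """Run the full causal cascade over a recording (zero initial state)."""
    cfg = cfg or PipelineConfig(sample_rate=rec.sample_rate)
    if cfg.sample_rate != rec.sample_rate:
        raise ConfigError("config sample_rate does not match recording")
    cascade = FilterCascade(cfg, len(rec.channels))
    return rec.with_samples(cascade.process(rec.samples))


def window_count(n_samples: int, cfg: PipelineConfig) -> int:
    n, step = cfg.window_samples, cfg.step_samples
    if n_samples < n:
        raise ConfigError(
            f"recording of {n_samples} samples shorter than one "
            f"{n}-sample analysis window"
        )
    return (n_samples - n) // step + 1


def window_starts(n_samples: int, cfg: PipelineConfig) -> np.ndarray:
    """Start sample index of each window (half-open ranges, 0-based)."""
    return np.arange(window_count(n_samples, cfg)) * cfg.step_samples


def sliding_windows(rec: EmgRecording, cfg: PipelineConfig) -> dict[str, list[EmgWindow]]:
    """Time-aligned sliding windows, per channel.

    Window ``k`` covers sample range ``[k*step, k*step + N)``; windows are
    identical in position across channels so simultaneity (the SELECT
    condition) is well defined.
    """
    starts = window_starts(rec.n_samples, cfg)
    n = cfg.window_samples
    out: dict[str, list[EmgWindow]] = {}
    for ci, ch in enumerate(rec.channels):
        row = rec.samples[ci]
        out[ch] = [
            EmgWindow(ch, row[s:s + n], rec.t0 + s / rec.sample_rate)
            for s in starts
        ]
    return out
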