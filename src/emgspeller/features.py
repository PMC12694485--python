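"""Time-domain features per analysis window: RMS, slope sign change, peak.

RMS = sqrt((1/N) * sum x_i^2) measures the energy of the window; SSC counts
slope reversals whose product of adjacent differences exceeds a threshold
(suppressing reversals caused by noise micro-fluctuations); peak is the
maximum of the rectified samples, capturing transient high-intensity
contraction.  The product in the SSC condition is on an amplitude-squared
scale, so the SSC threshold lives on that scale too; by default it is
auto-set to the squared baseline-noise RMS during calibration.

Features are computed on the rectified envelope, after the filter cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dsp import EmgWindow, PipelineConfig, window_starts
from .errors import ConfigError
from .synthetic import EmgRecording


@dataclass(frozen=True)
class FeatureConfig:
    #: SSC comparison threshold, on the (microvolt)^2 scale of the
    #: adjacent-difference product. None -> auto-set from the baseline noise.
    ssc_threshold: float | None = None

    def __post_init__(self):
        if self.ssc_threshold is not None and self.ssc_threshold < 0:
            raise ConfigError("ssc_threshold must be >= 0")


@dataclass(frozen=True)
class FeatureFrame:
    """Per-window, per-channel feature triple, time-aligned across channels."""

    start_time: float  # seconds, window start
    end_time: float  # seconds, window end (feature available at this time)
    channels: tuple[str, ...]
    rms: np.ndarray  # (n_channels,), microvolts
    ssc: np.ndarray  # (n_channels,), counts
    peak: np.ndarray  # (n_channels,), microvolts


def _samples(w) -> np.ndarray:
    x = w.samples if isinstance(w, EmgWindow) else np.asarray(w, dtype=float)
    return np.asarray(x, dtype=float)


def rms(w: EmgWindow | np.ndarray) -> float:
    x = _samples(w)
    if x.size == 0:
        raise ConfigError("rms of empty window")
    return float(np.sqrt(np.mean(x**2)))


def ssc(w: EmgWindow | np.ndarray, cfg: FeatureConfig | float = 0.0) -> int:
    """Count of interior samples i with (x_i - x_{i-1})(x_i - x_{i+1}) > threshold."""
    x = _samples(w)
    if x.size < 3:
        raise ConfigError("ssc needs at least 3 samples")
    thr = cfg.ssc_threshold if isinstance(cfg, FeatureConfig) else float(cfg)
    if thr is None:
        thr = 0.0
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(prod > thr))


def peak(w: EmgWindow | np.ndarray) -> float:
    x = _samples(w)
    if x.size == 0:
        raise ConfigError("peak of empty window")
    return float(np.max(x))


def extract_features(
    rec: EmgRecording,
    pcfg: PipelineConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> list[FeatureFrame]:
    """One FeatureFrame per sliding-window position of a (rectified) recording.

    Vectorized over windows but numerically identical (to fp round-off) to
    computing :func:`rms`, :func:`ssc`, :func:`peak` window by window.
    """
    pcfg = pcfg or PipelineConfig(sample_rate=rec.sample_rate)
    fcfg = fcfg or FeatureConfig(ssc_threshold=0.0)
    thr = fcfg.ssc_threshold if fcfg.ssc_threshold is not None else 0.0
    n = pcfg.window_samples
    step = pcfg.step_samples
    starts = window_starts(rec.n_samples, pcfg)

    x = rec.samples  # (n_ch, L)
    sw = sliding_window_view(x, n, axis=1)[:, ::step, :]  # (n_ch, n_win, N)
    rms_all = np.sqrt(np.mean(sw**2, axis=2))
    peak_all = np.max(sw, axis=2)

    prod = (x[:, 1:-1] - x[:, :-2]) * (x[:, 1:-1] - x[:, 2:])  # (n_ch, L-2)
    hits = (prod > thr).astype(np.int64)
    # interior points of window [s, s+N) are product indices [s, s+N-2)
    swh = sliding_window_view(hits, n - 2, axis=1)[:, ::step, :]
    ssc_all = swh.sum(axis=2)

    frames = []
    for k, s in enumerate(starts):
        t = rec.t0 + s / rec.sample_rate
        frames.append(
            FeatureFrame(
                start_time=t,
                end_time=t + pcfg.window_length,
                channels=rec.channels,
                rms=rms_all[:, k].copy(),
                ssc=ssc_all[:, k].copy(),
                peak=peak_all[:, k].copy(),
            )
        )
    return frames


def write_features(frames: list[FeatureFrame], path: str | Path) -> None:
    """Export frames as delimited text (for inspection or plotting)."""
    if not frames:
        raise ConfigError("no frames to write")
    chs = frames[0].channels
    cols = [f"{kind}_{ch}" for kind in ("rms", "ssc", "peak") for ch in chs]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("start_time," + ",".join(cols) + "\n")
        for fr in frames:
            vals = np.concatenate([fr.rms, fr.ssc, fr.peak])
            fh.write(f"{fr.start_time:.6f}," + ",".join(f"{v:.6g}" for v in vals) + "\n")
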