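"""Threshold-based command decoding from feature frames.

The decoder is calibration-then-threshold, with no learned model: the first
2 s of a session (guaranteed rest) give per-channel baseline RMS and peak
levels; thereafter a channel counts as active in a frame only when its RMS
exceeds a multiple of baseline, its SSC count clears a floor, and its peak
exceeds a multiple of the baseline peak — all three simultaneously.  Runs of
active frames become commands: a single-channel run maps through the channel
→ command table (1→UP, 2→DOWN, 3→LEFT, 4→RIGHT), a co-contraction of two or
more channels sustained beyond the hold time (0.3 s) is SELECT, and a
refractory period suppresses double-fires from one contraction.

Frames are timestamped at the window *end* — the moment the feature becomes
available to a causal system — so event onsets line up with contraction
onsets rather than leading them by a window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsp import PipelineConfig, preprocess
from .errors import CalibrationError, ConfigError
from .events import COMMANDS, CommandEvent
from .features import FeatureConfig, FeatureFrame, extract_features
from .synthetic import EmgRecording

DEFAULT_COMMAND_MAP: dict[int, str] = {0: "UP", 1: "DOWN", 2: "LEFT", 3: "RIGHT"}


@dataclass(frozen=True)
class ClassifierConfig:
    rms_gain: float = 2.0          # active needs rms > rms_gain * baseline_rms
    ssc_min: int = 10              # ... and ssc >= ssc_min
    peak_gain: float = 3.0         # ... and peak > peak_gain * baseline_peak
    select_hold: float = 0.3       # s of sustained co-contraction for SELECT
    refractory: float = 0.5        # s after an event during which runs are ignored
    min_command_duration: float = 0.1  # debounce for single-channel runs
    baseline_span: tuple[float, float] = (0.0, 2.0)  # s, quiet calibration period
    command_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_COMMAND_MAP)
    )

    def __post_init__(self):
        if self.select_hold <= 0:
            raise ConfigError("select_hold must be > 0")
        if self.rms_gain <= 1 or self.peak_gain <= 1:
            raise ConfigError("rms_gain and peak_gain must exceed 1")
        if any(cmd not in COMMANDS for cmd in self.command_map.values()):
            raise ConfigError("command_map contains an unknown command")


@dataclass(frozen=True)
class BaselineProfile:
    channels: tuple[str, ...]
    baseline_rms: np.ndarray   # (n_channels,), microvolts
    baseline_peak: np.ndarray  # (n_channels,), microvolts


def calibrate(
    frames: list[FeatureFrame], cfg: ClassifierConfig | None = None
) -> BaselineProfile:
    """Average per-channel RMS and peak over windows inside the baseline span."""
    cfg = cfg or ClassifierConfig()
    t0, t1 = cfg.baseline_span
    sel = [f for f in frames if f.start_time >= t0 and f.end_time <= t1]
    if not sel:
        raise CalibrationError(
            f"no complete analysis windows inside baseline span {cfg.baseline_span}"
        )
    base_rms = np.mean([f.rms for f in sel], axis=0)
    base_peak = np.mean([f.peak for f in sel], axis=0)
    if np.any(base_rms <= 0):
        raise CalibrationError(
            "degenerate all-zero baseline: activation thresholds undefined"
        )
    return BaselineProfile(sel[0].channels, base_rms, base_peak)


def detect_activation(
    frame: FeatureFrame, base: BaselineProfile, cfg: ClassifierConfig
) -> np.ndarray:
    """Per-channel boolean: all three feature gates passed simultaneously."""
    return (
        (frame.rms > cfg.rms_gain * base.baseline_rms)
        & (frame.ssc >= cfg.ssc_min)
        & (frame.peak > cfg.peak_gain * base.baseline_peak)
    )


def _consecutive_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i0, i1] (inclusive) index runs where mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def segment_commands(
    times: np.ndarray,
    active: np.ndarray,
    cfg: ClassifierConfig | None = None,
) -> list[CommandEvent]:
    """Turn a per-frame activation timeline into discrete command events.

    ``times``: frame timestamps (s), uniformly spaced; ``active``: boolean
    array of shape (n_frames, n_channels).

    Per maximal run of frames with any activation, at most one event:

    * a stretch of >=2 simultaneously active channels sustained longer than
      ``select_hold`` -> SELECT;
    * a run where exactly one channel is ever active, lasting at least
      ``min_command_duration`` -> that channel's mapped command;
    * a short co-activation that ends with one channel persisting alone is
      re-timed from the moment it became solo and judged as a single-channel
      run; any other short co-activation emits nothing (indeterminate).

    A run starting within ``refractory`` seconds of the previous event's
    offset is suppressed.
    """
    cfg = cfg or ClassifierConfig()
    times = np.asarray(times, dtype=float)
    active = np.asarray(active, dtype=bool)
    if active.ndim != 2 or len(times) != active.shape[0]:
        raise ConfigError("times and activation matrix disagree in length")
    if len(times) < 2:
        return []
    step = float(np.median(np.diff(times)))

    events: list[CommandEvent] = []
    last_offset = -np.inf
    for i0, i1 in _consecutive_runs(active.any(axis=1)):
        if times[i0] - last_offset < cfg.refractory:
            continue
        counts = active[i0:i1 + 1].sum(axis=1)
        multi_runs = _consecutive_runs(counts >= 2)
        ev: CommandEvent | None = None

        best = max(
            ((j1 - j0 + 1) * step, j0, j1) for j0, j1 in multi_runs
        ) if multi_runs else None
        if best is not None and best[0] > cfg.select_hold:
            _, j0, j1 = best
            ev = CommandEvent("SELECT", times[i0 + j0], times[i0 + j1] + step)
        else:
            seg0 = i0
            if multi_runs:
                # co-activation too short for SELECT: consider only the solo
                # tail after the last multi frame, re-timed from solo onset
                last_multi = i0 + multi_runs[-1][1]
                if last_multi == i1:
                    seg0 = None
                else:
                    seg0 = last_multi + 1
            if seg0 is not None:
                seg = active[seg0:i1 + 1]
                chans = np.flatnonzero(seg.any(axis=0))
                dur = (i1 - seg0 + 1) * step
                if len(chans) == 1 and dur >= cfg.min_command_duration:
                    cmd = cfg.command_map.get(int(chans[0]))
                    if cmd is not None:
                        ev = CommandEvent(cmd, times[seg0], times[i1] + step)
        if ev is not None:
            events.append(ev)
            last_offset = ev.offset
    return events


@dataclass(frozen=True)
class DecodeResult:
    events: list[CommandEvent]
    baseline: BaselineProfile
    frames: list[FeatureFrame]
    ssc_threshold: float


def decode_recording(
    rec: EmgRecording,
    pcfg: PipelineConfig | None = None,
    fcfg: FeatureConfig | None = None,
    ccfg: ClassifierConfig | None = None,
) -> DecodeResult:
    """Full pipeline: filter cascade → features → calibration → events.

    When the SSC threshold is left unset it is auto-calibrated to the squared
    baseline RMS (averaged over channels) of the rectified, filtered signal
    during the quiet lead-in, tying it to the noise floor.
    """
    pcfg = pcfg or PipelineConfig(sample_rate=rec.sample_rate)
    ccfg = ccfg or ClassifierConfig()
    fcfg = fcfg or FeatureConfig()
    filtered = preprocess(rec, pcfg)

    if fcfg.ssc_threshold is None:
        t0, t1 = ccfg.baseline_span
        i0 = int(round((t0 - rec.t0) * rec.sample_rate))
        i1 = int(round((t1 - rec.t0) * rec.sample_rate))
        seg = filtered.samples[:, max(i0, 0):i1]
        if seg.size == 0:
            raise CalibrationError("recording does not cover the baseline span")
        thr = float(np.mean(np.sqrt(np.mean(seg**2, axis=1))) ** 2)
        fcfg = FeatureConfig(ssc_threshold=thr)

    frames = extract_features(filtered, pcfg, fcfg)
    baseline = calibrate(frames, ccfg)
    active = np.array([detect_activation(f, baseline, ccfg) for f in frames])
    times = np.array([f.end_time for f in frames])
    events = segment_commands(times, active, ccfg)
    return DecodeResult(events, baseline, frames, fcfg.ssc_threshold)
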