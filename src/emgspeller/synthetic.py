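"""Synthetic surface-EMG generator for speller sessions.

Real recordings for this interface come from four bipolar channels on the
bilateral rectus femoris and gastrocnemius, digitized at 200 Hz.  This module
emulates the statistical structure that the threshold decoder relies on —
a quiet Gaussian baseline with voluntary-contraction bursts on the channels
mapped to each command — so the whole pipeline is testable without hardware.

A burst is band-limited white noise (default 20–90 Hz, the band the decoder
retains) scaled to a target RMS amplitude, with a 50 ms raised-cosine ramp at
onset and offset to avoid step discontinuities.  Optional mains contamination
(50 + 60 Hz sinusoids) exercises the notch stage.  No motor-unit physiology
is modeled: bursts are stationary within an event, which is the regime the
RMS/SSC/peak thresholds assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import ParseError, ScriptError
from .events import COMMANDS, DEFAULT_CHANNELS, DEFAULT_COMMAND_CHANNELS

#: hold time (s) a co-contraction must be sustained to count as SELECT
SELECT_HOLD_S = 0.3


@dataclass(frozen=True)
class GestureEvent:
    intended_command: str
    onset_time: float  # seconds
    duration: float  # seconds

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration


@dataclass(frozen=True)
class GestureScript:
    """Time-ordered, non-overlapping schedule of intended commands."""

    events: tuple[GestureEvent, ...]
    session_length: float  # seconds

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        prev_end = -np.inf
        for ev in self.events:
            if ev.intended_command not in COMMANDS:
                raise ScriptError(f"unknown command {ev.intended_command!r}")
            if ev.duration <= 0:
                raise ScriptError(f"non-positive duration at t={ev.onset_time}")
            if ev.onset_time < prev_end:
                raise ScriptError(
                    f"overlapping/out-of-order event at t={ev.onset_time}"
                )
            if ev.intended_command == "SELECT" and ev.duration < SELECT_HOLD_S:
                raise ScriptError(
                    f"SELECT at t={ev.onset_time} shorter than the "
                    f"{SELECT_HOLD_S} s hold threshold"
                )
            prev_end = ev.end_time
        if self.events and self.events[-1].end_time > self.session_length:
            raise ScriptError("events extend past session_length")

    @property
    def intended_commands(self) -> list[str]:
        return [ev.intended_command for ev in self.events]


@dataclass(frozen=True)
class BurstModelParams:
    """Amplitudes in microvolts; the physiological sEMG envelope is 50 µV–20 mV."""

    baseline_noise_sd: float = 15.0
    burst_amplitude: float = 1500.0  # RMS of the contraction carrier
    burst_band: tuple[float, float] = (20.0, 90.0)
    onset_jitter_sd: float = 0.02
    amplitude_jitter_fraction: float = 0.1
    powerline_amplitude: float = 0.0  # adds 50 Hz + 60 Hz sinusoids if > 0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_noise_sd <= 0:
            raise ScriptError("baseline_noise_sd must be > 0")
        if not 0 < self.burst_band[0] < self.burst_band[1] < 100.0:
            raise ScriptError("burst_band must lie inside (0, 100) Hz at 200 Hz fs")


@dataclass(frozen=True)
class EmgRecording:
    """Uniformly sampled multichannel signal, channel-major, in microvolts."""

    sample_rate: float
    channels: tuple[str, ...]
    samples: np.ndarray  # shape (n_channels, n_samples)
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(self.channels):
            raise ScriptError(
                f"samples shape {arr.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(arr)):
            raise ScriptError("recording contains non-finite values")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        return replace(self, samples=samples)


def _raised_cosine_envelope(n: int, ramp_n: int) -> np.ndarray:
    """Unit plateau with half-cosine ramps of ``ramp_n`` samples at both ends."""
    env = np.ones(n)
    r = min(ramp_n, n // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[n - r:] = ramp[::-1]
    return env


def generate_recording(
    script: GestureScript,
    params: BurstModelParams,
    sample_rate: float = 200.0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    command_channels: dict[str, tuple[int, ...]] | None = None,
    ramp_s: float = 0.05,
) -> EmgRecording:
    """Render a gesture script into a labeled multichannel EMG recording.

    Deterministic given ``params.seed``.  During each scripted event the
    channels mapped to its command carry the band-limited burst; everywhere
    else channels hold baseline noise (plus optional mains sinusoids).
    """
    if command_channels is None:
        command_channels = DEFAULT_COMMAND_CHANNELS
    n = int(round(script.session_length * sample_rate))
    rng = np.random.default_rng(params.seed)
    x = rng.normal(0.0, params.baseline_noise_sd, size=(len(channels), n))

    if params.powerline_amplitude > 0:
        t = np.arange(n) / sample_rate
        mains = params.powerline_amplitude * (
            np.sin(2 * np.pi * 50.0 * t) + np.sin(2 * np.pi * 60.0 * t)
        )
        x += mains  # common-mode: identical on every channel

    sos = signal.butter(
        4, params.burst_band, btype="bandpass", fs=sample_rate, output="sos"
    )
    ramp_n = int(round(ramp_s * sample_rate))
    for ev in script.events:
        jitter = rng.normal(0.0, params.onset_jitter_sd) if params.onset_jitter_sd else 0.0
        amp = params.burst_amplitude * max(
            1.0 + params.amplitude_jitter_fraction * rng.normal(), 0.1
        )
        i0 = int(round((ev.onset_time + jitter) * sample_rate))
        i1 = int(round((ev.end_time + jitter) * sample_rate))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 - i0 < 4:
            continue
        env = _raised_cosine_envelope(i1 - i0, ramp_n)
        for ch in command_channels[ev.intended_command]:
            carrier = signal.sosfilt(sos, rng.standard_normal(i1 - i0))
            rms = np.sqrt(np.mean(carrier**2))
            if rms > 0:
                carrier *= amp / rms
            x[ch, i0:i1] += carrier * env
    return EmgRecording(sample_rate=sample_rate, channels=channels, samples=x)


# ---------------------------------------------------------------------------
# recording / script file formats (delimited text, diff-able fixtures)
# ---------------------------------------------------------------------------

def write_recording(rec: EmgRecording, path: str | Path) -> None:
    """Write a recording as comma-delimited text.

    Line 1: ``# sample_rate=<Hz> channels=<a,b,...> t0=<s>``; line 2 a column
    header (``time`` + channel labels); then one row per sample, microvolts.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# sample_rate={rec.sample_rate:g} "
            f"channels={','.join(rec.channels)} t0={rec.t0:g}\n"
        )
        fh.write("time," + ",".join(rec.channels) + "\n")
        times = rec.times()
        cols = rec.samples.T
        for i in range(rec.n_samples):
            row = ",".join(f"{v:.10g}" for v in cols[i])
            fh.write(f"{times[i]:.10g},{row}\n")


def read_recording(path: str | Path) -> EmgRecording:
    """Parse the delimited-text recording format; errors name the bad line."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ParseError("missing '# sample_rate=... channels=...' header", 1)
        meta: dict[str, str] = {}
        for tok in header.lstrip("#").split():
            if "=" not in tok:
                raise ParseError(f"malformed header token {tok!r}", 1)
            k, v = tok.split("=", 1)
            meta[k] = v
        try:
            sample_rate = float(meta["sample_rate"])
            channels = tuple(meta["channels"].split(","))
        except KeyError as exc:
            raise ParseError(f"header missing {exc.args[0]}", 1) from None
        t0 = float(meta.get("t0", "0"))

        colhdr = fh.readline().strip()
        expected_cols = 1 + len(channels)
        if colhdr.split(",") != ["time", *channels]:
            raise ParseError("column header does not match channel list", 2)

        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=3):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != expected_cols:
                raise ParseError(
                    f"expected {expected_cols} columns, got {len(parts)}", lineno
                )
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError:
                raise ParseError("non-numeric cell", lineno) from None
    if not rows:
        raise ParseError("recording has no sample rows", 3)
    samples = np.array(rows, dtype=float).T
    return EmgRecording(sample_rate=sample_rate, channels=channels, samples=samples, t0=t0)


def write_script(script: GestureScript, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# session_length={script.session_length:g}\n")
        fh.write("# command,onset_s,duration_s\n")
        for ev in script.events:
            fh.write(f"{ev.intended_command},{ev.onset_time:.6f},{ev.duration:.6f}\n")


def read_script(path: str | Path) -> GestureScript:
    session_length = None
    events: list[GestureEvent] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("session_length="):
                    session_length = float(body.split("=", 1)[1])
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise ParseError(f"expected 3 fields, got {len(parts)}", lineno)
            try:
                events.append(
                    GestureEvent(parts[0].upper(), float(parts[1]), float(parts[2]))
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
    if session_length is None:
        session_length = (events[-1].end_time + 2.0) if events else 0.0
    return GestureScript(events=tuple(events), session_length=session_length)


# ---------------------------------------------------------------------------
# experiment schedules
# ---------------------------------------------------------------------------

#: one "set": each of the five commands performed twice -> 10 key operations
EXPERIMENT1_SEQUENCE: tuple[str, ...] = COMMANDS + COMMANDS

#: durations (s) of a voluntary contraction in the scripted protocols
DIRECTIONAL_DURATION_S = 0.8
SELECT_DURATION_S = 0.5
#: rest between consecutive commands within a trial
INTER_COMMAND_REST_S = 2.0
#: quiet lead-in used for baseline calibration (first 2 s must be rest)
BASELINE_LEAD_S = 2.5


def script_from_commands(
    commands: list[str],
    lead_s: float = BASELINE_LEAD_S,
    rest_s: float = INTER_COMMAND_REST_S,
    directional_duration: float = DIRECTIONAL_DURATION_S,
    select_duration: float = SELECT_DURATION_S,
) -> GestureScript:
    """Lay out a command list as evenly paced gesture events after a quiet lead-in."""
    events = []
    t = lead_s
    for cmd in commands:
        dur = select_duration if cmd == "SELECT" else directional_duration
        events.append(GestureEvent(cmd, t, dur))
        t += dur + rest_s
    return GestureScript(events=tuple(events), session_length=t)


def experiment1_script(
    n_trials: int,
    subjects: int,
    rest_s: float = INTER_COMMAND_REST_S,
) -> list[GestureScript]:
    """Per-trial gesture scripts for the command-recognition protocol.

    Each trial performs the five commands twice (10 key operations) with a
    2 s rest between commands; returns ``subjects * n_trials`` scripts, i.e.
    ``subjects * n_trials * 10`` events in total.
    """
    if n_trials < 1 or subjects < 1:
        raise ScriptError("n_trials and subjects must be >= 1")
    return [
        script_from_commands(list(EXPERIMENT1_SEQUENCE), rest_s=rest_s)
        for _ in range(subjects * n_trials)
    ]
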