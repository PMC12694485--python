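"""Command events: the five-symbol control alphabet shared by every stage.

The decoder emits one of five commands — four cursor directions plus SELECT —
each mapped to contraction of one EMG channel (SELECT to a simultaneous
co-contraction of two).  Channels follow the bilateral rectus femoris /
gastrocnemius montage: channel 1 = left thigh, 2 = right thigh, 3 = left
calf, 4 = right calf (0-based indices in code).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ParseError, ScriptError

COMMANDS: tuple[str, ...] = ("UP", "DOWN", "LEFT", "RIGHT", "SELECT")

#: default channel labels, in acquisition order
DEFAULT_CHANNELS: tuple[str, ...] = ("rf_left", "rf_right", "gc_left", "gc_right")

#: which channels contract for each command (0-based). SELECT is a
#: co-contraction; the {thigh-left, calf-left} pair is the default and is
#: configurable wherever it matters.
DEFAULT_COMMAND_CHANNELS: dict[str, tuple[int, ...]] = {
    "UP": (0,),
    "DOWN": (1,),
    "LEFT": (2,),
    "RIGHT": (3,),
    "SELECT": (0, 2),
}


@dataclass(frozen=True)
class CommandEvent:
    """A decoded (or scripted) command with its time extent in seconds."""

    command: str
    onset: float
    offset: float

    def __post_init__(self):
        if self.command not in COMMANDS:
            raise ScriptError(f"unknown command {self.command!r}")
        if not self.offset > self.onset:
            raise ScriptError(
                f"event offset must exceed onset ({self.onset}..{self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def write_events(events: list[CommandEvent], path: str | Path) -> None:
    """Write events as ``command,onset,offset`` lines (seconds)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# command,onset_s,offset_s\n")
        for ev in events:
            fh.write(f"{ev.command},{ev.onset:.6f},{ev.offset:.6f}\n")


def read_events(path: str | Path) -> list[CommandEvent]:
    events: list[CommandEvent] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise ParseError(f"expected 3 fields, got {len(parts)}", lineno)
            cmd = parts[0].upper()
            if cmd not in COMMANDS:
                raise ParseError(f"unknown command {parts[0]!r}", lineno)
            try:
                onset, offset = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            try:
                events.append(CommandEvent(cmd, onset, offset))
            except ScriptError as exc:
                raise ParseError(str(exc), lineno) from None
    return events
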