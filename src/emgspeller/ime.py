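"""Virtual Cheonjiin keyboard: cursor navigation, multi-tap consonants,
the three-element vowel automaton, and Hangul syllable assembly.

The Cheonjiin scheme builds every Korean medial vowel from three elements —
ㅣ (human), ㆍ (heaven), ㅡ (earth) — and groups consonants onto seven
multi-tap keys (e.g. ㄱㅋ: once ㄱ, twice ㅋ, three times ㄲ).  The keyboard
is a 4×4 grid with 14 active keys; a cursor driven by UP/DOWN/LEFT/RIGHT
commands highlights a key and SELECT presses it.  Syllables are assembled as
choseong (initial consonant) + jungseong (medial vowel) + optional jongseong
(final consonant) and committed with the enter key as precomposed Unicode
Hangul.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, ParseError
from .events import CommandEvent

# ---------------------------------------------------------------------------
# jamo inventories and Unicode composition
# ---------------------------------------------------------------------------

CHOSEONG = "ㄱㄲㄴㄷㄸㄹㅁㅂㅃㅅㅆㅇㅈㅉㅊㅋㅌㅍㅎ"  # 19 initials
JUNGSEONG = "ㅏㅐㅑㅒㅓㅔㅕㅖㅗㅘㅙㅚㅛㅜㅝㅞㅟㅠㅡㅢㅣ"  # 21 medials
JONGSEONG = "ㄱㄲㄳㄴㄵㄶㄷㄹㄺㄻㄼㄽㄾㄿㅀㅁㅂㅄㅅㅆㅇㅈㅊㅋㅌㅍㅎ"  # 27 finals

_HANGUL_BASE = 0xAC00


def compose_syllable(cho: str, jung: str, jong: str = "") -> str:
    """Precomposed Hangul code point: 0xAC00 + (cho*21 + jung)*28 + jong."""
    try:
        ci = CHOSEONG.index(cho)
        ji = JUNGSEONG.index(jung)
    except ValueError:
        raise ConfigError(f"invalid initial/medial jamo {cho!r}+{jung!r}") from None
    if jong:
        try:
            jo = JONGSEONG.index(jong) + 1
        except ValueError:
            raise ConfigError(f"invalid final jamo {jong!r}") from None
    else:
        jo = 0
    return chr(_HANGUL_BASE + (ci * 21 + ji) * 28 + jo)


def decompose_syllable(ch: str) -> tuple[str, str, str]:
    code = ord(ch) - _HANGUL_BASE
    if not 0 <= code < 19 * 21 * 28:
        raise ConfigError(f"{ch!r} is not a precomposed Hangul syllable")
    ci, rem = divmod(code, 21 * 28)
    ji, jo = divmod(rem, 28)
    return CHOSEONG[ci], JUNGSEONG[ji], JONGSEONG[jo - 1] if jo else ""


#: standard two-consonant final combinations (e.g. ㄱ+ㅅ -> ㄳ)
COMPOUND_FINALS: dict[tuple[str, str], str] = {
    ("ㄱ", "ㅅ"): "ㄳ", ("ㄴ", "ㅈ"): "ㄵ", ("ㄴ", "ㅎ"): "ㄶ",
    ("ㄹ", "ㄱ"): "ㄺ", ("ㄹ", "ㅁ"): "ㄻ", ("ㄹ", "ㅂ"): "ㄼ",
    ("ㄹ", "ㅅ"): "ㄽ", ("ㄹ", "ㅌ"): "ㄾ", ("ㄹ", "ㅍ"): "ㄿ",
    ("ㄹ", "ㅎ"): "ㅀ", ("ㅂ", "ㅅ"): "ㅄ",
}

# ---------------------------------------------------------------------------
# keys
# ---------------------------------------------------------------------------

VOWEL_KEYS = ("ㅣ", "ㆍ", "ㅡ")

#: multi-tap cycles; two-character groups cycle with period 2
CONSONANT_CYCLES: dict[str, str] = {
    "ㄱㅋ": "ㄱㅋㄲ",
    "ㄴㄹ": "ㄴㄹ",
    "ㄷㅌ": "ㄷㅌㄸ",
    "ㅂㅍ": "ㅂㅍㅃ",
    "ㅅㅎ": "ㅅㅎㅆ",
    "ㅈㅊ": "ㅈㅊㅉ",
    "ㅇㅁ": "ㅇㅁ",
}

FUNCTION_KEYS = ("del", "space", "enter", ".")

_I, _D, _E = VOWEL_KEYS

#: key sequence -> medial vowel. The three conflicted ㅘ/ㅝ/ㅞ entries follow
#: the standard Cheonjiin decompositions (ㅘ = ㅗ+ㅏ, ㅝ = ㅜ+ㅓ, ㅞ = ㅝ+ㅣ).
VOWEL_SEQUENCES: dict[tuple[str, ...], str] = {
    (_I,): "ㅣ",
    (_E,): "ㅡ",
    (_I, _D): "ㅏ",
    (_I, _D, _D): "ㅑ",
    (_I, _D, _I): "ㅐ",
    (_I, _D, _D, _I): "ㅒ",
    (_D, _I): "ㅓ",
    (_D, _I, _I): "ㅔ",
    (_D, _D, _I): "ㅕ",
    (_D, _D, _I, _I): "ㅖ",
    (_D, _E): "ㅗ",
    (_D, _D, _E): "ㅛ",
    (_D, _E, _I): "ㅚ",
    (_D, _E, _I, _D): "ㅘ",
    (_D, _E, _I, _D, _I): "ㅙ",
    (_E, _D): "ㅜ",
    (_E, _D, _D): "ㅠ",
    (_E, _D, _I): "ㅟ",
    (_E, _D, _D, _I): "ㅝ",
    (_E, _D, _D, _I, _I): "ㅞ",
    (_E, _I): "ㅢ",
}


class VowelAutomaton:
    """Prefix automaton over the three vowel keys; accepting states are the
    21 standard medial vowels."""

    def __init__(self, sequences: dict[tuple[str, ...], str] | None = None):
        self.accepting = dict(sequences or VOWEL_SEQUENCES)
        vowels = list(self.accepting.values())
        if len(set(vowels)) != len(vowels):
            raise ConfigError("two key sequences map to the same vowel")
        self._prefixes: set[tuple[str, ...]] = set()
        for seq in self.accepting:
            for k in range(1, len(seq) + 1):
                self._prefixes.add(seq[:k])

    def is_prefix(self, buffer: tuple[str, ...]) -> bool:
        return tuple(buffer) in self._prefixes

    def resolve(self, buffer) -> tuple[str | None, bool]:
        """(vowel if the buffer is accepting else None, extendable?)."""
        buf = tuple(buffer)
        if not buf:
            raise ConfigError("empty vowel buffer")
        if buf not in self._prefixes:
            raise ConfigError(f"buffer {buf} is not a prefix of any vowel sequence")
        extendable = any(
            buf + (k,) in self._prefixes for k in VOWEL_KEYS
        )
        return self.accepting.get(buf), extendable

    def vowels(self) -> set[str]:
        return set(self.accepting.values())


# ---------------------------------------------------------------------------
# layout and cursor
# ---------------------------------------------------------------------------

DEFAULT_GRID: tuple[tuple[str | None, ...], ...] = (
    ("ㅣ", "ㆍ", "ㅡ", "del"),
    ("ㄱㅋ", "ㄴㄹ", "ㄷㅌ", "space"),
    ("ㅂㅍ", "ㅅㅎ", "ㅈㅊ", "enter"),
    ("ㅇㅁ", ".", None, None),
)


@dataclass(frozen=True)
class KeyboardLayout:
    grid: tuple[tuple[str | None, ...], ...] = DEFAULT_GRID

    def __post_init__(self):
        object.__setattr__(
            self, "grid", tuple(tuple(row) for row in self.grid)
        )
        known = set(VOWEL_KEYS) | set(CONSONANT_CYCLES) | set(FUNCTION_KEYS)
        for row in self.grid:
            for cell in row:
                if cell is not None and cell not in known:
                    raise ConfigError(f"unknown key {cell!r} in layout")

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_cols(self) -> int:
        return len(self.grid[0])

    def key_at(self, row: int, col: int) -> str | None:
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return self.grid[row][col]
        return None

    def find(self, key: str) -> tuple[int, int]:
        for r, row in enumerate(self.grid):
            for c, cell in enumerate(row):
                if cell == key:
                    return (r, c)
        raise ConfigError(f"key {key!r} not in layout")

    def active_keys(self) -> list[str]:
        return [c for row in self.grid for c in row if c is not None]

    def jamo_keys(self) -> list[str]:
        return [
            k for k in self.active_keys()
            if k in VOWEL_KEYS or k in CONSONANT_CYCLES
        ]

    def validate_cheonjiin(self) -> None:
        """Structural invariants of the Cheonjiin grid."""
        keys = self.active_keys()
        if len(keys) != 14:
            raise ConfigError(f"expected 14 active keys, found {len(keys)}")
        if len(self.jamo_keys()) != 10:
            raise ConfigError("expected 10 jamo-producing keys (3 vowel + 7 consonant)")
        top = set(self.grid[0])
        if not (set(VOWEL_KEYS) | {"del"}) <= top:
            raise ConfigError("top row must hold the vowel keys and del")

    @classmethod
    def from_file(cls, path: str | Path) -> "KeyboardLayout":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cells = [c.strip() for c in line.split(",")]
                rows.append(tuple(None if c == "_" else c for c in cells))
        if not rows or len({len(r) for r in rows}) != 1:
            raise ParseError("layout must be a rectangular grid")
        return cls(grid=tuple(rows))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for row in self.grid:
                fh.write(",".join(c if c is not None else "_" for c in row) + "\n")


@dataclass(frozen=True)
class CursorState:
    row: int = 0
    col: int = 0


_DELTAS = {"UP": (-1, 0), "DOWN": (1, 0), "LEFT": (0, -1), "RIGHT": (0, 1)}


def move_cursor(cur: CursorState, cmd: str, layout: KeyboardLayout) -> CursorState:
    """Move one step in the commanded direction, skipping empty cells; at an
    edge (or when only empty cells remain in that direction) the cursor stays."""
    if cmd not in _DELTAS:
        raise ConfigError(f"{cmd!r} is not a directional command")
    dr, dc = _DELTAS[cmd]
    r, c = cur.row + dr, cur.col + dc
    while 0 <= r < layout.n_rows and 0 <= c < layout.n_cols:
        if layout.grid[r][c] is not None:
            return CursorState(r, c)
        r, c = r + dr, c + dc
    return cur


# ---------------------------------------------------------------------------
# composer
# ---------------------------------------------------------------------------

class Composer:
    """Incremental Hangul composer over key presses.

    State: an optional multi-tap context (key, press count), the vowel-key
    buffer with its automaton, the current syllable slots, and committed
    text.  Invalid presses are no-ops recorded in ``warnings``.
    """

    def __init__(self, automaton: VowelAutomaton | None = None):
        self.automaton = automaton or VowelAutomaton()
        self.committed: list[str] = []
        self.cho: str | None = None
        self.vowel_buffer: list[str] = []
        self.vowel_closed = False  # finalized by a rejected keypress
        self.jung: str | None = None
        self.jong_parts: list[str] = []
        self._tap: tuple[str, int] | None = None  # (key, consecutive presses)
        self.warnings: list[str] = []

    # -- helpers ----------------------------------------------------------

    @property
    def text(self) -> str:
        return "".join(self.committed)

    def _warn(self, msg: str) -> None:
        self.warnings.append(msg)

    def _jong_string(self, parts: list[str]) -> str | None:
        """Combined final, or None if the parts are not a valid jongseong."""
        if not parts:
            return ""
        if len(parts) == 1:
            return parts[0] if parts[0] in JONGSEONG else None
        if len(parts) == 2:
            return COMPOUND_FINALS.get((parts[0], parts[1]))
        return None

    def _reset_syllable(self) -> None:
        self.cho = None
        self.vowel_buffer = []
        self.vowel_closed = False
        self.jung = None
        self.jong_parts = []
        self._tap = None

    # -- key handling ------------------------------------------------------

    def press(self, key: str) -> None:
        if key in CONSONANT_CYCLES:
            self._press_consonant(key)
        elif key in VOWEL_KEYS:
            self._press_vowel(key)
        elif key == "enter":
            self._tap = None
            self._commit_syllable()
        elif key in ("space", "."):
            self._tap = None
            self._commit_syllable(flush_partial=True)
            self.committed.append(" " if key == "space" else ".")
        elif key == "del":
            self._delete()
        else:
            self._warn(f"unknown key {key!r} ignored")

    def _press_consonant(self, key: str) -> None:
        cycle = CONSONANT_CYCLES[key]
        if self._tap is not None and self._tap[0] == key:
            count = self._tap[1] + 1
            char = cycle[(count - 1) % len(cycle)]
            if self.jong_parts and self.jung is not None:
                old = self.jong_parts[-1]
                self.jong_parts[-1] = char
                if self._jong_string(self.jong_parts) is None:
                    self.jong_parts[-1] = old
                    self._warn(f"cycle to {char!r} makes an invalid final; kept {old!r}")
                    return
            else:
                self.cho = char
            self._tap = (key, count)
            return

        char = cycle[0]
        if self.jung is None and not self.vowel_buffer:
            if self.cho is not None:
                # consonant after consonant with no vowel: flush the pending
                # initial as a bare jamo and start over
                self.committed.append(self.cho)
                self.cho = None
            self.cho = char
        elif self.jung is None:
            self._warn("consonant pressed while a vowel is incomplete; ignored")
            return
        else:
            self.vowel_closed = True
            trial = self.jong_parts + [char]
            if self._jong_string(trial) is None:
                self._warn(f"{char!r} cannot extend the final; ignored")
                return
            self.jong_parts = trial
        self._tap = (key, 1)

    def _press_vowel(self, key: str) -> None:
        self._tap = None
        if self.jong_parts:
            self._warn("vowel after a final consonant; commit the syllable first")
            return
        if self.vowel_closed:
            self._warn("vowel already finalized; keypress rejected")
            return
        trial = tuple(self.vowel_buffer) + (key,)
        if self.automaton.is_prefix(trial):
            self.vowel_buffer.append(key)
            self.jung, _ = self.automaton.resolve(self.vowel_buffer)
        elif self.jung is not None:
            # extends no valid sequence: finalize the current vowel,
            # reject the keypress
            self.vowel_closed = True
            self._warn(f"{key!r} extends no vowel sequence; vowel finalized")
        else:
            self._warn(f"{key!r} does not start or extend a vowel sequence")

    def _commit_syllable(self, flush_partial: bool = False) -> bool:
        jong = self._jong_string(self.jong_parts)
        if jong is None:
            self._warn("pending final is not a valid jongseong")
            jong = ""
        if self.cho is not None and self.jung is not None:
            self.committed.append(compose_syllable(self.cho, self.jung, jong))
            self._reset_syllable()
            return True
        if flush_partial:
            if self.cho is not None:
                self.committed.append(self.cho)
            elif self.jung is not None:
                self._warn("pending vowel without an initial cannot be committed")
            self._reset_syllable()
            return False
        if self.cho is not None or self.jung is not None or self.vowel_buffer:
            self._warn("syllable incomplete; enter ignored")
        return False

    def _delete(self) -> None:
        self._tap = None
        if self.jong_parts:
            self.jong_parts.pop()
        elif self.vowel_buffer:
            self.vowel_buffer.pop()
            self.vowel_closed = False
            self.jung = (
                self.automaton.resolve(self.vowel_buffer)[0]
                if self.vowel_buffer else None
            )
        elif self.cho is not None:
            self.cho = None
        elif self.committed:
            self.committed.pop()


def type_keys(
    keys: list[str], automaton: VowelAutomaton | None = None
) -> tuple[str, list[str]]:
    """Replay a key-press sequence; returns (committed text, warnings)."""
    comp = Composer(automaton)
    for k in keys:
        comp.press(k)
    return comp.text, comp.warnings


# ---------------------------------------------------------------------------
# command replay and path planning
# ---------------------------------------------------------------------------

def type_commands(
    events: list[CommandEvent],
    layout: KeyboardLayout | None = None,
    start: CursorState = CursorState(0, 0),
) -> str:
    """Replay decoded command events: directions move the cursor, SELECT
    presses the highlighted key.  Deterministic."""
    layout = layout or KeyboardLayout()
    cursor = start
    comp = Composer()
    for ev in sorted(events, key=lambda e: e.onset):
        if ev.command == "SELECT":
            key = layout.key_at(cursor.row, cursor.col)
            if key is not None:
                comp.press(key)
        else:
            cursor = move_cursor(cursor, ev.command, layout)
    return comp.text


def plan_commands(
    keys: list[str],
    layout: KeyboardLayout | None = None,
    start: CursorState = CursorState(0, 0),
) -> list[str]:
    """Command sequence (directions + SELECT) that presses ``keys`` in order,
    using breadth-first shortest paths under the cursor-motion rules."""
    layout = layout or KeyboardLayout()
    commands: list[str] = []
    cur = start
    for key in keys:
        target = CursorState(*layout.find(key))
        commands.extend(_bfs_path(cur, target, layout))
        commands.append("SELECT")
        cur = target
    return commands


def _bfs_path(
    start: CursorState, goal: CursorState, layout: KeyboardLayout
) -> list[str]:
    if start == goal:
        return []
    from collections import deque

    prev: dict[CursorState, tuple[CursorState, str]] = {}
    q = deque([start])
    seen = {start}
    while q:
        node = q.popleft()
        for cmd in _DELTAS:
            nxt = move_cursor(node, cmd, layout)
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = (node, cmd)
            if nxt == goal:
                path = []
                while nxt != start:
                    nxt, cmd2 = prev[nxt]
                    path.append(cmd2)
                return path[::-1]
            q.append(nxt)
    raise ConfigError(f"no cursor path from {start} to {goal}")


def render(
    layout: KeyboardLayout, cursor: CursorState, comp: Composer | None = None
) -> str:
    """Headless state renderer: grid with the cursor marked, plus buffers."""
    lines = []
    for r, row in enumerate(layout.grid):
        cells = []
        for c, cell in enumerate(row):
            label = cell if cell is not None else " "
            mark = f"[{label}]" if (r, c) == (cursor.row, cursor.col) else f" {label} "
            cells.append(f"{mark:^7}")
        lines.append("|".join(cells))
    if comp is not None:
        pending = "".join(
            p for p in (comp.cho, comp.jung, "".join(comp.jong_parts)) if p
        )
        lines.append(f"pending: {pending or '-'}   text: {comp.text!r}")
    return "\n".join(lines)


# canonical key sequences for the two text-entry tasks
WORD_TASK_TEXT = "다리"
WORD_TASK_KEYS: tuple[str, ...] = (
    "ㄷㅌ", "ㅣ", "ㆍ", "enter", "ㄴㄹ", "ㄴㄹ", "ㅣ", "enter",
)

SENTENCE_TASK_TEXT = "안녕하세요"
SENTENCE_TASK_KEYS: tuple[str, ...] = (
    "ㅇㅁ", "ㅣ", "ㆍ", "ㄴㄹ", "enter",          # 안
    "ㄴㄹ", "ㆍ", "ㆍ", "ㅣ", "ㅇㅁ", "enter",     # 녕
    "ㅅㅎ", "ㅅㅎ", "ㅣ", "ㆍ", "enter",          # 하
    "ㅅㅎ", "ㆍ", "ㅣ", "ㅣ", "enter",            # 세
    "ㅇㅁ", "ㆍ", "ㆍ", "ㅡ", "enter",            # 요
)
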