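"""Cheonjiin keyboard: layout structure, cursor motion, multi-tap cycling,
the vowel automaton, Unicode syllable composition, and full text replay."""

import pytest

import emgspeller as es
from emgspeller import ime
from emgspeller.ime import (
    CHOSEONG,
    CONSONANT_CYCLES,
    JONGSEONG,
    JUNGSEONG,
    SENTENCE_TASK_KEYS,
    SENTENCE_TASK_TEXT,
    VOWEL_SEQUENCES,
    WORD_TASK_KEYS,
    WORD_TASK_TEXT,
    Composer,
    CursorState,
    KeyboardLayout,
    VowelAutomaton,
    compose_syllable,
    decompose_syllable,
    move_cursor,
    plan_commands,
    type_commands,
    type_keys,
)


class TestLayout:
    def test_default_layout_invariants(self):
        lay = KeyboardLayout()
        lay.validate_cheonjiin()
        assert len(lay.active_keys()) == 14
        assert len(lay.jamo_keys()) == 10

    def test_file_round_trip(self, tmp_path):
        lay = KeyboardLayout()
        path = tmp_path / "layout.txt"
        lay.to_file(path)
        back = KeyboardLayout.from_file(path)
        assert back.grid == lay.grid
        back.validate_cheonjiin()

    def test_layout_missing_keys_fails_validation(self):
        grid = tuple(tuple(row) for row in KeyboardLayout().grid)
        broken = KeyboardLayout(grid=grid[:3] + ((None, None, None, None),))
        with pytest.raises(es.ConfigError):
            broken.validate_cheonjiin()

    def test_unknown_key_rejected(self):
        with pytest.raises(es.ConfigError):
            KeyboardLayout(grid=((("q",) + ("ㆍ", "ㅡ", "del")),) + KeyboardLayout().grid[1:])


class TestCursor:
    def test_edge_clamp(self):
        lay = KeyboardLayout()
        assert move_cursor(CursorState(0, 0), "LEFT", lay) == CursorState(0, 0)
        assert move_cursor(CursorState(0, 0), "UP", lay) == CursorState(0, 0)

    def test_simple_step(self):
        lay = KeyboardLayout()
        assert move_cursor(CursorState(0, 0), "RIGHT", lay) == CursorState(0, 1)

    def test_empty_cells_are_skipped_or_clamped(self):
        lay = KeyboardLayout()
        # (3,1) '.' RIGHT: (3,2) and (3,3) are empty -> stays
        assert move_cursor(CursorState(3, 1), "RIGHT", lay) == CursorState(3, 1)
        # (2,2) DOWN: (3,2) empty, no further rows -> stays
        assert move_cursor(CursorState(2, 2), "DOWN", lay) == CursorState(2, 2)

    @pytest.mark.parametrize("fwd,back", [("DOWN", "UP"), ("RIGHT", "LEFT")])
    def test_motion_reversible_over_all_cells(self, fwd, back):
        lay = KeyboardLayout()
        for r in range(lay.n_rows):
            for c in range(lay.n_cols):
                if lay.grid[r][c] is None:
                    continue
                cur = CursorState(r, c)
                moved = move_cursor(cur, fwd, lay)
                if moved != cur:
                    assert move_cursor(moved, back, lay) == cur


class TestVowelAutomaton:
    @pytest.mark.parametrize("seq,vowel", sorted(VOWEL_SEQUENCES.items()))
    def test_every_sequence_reaches_its_vowel(self, seq, vowel):
        got, _ = VowelAutomaton().resolve(seq)
        assert got == vowel

    def test_exactly_21_distinct_vowels(self):
        auto = VowelAutomaton()
        assert auto.vowels() == set(JUNGSEONG)
        assert len(auto.vowels()) == 21

    def test_exhaustive_enumeration_matches_table(self):
        """Depth-5 enumeration over the three keys finds exactly the 21
        accepting sequences and no ambiguity."""
        auto = VowelAutomaton()
        found = {}
        def walk(prefix):
            if len(prefix) > 5:
                return
            for k in ime.VOWEL_KEYS:
                seq = prefix + (k,)
                if auto.is_prefix(seq):
                    v = auto.accepting.get(seq)
                    if v is not None:
                        assert v not in found.values()
                        found[seq] = v
                    walk(seq)
        walk(())
        assert len(found) == 21

    def test_partial_and_extendable_states(self):
        auto = VowelAutomaton()
        v, ext = auto.resolve(("ㅡ",))
        assert v == "ㅡ" and ext  # ㅡ + ㆍ -> ㅜ
        v, ext = auto.resolve(("ㆍ",))
        assert v is None and ext  # pure partial

    def test_examples(self):
        auto = VowelAutomaton()
        assert auto.resolve(("ㅣ", "ㆍ"))[0] == "ㅏ"
        assert auto.resolve(("ㆍ", "ㆍ", "ㅣ"))[0] == "ㅕ"
        assert auto.resolve(("ㆍ", "ㅡ"))[0] == "ㅗ"
        assert auto.resolve(("ㅡ", "ㆍ"))[0] == "ㅜ"

    def test_invalid_buffer_is_internal_error(self):
        with pytest.raises(es.ConfigError):
            VowelAutomaton().resolve(("ㆍ", "ㆍ", "ㆍ"))


class TestMultiTap:
    def test_double_tap_gives_second_character(self):
        comp = Composer()
        comp.press("ㄱㅋ")
        comp.press("ㄱㅋ")
        assert comp.cho == "ㅋ"

    def test_triple_tap_gives_tense_consonant(self):
        comp = Composer()
        for _ in range(3):
            comp.press("ㅅㅎ")
        assert comp.cho == "ㅆ"

    def test_two_character_group_cycles_with_period_two(self):
        comp = Composer()
        for _ in range(3):
            comp.press("ㅇㅁ")
        assert comp.cho == "ㅇ"

    def test_cycles_cover_all_19_initials(self):
        produced = set("".join(CONSONANT_CYCLES.values()))
        assert produced == set(CHOSEONG)


class TestComposeSyllable:
    @pytest.mark.parametrize(
        "cho,jung,jong,expect",
        [("ㄷ", "ㅏ", "", "다"), ("ㅇ", "ㅏ", "ㄴ", "안"), ("ㄱ", "ㅏ", "", "가")],
    )
    def test_unicode_formula_examples(self, cho, jung, jong, expect):
        assert compose_syllable(cho, jung, jong) == expect

    def test_base_code_point(self):
        assert ord(compose_syllable("ㄱ", "ㅏ")) == 0xAC00

    def test_invalid_jamo_rejected(self):
        with pytest.raises(es.ConfigError):
            compose_syllable("ㅏ", "ㄱ")
        with pytest.raises(es.ConfigError):
            compose_syllable("ㄱ", "ㅏ", "ㄸ")

    def test_exhaustive_round_trip(self):
        """compose/decompose identity over all 19 x 21 x 28 combinations."""
        count = 0
        for cho in CHOSEONG:
            for jung in JUNGSEONG:
                for jong in [""] + list(JONGSEONG):
                    assert decompose_syllable(
                        compose_syllable(cho, jung, jong)
                    ) == (cho, jung, jong)
                    count += 1
        assert count == 19 * 21 * 28


class TestComposer:
    def test_word_task_key_sequence(self):
        text, warnings = type_keys(list(WORD_TASK_KEYS))
        assert text == WORD_TASK_TEXT
        assert warnings == []

    def test_sentence_task_key_sequence(self):
        text, warnings = type_keys(list(SENTENCE_TASK_KEYS))
        assert text == SENTENCE_TASK_TEXT
        assert warnings == []

    def test_empty_stream(self):
        assert type_keys([]) == ("", [])

    def test_enter_with_empty_syllable_is_noop(self):
        text, _ = type_keys(["enter", "enter"])
        assert text == ""

    def test_space_and_period(self):
        text, _ = type_keys(
            ["ㄱㅋ", "ㅣ", "ㆍ", "enter", "space", "ㄱㅋ", "ㅣ", "ㆍ", "enter", "."]
        )
        assert text == "가 가."

    def test_compound_final(self):
        # 닭: ㄷ + ㅏ + ㄹ + ㄱ
        text, _ = type_keys(
            ["ㄷㅌ", "ㅣ", "ㆍ", "ㄴㄹ", "ㄴㄹ", "ㄱㅋ", "enter"]
        )
        assert text == "닭"

    def test_del_removes_last_jamo_first(self):
        comp = Composer()
        for k in ("ㅇㅁ", "ㅣ", "ㆍ", "ㄴㄹ"):
            comp.press(k)
        comp.press("del")  # removes the pending final ㄴ
        comp.press("enter")
        assert comp.text == "아"

    def test_del_on_committed_text(self):
        comp = Composer()
        for k in ("ㄱㅋ", "ㅣ", "ㆍ", "enter", "del"):
            comp.press(k)
        assert comp.text == ""

    def test_vowel_without_initial_held_not_committed(self):
        comp = Composer()
        comp.press("ㅣ")
        comp.press("enter")
        assert comp.text == ""
        assert comp.warnings  # incomplete-syllable no-op is flagged

    def test_rejected_vowel_key_finalizes_buffer(self):
        comp = Composer()
        for k in ("ㅇㅁ", "ㅡ", "ㅣ"):  # ㅢ
            comp.press(k)
        comp.press("ㆍ")  # ㅡㅣㆍ extends nothing -> vowel finalized
        comp.press("enter")
        assert comp.text == "의"


class TestCommandReplay:
    def test_word_task_via_planned_commands(self):
        cmds = plan_commands(list(WORD_TASK_KEYS))
        events = [
            es.CommandEvent(c, 2.5 + 3.0 * i, 3.0 + 3.0 * i)
            for i, c in enumerate(cmds)
        ]
        assert type_commands(events) == WORD_TASK_TEXT

    def test_sentence_task_via_planned_commands(self):
        cmds = plan_commands(list(SENTENCE_TASK_KEYS))
        events = [
            es.CommandEvent(c, 2.5 + 3.0 * i, 3.0 + 3.0 * i)
            for i, c in enumerate(cmds)
        ]
        assert type_commands(events) == SENTENCE_TASK_TEXT

    def test_empty_command_stream(self):
        assert type_commands([]) == ""

    def test_replay_deterministic(self):
        cmds = plan_commands(list(WORD_TASK_KEYS))
        events = [
            es.CommandEvent(c, 2.5 + 3.0 * i, 3.0 + 3.0 * i)
            for i, c in enumerate(cmds)
        ]
        assert type_commands(events) == type_commands(events)

    def test_planner_visits_each_target_key(self):
        lay = KeyboardLayout()
        cmds = plan_commands(["ㅈㅊ", "ㅣ"], lay)
        cursor = CursorState(0, 0)
        pressed = []
        for c in cmds:
            if c == "SELECT":
                pressed.append(lay.key_at(cursor.row, cursor.col))
            else:
                cursor = move_cursor(cursor, c, lay)
        assert pressed == ["ㅈㅊ", "ㅣ"]

    def test_render_headless_state(self):
        lay = KeyboardLayout()
        out = ime.render(lay, CursorState(0, 0), Composer())
        assert "[ㅣ]" in out and "text:" in out
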