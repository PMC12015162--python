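"""Game-mechanic unit tests: every rule constant in a scripted micro-scenario."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishcards import GameConfig
from fishcards.agents import ScriptedAgent
from fishcards.engine import (LOST_DEPLETION, LOST_ESCAPE, WON_PHASE,
                              EngineError, advance, generate_card, new_game,
                              regen_tick, register_hit, run_attempt, run_phase,
                              sample_submarine_interval, submarine_step)
from fishcards._rng import child_rng


def fresh(config, phase=2, seed=0):
    """A game with the first round opened (ops require an active round)."""
    state = new_game(config, phase, seed)
    advance(state, None)
    return state


def give_fish(state, n=1):
    for _ in range(n):
        state.active_fish.append((state.play_tick, state.play_tick + 10 ** 9))


class TestNewGame:
    def test_phase2_starts_full_bar_and_two_submarines(self, game):
        state = new_game(game, 2, seed=1)
        assert state.bar_pct == 100.0
        assert len(state.submarines) == 2

    def test_phase1_three_hearts_no_submarines(self, game):
        state = new_game(game, 1, seed=1)
        assert state.hearts == 3
        assert state.submarines == []

    def test_invalid_phase_rejected(self, game):
        with pytest.raises(EngineError):
            new_game(game, 3, seed=1)

    def test_submarines_start_in_slowest_bracket(self, game):
        state = new_game(game, 2, seed=7)
        for sub in state.submarines:
            assert 6.0 <= sub.current_interval_s <= 10.0


class TestGenerateCard:
    def test_radar_costs_five_points(self, game):
        state = fresh(game)
        state.score = 10
        generate_card(state, "radar")
        assert state.score == 5

    def test_rod_cost_allows_negative_score(self, game):
        state = fresh(game)
        assert state.score == 0
        generate_card(state, "rod")
        assert state.score == -1

    def test_fourth_consecutive_click_rejected_and_cooled(self, game):
        state = fresh(game)
        give_fish(state, 10)
        for _ in range(3):
            generate_card(state, "rod")
            register_hit(state, "rod")
        state.play_tick = 120                      # t = 12.0 s
        ev = generate_card(state, "rod")           # 4th in a row
        assert ev is None
        assert state.cooldown_until["rod"] == 120 + game.cooldown_ticks  # 20.0 s
        state.play_tick = 150                      # t = 15.0 s
        assert generate_card(state, "rod") is None  # still cooling
        state.play_tick = 200                      # t = 20.0 s: expired
        assert generate_card(state, "rod") is not None

    def test_opposite_panel_resets_counter(self, game):
        state = fresh(game)
        give_fish(state, 10)
        for card in ("rod", "rod", "rod", "radar", "rod"):
            ev = generate_card(state, card)
            assert ev is not None
            register_hit(state, card)

    def test_outside_round_is_error(self, game):
        state = new_game(game, 1, seed=0)
        with pytest.raises(EngineError):
            generate_card(state, "rod")


class TestRegisterHit:
    def test_radar_hit_extracts_fifteen(self, game):
        state = fresh(game)
        give_fish(state)
        state.held_card = "radar"
        register_hit(state, "radar")
        assert state.bar_pct == 85.0

    def test_rod_hit_extracts_five(self, game):
        state = fresh(game)
        state.bar_pct = 50.0
        give_fish(state)
        state.held_card = "rod"
        register_hit(state, "rod")
        assert state.bar_pct == 45.0

    def test_depletion_loss_at_zero(self, game):
        state = fresh(game)
        state.bar_pct = 10.0
        give_fish(state)
        state.held_card = "radar"
        events = []
        register_hit(state, "radar", events)
        assert state.bar_pct == 0.0
        assert state.outcome == LOST_DEPLETION
        assert any(e.event_type == "defeat" for e in events)

    def test_gains_rod_one_radar_nine(self, game):
        state = fresh(game, phase=1)
        give_fish(state, 2)
        state.held_card = "rod"
        register_hit(state, "rod")
        assert state.score == 1
        state.held_card = "radar"
        register_hit(state, "radar")
        assert state.score == 10

    def test_hit_without_card_or_fish_is_error(self, game):
        state = fresh(game, phase=1)
        with pytest.raises(EngineError):
            register_hit(state, "rod")
        state.held_card = "rod"
        with pytest.raises(EngineError):
            register_hit(state, "rod")

    def test_irt_absent_on_first_hit_then_tick_exact(self, game):
        state = fresh(game, phase=1)
        give_fish(state, 2)
        state.held_card = "rod"
        ev1 = register_hit(state, "rod")
        assert ev1.irt_s is None
        state.play_tick += 37
        state.held_card = "rod"
        ev2 = register_hit(state, "rod")
        assert ev2.irt_s == pytest.approx(3.7)


class TestRegen:
    @pytest.mark.parametrize("start,expected", [(50.0, 55.0), (100.0, 100.0),
                                                (98.0, 100.0)])
    def test_regen_step_and_clamp(self, game, start, expected):
        state = fresh(game)
        state.bar_pct = start
        regen_tick(state)
        assert state.bar_pct == expected

    def test_regen_fires_every_two_seconds_in_round(self, open_water):
        state = new_game(open_water, 2, seed=3)
        state.bar_pct = 40.0
        for sub in state.submarines:           # park submarines far away
            sub.next_capture_tick = 10 ** 9
        events = []
        for _ in range(41):                    # 4.1 s of round time
            advance(state, None, events)
        regens = [e for e in events if e.event_type == "regen_tick"]
        assert [e.t_global for e in regens] == [2.0, 4.0]
        assert state.bar_pct == 50.0


class TestSubmarines:
    @pytest.mark.parametrize("irt,lo,hi", [(2.0, 2.0, 4.0), (3.5, 2.0, 4.0),
                                           (4.0, 4.0, 6.0), (5.0, 4.0, 6.0),
                                           (6.0, 6.0, 10.0), (8.0, 6.0, 10.0),
                                           (None, 6.0, 10.0)])
    def test_interval_brackets(self, game, rng, irt, lo, hi):
        draws = [sample_submarine_interval(irt, game, rng) for _ in range(50)]
        assert all(lo <= d <= hi for d in draws)

    @given(irt=st.floats(min_value=0.1, max_value=60.0,
                         allow_nan=False, allow_infinity=False))
    def test_every_player_irt_maps_into_a_bracket(self, irt):
        config = GameConfig()
        rng = child_rng(0, 1)
        d = sample_submarine_interval(irt, config, rng)
        brackets = [(lo, hi) for _, lo, hi in config.submarine_irt_brackets]
        assert any(lo <= d <= hi for lo, hi in brackets)

    def test_capture_drains_ten_and_activates_warning(self, game):
        state = fresh(game)
        state.bar_pct = 40.0
        sub = state.submarines[0]
        sub.next_capture_tick = state.play_tick
        state.submarines[1].next_capture_tick = 10 ** 9
        events = []
        submarine_step(state, events)
        assert state.bar_pct == 30.0
        advance(state, None, events)
        assert state.warning_active
        assert any(e.event_type == "warning_on" for e in events)

    def test_capture_then_four_second_wait_before_resampling(self, game):
        state = fresh(game)
        sub = state.submarines[0]
        state.play_tick = 200                      # t = 20 s
        sub.next_capture_tick = 200
        submarine_step(state)
        assert sub.resample_tick == 200 + game.submarine_wait_ticks  # t = 24 s
        state.play_tick = 239
        interval_before = sub.current_interval_s
        submarine_step(state)
        assert sub.current_interval_s == interval_before  # still waiting
        state.play_tick = 240
        state.last_participant_irt = 2.0
        submarine_step(state)
        assert 2.0 <= sub.current_interval_s <= 4.0

    def test_capture_at_five_percent_depletes(self, game):
        state = fresh(game)
        state.bar_pct = 5.0
        state.submarines[0].next_capture_tick = state.play_tick
        submarine_step(state)
        assert state.bar_pct == 0.0
        assert state.outcome == LOST_DEPLETION


class TestAdvance:
    def test_escaped_fish_costs_a_heart(self, game):
        cfg = GameConfig(fish_spawn_interval_s=1.0, fish_transit_s=2.0)
        state = new_game(cfg, 1, seed=5)
        events = []
        while state.hearts == 3 and state.outcome == "in_progress":
            advance(state, None, events)
        assert state.hearts == 2
        assert any(e.event_type == "fish_escape" for e in events)

    def test_three_escapes_lose_the_game(self):
        cfg = GameConfig(fish_spawn_interval_s=1.0, fish_transit_s=2.0)
        state = new_game(cfg, 1, seed=5)
        events = []
        while state.outcome == "in_progress":
            advance(state, None, events)
        assert state.outcome == LOST_ESCAPE
        assert state.hearts == 0
        assert sum(e.event_type == "fish_escape" for e in events) == 3

    def test_ten_clean_rounds_win_the_phase(self, open_water):
        state = new_game(open_water, 1, seed=2)
        agent = ScriptedAgent(5.0, "rod")
        events = run_attempt(state, agent)
        assert state.outcome == WON_PHASE
        assert sum(e.event_type == "round_end" for e in events) == 10
        assert events[-1].event_type == "phase_won"

    def test_advancing_finished_game_is_error(self, open_water):
        state = new_game(open_water, 1, seed=2)
        run_attempt(state, ScriptedAgent(5.0, "rod"))
        with pytest.raises(EngineError):
            advance(state, None)

    def test_warning_flag_tracks_threshold_every_tick(self, open_water):
        state = new_game(open_water, 2, seed=9)
        agent = ScriptedAgent(3.0, "radar")
        while state.outcome == "in_progress":
            advance(state, agent.act(state))
            assert state.warning_active == (
                state.bar_pct <= open_water.warning_threshold_pct)
        assert state.outcome == LOST_DEPLETION


class TestRunPhase:
    def test_no_loss_agent_plays_exactly_ten_rounds(self, open_water):
        events, summary = run_phase(lambda a: ScriptedAgent(4.0, "rod"),
                                    open_water, 1, seed=11)
        assert summary["outcome"] == WON_PHASE
        assert summary["attempts"] == 1
        assert sum(e.event_type == "round_end" for e in events) == 10

    def test_radar_spam_depletes_before_any_win(self, open_water):
        events, summary = run_phase(lambda a: ScriptedAgent(2.0, "radar"),
                                    open_water, 2, seed=11, max_attempts=3)
        assert "lost_depletion" in summary["attempt_outcomes"]
        assert summary["attempt_outcomes"][0] == LOST_DEPLETION

    def test_same_seed_reproduces_identical_event_log(self, open_water):
        logs = []
        for _ in range(2):
            events, _ = run_phase(lambda a: ScriptedAgent(6.0, "rod", alternate=True),
                                  open_water, 2, seed=21)
            logs.append([(e.t_global, e.event_type, e.card, e.points_delta,
                          e.bar_after, e.hearts_after, e.irt_s) for e in events])
        assert logs[0] == logs[1]

    def test_attempt_cap_reports_non_convergence(self, open_water):
        events, summary = run_phase(lambda a: ScriptedAgent(2.0, "radar"),
                                    open_water, 2, seed=3, max_attempts=2)
        assert summary["converged"] is False
        assert summary["attempts"] == 2
        assert len(events) > 0


class TestLedgerAndDrift:
    """Score-conservation and bar-step invariants on seeded runs."""

    def test_score_equals_event_ledger_and_bar_steps_are_legal(self, open_water):
        from fishcards.engine import run_attempt
        for seed in range(5):
            state = new_game(open_water, 2, seed=seed)
            agent = ScriptedAgent(7.0, "rod", alternate=True)
            events = run_attempt(state, agent)
            ledger = sum(e.points_delta for e in events)
            assert state.score == ledger
            bar = open_water.bar_initial_pct
            for e in events:
                if e.event_type == "hit":
                    bar = max(0.0, bar - open_water.card_extraction(e.card))
                elif e.event_type == "submarine_capture":
                    bar = max(0.0, bar - open_water.submarine_extraction_pct)
                elif e.event_type == "regen_tick":
                    bar = min(100.0, bar + open_water.regen_pct)
                if e.bar_after is not None:
                    assert e.bar_after == pytest.approx(bar, abs=1e-9)
                    assert 0.0 <= e.bar_after <= 100.0
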