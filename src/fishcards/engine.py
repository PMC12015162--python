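"""Time-stepped Fishing Cards engine.

The engine plays the two experimental conditions of the task headlessly:

* **Phase 1** — unlimited resources: the player generates rod or radar cards,
  strikes fish, and must complete ten consecutive 40 s rounds without losing
  all three hearts to escaped fish.
* **Phase 2** — limited, shared common-pool resource: a green bar (0–100 %)
  is drained by every hit (rod −5 pp, radar −15 pp) and by two submarines
  (virtual co-harvesters, −10 pp per capture) whose capture intervals track
  the player's own inter-response times, and regenerates +5 pp every 2 s of
  in-round time. The bar reaching 0 % is an immediate depletion loss.

Time is a fixed grid of ``tick_s`` (default 0.1 s) steps; all clocks are
integer tick counters, so replaying a log is exact. The "play clock"
(`play_tick`) advances only during active rounds — the pause between rounds
carries no time — and inter-response times (IRTs) are differences on that
clock, which makes the last-hit-of-round-k to first-hit-of-round-k+1
interval a single IRT, as the task defines it.

Within-tick ordering: (1) fish spawn/escape, (2) regeneration, (3) submarine
captures, (4) the agent's action, (5) warning/round-end/phase-won checks.
Depletion is checked immediately after every extraction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from ._rng import STREAM_FISH, STREAM_SUBMARINES, child_rng
from .config import CARDS, GameConfig

IN_PROGRESS = "in_progress"
WON_PHASE = "won_phase"
LOST_ESCAPE = "lost_escape"
LOST_DEPLETION = "lost_depletion"

EVENT_TYPES = (
    "round_start", "generate_card", "hit", "fish_spawn", "fish_escape",
    "submarine_capture", "regen_tick", "warning_on", "warning_off",
    "cooldown_start", "round_end", "defeat", "phase_won",
)


class EngineError(RuntimeError):
    pass


@dataclass
class EventRecord:
    """One timestamped simulator event (one CSV row)."""
    t_global: float
    phase: int
    round_in_streak: int
    event_type: str
    card: Optional[str] = None
    points_delta: int = 0
    bar_after: Optional[float] = None
    hearts_after: int = 0
    irt_s: Optional[float] = None
    attempt: int = 1


@dataclass
class SubmarineState:
    current_interval_s: float
    next_capture_tick: int
    resample_tick: Optional[int] = None  # set while waiting after a capture
    bracket: tuple[float, float, float] = (np.inf, 6.0, 10.0)


@dataclass
class GameState:
    config: GameConfig
    phase: int
    t_round_tick: int = 0           # ticks elapsed in the current round
    play_tick: int = 0              # cumulative in-round ticks this attempt
    round_in_streak: int = 0        # completed consecutive undefeated rounds
    bar_pct: float = 100.0          # meaningful only in phase 2
    hearts: int = 3
    score: int = 0
    last_panel: Optional[str] = None
    consecutive_clicks: int = 0
    cooldown_until: dict = field(default_factory=dict)  # card -> play_tick
    held_card: Optional[str] = None
    active_fish: deque = field(default_factory=deque)   # (spawn_tick, escape_tick)
    next_spawn_tick: Optional[int] = None
    last_hit_tick: Optional[int] = None
    last_participant_irt: Optional[float] = None
    submarines: list = field(default_factory=list)
    warning_active: bool = False
    outcome: str = IN_PROGRESS
    round_open: bool = False

    @property
    def t_in_round(self) -> float:
        return self.t_round_tick * self.config.tick_s

    @property
    def t_play(self) -> float:
        return self.play_tick * self.config.tick_s

    def card_in_cooldown(self, card: str) -> bool:
        until = self.cooldown_until.get(card)
        return until is not None and self.play_tick < until

    def fish_available(self) -> bool:
        return len(self.active_fish) > 0


def sample_submarine_interval(player_irt: Optional[float], config: GameConfig,
                              rng: np.random.Generator) -> float:
    """Draw a submarine capture interval for the bracket matching ``player_irt``.

    No recorded IRT yet maps to the slowest (last) bracket.
    """
    ub, lo, hi = _bracket_for(player_irt, config)
    return float(rng.uniform(lo, hi))


def _bracket_for(player_irt: Optional[float], config: GameConfig):
    if player_irt is None:
        return config.submarine_irt_brackets[-1]
    for ub, lo, hi in config.submarine_irt_brackets:
        if player_irt < ub:
            return (ub, lo, hi)
    return config.submarine_irt_brackets[-1]


def new_game(config: GameConfig, phase: int, seed: int, *, score: int = 0,
             attempt: int = 1, stream_key: tuple = ()) -> GameState:
    """Create a fresh attempt of the given phase.

    Phase 2 starts with a full bar and ``n_submarines`` submarines in the
    slowest bracket; phase 1 has neither bar nor submarines. ``score`` lets a
    caller carry points in when continuing; attempts normally start at 0.
    """
    if phase not in (1, 2):
        raise EngineError(f"invalid phase {phase!r}")
    state = GameState(config=config, phase=phase, hearts=config.initial_hearts,
                      score=score, bar_pct=config.bar_initial_pct)
    state._attempt = attempt
    state._rng_fish = child_rng(seed, *stream_key, STREAM_FISH, phase, attempt)
    state._rng_subs = child_rng(seed, *stream_key, STREAM_SUBMARINES, phase, attempt)
    if phase == 2:
        for _ in range(config.n_submarines):
            iv = sample_submarine_interval(None, config, state._rng_subs)
            state.submarines.append(SubmarineState(
                current_interval_s=iv,
                next_capture_tick=config._as_ticks(iv),
                bracket=_bracket_for(None, config)))
    state.next_spawn_tick = _draw_spawn_gap(state)
    return state


def _draw_spawn_gap(state: GameState) -> int:
    gap_s = state._rng_fish.exponential(state.config.fish_spawn_interval_s)
    return state.play_tick + max(1, int(round(gap_s / state.config.tick_s)))


def _t(state: GameState) -> float:
    return round(state.play_tick * state.config.tick_s, 1)


def _emit(state: GameState, events: list, event_type: str, **kw) -> EventRecord:
    ev = EventRecord(t_global=_t(state), phase=state.phase,
                     round_in_streak=state.round_in_streak, event_type=event_type,
                     hearts_after=state.hearts,
                     bar_after=round(state.bar_pct, 6) if state.phase == 2 else None,
                     attempt=getattr(state, "_attempt", 1), **kw)
    events.append(ev)
    return ev


def _extract(state: GameState, pct: float) -> bool:
    """Apply an extraction to the bar; return True on depletion loss."""
    state.bar_pct = max(0.0, state.bar_pct - pct)
    if state.bar_pct <= 0.0:
        state.outcome = LOST_DEPLETION
        return True
    return False


def generate_card(state: GameState, card: str, events: Optional[list] = None):
    """Click a panel to generate a card.

    Costs the card's points (rod 1, radar 5; the score has no floor). The
    click that exceeds ``max_consecutive_clicks`` consecutive same-panel
    clicks is itself rejected and starts the cooldown; clicks during an
    active cooldown are rejected with no state change. Returns the event (or
    None for a rejected click).
    """
    if card not in CARDS:
        raise EngineError(f"unknown card {card!r}")
    if not state.round_open:
        raise EngineError("cannot generate a card outside an active round")
    if events is None:
        events = []
    if state.card_in_cooldown(card):
        return None
    if card == state.last_panel:
        if state.consecutive_clicks >= state.config.max_consecutive_clicks:
            state.cooldown_until[card] = state.play_tick + state.config.cooldown_ticks
            state.consecutive_clicks = 0
            state.last_panel = None
            _emit(state, events, "cooldown_start", card=card)
            return None
        state.consecutive_clicks += 1
    else:
        state.last_panel = card
        state.consecutive_clicks = 1
    state.score -= state.config.card_cost(card)
    state.held_card = card
    return _emit(state, events, "generate_card", card=card,
                 points_delta=-state.config.card_cost(card))


def register_hit(state: GameState, card: str, events: Optional[list] = None):
    """Strike the oldest active fish with the held card.

    Earns the card's gain (rod +1, radar +9); in phase 2 the bar drops by the
    card's extraction (rod 5 pp, radar 15 pp) with an immediate depletion
    check. The IRT is the in-round time elapsed since the previous hit of the
    attempt (absent on the first hit).
    """
    if state.held_card != card:
        raise EngineError("no held card of that kind to strike with")
    if not state.active_fish:
        raise EngineError("no fish available to strike")
    if events is None:
        events = []
    state.active_fish.popleft()
    state.held_card = None
    state.score += state.config.card_gain(card)
    irt = None
    if state.last_hit_tick is not None:
        irt = round((state.play_tick - state.last_hit_tick) * state.config.tick_s, 1)
        state.last_participant_irt = irt
    state.last_hit_tick = state.play_tick
    depleted = False
    if state.phase == 2:
        depleted = _extract(state, state.config.card_extraction(card))
    ev = _emit(state, events, "hit", card=card,
               points_delta=state.config.card_gain(card), irt_s=irt)
    if depleted:
        _emit(state, events, "defeat")
    return ev


def regen_tick(state: GameState, events: Optional[list] = None):
    """Periodic +regen_pct growth of the bar, clamped at 100 (phase 2 only)."""
    if state.phase != 2:
        raise EngineError("regeneration only applies in phase 2")
    if events is None:
        events = []
    state.bar_pct = min(100.0, state.bar_pct + state.config.regen_pct)
    return _emit(state, events, "regen_tick")


def submarine_step(state: GameState, events: Optional[list] = None) -> None:
    """Fire any submarine whose capture or re-sampling moment has arrived.

    A capture drains the bar and is followed by a fixed wait, after which the
    submarine re-reads the participant's most recent IRT, samples a fresh
    interval from the matching bracket, and schedules its next capture.
    """
    if events is None:
        events = []
    cfg = state.config
    for sub in state.submarines:
        if sub.resample_tick is not None and state.play_tick >= sub.resample_tick:
            sub.bracket = _bracket_for(state.last_participant_irt, cfg)
            sub.current_interval_s = float(
                state._rng_subs.uniform(sub.bracket[1], sub.bracket[2]))
            sub.next_capture_tick = sub.resample_tick + cfg._as_ticks(sub.current_interval_s)
            sub.resample_tick = None
        if sub.resample_tick is None and state.play_tick >= sub.next_capture_tick:
            depleted = _extract(state, cfg.submarine_extraction_pct)
            _emit(state, events, "submarine_capture")
            sub.resample_tick = state.play_tick + cfg.submarine_wait_ticks
            if depleted:
                _emit(state, events, "defeat")
                return


def _update_warning(state: GameState, events: list) -> None:
    flag = state.phase == 2 and state.bar_pct <= state.config.warning_threshold_pct
    if flag and not state.warning_active:
        state.warning_active = True
        _emit(state, events, "warning_on")
    elif not flag and state.warning_active:
        state.warning_active = False
        _emit(state, events, "warning_off")


def advance(state: GameState, action, events: Optional[list] = None) -> list:
    """Advance the simulation by one tick, applying ``action`` for the agent.

    ``action`` is None (wait), ``("generate", card)`` or ``("strike",)``.
    Returns the events emitted during the tick.
    """
    if state.outcome != IN_PROGRESS:
        raise EngineError("cannot advance a finished game")
    if events is None:
        events = []
    cfg = state.config

    if not state.round_open:
        state.round_open = True
        state.t_round_tick = 0
        _emit(state, events, "round_start")

    state.t_round_tick += 1
    state.play_tick += 1

    # (1) fish spawn / escape: a free-running Poisson-like spawn clock;
    # spawn moments that find the screen at capacity are skipped.
    if state.play_tick >= state.next_spawn_tick:
        if len(state.active_fish) < cfg.max_concurrent_fish:
            state.active_fish.append(
                (state.play_tick, state.play_tick + cfg.fish_transit_ticks))
            _emit(state, events, "fish_spawn")
        state.next_spawn_tick = _draw_spawn_gap(state)
    while state.active_fish and state.play_tick >= state.active_fish[0][1]:
        state.active_fish.popleft()
        state.hearts -= 1
        _emit(state, events, "fish_escape")
        if state.hearts <= 0:
            state.outcome = LOST_ESCAPE
            _emit(state, events, "defeat")
            return events

    # (2) regeneration on in-round time 2, 4, ... s (re-anchored each round)
    if state.phase == 2 and state.t_round_tick % cfg.regen_ticks == 0:
        regen_tick(state, events)

    # (3) submarines
    if state.phase == 2:
        submarine_step(state, events)
        if state.outcome != IN_PROGRESS:
            return events

    # (4) agent action
    if action is not None:
        kind = action[0]
        if kind == "generate":
            generate_card(state, action[1], events)
        elif kind == "strike":
            if state.held_card is not None and state.active_fish:
                register_hit(state, state.held_card, events)
                if state.outcome != IN_PROGRESS:
                    return events
        elif kind != "wait":
            raise EngineError(f"unknown action {action!r}")

    # (5) warning, round end, phase won
    _update_warning(state, events)
    if state.t_round_tick >= cfg.round_ticks:
        state.round_in_streak += 1
        _emit(state, events, "round_end")
        state.round_open = False
        if state.round_in_streak >= cfg.rounds_to_win:
            state.outcome = WON_PHASE
            _emit(state, events, "phase_won")
    return events


def run_attempt(state: GameState, agent, events: Optional[list] = None) -> list:
    """Play one attempt to its outcome, asking ``agent`` for a tick action.

    The agent is called as ``agent.act(state)`` and returns an engine action.
    """
    if events is None:
        events = []
    while state.outcome == IN_PROGRESS:
        advance(state, agent.act(state), events)
    return events


def run_phase(agent_factory: Callable[[int], object], config: GameConfig, phase: int,
              seed: int, *, max_attempts: int = 50) -> tuple[list, dict]:
    """Play a phase with retries until it is won (or the attempt cap is hit).

    Each loss resets the streak: a fresh attempt starts with full hearts and
    a zero score. ``agent_factory(attempt)`` builds the agent for an attempt
    (policies are stateless across attempts apart from their parameters).

    Returns the full annotated event log and a summary dict with the
    outcome, attempt count, per-attempt outcomes, and final score. Exceeding
    the cap is reported as a non-convergent run with the partial log.
    """
    all_events: list = []
    outcomes = []
    offset_ticks = 0
    for attempt in range(1, max_attempts + 1):
        state = new_game(config, phase, seed, attempt=attempt)
        agent = agent_factory(attempt)
        events = run_attempt(state, agent)
        if offset_ticks:
            shift = offset_ticks * config.tick_s
            for ev in events:
                ev.t_global = round(ev.t_global + shift, 1)
        offset_ticks += state.play_tick
        all_events.extend(events)
        outcomes.append(state.outcome)
        if state.outcome == WON_PHASE:
            return all_events, {
                "outcome": WON_PHASE, "attempts": attempt,
                "attempt_outcomes": outcomes, "final_score": state.score,
                "converged": True,
            }
    return all_events, {
        "outcome": "non_convergent", "attempts": max_attempts,
        "attempt_outcomes": outcomes, "final_score": None, "converged": False,
    }


def iter_hits(events: Iterable[EventRecord]):
    for ev in events:
        if ev.event_type == "hit":
            yield ev
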