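"""Parametric participant policies.

A `ParticipantPolicy` stands in for a human player. Its two behavioral
components mirror the quantities the analysis estimates:

* **pace** — waiting times between intended strikes are gamma distributed
  with a phase-specific mean (seconds) scaled by a participant-level
  log-normal intercept and, optionally, response-index-level multipliers
  shared across the cohort;
* **choice** — the radar (high-extraction) card is chosen with probability
  ``invlogit(intercept + participant intercept + index effect
  + [phase 2] * phase2_shift + [phase 2] * resource_slope * bar_pct)``.

The runtime `PolicyAgent` turns a policy into tick-level engine actions: it
waits out the scheduled gap, generates a card, and strikes on the following
tick. The card is drawn exactly once per response, at the moment of
generation, and the agent insists on its drawn card across any cooldown it
meets (switching only when a fish would otherwise escape), so the realized
card stream follows the generative choice law. A fish about to escape is
struck early — policies protect their hearts — so realized IRTs are the
scheduled waits censored by fish availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import CARDS, RADAR, ROD
from .engine import GameState


def _invlogit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@dataclass
class ParticipantPolicy:
    participant_id: str = "P00"
    age_group: str = "adult"                      # {"teen", "adult"}
    irt_mean_s: dict = field(default_factory=lambda: {1: 3.5, 2: 9.0})
    irt_shape: float = 4.0
    choice_intercept: float = 0.0
    choice_phase2_shift: float = 0.0
    choice_resource_slope: float = 0.0            # log-odds per pp of bar (phase 2)
    random_intercept_irt: float = 0.0             # log-scale participant deviation
    random_intercept_choice: float = 0.0          # log-odds participant deviation
    hit_success_prob: float = 1.0
    #: optional cohort-shared response-index effects (log scale / log-odds)
    irt_index_effects: Optional[np.ndarray] = None
    choice_index_effects: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.irt_mean_s.values()) or self.irt_shape <= 0:
            raise ValueError("IRT mean and shape must be positive")
        if not (0.0 <= self.hit_success_prob <= 1.0):
            raise ValueError("hit_success_prob must be in [0, 1]")

    # -- generative primitives ------------------------------------------
    def radar_logit(self, phase: int, bar_pct: Optional[float],
                    index_effect: float = 0.0) -> float:
        eta = self.choice_intercept + self.random_intercept_choice + index_effect
        if phase == 2:
            if bar_pct is None:
                raise ValueError("bar_pct required in phase 2")
            eta += self.choice_phase2_shift + self.choice_resource_slope * bar_pct
        return eta

    def choose_card(self, phase: int, bar_pct: Optional[float],
                    rng: np.random.Generator, index_effect: float = 0.0) -> str:
        """Draw a card: radar with probability invlogit(linear predictor)."""
        p = _invlogit(self.radar_logit(phase, bar_pct, index_effect))
        return RADAR if rng.random() < p else ROD

    def sample_wait(self, phase: int, rng: np.random.Generator,
                    index_effect: float = 0.0) -> float:
        """Gamma waiting time with mean irt_mean_s[phase] * exp(intercepts)."""
        mean = self.irt_mean_s[phase] * np.exp(self.random_intercept_irt + index_effect)
        return float(rng.gamma(self.irt_shape, mean / self.irt_shape))

    def _index_effect(self, which: str, idx: int) -> float:
        arr = self.irt_index_effects if which == "irt" else self.choice_index_effects
        if arr is None or idx >= len(arr):
            return 0.0
        return float(arr[idx])


def choose_card(policy: ParticipantPolicy, phase: int, bar_pct: Optional[float],
                rng: np.random.Generator) -> str:
    """Module-level convenience wrapper over ``policy.choose_card``."""
    return policy.choose_card(phase, bar_pct, rng)


class PolicyAgent:
    """Tick-level actor for a `ParticipantPolicy`.

    ``escape_margin_s`` is how long before a fish's escape deadline the agent
    abandons its schedule and strikes anyway (it needs one tick to generate
    and one to strike).
    """

    def __init__(self, policy: ParticipantPolicy, phase: int,
                 rng: np.random.Generator, *, escape_margin_s: float = 0.4,
                 start_index: int = 0):
        self.policy = policy
        self.phase = phase
        self.rng = rng
        self.escape_margin_s = escape_margin_s
        # cumulative response counter; the offset aligns response-index
        # effects with the recorded per-participant response index
        self.response_count = start_index
        self._next_strike_play_s: Optional[float] = None
        self._swing_at_s: Optional[float] = None
        self._pending_card: Optional[str] = None

    def _schedule(self, now_s: float) -> None:
        wait = self.policy.sample_wait(
            self.phase, self.rng,
            self.policy._index_effect("irt", self.response_count))
        self._next_strike_play_s = now_s + wait

    def act(self, state: GameState):
        now = state.t_play
        if self._next_strike_play_s is None:
            self._schedule(now)
        if state.held_card is not None:
            self._pending_card = None       # generation succeeded
            # card in hand: swing as soon as the swing moment arrives
            if state.active_fish and (self._swing_at_s is None or now >= self._swing_at_s):
                if self.policy.hit_success_prob >= 1.0 or (
                        self.rng.random() < self.policy.hit_success_prob):
                    self.response_count += 1
                    self._swing_at_s = None
                    self._schedule(now)
                    return ("strike",)
                self._swing_at_s = now + 0.5   # missed swing, retry shortly
            return None
        if not state.active_fish:
            return None
        margin = self.escape_margin_s + 2 * state.config.tick_s
        deadline_s = state.active_fish[0][1] * state.config.tick_s
        urgent = now >= deadline_s - margin
        if not (urgent or now >= self._next_strike_play_s):
            return None
        if self._pending_card is None:
            if any(state.card_in_cooldown(c) for c in CARDS) and not urgent:
                # postpone the draw itself while a panel cools, so the draw
                # conditions on the bar level close to the generation moment
                return None
            # exactly one draw per response; the draw is insisted upon even
            # if generating it triggers (or meets) a cooldown, so every draw
            # is eventually realized and the generative choice law survives
            # the click-limit mechanic intact
            self._pending_card = self.policy.choose_card(
                self.phase, state.bar_pct if self.phase == 2 else None, self.rng,
                self.policy._index_effect("choice", self.response_count))
        card = self._pending_card
        if state.card_in_cooldown(card):
            if not urgent:
                return None             # wait for the chosen panel
            card = ROD if card == RADAR else RADAR  # forced switch to save the fish
            if state.card_in_cooldown(card):
                return None
            self._pending_card = None
        self._swing_at_s = None
        return ("generate", card)


class ScriptedAgent:
    """Deterministic fixed-pace agent for engine and sustainability tests.

    Strikes every ``irt_s`` seconds of play time with a fixed card (or an
    alternating pattern), whenever a fish is available.
    """

    def __init__(self, irt_s: float, card: str = ROD, *, alternate: bool = False,
                 substitute: bool = True):
        self.irt_s = irt_s
        self.card = card
        self.alternate = alternate
        self.substitute = substitute   # False: wait out cooldowns instead
        self._next_strike_s = irt_s
        self._pending = False
        self._n = 0

    def act(self, state: GameState):
        if self._pending:
            self._pending = False
            if state.held_card is not None and state.active_fish:
                self._next_strike_s += self.irt_s
                self._n += 1
                return ("strike",)
            return None
        if state.t_play + state.config.tick_s >= self._next_strike_s and state.active_fish:
            card = self.card
            if self.alternate and self._n % 2 == 1:
                card = ROD if card == RADAR else RADAR
            if state.card_in_cooldown(card):
                if not self.substitute:
                    return None
                card = ROD if card == RADAR else RADAR
                if state.card_in_cooldown(card):
                    return None
            self._pending = True
            return ("generate", card)
        return None
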