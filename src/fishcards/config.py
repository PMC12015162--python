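"""Game and cohort configuration.

`GameConfig` carries every mechanic parameter of the Fishing Cards task with
the published defaults: a 40 s round, ten consecutive undefeated rounds to
win, three hearts, rod cost/gain 1/1 and radar cost/gain 5/9 points, bar
extraction of 5/15/10 percentage points for rod/radar/submarine, +5 pp
regeneration every 2 s, warning at 30 %, a cooldown of 8 s after more than
three consecutive same-panel clicks, and two submarines that wait 4 s after
each capture before re-reading the player's latest inter-response time (IRT)
and sampling a new capture interval from the matching bracket.

Fish presentation (spawn interval, transit time, concurrency) is not fixed by
the task description; those are declared design parameters with defaults that
leave moderate-paced players a comfortable no-escape margin.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, fields

import yaml

ROD = "rod"
RADAR = "radar"
CARDS = (ROD, RADAR)

#: (exclusive upper bound on player IRT in s, interval low, interval high)
#: Player IRT below 4 s -> submarine interval drawn uniformly from [2, 4] s;
#: in [4, 6) -> [4, 6]; 6 s and above (or no IRT yet) -> [6, 10].
DEFAULT_SUBMARINE_BRACKETS: tuple[tuple[float, float, float], ...] = (
    (4.0, 2.0, 4.0),
    (6.0, 4.0, 6.0),
    (math.inf, 6.0, 10.0),
)


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass(frozen=True)
class GameConfig:
    round_duration_s: float = 40.0
    rounds_to_win: int = 10
    initial_hearts: int = 3
    rod_cost_pts: int = 1
    rod_gain_pts: int = 1
    radar_cost_pts: int = 5
    radar_gain_pts: int = 9
    rod_extraction_pct: float = 5.0
    radar_extraction_pct: float = 15.0
    submarine_extraction_pct: float = 10.0
    regen_pct: float = 5.0
    regen_period_s: float = 2.0
    bar_initial_pct: float = 100.0
    warning_threshold_pct: float = 30.0
    max_consecutive_clicks: int = 3
    cooldown_s: float = 8.0
    n_submarines: int = 2
    submarine_wait_s: float = 4.0
    submarine_irt_brackets: tuple[tuple[float, float, float], ...] = DEFAULT_SUBMARINE_BRACKETS
    fish_spawn_interval_s: float = 3.0
    fish_transit_s: float = 22.0
    max_concurrent_fish: int = 1
    tick_s: float = 0.1

    def __post_init__(self) -> None:
        durations = {
            "round_duration_s": self.round_duration_s,
            "regen_period_s": self.regen_period_s,
            "cooldown_s": self.cooldown_s,
            "submarine_wait_s": self.submarine_wait_s,
            "fish_spawn_interval_s": self.fish_spawn_interval_s,
            "fish_transit_s": self.fish_transit_s,
            "tick_s": self.tick_s,
        }
        for name, v in durations.items():
            if not (v > 0):
                raise ConfigError(f"{name} must be > 0, got {v}")
        pcts = {
            "rod_extraction_pct": self.rod_extraction_pct,
            "radar_extraction_pct": self.radar_extraction_pct,
            "submarine_extraction_pct": self.submarine_extraction_pct,
            "regen_pct": self.regen_pct,
            "bar_initial_pct": self.bar_initial_pct,
            "warning_threshold_pct": self.warning_threshold_pct,
        }
        for name, v in pcts.items():
            if not (0.0 <= v <= 100.0):
                raise ConfigError(f"{name} must be in [0, 100], got {v}")
        for name in ("rounds_to_win", "initial_hearts", "max_consecutive_clicks",
                     "max_concurrent_fish"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_submarines < 0:
            raise ConfigError("n_submarines must be >= 0")
        brackets = tuple(tuple(float(x) for x in b) for b in self.submarine_irt_brackets)
        if not brackets:
            raise ConfigError("submarine_irt_brackets must be non-empty")
        for ub, lo, hi in brackets:
            if lo > hi:
                raise ConfigError(f"submarine bracket low {lo} exceeds high {hi}")
        if not math.isinf(brackets[-1][0]):
            raise ConfigError("last submarine bracket must be unbounded (upper bound inf/null)")
        object.__setattr__(self, "submarine_irt_brackets", brackets)
        for name in ("regen_period_s", "round_duration_s", "cooldown_s", "submarine_wait_s"):
            if not self._is_tick_multiple(getattr(self, name)):
                raise ConfigError(f"tick_s must divide {name}")

    # -- tick arithmetic -------------------------------------------------
    def _is_tick_multiple(self, seconds: float) -> bool:
        r = seconds / self.tick_s
        return abs(r - round(r)) < 1e-9

    def _as_ticks(self, seconds: float) -> int:
        return int(round(seconds / self.tick_s))

    @property
    def round_ticks(self) -> int:
        return self._as_ticks(self.round_duration_s)

    @property
    def regen_ticks(self) -> int:
        return self._as_ticks(self.regen_period_s)

    @property
    def cooldown_ticks(self) -> int:
        return self._as_ticks(self.cooldown_s)

    @property
    def submarine_wait_ticks(self) -> int:
        return self._as_ticks(self.submarine_wait_s)

    @property
    def fish_transit_ticks(self) -> int:
        return self._as_ticks(self.fish_transit_s)

    def card_cost(self, card: str) -> int:
        return self.rod_cost_pts if card == ROD else self.radar_cost_pts

    def card_gain(self, card: str) -> int:
        return self.rod_gain_pts if card == ROD else self.radar_gain_pts

    def card_extraction(self, card: str) -> float:
        return self.rod_extraction_pct if card == ROD else self.radar_extraction_pct


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    The default cohort mirrors the study composition (12 teenagers, 18
    adults) and encodes the qualitative behavioral structure the task is
    designed to elicit: a slower fishing pace in the limited-resource phase,
    a reduced preference for the high-extraction radar card in that phase
    (more strongly reduced for adults), and a card choice that tracks the
    current resource level (radar more likely when the bar is high).

    IRT waiting times are gamma distributed with a phase-specific mean;
    participant- and response-index-level heterogeneity enter the IRT model
    multiplicatively (log-normal intercepts) and the choice model additively
    on the log-odds scale, matching the crossed random-intercept structure
    assumed by the analysis module.
    """

    n_teens: int = 12
    n_adults: int = 18
    irt_mean_phase1_s: float = 3.5
    irt_mean_phase2_s: float = 9.0
    irt_shape: float = 4.0
    irt_participant_sd: float = 0.15
    irt_index_sd: float = 0.05
    choice_intercept: float = 0.6
    choice_phase2_shift_teen: float = -2.8
    choice_phase2_shift_adult: float = -4.4
    choice_resource_slope: float = 0.02
    choice_participant_sd: float = 0.4
    choice_index_sd: float = 0.2
    hit_success_prob: float = 1.0
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if self.n_teens < 1 or self.n_adults < 1:
            raise ConfigError("cohort group counts must be >= 1")
        for name in ("irt_mean_phase1_s", "irt_mean_phase2_s", "irt_shape"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be > 0")
        for name in ("irt_participant_sd", "irt_index_sd",
                     "choice_participant_sd", "choice_index_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.hit_success_prob <= 1.0):
            raise ConfigError("hit_success_prob must be in [0, 1]")
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")

    @property
    def n_participants(self) -> int:
        return self.n_teens + self.n_adults


def _build(cls, section: dict, name: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown {name} keys: {sorted(unknown)}")
    if cls is GameConfig and "submarine_irt_brackets" in section:
        raw = section["submarine_irt_brackets"]
        section = dict(section)
        section["submarine_irt_brackets"] = tuple(
            (math.inf if b[0] is None else float(b[0]), float(b[1]), float(b[2])) for b in raw
        )
    return cls(**section)


def load_config(path) -> tuple[GameConfig, CohortSpec]:
    """Load a YAML (or JSON) experiment config.

    The file may contain ``game:`` and ``cohort:`` sections; any field left
    out takes its default. An empty file resolves to all defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"game", "cohort"}
    if unknown:
        raise ConfigError(f"unknown top-level config sections: {sorted(unknown)}")
    game = _build(GameConfig, raw.get("game", {}) or {}, "game")
    cohort = _build(CohortSpec, raw.get("cohort", {}) or {}, "cohort")
    return game, cohort


def dump_config(game: GameConfig, cohort: CohortSpec, path) -> None:
    """Write a fully resolved config (round-trips through load_config)."""
    g = asdict(game)
    g["submarine_irt_brackets"] = [
        [None if math.isinf(ub) else ub, lo, hi] for ub, lo, hi in game.submarine_irt_brackets
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"game": g, "cohort": asdict(cohort)}, fh, sort_keys=True)


def config_hash(game: GameConfig, cohort: CohortSpec) -> str:
    """Stable hash of the fully resolved configuration."""
    g = asdict(game)
    g["submarine_irt_brackets"] = [
        ["inf" if math.isinf(ub) else ub, lo, hi] for ub, lo, hi in game.submarine_irt_brackets
    ]
    payload = json.dumps({"game": g, "cohort": asdict(cohort)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
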