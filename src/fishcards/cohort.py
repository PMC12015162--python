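"""Synthetic-experiment generator.

Builds a cohort of participant policies (12 teenagers + 18 adults by
default), runs the full two-phase protocol for each participant — Phase 1 to
completion, then Phase 2 with retries after every loss — and emits an
analysis-ready response-record table.

One row per successful hit: participant, age group, phase, response index
(strictly increasing within a participant across phases and attempts), IRT
in seconds (absent for the first response of a phase attempt), the card
used, and the bar level read at the moment the card was generated (phase 2
only). ``in_analysis_window`` flags the rows the statistical pipeline uses:
the ten winning-streak rounds of each phase's victorious attempt (10 + 10
rounds per participant), so the window never mixes rounds from failed
attempts.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from ._rng import STREAM_AGENT, STREAM_COHORT, child_rng
from .agents import ParticipantPolicy, PolicyAgent
from .config import CohortSpec, GameConfig
from .engine import WON_PHASE, new_game, run_attempt

RECORD_COLUMNS = [
    "participant_id", "age_group", "phase", "response_index", "irt_s",
    "card", "bar_pct_at_choice", "in_analysis_window",
]

#: pre-drawn length of the shared response-index effect series
_MAX_INDEX_EFFECTS = 20000


class NonConvergentParticipant(UserWarning):
    pass


def generate_cohort(spec: CohortSpec, seed: int) -> list[ParticipantPolicy]:
    """Draw one policy per participant from the cohort-level distributions.

    Participant random intercepts are normal with the configured SDs; the
    response-index effect series (one per outcome, shared by the whole
    cohort, as a crossed random factor requires) are drawn once here and
    attached to every policy.
    """
    rng = child_rng(seed, STREAM_COHORT)
    irt_idx = rng.normal(0.0, spec.irt_index_sd, size=_MAX_INDEX_EFFECTS)
    choice_idx = rng.normal(0.0, spec.choice_index_sd, size=_MAX_INDEX_EFFECTS)
    policies = []
    groups = ["teen"] * spec.n_teens + ["adult"] * spec.n_adults
    for i, group in enumerate(groups):
        shift = (spec.choice_phase2_shift_teen if group == "teen"
                 else spec.choice_phase2_shift_adult)
        policies.append(ParticipantPolicy(
            participant_id=f"P{i:02d}",
            age_group=group,
            irt_mean_s={1: spec.irt_mean_phase1_s, 2: spec.irt_mean_phase2_s},
            irt_shape=spec.irt_shape,
            choice_intercept=spec.choice_intercept,
            choice_phase2_shift=shift,
            choice_resource_slope=spec.choice_resource_slope,
            random_intercept_irt=float(rng.normal(0.0, spec.irt_participant_sd)),
            random_intercept_choice=float(rng.normal(0.0, spec.choice_participant_sd)),
            hit_success_prob=spec.hit_success_prob,
            irt_index_effects=irt_idx,
            choice_index_effects=choice_idx,
        ))
    return policies


def _events_to_responses(events, policy, phase, winning_attempt, start_index):
    """Pair each hit with the generation that produced its card."""
    rows = []
    pending = {}  # card kind -> bar at generation
    idx = start_index
    current_attempt = None
    for ev in events:
        if ev.attempt != current_attempt:
            current_attempt = ev.attempt
            pending.clear()
        if ev.event_type == "generate_card":
            pending[ev.card] = ev.bar_after
        elif ev.event_type == "hit":
            idx += 1
            rows.append({
                "participant_id": policy.participant_id,
                "age_group": policy.age_group,
                "phase": phase,
                "response_index": idx,
                "irt_s": np.nan if ev.irt_s is None else ev.irt_s,
                "card": ev.card,
                "bar_pct_at_choice": (pending.get(ev.card, np.nan)
                                      if phase == 2 else np.nan),
                "in_analysis_window": ev.attempt == winning_attempt,
            })
    return rows, idx


def run_participant(policy: ParticipantPolicy, config: GameConfig, seed: int,
                    participant_index: int, *, max_attempts: int = 50):
    """Run both phases for one participant.

    Returns (response rows, event list, info dict). A participant who cannot
    win a phase within ``max_attempts`` is reported as non-convergent; their
    rows carry no analysis window.
    """
    all_rows: list[dict] = []
    all_events = []
    info = {"participant_id": policy.participant_id, "converged": True,
            "attempts": {}, "outcomes": {}}
    response_index = 0
    for phase in (1, 2):
        events = []
        winning_attempt = None
        offset_ticks = 0
        phase_start_index = response_index
        for attempt in range(1, max_attempts + 1):
            rng = child_rng(seed, STREAM_AGENT, participant_index, phase, attempt)
            agent = PolicyAgent(policy, phase, rng, start_index=response_index)
            state = new_game(config, phase, seed, attempt=attempt,
                             stream_key=(participant_index,))
            attempt_events = run_attempt(state, agent)
            if offset_ticks:
                shift = offset_ticks * config.tick_s
                for ev in attempt_events:
                    ev.t_global = round(ev.t_global + shift, 1)
            offset_ticks += state.play_tick
            events.extend(attempt_events)
            response_index = agent.response_count
            if state.outcome == WON_PHASE:
                winning_attempt = attempt
                info["attempts"][phase] = attempt
                info["outcomes"][phase] = WON_PHASE
                break
        else:
            info["converged"] = False
            info["attempts"][phase] = max_attempts
            info["outcomes"][phase] = "non_convergent"
        rows, response_index = _events_to_responses(
            events, policy, phase, winning_attempt, start_index=phase_start_index)
        all_rows.extend(rows)
        all_events.extend((policy.participant_id, policy.age_group, ev)
                          for ev in events)
        if not info["converged"]:
            break
    return all_rows, all_events, info


def run_experiment(policies: list[ParticipantPolicy], config: GameConfig,
                   seed: int, *, max_attempts: int = 50):
    """Run the full protocol for every participant.

    Returns ``(records, events, infos)`` where ``records`` is a DataFrame
    with `RECORD_COLUMNS`, ``events`` a DataFrame of every simulator event
    annotated with participant columns, and ``infos`` the per-participant
    convergence report. Non-convergent participants are excluded from the
    record table with a warning.
    """
    all_rows = []
    event_rows = []
    infos = []
    for i, policy in enumerate(policies):
        rows, events, info = run_participant(policy, config, seed, i,
                                             max_attempts=max_attempts)
        infos.append(info)
        if not info["converged"]:
            warnings.warn(
                f"participant {policy.participant_id} did not complete the "
                f"protocol within {max_attempts} attempts; excluded",
                NonConvergentParticipant)
            continue
        all_rows.extend(rows)
        for pid, group, ev in events:
            event_rows.append({
                "participant_id": pid, "age_group": group,
                "t_global": ev.t_global, "attempt": ev.attempt,
                "phase": ev.phase, "round_in_streak": ev.round_in_streak,
                "event_type": ev.event_type, "card": ev.card,
                "points_delta": ev.points_delta, "bar_after": ev.bar_after,
                "hearts_after": ev.hearts_after, "irt_s": ev.irt_s,
            })
    records = pd.DataFrame(all_rows, columns=RECORD_COLUMNS)
    events_df = pd.DataFrame(event_rows)
    return records, events_df, infos


def generate_records(spec: CohortSpec, config: GameConfig, seed: int) -> pd.DataFrame:
    """Convenience: cohort -> experiment -> response records."""
    policies = generate_cohort(spec, seed)
    records, _, _ = run_experiment(policies, config, seed,
                                   max_attempts=spec.max_attempts)
    return records
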