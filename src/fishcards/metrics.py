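"""Descriptive log-derived measures.

Everything here recomputes quantities from the raw event log alone, which
makes the module double as a consistency oracle for the engine: IRTs are
rebuilt from hit timestamps and round boundaries (in-round time only) and
must match the simulator's logged values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class PhaseSummary:
    participant_id: str
    phase: int
    mean_irt_s: float
    median_irt_s: float
    prop_radar: float            # radar hits / all hits (analysis window)
    prop_radar_generated: float  # radar generations / all generations
    n_responses: int
    n_attempts: int
    depletion_losses: int
    escape_losses: int


def _decisec(t: float) -> int:
    return int(round(t * 10))


def reconstruct_irts(events: pd.DataFrame) -> pd.DataFrame:
    """Recompute IRTs from hit events using cumulative in-round time only.

    ``events`` is an event-log DataFrame (one attempt/phase mix allowed; the
    series is computed independently per participant, phase and attempt).
    The inter-round pause contributes nothing: elapsed time between two hits
    is the sum of their overlap with [round_start, round_end] intervals.
    Returns a DataFrame with the hit rows' identifying columns and the
    recomputed ``irt_s``; a phase-attempt with a single hit yields an empty
    series for that group.
    """
    df = events.copy()
    if "participant_id" not in df.columns:
        df["participant_id"] = "P0"
    if "attempt" not in df.columns:
        df["attempt"] = 1
    out = []
    for (pid, phase, attempt), grp in df.groupby(
            ["participant_id", "phase", "attempt"], sort=False):
        grp = grp.sort_values("t_global", kind="stable")
        # build in-round intervals in deciseconds
        intervals = []
        open_t: Optional[int] = None
        bnd = grp[grp.event_type.isin(("round_start", "round_end", "defeat", "phase_won"))]
        for et, tg in zip(bnd.event_type.to_numpy(), bnd.t_global.to_numpy()):
            if et == "round_start":
                open_t = _decisec(tg)
            elif open_t is not None:
                intervals.append((open_t, _decisec(tg)))
                open_t = None
        if open_t is not None:
            intervals.append((open_t, _decisec(grp.t_global.max())))
        if not intervals:
            continue
        lo = np.array([iv[0] for iv in intervals])
        hi = np.array([iv[1] for iv in intervals])
        cum = np.concatenate([[0], np.cumsum(hi - lo)])  # play time before interval k

        hits = grp[grp.event_type == "hit"]
        if len(hits) < 2:
            continue
        t = np.round(hits.t_global.to_numpy() * 10).astype(np.int64)
        k = np.searchsorted(lo, t, side="right") - 1
        playpos = cum[k] + (t - lo[k])       # cumulative in-round deciseconds
        irts = np.diff(playpos) / 10.0
        for tg, irt in zip(hits.t_global.to_numpy()[1:], irts):
            out.append({
                "participant_id": pid, "phase": phase, "attempt": attempt,
                "t_global": tg, "irt_s": round(float(irt), 1),
            })
    return pd.DataFrame(out, columns=["participant_id", "phase", "attempt",
                                      "t_global", "irt_s"])


def summarize_phase(events: pd.DataFrame) -> pd.DataFrame:
    """Aggregate one `PhaseSummary` row per participant-phase.

    Pace and card proportions are computed over the winning attempt (the
    analysis window); attempt counts and loss tallies cover all attempts.
    Proportions are reported both over hits (successful extractions) and
    over generations, since a game log contains both.
    """
    df = events.copy()
    if "participant_id" not in df.columns:
        df["participant_id"] = "P0"
    if "attempt" not in df.columns:
        df["attempt"] = 1
    rows = []
    for (pid, phase), grp in df.groupby(["participant_id", "phase"], sort=False):
        won = grp[grp.event_type == "phase_won"]
        win_attempt = int(won.attempt.iloc[0]) if len(won) else None
        window = grp[grp.attempt == win_attempt] if win_attempt else grp.iloc[0:0]
        hits = window[window.event_type == "hit"]
        gens = window[window.event_type == "generate_card"]
        irts = hits.irt_s.dropna()
        outcomes = grp[grp.event_type == "defeat"]
        # defeat cause: depletion iff bar_after == 0 on the defeat row
        depletion = int((outcomes.bar_after.fillna(-1) <= 0).sum()) \
            if len(outcomes) else 0
        rows.append(PhaseSummary(
            participant_id=pid, phase=int(phase),
            mean_irt_s=float(irts.mean()) if len(irts) else np.nan,
            median_irt_s=float(irts.median()) if len(irts) else np.nan,
            prop_radar=float((hits.card == "radar").mean()) if len(hits) else np.nan,
            prop_radar_generated=float((gens.card == "radar").mean()) if len(gens) else np.nan,
            n_responses=int(len(hits)),
            n_attempts=int(grp.attempt.max()),
            depletion_losses=depletion,
            escape_losses=int(len(outcomes)) - depletion,
        ).__dict__)
    return pd.DataFrame(rows)
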