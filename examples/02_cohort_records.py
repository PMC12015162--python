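"""Generate a small synthetic cohort and inspect its response records.

Each participant plays Phase 1 (unlimited resources) to completion, then
Phase 2 (limited, shared) with retries after every loss. One row per
successful hit; `in_analysis_window` marks the rows from the winning
attempts that the statistical pipeline analyzes.
"""

from fishcards import CohortSpec, GameConfig, generate_cohort, run_experiment
from fishcards.metrics import summarize_phase

spec = CohortSpec(n_teens=3, n_adults=3)
policies = generate_cohort(spec, seed=11)
records, events, infos = run_experiment(policies, GameConfig(), seed=11)

print(records.head(8).to_string(index=False))
print(f"\n{len(records)} responses from {records.participant_id.nunique()} "
      "participants")

window = records[records.in_analysis_window]
by_phase = window.groupby("phase").agg(
    mean_irt_s=("irt_s", "mean"),
    prop_radar=("card", lambda c: (c == "radar").mean()),
    n=("card", "size"))
print("\nAnalysis-window behavior by phase:")
print(by_phase.round(3).to_string())
print("\nUnder limited shared resources (phase 2) the cohort fishes more "
      "slowly and shifts from the radar card (-15 pp per hit) toward the "
      "rod (-5 pp).")

print("\nPer participant-phase summaries (from the event log):")
print(summarize_phase(events).round(2).to_string(index=False))
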