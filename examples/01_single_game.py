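"""Play single Phase-2 attempts with fixed-pace scripted harvesters.

A slow rod fisher keeps total extraction under the bar's 2.5 pp/s
regeneration and survives; a fast radar fisher overshoots it and depletes
the common pool.
"""

from fishcards import GameConfig
from fishcards.agents import ScriptedAgent
from fishcards.engine import new_game, run_attempt

config = GameConfig(fish_spawn_interval_s=1.0, fish_transit_s=300.0,
                    max_concurrent_fish=3)

for irt, card in [(12.0, "rod"), (3.0, "radar")]:
    state = new_game(config, phase=2, seed=7)
    events = run_attempt(state, ScriptedAgent(irt, card))
    bars = [e.bar_after for e in events if e.bar_after is not None]
    hits = sum(e.event_type == "hit" for e in events)
    print(f"{card} every {irt:4.1f} s -> {state.outcome:15s} "
          f"after {state.t_play:6.1f} s | hits {hits:3d} | score {state.score:4d} "
          f"| bar min {min(bars):5.1f}%")

print("\nOutcome 'won_phase' means ten consecutive 40 s rounds without "
      "depleting the bar or losing all hearts; 'lost_depletion' means the "
      "shared resource hit 0%.")
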