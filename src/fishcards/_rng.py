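"""Named child random streams derived from one root seed.

Every source of randomness in the package (fish spawning, submarine interval
draws, each participant's policy, cohort-level effect draws) gets its own
`numpy` Generator derived from the root seed plus a fixed integer key path.
Adding a participant or re-ordering stages therefore never perturbs another
stream's draws.
"""

from __future__ import annotations

import numpy as np

# fixed stream identifiers; never renumber
STREAM_FISH = 1
STREAM_SUBMARINES = 2
STREAM_AGENT = 3
STREAM_COHORT = 4


def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the child stream addressed by ``key``.

    Parameters
    ----------
    root_seed
        Root seed of the whole run (non-negative integer).
    key
        Fixed integer path, e.g. ``(STREAM_AGENT, participant_index, phase,
        attempt)``.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))
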