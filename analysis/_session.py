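"""The canonical synthetic session shared by the numbered drivers.

30 units with a heterogeneous mix of programmed remap behaviours, three
tilt blocks of 20 laps each, theta LFP, seed 1.  Regenerated
deterministically by each driver (generation takes well under a second)
so the drivers can run independently and in any order.
"""

import numpy as np

from slopecell.synthetic import ScenarioConfig, generate_session, mixed_ensemble

SEED = 1


def make_session():
    config = ScenarioConfig()
    units = mixed_ensemble(30, np.random.default_rng(SEED))
    session, truth = generate_session(config, units, seed=SEED)
    return session, truth
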