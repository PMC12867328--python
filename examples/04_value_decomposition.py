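"""Split a trained agent's value function into its two frame components.

Because Q is linear in the concatenated SR features, V = V_a + V_e holds
exactly: V_a is a smooth allocentric gradient towards the reward, V_e
carries local, heading-dependent penalties around walls and barriers.
"""

import numpy as np

from srnav import (AgentConfig, GeneratorParams, Lesion, PolicyParams,
                   decompose_value, generate_task)
from srnav.runner import make_bundle, prepare_task, run_episode

cfg = AgentConfig()
task = generate_task(GeneratorParams(), np.random.default_rng(1),
                     episodes_per_world=150)
prep = prepare_task(task, cfg)
bundle = make_bundle(prep, cfg, Lesion.FULL)
pol = PolicyParams(cfg.epsilon, cfg.tau)
for ep in range(150):
    start = int(prep.tables[0].free_poses[(11 * ep) % 400])
    run_episode(bundle, 0, start, 42 + ep, pol, cap=2000)

dec = decompose_value(bundle.model, bundle.sr, prep.tables[0])
ok = ~np.isnan(dec.V)
print(f"max |V - (V_a + V_e)| = {np.max(np.abs(dec.V[ok] - (dec.V_a + dec.V_e)[ok]))}")
rx, ry = task.worlds[0].reward_cell
print(f"V_a near reward {dec.V_a_mean[ry - 1, rx - 2]:.3f} vs far corner "
      f"{dec.V_a_mean[16, 0]:.3f} (allocentric gradient)")
cav = sorted(task.worlds[0].cavity_cells)[0]
print(f"direction-averaged V_e inside a barrier cavity {dec.V_e_mean[cav[1]-1, cav[0]-1]:.3f} "
      f"vs open space {np.nanmean(dec.V_e_mean):.3f} (local penalty)")
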