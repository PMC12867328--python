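"""Compare the composite agent against its allocentric-only lesion.

Runs the paired comparison at a small scale (2 task seeds): both agents
see bit-identical worlds, start states and exploration draws.  The
composite agent's egocentric SR transfers local structure (how barriers
look and behave) across world switches, so it relearns faster and gets
trapped less.
"""

from srnav import Lesion
from srnav.protocols import (fast_lesion_protocol, hole_seed_means,
                             post_switch_seed_means)

comp = fast_lesion_protocol(base_seed=0, n_tasks=2,
                            variants=[Lesion.FULL, Lesion.ALLO_ONLY])

for v in (Lesion.FULL, Lesion.ALLO_ONLY):
    steps = post_switch_seed_means(comp, v)
    holes = hole_seed_means(comp, v)
    print(f"{v.value:10s} post-switch counted steps (first 100 episodes, "
          f"worlds 2-5): {steps.mean():6.1f}   hole time: {holes.mean():5.1f}")

print("\nLower is better; 'hole time' counts primitive steps spent inside")
print("a U-barrier cavity. The FULL agent should win on both.")
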