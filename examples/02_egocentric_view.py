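"""Extract an occluded egocentric view and show aliasing.

The agent sees an (H+1) x (2H+1) window aligned with its heading; opaque
cells hide what lies behind them (OCCLUDED), and many poses share the
same view (aliasing) — the basis of egocentric generalisation.
"""

import numpy as np

from srnav import AgentState, GeneratorParams, ego_view, generate_task
from srnav.sr import EgoCodebook, build_world_tables

LABEL = {0: ".", 1: "#", 2: "N", 3: "E", 4: "S", 5: "W", 6: " ", 7: "?"}

task = generate_task(GeneratorParams(), np.random.default_rng(0))
world = task.worlds[0]

# stand south of the first barrier, facing it
b = world.barriers[0]
state = AgentState(b.x + 1, b.y + b.height + 1, 0)  # facing north
view = ego_view(world, state, horizon=3)
print(f"agent at {(state.x, state.y)} facing N; rows = cells ahead:")
for k in range(view.pixels.shape[0] - 1, -1, -1):
    print("  " + "".join(LABEL[int(p)] for p in view.pixels[k]))
print("('#' barrier, '?' occluded, ' ' outside, NESW walls)\n")

codebook = EgoCodebook(horizon=2)
tables = [build_world_tables(w, 2, codebook) for w in task.worlds]
n_poses = sum(int((t.view_of_u >= 0).sum()) for t in tables)
print(f"distinct views across the task (H=2): N_E = {codebook.n_views} "
      f"from {n_poses} poses -> {n_poses / codebook.n_views:.1f}-fold aliasing")
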