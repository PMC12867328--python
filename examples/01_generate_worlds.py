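"""Generate a 5-world task and print its structure.

Each task is a sequence of walled gridworlds with U-shaped barriers and a
reward that alternates between the top-right and bottom-right corners.
The first world's barriers share one orientation; later worlds are
unconstrained.
"""

import numpy as np

from srnav import GeneratorParams, Paradigm, generate_task

CHARS = {0: ".", 1: "#", 2: "=", 3: "|", 4: "=", 5: "|"}

params = GeneratorParams(paradigm=Paradigm.MAIN)
task = generate_task(params, np.random.default_rng(0), episodes_per_world=1000)

for i, world in enumerate(task.worlds):
    print(f"world {i}: reward at {world.reward_cell} "
          f"({world.meta['reward_corner']}), {len(world.barriers)} barriers, "
          f"{world.barrier_pixel_count()} barrier pixels, "
          f"{len(world.cavity_cells)} cavity cells")
print()
w = task.worlds[0]
for y in range(w.height):
    row = "".join("R" if (x, y) == w.reward_cell else CHARS[int(w.cells[y, x])]
                  for x in range(w.width))
    print(row)
print("\n('#' barrier, 'R' reward; '='/'|' walls). The number of barriers")
print("varies because placements respecting the one-cell buffer can fail.")
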