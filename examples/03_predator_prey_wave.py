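"""Predator-prey traveling wave through a maze.

Seeds prey and predator (both at concentration 1) in a zone at the bottom
of the maze, runs the split-operator scheme, and reports how the prey
wave explores the maze: the per-node first-passage map shows the wave
following corridors and splitting at junctions, while the predator front
trails behind and consumes the prey.
"""

from pathlib import Path

import numpy as np

import rdfem
from rdfem import io as rio

mask = rdfem.generate_maze(4, 4, 3, 1, seed=2)
mesh = rdfem.build_mesh(mask, 2)
D, S = rdfem.assemble(mesh)
zone = rdfem.starting_zone(mask, rdfem.ZoneSpec(
    rows=(mask.height - 4, mask.height), cols=(0, 4)))
N0, P0 = rdfem.initialize_fields(mesh, zone)

cfg = rdfem.SimulationConfig(tau=0.01, n_steps=4000, snapshot_stride=100)
result = rdfem.run(mesh, D, S, cfg, N0, P0)

arrival = rdfem.arrival_time_map(result.snapshots, threshold=0.1)
reached = np.isfinite(arrival)
print(f"mesh: {mesh.n_nodes} nodes; simulated {cfg.n_steps} steps "
      f"(t = {cfg.n_steps * cfg.tau:.0f} time units)")
print(f"wave reached {reached.mean() * 100:.1f}% of nodes; "
      f"median arrival step {np.median(arrival[reached]):.0f}")
final = result.final
print(f"final prey range [{final.N.min():.3g}, {final.N.max():.3g}], "
      f"predator range [{final.P.min():.3g}, {final.P.max():.3g}]")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
rio.render_snapshot(mesh, final.N / max(final.N.max(), 1),
                    final.P / max(final.P.max(), 1), out / "wave.png")
print(f"rendered final state to {out / 'wave.png'} "
      "(prey = red channel, predator = blue channel)")
# Behind the front the prey is extinct (consumed); the predator lingers —
# the wave passes through each corridor exactly once.
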