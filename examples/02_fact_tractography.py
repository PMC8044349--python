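"""Toy deterministic tractography and connectome construction.

Tracks streamlines through a two-region synthetic FA/direction field with
the FACT stopping rules (FA < 0.2, turn > 45 degrees), tallies endpoint
pairs into a count matrix, and applies the >3-fiber edge rule.
"""

import numpy as np

from strucnet import (
    DirectionVolume,
    Parcellation,
    ScalarVolume,
    build_connectome,
    count_streamline_edges,
    fact_track,
)

shape = (24, 12, 12)
fa = np.full(shape, 0.7)
fa[:, :2, :] = 0.1  # an isotropic band tracking cannot enter
directions = np.zeros((*shape, 3))
directions[...] = (1.0, 0.0, 0.0)  # a left-right fiber bundle

labels = np.zeros(shape, dtype=np.int32)
labels[:4] = 1   # "left" region
labels[20:] = 2  # "right" region

seeds = [(12.0, y, z) for y in range(4, 10) for z in range(4, 10)]
streams = fact_track(ScalarVolume(fa), DirectionVolume(directions), seeds)
print(f"{len(streams.streamlines)} streamlines; "
      f"termination reasons: {sorted(set(streams.reasons))}")

counts = count_streamline_edges(streams, Parcellation(labels, ("left", "right")))
print("count matrix:\n", counts)

connectome = build_connectome(counts, labels=("left", "right"))
print("adjacency (count > 3):\n", connectome.adjacency)
# Every streamline spans the bundle from the left to the right region, so
# counts[left, right] equals the seed count and far exceeds the edge rule.
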