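"""Generate a two-class synthetic cohort with planted network structure.

Each class has its own community partition of the regions; within a class,
subjects share the planted self-representation matrix up to a +/-10% jitter
and fresh noise.  Fiber counts concentrate on within-community pairs.
"""

import numpy as np

from unibrainnet import PlantedModel, contiguous_blocks, simulate_cohort, write_cohort

n_regions, n_timepoints = 20, 60
models = [
    PlantedModel(n_regions, n_timepoints, rank=4,
                 blocks=contiguous_blocks(n_regions, 2), noise_sd=0.3, seed=11),
    PlantedModel(n_regions, n_timepoints, rank=4,
                 blocks=tuple(tuple(int(i) for i in p) for p in
                              np.array_split(np.roll(np.arange(n_regions), 5), 2)),
                 noise_sd=0.3, seed=12),
]
cohort = simulate_cohort(models, n_per_class=10, seed=42)
manifest = write_cohort(cohort, "scratch/example_cohort")

g = cohort[0].G
within = g[:10, :10][~np.eye(10, dtype=bool)].mean()
between = g[:10, 10:].mean()
print(f"{len(cohort)} subjects written; manifest at {manifest}")
print(f"subject 0: X is {cohort[0].X.shape}, G is {g.shape}")
print(f"mean fiber count within community: {within:.1f}, between: {between:.1f}")
# The within/between contrast is the structural signal the Laplacian
# penalty feeds into network estimation.
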