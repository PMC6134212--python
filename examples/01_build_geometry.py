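"""Build the synthetic helmet, its eight-lobe partition, and the scan grid.

The helmet emulates a 306-channel whole-head system: 102 sites, each with one
magnetometer and two orthogonal planar gradiometers, laid out on a spherical
cap 20 mm above a 75 mm head sphere.  Sensors are partitioned into eight
lobes (frontal/temporal/parietal/occipital x left/right) by site geometry.
"""

import numpy as np

from plsbeam import (HeadSphere, build_helmet_array, build_source_grid,
                     partition_regions, subsample_grid)

sphere = HeadSphere()                       # center (0, 0, 40) mm, radius 75 mm
helmet = build_helmet_array(102, sphere)
partition = partition_regions(helmet, sphere)
grid = build_source_grid(sphere, spacing=10.0, interior_margin=10.0,
                         central_exclusion=25.0)

print(f"helmet: {helmet.n_sites} sites -> {helmet.n_channels} channels")
print("channels per region:")
for region, n in partition.counts.items():
    print(f"  {region:12s} {n}")
print(f"scan grid: {grid.n_points} points at {grid.spacing:.0f} mm spacing")
sub = subsample_grid(grid, 12)
print(f"every 12th point: {len(sub)} scan locations")
# The region counts sum to 306 (all channels labelled exactly once); the grid
# covers the head interior outside a 25 mm core where a spherical conductor
# is magnetically near-silent.
assert sum(partition.counts.values()) == helmet.n_channels
depth = np.linalg.norm(grid.points - sphere.center, axis=1)
print(f"grid depth range: {depth.min():.1f} .. {depth.max():.1f} mm from center")
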