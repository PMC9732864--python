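"""Three lesion-electrode distances for a strip of electrodes.

Builds a spherical cortical surface with a small lesion abutting it,
marches a 1x8 electrode strip away from the lesion, and prints the three
distance models per bipolar channel: the straight line to the lesion edge
(d_edge), to its centre of mass (d_com), and the geodesic route along the
cortex from the COM's surface entry point (d_geo).  Geodesic distances
exceed the straight-line ones because they respect the cortical sheet.
"""

import numpy as np

from ecogdist import (
    bipolar_midpoint,
    construct_array_on_surface,
    euclidean_com_distance,
    euclidean_edge_distance,
    geodesic_distance,
    make_lesion,
    make_surface,
)

surface = make_surface("sphere", min_vertices=2500, radius=65.0)
anchor = surface.nearest_vertex([0.0, 0.0, 65.0])
lesion = make_lesion(surface, volume_target_cm3=2.5, seed=1, anchor_vertex=anchor)

strip = construct_array_on_surface(
    surface, p0_hint=[12.0, 0.0, 64.0], direction_hint=[1.0, 0.0, 0.0],
    n_rows=1, n_cols=8, array_id="strip",
)

print("channel   d_edge   d_com    d_geo   (mm)")
for i in range(7):
    mid = bipolar_midpoint(strip.coordinates[i], strip.coordinates[i + 1])
    d_e = euclidean_edge_distance(mid, lesion)
    d_c = euclidean_com_distance(mid, lesion)
    d_g = geodesic_distance(mid, lesion, surface)
    print(f"e{i+1}-e{i+2}    {d_e:6.1f}  {d_c:6.1f}  {d_g:6.1f}")
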