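"""Compute the 14 spatial measures on a clustered versus a random ROI.

Both maps share the same overall TIL density; they differ only in how the
TIL patches are placed.  Clustered placement raises Ripley's L at the search
radius and Moran's I, and lowers spatial chaos — the orderings the survival
analysis ultimately exploits.
"""

import tilscape as ts

common = dict(height=100, width=100, n_fragments=1, fragment_radius=40,
              til_density=0.08, n_artifact_lines=0, speckle_count=0)

rows = {}
for label, spec in (
    ("clustered", ts.MapSpec(clustering="clustered", cluster_parent_rate=12,
                             cluster_radius=6, seed=0, **common)),
    ("random", ts.MapSpec(clustering="csr", seed=0, **common)),
):
    tmap, _ = ts.generate_til_map(spec)
    # score the whole map as one region so the two patterns stay comparable
    roi = ts.ROI(grid=tmap.grid, offset=(0, 0), parent_map_id=label, roi_index=0)
    rows[label] = ts.compute_measures(roi, radius=10, ap_max_points=1000, seed=1)

header = f"{'measure':26s} {'clustered':>12s} {'random':>12s}"
print(header)
print("-" * len(header))
for name in ts.ALL_COLUMNS:
    print(f"{name:26s} {rows['clustered'][name]:12.4f} {rows['random'][name]:12.4f}")

print()
print("Ripley L and Moran's I are higher for the clustered pattern; spatial")
print("chaos is lower — coherent aggregates give contiguous edges.")
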