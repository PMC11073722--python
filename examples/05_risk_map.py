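"""Risk indices over a synthetic latitudinal climate gradient.

Builds monthly climate normals running from a hot equator to a cold
high latitude, computes per-pixel ERI (establishment), GI (generations
per year) and AI (activity), classifies them and accounts class areas.
"""

import numpy as np

from fawphen import classify_and_area, generate_climate_raster, map_indices, reference_model

model = reference_model()
grid = generate_climate_raster(
    shape=(12, 3), lat_range=(0.0, 60.0), lon_range=(0.0, 6.0),
    mean_at_equator=38.0, gradient_per_degree=-0.5,
    seasonal_amplitude=3.0, seed=1,
)
surface = map_indices(model, grid)

lats = grid.spec.lat_centers()
print(f"{'lat (deg)':>10} {'tmean (C)':>10} {'ERI':>6} {'GI':>7} {'AI':>8}")
tmean = 0.5 * (grid.tmin + grid.tmax).mean(axis=0)
for i in range(grid.spec.nrows):
    print(f"{lats[i]:10.1f} {tmean[i, 0]:10.1f} {surface.eri[i, 0]:6.3f} "
          f"{surface.gi[i, 0]:7.2f} {surface.ai[i, 0]:8.1f}")

print("\nAll three indices peak in the warm-but-not-hot band and fall off "
      "toward both the overheated equator and the cold high latitudes — "
      "the equatorial-belt pattern of pest risk.")

areas = classify_and_area(surface)
print("\nclass areas (km^2):")
print(areas.to_string(index=False))
total = areas.groupby("index")["area_km2"].sum()
print("\nPer-index totals agree"
      f" ({', '.join(f'{k}: {v:,.0f}' for k, v in total.items())}):"
      " classification conserves the mapped area.")
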