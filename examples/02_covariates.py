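"""Station covariates: canopy closure and village kernel density.

Canopy closure is the vegetation fraction of binarized upward photographs
averaged over a station's five photos; village density is an unnormalized
quartic-kernel density of village points with a 15 km radius. Both are
z-scored per landscape before entering the occupancy model.
"""

import numpy as np

from defaunation import normalize, station_canopy, village_density

# five synthetic binarized canopy photos (0 = vegetation, 255 = sky)
rng = np.random.default_rng(42)
photos = [(rng.random((120, 120)) > frac).astype(np.uint8) * 255
          for frac in (0.92, 0.88, 0.95, 0.85, 0.90)]
canopy = station_canopy(photos)
print(f"mean canopy closure over 5 photos: {canopy:.3f} "
      "(fraction of sky obscured by vegetation)")

# three stations on a 2.5 km grid, two villages nearby (meters)
stations = np.array([[500_000.0, 500_000.0],
                     [502_500.0, 500_000.0],
                     [505_000.0, 500_000.0]])
villages = np.array([[498_000.0, 501_000.0],
                     [510_000.0, 500_000.0]])
dens = village_density(stations, villages, radius=15_000.0)
for i, v in enumerate(dens):
    print(f"station {i}: village density {v:.3f} (unitless; higher = "
          "closer to more villages)")

z = normalize(dens)
print("z-scored within the landscape:", np.round(z, 3),
      "(mean 0, sd 1 — the scale the model sees)")
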