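"""Fit the six parametric maps of a phantom by dictionary matching.

A dictionary of simulated curves over the coarse parameter grid is matched
voxel-wise (minimal L2 after a closed-form amplitude fit).  With on-grid
ground truth and no noise the recovery is exact; at SNR 20 the aggregation
rates remain identifiable while the exchange rates are not (the
compartments equilibrate faster than the 162-s frame spacing can sample).
"""

import numpy as np

from placentadce import (
    AcquisitionProtocol,
    ParameterGrid,
    PhantomConfig,
    Relaxivity,
    fit_volume,
    generate_phantom,
    phase_maps_volume,
    summarize_maps,
)

grid = ParameterGrid.coarse()
print(f"coarse dictionary: {grid.n_entries} entries "
      f"(default grid: {ParameterGrid.default().n_entries})")

protocol, rel = AcquisitionProtocol(), Relaxivity()
cfg = PhantomConfig(seed=1, snap_grid=grid)
series, truth = generate_phantom(cfg, protocol, rel)
mask = truth.placenta_mask

maps = fit_volume(series, mask, phase_maps_volume(series, mask), grid, protocol, rel)

def one_step(fitted, tru, gv):
    gv = np.asarray(gv)
    fi = np.argmin(np.abs(fitted[:, None] - gv[None, :]), axis=1)
    ti = np.argmin(np.abs(tru[:, None] - gv[None, :]), axis=1)
    return (np.abs(fi - ti) <= 1).mean()

print(f"\nrecovery within one grid step over {int(mask.sum())} voxels at SNR 20:")
for name in ("k12", "k23", "r2agg_elevation", "r2agg_reduction", "r2agg_recovery"):
    frac = one_step(maps.as_dict()[name][mask], getattr(truth, name)[mask],
                    getattr(grid, name))
    print(f"  {name:18s} {frac:6.1%}")
print("-> the aggregation (T2*) rates dominate the signal and recover almost"
      "\n   perfectly; the exchange rates saturate before the first frame and"
      "\n   are only weakly identifiable at this frame rate")

print("\nper-zone mean fitted reduction-phase T2* (ms):")
df = summarize_maps(maps, truth.zones, names={1: "decidua", 2: "junctional", 3: "labyrinth"})
red = df[df["parameter"] == "r2agg_reduction"]
for _, row in red.iterrows():
    print(f"  {row['roi']:12s} {1000.0 / row['mean']:.2f}")
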