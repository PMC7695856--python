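"""Generate a DCE phantom and map aggregate formation/clearance frames.

The phantom programs formation to propagate outward-in (decidua ->
junctional zone -> labyrinth) and clearance in the reverse direction; the
per-voxel detector recovers those transition frames from the noisy signal
alone.
"""

import numpy as np

from placentadce import PhantomConfig, generate_phantom, phase_maps_volume
from placentadce.synthetic import DECIDUA, JUNCTIONAL, LABYRINTH

cfg = PhantomConfig(seed=1)  # 48 x 48 x 4, SNR 20
series, truth = generate_phantom(cfg)
mask = truth.placenta_mask
print(f"phantom: {series.shape}, {int(mask.sum())} placental voxels, SNR {cfg.snr}")

maps = phase_maps_volume(series, mask)
exact_tf = (maps.t_formation[mask] == truth.t_formation[mask]).mean()
exact_tc = (maps.t_clearance[mask] == truth.t_clearance[mask]).mean()
print(f"formation frame exactly recovered in {exact_tf:.1%} of voxels")
print(f"clearance frame exactly recovered in {exact_tc:.1%} of voxels\n")

print("zone          median detected t_formation   t_clearance")
for name, z in (("decidua", DECIDUA), ("junctional", JUNCTIONAL), ("labyrinth", LABYRINTH)):
    zm = (truth.zones == z) & (maps.t_formation >= 0)
    print(
        f"{name:12s}  {np.median(maps.t_formation[zm]):10.0f} "
        f"{np.median(maps.t_clearance[zm]):22.0f}"
    )
print(
    "-> attenuation starts at the decidua and reaches the labyrinth last;\n"
    "   recovery propagates back from the labyrinth, as programmed"
)
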