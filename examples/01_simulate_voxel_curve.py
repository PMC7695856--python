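"""Simulate the three-phase dynamic signal of a single placental voxel.

A voxel with the reported mean kinetics (k12 = 0.045 s^-1, k23 = 0.059
s^-1, C2 fraction 0.75) fills with contrast from the constant arterial
pool, then transporter-driven aggregation collapses the signal through
its T2* effect between frames 5 and 11, after which clearance restores
most of it.
"""

import numpy as np

from placentadce import (
    AcquisitionProtocol,
    AggregationSchedule,
    KineticParams,
    Relaxivity,
    VoxelModel,
    simulate_voxel,
    solve_compartments,
)

protocol = AcquisitionProtocol()  # 20 frames / 54 min, TR 10 ms, TE 3 ms, 15 deg
rel = Relaxivity()  # r1 = 120, r2 = 17 s^-1 mM^-1

kin = KineticParams(k12=0.045, k23=0.059, c1=0.104)
cc = solve_compartments(kin, protocol.times)
print("concentrations at the first three frame centres (mM):")
for t, c2, c3 in zip(protocol.times[:3], cc.c2[:3], cc.c3[:3]):
    print(f"  t = {t:6.0f} s   c2 = {c2:.4f}   c3 = {c3:.4f}")
print("-> both compartments approach the arterial 0.104 mM within ~2 frames\n")

vm = VoxelModel(
    kinetics=kin,
    aggregation=AggregationSchedule(
        r2agg_elevation=1000 / 63.3,   # T2* 63.3 ms during elevation
        r2agg_reduction=1000 / 2.7,    # T2*  2.7 ms during reduction
        r2agg_recovery=1000 / 13.6,    # T2* 13.6 ms during recovery
        t_formation=5, t_clearance=11,
    ),
    v23=0.75, m0=1000.0,
)
curve = simulate_voxel(vm, protocol, rel)
print("frame  time_min  signal (a.u.)")
for n, (t, s) in enumerate(zip(curve.frame_times, curve.values)):
    phase = "elevation" if n < 5 else ("reduction" if n < 11 else "recovery")
    print(f"{n:5d}  {t / 60:8.1f}  {s:10.2f}   {phase}")
print(
    f"\nthe signal drops to {curve.values[5] / curve.values[4]:.0%} of its "
    f"pre-formation level at frame 5 and recovers to "
    f"{curve.values[-1] / curve.values[4]:.0%} by the end"
)
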