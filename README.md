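# placentadce

Sub-voxel three-compartment modelling of dynamic contrast-enhanced (DCE)
MRI of the murine placenta, built around a transporter-kinetics signal
model: a biotinylated albumin–GdDTPA contrast agent perfuses the placenta,
is taken up by trophoblast cells through biotin transporters, aggregates —
collapsing the signal through a strong T2\* effect — and is later cleared.
The package simulates this signal, detects the aggregation phases, fits
six parametric maps by dictionary matching, and quantifies fluorescently
labelled aggregates in histology sections.  It is aimed at preclinical MR
physicists and placental biologists who want to model, simulate or re-fit
this class of experiment.

## Model

Per voxel, two sub-voxel compartments — maternal intravascular space C2
(volume fraction V₂₃) and trophoblast cells C3 — exchange contrast with a
constant arterial pool C1:

    ċ₂ = k₁₂ (c₁ − c₂) − k₂₃ (c₂ − c₃)
    ċ₃ = k₂₃ (c₂ − c₃)

solved in closed form.  Concentrations set relaxation rates
(R₁ = 120·c, R₂ = 17·c s⁻¹ per mM) in the spoiled-GRE steady-state signal

    S(n) = M₀ sinθ (1 − e^(−TR·R₁)) / (1 − cosθ·e^(−TR·R₁)) · e^(−TE·R₂*) · e^(−TE·R₂,Agg*(n))

where the aggregate term R₂,Agg\* switches between three per-phase values
at the formation and clearance frames.  Fitting matches each voxel's
20-frame curve against a dictionary of ~166,000 simulated curves (minimal
L2 norm, closed-form amplitude), yielding maps of k₁₂, k₂₃, V₂₃ and the
three phase T2\* values, plus the T_formation/T_clearance transition maps
from a per-voxel change detector.  See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
from placentadce import (AcquisitionProtocol, ParameterGrid, PhantomConfig,
                         Relaxivity, fit_volume, generate_phantom,
                         phase_maps_volume)

grid = ParameterGrid.coarse()
series, truth = generate_phantom(PhantomConfig(seed=1, snap_grid=grid))
maps = fit_volume(series, truth.placenta_mask,
                  phase_maps_volume(series, truth.placenta_mask),
                  grid, AcquisitionProtocol(), Relaxivity())
```

Running `python examples/03_dictionary_fitting.py` (which executes exactly
this) prints:

```
recovery within one grid step over 5264 voxels at SNR 20:
  k12                 63.3%
  k23                 26.8%
  r2agg_elevation     94.0%
  r2agg_reduction    100.0%
  r2agg_recovery      89.4%

per-zone mean fitted reduction-phase T2* (ms):
  decidua      2.76
  junctional   2.80
  labyrinth    2.87
```

The aggregation rates — the quantities that switch the signal off and on —
are recovered almost perfectly (fitted reduction-phase T2\* ≈ 2.8 ms
against a ground-truth mean of 2.7 ms), while the exchange rates are only
weakly identifiable at this frame rate: at k ≈ 0.05 s⁻¹ the compartments
equilibrate before the first 162-s frame, so their recovery percentages
are noise-bound.  `examples/01`–`04` walk through the forward model, phase
mapping, fitting and histology one capability at a time.

The same pipeline is scriptable from the shell:

```bash
placentadce --output-dir out simulate --seed 1
placentadce --output-dir out detect-phases out/phantom.nii.gz out/phantom_zones.nii.gz
placentadce --output-dir out fit out/phantom.nii.gz out/phantom_zones.nii.gz \
    out/phases_t_formation.nii.gz out/phases_t_clearance.nii.gz --grid-preset coarse
placentadce --output-dir out histology green.tif blue.tif --pixel-size-um 1.0
```

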