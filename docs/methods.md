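# Methods

## The model

A placental voxel is modelled as a mixture of two sub-voxel compartments —
the maternal intravascular space C2 (volume fraction `v23`) and the
trophoblast-cell compartment C3 (fraction `1 − v23`) — both fed from a
maternal arterial pool C1 that holds a constant concentration `c1` of a
macromolecular Gd contrast agent (the agent does not cross the placental
barrier, so no fetal compartment exists).  Exchange is first-order and
unidirectional in its driving differences:

    dc2/dt = k12 (c1 − c2) − k23 (c2 − c3)
    dc3/dt = k23 (c2 − c3)

with `k12` the perfusion-driven delivery rate into C2 and `k23` the
transporter-mediated uptake rate into C3 (both s⁻¹).  The system is linear
with constant input, so it is solved in closed form: the 2×2 system matrix
`A = [[−(k12+k23), k23], [k23, −k23]]` has eigenvalues
`λ± = (−(k12+2k23) ± √(k12²+4k23²))/2`, both real and negative whenever
both rates are positive, and the fixed point is `c2 = c3 = c1`.  Degenerate
cases (`k12 = 0` or `k23 = 0`) reduce to scalar exponentials and are handled
by explicit branches.  The closed form is verified against an independent
adaptive Runge–Kutta integration to better than 1 part in 10⁶ over the full
acquisition window.

Soluble agent shortens relaxation times linearly with concentration,
`R1 = r1·c` and `R2 = r2·c`, with relaxivities `r1 = 120` and
`r2 = 17 s⁻¹ mM⁻¹`.  Configurable tissue baselines (defaults
`R1 = 0.5 s⁻¹`, `R2* = 30 s⁻¹`, typical of high-field tissue) are added so
the pre-contrast signal is finite; whether the original analysis included
such baselines is not documented, so they are exposed as config keys.

The measured signal follows the steady-state spoiled gradient-echo
expression with the standard negative exponents,

    S = M0 sinθ (1 − e^(−TR·R1)) / (1 − cosθ e^(−TR·R1)) · e^(−TE·R2*),

(the source prints the TR·R1 exponents with a positive sign, which
diverges; the standard form is used).  Transporter-driven aggregation of
the agent adds a phase-dependent effective transverse rate `R2*_Agg` —
up to two orders of magnitude stronger than the soluble-Gd effect — as an
extra factor `e^(−TE·R2*_Agg(n))`.  One rate applies per kinetic phase:
elevation before the formation frame `t_formation`, reduction in
`[t_formation, t_clearance)`, recovery afterwards.  Because the fitted
model carries a single aggregate rate per phase, the factor is applied
voxel-wide, multiplying both sub-compartment signals; the voxel signal is
the volume-weighted mixture `v23·S_C2 + (1−v23)·S_C3` sharing one `M0`.

Concentrations are treated as stepwise-constant within each dynamic frame
and evaluated at the frame-centre times.  The default protocol is 20
frames spanning 54 min (162 s per frame); TR = 10 ms, TE = 3 ms and a 15°
flip angle are typical preclinical 3D-GRE values, configurable because the
actual sequence timings are not documented.  All rates are carried in s⁻¹
and times in seconds internally; T2* maps are additionally exported in ms
(`T2* = 1000/rate`).

The default arterial concentration is 0.104 mM.  Two inconsistent values
circulate for this quantity (a "≈100 mM" estimate and a measured
104 µM ± 12 SD); the measured value is adopted — 100 mM of an albumin-bound
Gd conjugate in blood is not physically plausible — and it is a config key.

## Phase detection

The transition frames are defined operationally on each voxel's curve.
The curve is smoothed with a centred moving average (window 3,
edge-truncated).  Formation is the first frame whose smoothed value falls
more than δ below the running maximum so far, with the next frame not
exceeding that maximum; clearance is the first later frame starting two
consecutive smoothed increases, each exceeding `min_rise_frac` of the
running maximum.  Candidates found on the smoothed curve are snapped onto
the raw curve within half a smoothing window, because a 3-frame average
leaks a sharp drop into the preceding frame; without the snap, detection
is systematically one frame early.  The rise threshold exists because the
compartments keep enhancing slowly inside the reduction window, so a bare
"two increases" rule would fire immediately after the drop even on
noise-free curves.

Both thresholds are relative, making detection invariant to amplitude
scaling.  Defaults: δ = 0.20 and `min_rise_frac` = 0.08.  δ sits between
the two regimes it must separate: at a voxel SNR of 20, the smoothed curve
fluctuates with σ ≈ 2.9% of its level and the running maximum of ~19 noisy
samples is biased about +1.9σ, so a 10% criterion is only a ~1.7σ event
(it false-triggers on ~18% of aggregation-free voxels), while every
genuine reduction drop under the physiological rate ranges (reduction rate
≥ 169 s⁻¹ against elevation ≤ 80 s⁻¹ at TE = 3 ms) is at least 23%.  The
rise threshold is ~2.5σ of the smoothed-difference noise at the same
nominal SNR.  Clearance recovery is exact when the clearance jump exceeds
the rise threshold (it is a ≥ 2× jump at the reported phase T2* values);
voxels whose reduction and recovery rates nearly coincide have no
detectable clearance in principle and report the sentinel.  Voxels whose
mean signal falls below a configurable floor are excluded.

## Dictionary fitting

The six unknowns per voxel — `k12`, `k23`, `v23` and the three phase
aggregate rates — are estimated by exhaustive search over a precomputed
dictionary of simulated curves.  The default grid uses 10 log-spaced
values for each exchange rate (`k12` ∈ [0.005, 0.20], `k23` ∈
[0.005, 0.25] s⁻¹), five `v23` levels, 5 log-spaced elevation rates in
[5, 80] s⁻¹, 17 reduction rates in [50, 1000] s⁻¹ and 5 recovery rates in
[10, 300] s⁻¹, bracketing the reported parameter means.  A physical
ordering filter keeps only combinations where the reduction rate exceeds
both other rates (the reduction phase is by definition the most
attenuated), pruning 212,500 combinations to 166,000 dictionary rows; a
`prune=False` flag disables it.  A coarse preset (~7,700 rows) serves fast
volume fitting.  Grid resolution is this package's calibration — how the
original ~170,000 entries were distributed is not documented.

Matching minimises `‖s − a·d‖₂` over rows `d` with the nonnegative
amplitude fitted in closed form, `a* = max(⟨s,d⟩,0)/⟨d,d⟩`, so `M0` is a
nuisance parameter and matching is invariant to positive rescaling.  Ties
go to the lowest row index.  The winning residual is recomputed directly
as `‖s − a·d‖` rather than from the expanded quadratic, which suffers
catastrophic cancellation near perfect matches (the expanded form bottoms
out around 10⁻⁸ relative; the direct form reaches machine precision).
Phase boundaries are inputs from phase detection, not grid dimensions:
volume fitting groups voxels by their detected `(t_formation, t_clearance)`
pair and builds one cached dictionary per distinct pair.  Voxels with no
detected formation are fitted against a dictionary whose aggregation
dimensions are collapsed to zero.

### Identifiability

At the reported exchange rates (~0.05 s⁻¹) the compartments equilibrate
with time constants of 22–105 s, while the frame schedule samples every
162 s: C2 reaches 97% of its plateau before the first frame centre.  The
curve shape therefore carries almost no information about `k12` and `k23`,
and at SNR 20 even matching pure dictionary rows corrupted by noise
recovers `k23` within one grid step only ~40% of the time.  The
aggregation rates, which control large per-phase signal factors, recover
within one grid step in ≳90–100% of voxels, and noise-free on-grid
recovery of all six parameters is exact (relative residual ~10⁻¹⁵).  This
is an intrinsic limit of the model-plus-protocol combination, not of the
search: resolving exchange rates of this magnitude would need
second-scale, not minute-scale, sampling.

## Histology pipeline

The Fiji-style quantification is reproduced as composable functions.
Nuclei: difference-of-Gaussians band-pass (σ = 1 and 15 px), Rényi-entropy
auto-threshold, removal of specks below 16 px (sub-nuclear size), hole
filling, then a marker watershed on the (lightly smoothed) distance
transform whose ridge lines are cut from the mask so touching nuclei
separate.  Aggregates: Kapur maximum-entropy threshold on the green
channel, nuclei pixels excluded, 8-connected labelling, objects below
5 µm² dropped, per-object area/perimeter/equivalent-diameter records.
Size classes partition on the equivalent circular diameter: small < 50 µm,
medium 50–500 µm (boundary values fold into medium), large > 500 µm.
Whole placenta: per-channel min–max rescale to 8-bit, channel average,
Gaussian blur (σ = 10 px), mean-intensity threshold, morphological closing
(disk radius 5) and hole filling.  Statistics normalise counts and areas
by the placental area.

The entropy thresholds are computed from 256-bin histograms (first
maximising bin wins, following the ImageJ convention); the Rényi criterion
maximises the summed order-α class entropies with α = 2 by default, and
the Kapur threshold is its Shannon limit (α → 1).  The three-α weighting
scheme some ImageJ plugins layer on top is not reproduced.  A practical
caveat verified during development: with strongly imbalanced classes these
criteria cut into the upper tail of the background mode — a property of
the criteria themselves, visible on any sparse-foreground image — which is
why the aggregate filter at 5 µm² matters and why band-pass σ values are
exposed as parameters.

## Synthetic data

The DCE phantom (default 48×48×4 voxels) lays out, in every slice, a
central maternal-canal disk carrying the constant arterial signal inside
three concentric placental rings: labyrinth (innermost), junctional zone,
decidua (outermost).  Placental voxels draw ground truth from truncated
normals around the reported values — `k12` = 0.045 ± 0.034 s⁻¹,
`k23` = 0.059 ± 0.035 s⁻¹, `v23` = 0.75 ± 0.25, phase T2* of 63.3 ± 39.7,
2.7 ± 1.6 and 13.6 ± 10.0 ms — truncated at 2 SD and clipped to the
default grid ranges so recovery experiments are well posed; sampled
recovery/elevation rates are capped at 0.9× the reduction rate to respect
the phase ordering.  An optional `snap_grid` projects the truth onto a
fitting grid for on-grid recovery experiments.  Phase boundaries are
programmed as zone-wise frame offsets (formation at frames 5/6/7 for
decidua/junctional/labyrinth, clearance at 13/12/11), emulating the
observed outward-in formation and inward-out clearance without a fluid
model.  Noise is Rician on the magnitude signal: SNR is defined as the
noise-free mean signal over perfused tissue divided by the Gaussian σ of
the underlying channels (default 20; `inf` disables noise).  Noise-free
phantom curves equal the forward model bit for bit — the generator and
`simulate_voxel` share one code path.

The competition phantom emulates transporter pre-saturation with native
biotin: all aggregation rates are zero (no signal dip; sentinel phase
maps) and `k23` is scaled by a suppression factor (default 0.3).  It
consumes the random stream identically to the contrast phantom, so paired
runs share sampling and noise draws.  One caveat: with a constant arterial
input and fast equilibration, suppressing `k23` cannot lower the
late-time plateau, so the competition curve's peak is not below the
contrast curve's peak as observed in vivo — the in-vivo difference
reflects reduced accumulation that a constant-`c1` model cannot express
through `k23` alone.

Fluorescence fixtures render, at 1 µm/px, an elliptical tissue region
covering about half the 512² field (so the mean-intensity placenta
threshold sits at the half-height of the blurred boundary and its area
bias is negligible), Poisson-placed nuclei disks in the blue channel and
aggregate disks in the green channel with per-phase counts and radii that
reproduce the reported coverage ordering (reduction ≈ 6.6% > recovery ≈
2.5% > elevation ≈ 1.6%).  Channels carry per-pixel texture and per-disk
brightness variation — with perfectly uniform levels the entropy
thresholds degenerate, a regime real images never exhibit.  Aggregates are
mutually separated and clear of nuclei and of the tissue boundary, so the
truth tables guarantee exact count recovery.  What the fixtures do not
emulate: out-of-focus light, uneven illumination, touching or irregular
aggregates, section artefacts — passing pipelines here demonstrates the
bookkeeping and thresholds, not robustness to real microscopy.

## Problem sizes and numerical choices

The shipped experiments use the 48×48×4 phantom (~5,300 placental voxels)
with the ~7,700-row coarse dictionary, a 1,000-row dictionary for
exhaustive self-matching, 100 parameter sets for the ODE oracle and 512²
(class fixture: ~1,800²) histology images; these run end to end in well
under a minute each.  Dictionary capacity is capped at 2×10⁶ rows with an
explicit error advising a coarser grid.  Matching is chunked (128 voxels
at a time) to bound memory.  All randomness flows through
`numpy.random.default_rng` seeds carried in config objects; identical
(config, seed) reproduce phantoms, maps and tables byte for byte.

## Known limitations

- Exchange-rate maps at the reported rate scale are noise-dominated under
  the 162-s frame schedule (see Identifiability); the aggregation maps
  are the robust product.
- No sub-frame (continuous-time) transition estimation, no spatial
  regularisation of phase or parameter maps, no gradient-based refinement
  off the grid.
- The arterial input is constant; bolus dispersion and wash-in within C1
  are not modelled.
- Histology operates on single 2-D sections; no 3-D stacks, registration
  or co-localisation analysis.
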