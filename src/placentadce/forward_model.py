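"""Forward signal model: compartment exchange ODEs and spoiled-GRE synthesis.

The placenta is modelled as three sub-voxel compartments: a maternal arterial
pool C1 holding a constant agent concentration ``c1``, a maternal
intravascular compartment C2 and a trophoblast-cell compartment C3, coupled
by unidirectional exchange rates ``k12`` (C1 -> C2) and ``k23`` (C2 -> C3)::

    dc2/dt = k12 (c1 - c2) - k23 (c2 - c3)
    dc3/dt = k23 (c2 - c3)

This linear system is solved in closed form by eigen-decomposition of the
2x2 system matrix.  Soluble agent shortens T1 and T2 linearly with
concentration; transporter-driven aggregation adds a much stronger,
phase-dependent effective transverse rate ``R2*_Agg`` that multiplies the
whole voxel signal through an extra ``exp(-TE * R2*_Agg)`` factor.  The
measured voxel signal is a volume-weighted mixture of the C2 and C3
spoiled-GRE sub-signals with C2 fraction ``v23``.

The steady-state spoiled-GRE expression is used with the standard negative
exponents

    S = M0 sin(theta) (1 - E1) / (1 - cos(theta) E1) * exp(-TE R2*),
    E1 = exp(-TR R1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, Relaxivity

__all__ = [
    "KineticParams",
    "AggregationSchedule",
    "VoxelModel",
    "ConcentrationCurve",
    "SignalCurve",
    "solve_compartments",
    "relaxation_rates",
    "spgr_signal",
    "simulate_voxel",
    "phase_rate_schedule",
]

#: Sentinel frame index meaning "this phase transition never occurs".
NEVER = -1


@dataclass(frozen=True)
class KineticParams:
    """Exchange rates and boundary conditions of the compartment system.

    k12, k23 : unidirectional exchange rates, s^-1 (>= 0)
    c1       : constant arterial concentration, mM
    c2_0, c3_0 : initial concentrations in C2 and C3, mM (default 0: the
        bolus arrives at t=0 into C1 only)
    """

    k12: float
    k23: float
    c1: float = 0.104
    c2_0: float = 0.0
    c3_0: float = 0.0

    def __post_init__(self):
        for name in ("k12", "k23", "c1", "c2_0", "c3_0"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class AggregationSchedule:
    """Aggregate-induced effective transverse rates per kinetic phase.

    One rate (s^-1) applies per phase: elevation before ``t_formation``,
    reduction in ``[t_formation, t_clearance)``, recovery from
    ``t_clearance`` on.  A frame index of -1 means the transition never
    occurs (the preceding phase extends to the end of the series).
    """

    r2agg_elevation: float = 0.0
    r2agg_reduction: float = 0.0
    r2agg_recovery: float = 0.0
    t_formation: int = NEVER
    t_clearance: int = NEVER

    def __post_init__(self):
        for name in ("r2agg_elevation", "r2agg_reduction", "r2agg_recovery"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        tf, tc = self.t_formation, self.t_clearance
        if tf >= 0 and tc >= 0 and not tf < tc:
            raise ValueError(
                f"t_formation ({tf}) must precede t_clearance ({tc})"
            )


@dataclass(frozen=True)
class VoxelModel:
    """Complete per-voxel model: kinetics, aggregation, mixing and scale.

    ``v23`` is the fraction of the voxel volume occupied by the maternal
    intravascular compartment C2 (the remainder 1 - v23 is C3); ``m0`` is
    the proton density weighted by the receiver-coil sensitivity.
    """

    kinetics: KineticParams
    aggregation: AggregationSchedule
    v23: float
    m0: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.v23 <= 1.0:
            raise ValueError(f"v23 must lie in [0, 1], got {self.v23}")
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Concentration time-courses of C2 and C3 (mM) at given times (s)."""

    times: np.ndarray
    c2: np.ndarray
    c3: np.ndarray


@dataclass(frozen=True)
class SignalCurve:
    """Per-frame voxel signal (a.u.) at the protocol frame times (s)."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.frame_times, dtype=float)
        if v.shape != t.shape:
            raise ValueError("values and frame_times must have equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "frame_times", t)


# ---------------------------------------------------------------------------
# closed-form compartment solution
# ---------------------------------------------------------------------------

def _solve_c2c3(k12, k23, c1, c2_0, c3_0, times):
    """Vectorised closed-form solution of the exchange system.

    All kinetic arguments broadcast against each other with a trailing time
    axis appended; ``times`` is a 1-D array of evaluation times (s).
    Returns ``(c2, c3)`` with shape ``broadcast(kinetics) + (len(times),)``.

    For k12, k23 > 0 the system matrix ``A = [[-(k12+k23), k23], [k23, -k23]]``
    has eigenvalues ``lam = (-(k12+2 k23) +/- sqrt(k12^2 + 4 k23^2)) / 2``,
    both real and negative, and fixed point ``c2 = c3 = c1``.  Degenerate
    rate combinations (k12 = 0 or k23 = 0) reduce to scalar exponential
    relaxations and are handled explicitly.
    """
    t = np.asarray(times, dtype=float)
    a, b, c1, c2_0, c3_0 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (k12, k23, c1, c2_0, c3_0))
    )
    shape = a.shape
    a = a[..., None]
    b = b[..., None]
    c1 = c1[..., None]
    c2_0 = c2_0[..., None]
    c3_0 = c3_0[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        # generic branch: a > 0, b > 0
        disc = np.sqrt(a * a + 4.0 * b * b)
        lam1 = 0.5 * (-(a + 2.0 * b) + disc)
        lam2 = 0.5 * (-(a + 2.0 * b) - disc)
        d2 = c2_0 - c1
        d3 = c3_0 - c1
        b_safe = np.where(b > 0, b, 1.0)
        det = b_safe * (lam1 - lam2)
        det = np.where(det != 0, det, 1.0)
        alpha1 = (b_safe * d2 - (b_safe + lam2) * d3) / det
        alpha2 = (-b_safe * d2 + (b_safe + lam1) * d3) / det
        e1 = np.exp(lam1 * t)
        e2 = np.exp(lam2 * t)
        c2_gen = c1 + alpha1 * (b_safe + lam1) * e1 + alpha2 * (b_safe + lam2) * e2
        c3_gen = c1 + alpha1 * b_safe * e1 + alpha2 * b_safe * e2

        # b == 0: C3 frozen, C2 relaxes to c1 with rate a (constant if a == 0)
        c2_b0 = c1 + (c2_0 - c1) * np.exp(-a * t)
        c3_b0 = c3_0 * np.ones_like(t)

        # a == 0, b > 0: pure C2<->C3 mixing, conserved sum
        s0 = c2_0 + c3_0
        diff = (c2_0 - c3_0) * np.exp(-2.0 * b * t)
        c2_a0 = 0.5 * (s0 + diff)
        c3_a0 = 0.5 * (s0 - diff)

    mask_b0 = np.broadcast_to(b == 0, c2_gen.shape)
    mask_a0 = np.broadcast_to((a == 0) & (b > 0), c2_gen.shape)
    c2 = np.where(mask_b0, c2_b0, np.where(mask_a0, c2_a0, c2_gen))
    c3 = np.where(mask_b0, c3_b0, np.where(mask_a0, c3_a0, c3_gen))
    # guard against tiny negative round-off
    np.clip(c2, 0.0, None, out=c2)
    np.clip(c3, 0.0, None, out=c3)
    if shape == ():
        return c2.reshape(t.shape), c3.reshape(t.shape)
    return c2, c3


def solve_compartments(kp: KineticParams, times) -> ConcentrationCurve:
    """Exact concentrations of C2 and C3 at the requested times.

    Parameters
    ----------
    kp : KineticParams
    times : array-like of float
        Nonnegative, strictly increasing evaluation times in seconds.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    c2, c3 = _solve_c2c3(kp.k12, kp.k23, kp.c1, kp.c2_0, kp.c3_0, t)
    return ConcentrationCurve(times=t, c2=c2, c3=c3)


def relaxation_rates(c, rel: Relaxivity):
    """Contrast-induced relaxation rates (R1, R2) in s^-1 for concentration c (mM).

    Linear in concentration through the origin; tissue baselines are *not*
    added here (they are composed in :func:`simulate_voxel`).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    r1 = rel.r1 * c
    r2 = rel.r2 * c
    if c.ndim == 0:
        return float(r1), float(r2)
    return r1, r2


def spgr_signal(r1_total, r2star_total, protocol: AcquisitionProtocol, m0=1.0):
    """Steady-state spoiled-GRE signal for total relaxation rates (s^-1).

    Vectorised over ``r1_total`` / ``r2star_total``.  The signal is bounded
    by ``m0``, strictly increasing in R1 and strictly decreasing in R2*
    whenever TE > 0.
    """
    r1 = np.asarray(r1_total, dtype=float)
    r2s = np.asarray(r2star_total, dtype=float)
    if np.any(r1 < 0) or np.any(r2s < 0):
        raise ValueError("relaxation rates must be nonnegative")
    if np.any(np.asarray(m0) <= 0):
        raise ValueError("m0 must be positive")
    e1 = np.exp(-protocol.tr * r1)
    s = (
        m0
        * np.sin(protocol.flip_angle)
        * (1.0 - e1)
        / (1.0 - np.cos(protocol.flip_angle) * e1)
        * np.exp(-protocol.te * r2s)
    )
    if np.ndim(r1) == 0 and np.ndim(r2s) == 0 and np.ndim(m0) == 0:
        return float(s)
    return s


def phase_rate_schedule(agg: AggregationSchedule, n_frames: int) -> np.ndarray:
    """Per-frame aggregate rate (s^-1) implied by the phase boundaries.

    Elevation applies before ``t_formation``, reduction in
    ``[t_formation, t_clearance)`` and recovery from ``t_clearance`` on;
    sentinel boundaries extend the preceding phase to the end.
    """
    if agg.t_formation >= n_frames or agg.t_clearance >= n_frames:
        raise ValueError("phase boundary indices must be below the frame count")
    n = np.arange(n_frames)
    rates = np.full(n_frames, agg.r2agg_elevation, dtype=float)
    if agg.t_formation >= 0:
        rates[n >= agg.t_formation] = agg.r2agg_reduction
        if agg.t_clearance >= 0:
            rates[n >= agg.t_clearance] = agg.r2agg_recovery
    return rates


def _mixture_signal(c2, c3, v23, protocol, rel):
    """Volume-weighted mixture of the C2/C3 spoiled-GRE sub-signals (m0 = 1).

    The per-compartment rates add the tissue baselines to the
    concentration-scaled relaxivities; the aggregate factor is applied by
    the caller (it is shared by both sub-signals).
    """
    s2 = spgr_signal(rel.baseline_r1 + rel.r1 * c2, rel.baseline_r2star + rel.r2 * c2, protocol)
    s3 = spgr_signal(rel.baseline_r1 + rel.r1 * c3, rel.baseline_r2star + rel.r2 * c3, protocol)
    return v23 * s2 + (1.0 - v23) * s3


def simulate_voxel(vm: VoxelModel, protocol: AcquisitionProtocol, rel: Relaxivity) -> SignalCurve:
    """Simulate the dynamic voxel signal for a complete voxel model.

    Concentrations are evaluated at the frame-centre times (stepwise-constant
    within a frame); the phase-dependent aggregate attenuation
    ``exp(-TE * R2*_Agg(n))`` multiplies the mixed voxel signal voxel-wide.
    """
    times = protocol.times
    c2, c3 = _solve_c2c3(
        vm.kinetics.k12, vm.kinetics.k23, vm.kinetics.c1, vm.kinetics.c2_0, vm.kinetics.c3_0, times
    )
    mix = _mixture_signal(c2, c3, vm.v23, protocol, rel)
    agg_rates = phase_rate_schedule(vm.aggregation, protocol.n_frames)
    values = vm.m0 * np.exp(-protocol.te * agg_rates) * mix
    return SignalCurve(values=values, frame_times=times)
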