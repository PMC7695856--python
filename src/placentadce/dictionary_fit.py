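"""Dictionary-based exhaustive-search fitting of the six-parameter model.

A dictionary of simulated signal time-courses is built over a Cartesian
grid of the six unknowns (k12, k23, v23 and the three phase aggregate
rates), and each measured voxel curve is assigned the grid entry minimising
the L2 distance after fitting a closed-form nonnegative amplitude (M0 is a
nuisance parameter, making the match amplitude-invariant).  Phase
boundaries are inputs from phase detection, not grid dimensions; one
dictionary is built and cached per distinct (t_formation, t_clearance)
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iter_product

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, Relaxivity
from .forward_model import (
    NEVER,
    AggregationSchedule,
    KineticParams,
    SignalCurve,
    _mixture_signal,
    _solve_c2c3,
    phase_rate_schedule,
)

__all__ = [
    "ParameterGrid",
    "SignalDictionary",
    "ParametricMaps",
    "build_dictionary",
    "match_curve",
    "fit_volume",
    "summarize_maps",
    "PARAM_NAMES",
]

PARAM_NAMES = ("k12", "k23", "v23", "r2agg_elevation", "r2agg_reduction", "r2agg_recovery")

#: Hard cap on dictionary entries; exceeding it raises a capacity error.
MAX_ENTRIES = 2_000_000


def _logspace(lo, hi, n):
    return tuple(float(v) for v in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class ParameterGrid:
    """Value lists for the six fitted parameters.

    Enumeration is lexicographic in the field order (k12, k23, v23,
    r2agg_elevation, r2agg_reduction, r2agg_recovery).  When ``prune`` is
    on, aggregation triples violating the physical ordering
    ``r2agg_reduction > max(r2agg_elevation, r2agg_recovery)`` (the
    reduction phase must be the most attenuated) are dropped.
    """

    k12: tuple
    k23: tuple
    v23: tuple
    r2agg_elevation: tuple
    r2agg_reduction: tuple
    r2agg_recovery: tuple
    prune: bool = True

    def __post_init__(self):
        for name in PARAM_NAMES:
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ValueError(f"grid for {name} must be nonempty")
            if any(v < 0 for v in vals):
                raise ValueError(f"grid values for {name} must be nonnegative")
            if list(vals) != sorted(vals):
                raise ValueError(f"grid values for {name} must be sorted ascending")
            object.__setattr__(self, name, vals)
        if any(not 0 <= v <= 1 for v in self.v23):
            raise ValueError("v23 grid values must lie in [0, 1]")

    @classmethod
    def default(cls) -> "ParameterGrid":
        """Default fitting grid (166,000 entries after pruning).

        Ranges bracket physiologically reported placental values:
        k12 in [0.005, 0.20] s^-1, k23 in [0.005, 0.25] s^-1 (10 log-spaced
        values each), five v23 levels, and log-spaced aggregate rates whose
        reciprocals cover T2* from tens of ms (elevation) down to 1 ms
        (reduction).
        """
        return cls(
            k12=_logspace(0.005, 0.20, 10),
            k23=_logspace(0.005, 0.25, 10),
            v23=(0.125, 0.3125, 0.5, 0.6875, 0.875),
            r2agg_elevation=_logspace(5.0, 80.0, 5),
            r2agg_reduction=_logspace(50.0, 1000.0, 17),
            r2agg_recovery=_logspace(10.0, 300.0, 5),
        )

    @classmethod
    def coarse(cls) -> "ParameterGrid":
        """Coarse preset (~7,700 entries) for fast volume fitting."""
        return cls(
            k12=_logspace(0.005, 0.20, 8),
            k23=_logspace(0.005, 0.25, 8),
            v23=(0.125, 0.3125, 0.5, 0.6875, 0.875),
            r2agg_elevation=(5.0, 20.0, 80.0),
            r2agg_reduction=(100.0, 300.0, 1000.0),
            r2agg_recovery=(30.0, 75.0, 150.0),
        )

    @classmethod
    def no_aggregation(cls, base: "ParameterGrid") -> "ParameterGrid":
        """Copy of ``base`` with the aggregation dimensions collapsed to {0}."""
        return cls(
            k12=base.k12,
            k23=base.k23,
            v23=base.v23,
            r2agg_elevation=(0.0,),
            r2agg_reduction=(0.0,),
            r2agg_recovery=(0.0,),
            prune=False,
        )

    @property
    def sizes(self) -> tuple:
        return tuple(len(getattr(self, name)) for name in PARAM_NAMES)

    def aggregation_triples(self) -> np.ndarray:
        """Valid (elevation, reduction, recovery) triples, lexicographic."""
        triples = np.array(
            list(iter_product(self.r2agg_elevation, self.r2agg_reduction, self.r2agg_recovery)),
            dtype=float,
        )
        if self.prune:
            keep = triples[:, 1] > np.maximum(triples[:, 0], triples[:, 2])
            triples = triples[keep]
        return triples

    @property
    def n_entries(self) -> int:
        n_base = len(self.k12) * len(self.k23) * len(self.v23)
        return n_base * len(self.aggregation_triples())


@dataclass(frozen=True)
class SignalDictionary:
    """Precomputed signal dictionary.

    entries : ndarray (n_entries, n_frames) of raw simulated curves (m0 = 1)
    params : ndarray (n_entries, 6) of the parameter tuple per row, in the
        order of :data:`PARAM_NAMES`
    norms_sq : ndarray (n_entries,) squared L2 norm of each row
    boundaries : (t_formation, t_clearance) used for all rows
    fingerprint : protocol fingerprint active at build time
    """

    entries: np.ndarray
    params: np.ndarray
    norms_sq: np.ndarray
    boundaries: tuple
    fingerprint: str

    @property
    def n_entries(self) -> int:
        return self.entries.shape[0]

    @property
    def n_frames(self) -> int:
        return self.entries.shape[1]


def build_dictionary(
    grid: ParameterGrid,
    protocol: AcquisitionProtocol,
    rel: Relaxivity,
    boundaries: tuple = (NEVER, NEVER),
    kinetics_base: KineticParams | None = None,
) -> SignalDictionary:
    """Simulate one dictionary row per grid point (m0 = 1).

    ``kinetics_base`` supplies the shared arterial concentration and initial
    conditions; ``boundaries`` are the phase-transition frame indices used
    for every row (sentinels allowed).  Rows follow the grid's lexicographic
    enumeration order and are produced by the same forward-model kernels as
    :func:`placentadce.forward_model.simulate_voxel`, so a row equals the
    single-voxel simulation bit for bit.
    """
    if kinetics_base is None:
        kinetics_base = KineticParams(k12=0.0, k23=0.0)
    tf, tc = boundaries
    nf = protocol.n_frames
    if (tf >= nf) or (tc >= nf):
        raise ValueError("phase boundaries exceed the protocol frame count")
    if tf >= 0 and tc >= 0 and tf >= tc:
        raise ValueError("t_formation must precede t_clearance")
    if grid.n_entries > MAX_ENTRIES:
        raise MemoryError(
            f"grid enumerates {grid.n_entries} entries, above the "
            f"{MAX_ENTRIES} capacity; use a coarser grid"
        )

    times = protocol.times
    k12 = np.asarray(grid.k12)[:, None]
    k23 = np.asarray(grid.k23)[None, :]
    c2, c3 = _solve_c2c3(
        k12, k23, kinetics_base.c1, kinetics_base.c2_0, kinetics_base.c3_0, times
    )  # (n12, n23, T)
    v = np.asarray(grid.v23)
    mix = np.stack(
        [_mixture_signal(c2, c3, vv, protocol, rel) for vv in v], axis=2
    )  # (n12, n23, nv, T)

    triples = grid.aggregation_triples()
    att = np.empty((len(triples), nf))
    for i, (e, r, c) in enumerate(triples):
        sched = AggregationSchedule(
            r2agg_elevation=e, r2agg_reduction=r, r2agg_recovery=c,
            t_formation=int(tf), t_clearance=int(tc),
        )
        att[i] = np.exp(-protocol.te * phase_rate_schedule(sched, nf))

    base = mix.reshape(-1, nf)  # lexicographic in (k12, k23, v23)
    entries = (att[None, :, :] * base[:, None, :]).reshape(-1, nf)

    kin_params = np.array(list(iter_product(grid.k12, grid.k23, grid.v23)), dtype=float)
    n_base, n_att = kin_params.shape[0], triples.shape[0]
    params = np.empty((n_base * n_att, 6))
    params[:, :3] = np.repeat(kin_params, n_att, axis=0)
    params[:, 3:] = np.tile(triples, (n_base, 1))

    norms_sq = np.einsum("ij,ij->i", entries, entries)
    return SignalDictionary(
        entries=entries,
        params=params,
        norms_sq=norms_sq,
        boundaries=(int(tf), int(tc)),
        fingerprint=protocol.fingerprint(),
    )


def _match_many(signals: np.ndarray, dictionary: SignalDictionary, chunk: int = 128):
    """Vectorised match of many curves; returns (rows, scales, residuals).

    For each row d the optimal nonnegative scale is
    ``a* = max(<s, d>, 0) / <d, d>`` and the squared residual is
    ``|s|^2 - a*^2 <d, d>``; the row minimising the residual wins, ties
    going to the lowest row index.
    """
    D = dictionary.entries
    dn = dictionary.norms_sq
    dn_safe = np.where(dn > 0, dn, 1.0)
    n = signals.shape[0]
    rows = np.full(n, NEVER, dtype=np.int64)
    scales = np.zeros(n)
    residuals = np.full(n, np.nan)
    snorm_sq = np.einsum("ij,ij->i", signals, signals)
    nonzero = snorm_sq > 0
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        dots = signals[sl] @ D.T
        pos = np.clip(dots, 0.0, None)
        res_sq = snorm_sq[sl, None] - pos * pos / dn_safe[None, :]
        if np.any(dn == 0):
            # an all-zero dictionary row matches nothing: residual = |s|
            res_sq[:, dn == 0] = snorm_sq[sl, None]
        best = np.argmin(res_sq, axis=1)
        idx = np.arange(sl.start, sl.stop)
        rows[idx] = best
        a = pos[np.arange(best.size), best] / dn_safe[best]
        scales[idx] = a
        # recompute the winning residual directly: the expanded quadratic
        # form suffers catastrophic cancellation near perfect matches
        residuals[idx] = np.linalg.norm(signals[sl] - a[:, None] * D[best], axis=1)
    rows[~nonzero] = NEVER
    scales[~nonzero] = 0.0
    residuals[~nonzero] = np.nan
    return rows, scales, residuals


def match_curve(curve, dictionary: SignalDictionary):
    """Exhaustively match one curve against the dictionary.

    Parameters
    ----------
    curve : SignalCurve or array-like
    dictionary : SignalDictionary

    Returns
    -------
    (row_index, scale, residual)
        ``row_index`` is -1 (sentinel) for an all-zero input curve.
    """
    s = np.asarray(getattr(curve, "values", curve), dtype=float)
    if s.ndim != 1 or s.size != dictionary.n_frames:
        raise ValueError(
            f"curve length {s.size} does not match dictionary frame count {dictionary.n_frames}"
        )
    rows, scales, residuals = _match_many(s[None, :], dictionary)
    return int(rows[0]), float(scales[0]), float(residuals[0])


@dataclass
class ParametricMaps:
    """Six fitted parameter maps plus amplitude, residual and mask."""

    k12: np.ndarray
    k23: np.ndarray
    v23: np.ndarray
    r2agg_elevation: np.ndarray
    r2agg_reduction: np.ndarray
    r2agg_recovery: np.ndarray
    scale: np.ndarray
    residual: np.ndarray
    mask: np.ndarray

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES + ("scale", "residual")}


def fit_volume(
    series,
    mask,
    phase_maps,
    grid: ParameterGrid,
    protocol: AcquisitionProtocol,
    rel: Relaxivity,
    kinetics_base: KineticParams | None = None,
    chunk: int = 128,
) -> ParametricMaps:
    """Fit every masked voxel of a 4-D series by dictionary matching.

    Voxels are grouped by their detected (t_formation, t_clearance) pair
    and one dictionary is built (and cached) per distinct pair.  Voxels
    with sentinel phases (no detected aggregation) are fitted against a
    dictionary whose aggregation dimensions are collapsed to zero.
    """
    series = np.asarray(series, dtype=float)
    mask_b = np.asarray(mask).astype(bool)
    if series.ndim != 4:
        raise ValueError(f"series must be 4-D, got shape {series.shape}")
    if mask_b.shape != series.shape[:3]:
        raise ValueError("mask shape does not match series spatial shape")
    tf_map = np.asarray(phase_maps.t_formation)
    tc_map = np.asarray(phase_maps.t_clearance)
    if tf_map.shape != mask_b.shape:
        raise ValueError("phase map shape does not match series spatial shape")

    shape = mask_b.shape
    out = {name: np.zeros(shape) for name in PARAM_NAMES}
    scale = np.zeros(shape)
    residual = np.full(shape, np.nan)

    coords = np.argwhere(mask_b)
    if coords.size:
        pairs = np.stack([tf_map[mask_b], tc_map[mask_b]], axis=1)
        cache: dict = {}
        for pair in {tuple(p) for p in pairs.tolist()}:
            tf, tc = pair
            sel = (pairs[:, 0] == tf) & (pairs[:, 1] == tc)
            vox = coords[sel]
            if tf < 0:
                key = ("noagg",)
                if key not in cache:
                    cache[key] = build_dictionary(
                        ParameterGrid.no_aggregation(grid), protocol, rel,
                        (NEVER, NEVER), kinetics_base,
                    )
                d = cache[key]
            else:
                key = (int(tf), int(tc))
                if key not in cache:
                    cache[key] = build_dictionary(grid, protocol, rel, key, kinetics_base)
                d = cache[key]
            sigs = series[vox[:, 0], vox[:, 1], vox[:, 2], :]
            rows, sc, res = _match_many(sigs, d, chunk=chunk)
            ok = rows >= 0
            p = np.zeros((rows.size, 6))
            p[ok] = d.params[rows[ok]]
            for j, name in enumerate(PARAM_NAMES):
                out[name][vox[:, 0], vox[:, 1], vox[:, 2]] = p[:, j]
            scale[vox[:, 0], vox[:, 1], vox[:, 2]] = sc
            residual[vox[:, 0], vox[:, 1], vox[:, 2]] = res

    return ParametricMaps(
        **out, scale=scale, residual=residual, mask=mask_b,
    )


def summarize_maps(maps: ParametricMaps, rois, names: dict | None = None) -> pd.DataFrame:
    """Per-ROI mean +/- SD of every fitted map.

    ``rois`` is an integer label volume; label 0 is background.  Returns a
    tidy DataFrame with one row per (ROI, parameter).
    """
    rois = np.asarray(rois)
    records = []
    for label in np.unique(rois):
        if label == 0:
            continue
        sel = (rois == label) & maps.mask
        if not np.any(sel):
            continue
        roi_name = (names or {}).get(int(label), f"roi_{int(label)}")
        for name, arr in maps.as_dict().items():
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            records.append(
                {
                    "roi": roi_name,
                    "label": int(label),
                    "parameter": name,
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "n_voxels": int(vals.size),
                }
            )
    return pd.DataFrame.from_records(records)
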