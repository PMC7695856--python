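"""Seeded synthetic data: DCE phantoms and fluorescence fixtures.

The 4-D phantom emulates a dynamic placental acquisition: a central
maternal-canal region carries the constant arterial signal, surrounded by
three concentric placental zones (labyrinth innermost, then junctional,
decidua outermost).  Placental voxels receive ground-truth kinetic and
aggregation parameters drawn from truncated normal distributions around
physiologically reported means, a three-phase signal (elevation /
reduction / recovery) whose transition frames propagate decidua-to-
labyrinth for formation and back for clearance, and Rician magnitude
noise.  A competition mode emulates transporter pre-saturation: no
aggregation (the signal dip disappears) and suppressed cellular uptake.

The fluorescence fixtures emulate two-channel histology sections: a
placenta-shaped tissue region, DAPI-like nuclei in the blue channel and
labelled aggregate disks of known geometry in the green channel, with
per-phase densities mirroring the densest-during-reduction ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import AcquisitionProtocol, Relaxivity
from .forward_model import NEVER, _mixture_signal, _solve_c2c3
from .histology import FluorescenceImage, classify_diameter
from .dictionary_fit import ParameterGrid

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "FluorescenceFixtureConfig",
    "generate_phantom",
    "generate_competition_phantom",
    "generate_fluorescence_fixture",
    "render_disk_fixture",
    "rician_noise",
]

# zone labels
BACKGROUND, DECIDUA, JUNCTIONAL, LABYRINTH, CANAL = 0, 1, 2, 3, 4
PLACENTAL_ZONES = (DECIDUA, JUNCTIONAL, LABYRINTH)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, ground-truth sampling and noise of the DCE phantom.

    Ground-truth means/SDs are the reported placental values: exchange
    rates k12 = 0.045 +/- 0.034 s^-1 and k23 = 0.059 +/- 0.035 s^-1, phase
    T2* of 63.3 +/- 39.7 ms (elevation), 2.7 +/- 1.6 ms (reduction) and
    13.6 +/- 10.0 ms (recovery), and a C2 volume fraction of 0.75 +/- 0.25.
    Sampling is truncated at 2 SD and clipped to the default fitting-grid
    range so recovery experiments are well posed.  ``snap_grid`` optionally
    snaps every sampled value onto a :class:`ParameterGrid` (on-grid
    truth).  SNR is noise-free mean placental signal divided by the
    Gaussian sigma of the underlying complex channels (Rician magnitude
    noise); use ``math.inf`` to disable noise.
    """

    shape: tuple = (48, 48, 4)
    canal_radius: float = 5.0
    outer_radius: float = 21.0
    c1: float = 0.104
    k12_mean: float = 0.045
    k12_sd: float = 0.034
    k23_mean: float = 0.059
    k23_sd: float = 0.035
    v23_mean: float = 0.75
    v23_sd: float = 0.25
    t2star_elevation_ms: tuple = (63.3, 39.7)
    t2star_reduction_ms: tuple = (2.7, 1.6)
    t2star_recovery_ms: tuple = (13.6, 10.0)
    base_t_formation: int = 5
    base_t_clearance: int = 11
    phase_offset_frames: int = 1
    snr: float = 20.0
    m0: float = 1000.0
    seed: int = 0
    snap_grid: ParameterGrid | None = None
    competition_suppression: float = 0.3

    def __post_init__(self):
        if any(s <= 0 for s in self.shape) or len(self.shape) != 3:
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if not 0 < self.canal_radius < self.outer_radius:
            raise ValueError("need 0 < canal_radius < outer_radius")
        if not self.snr > 0:
            raise ValueError("snr must be positive (math.inf disables noise)")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel ground-truth maps of the generated phantom."""

    k12: np.ndarray
    k23: np.ndarray
    v23: np.ndarray
    r2agg_elevation: np.ndarray
    r2agg_reduction: np.ndarray
    r2agg_recovery: np.ndarray
    t_formation: np.ndarray
    t_clearance: np.ndarray
    zones: np.ndarray
    m0: np.ndarray
    config: PhantomConfig
    seed: int

    @property
    def placenta_mask(self) -> np.ndarray:
        return np.isin(self.zones, PLACENTAL_ZONES)

    @property
    def canal_mask(self) -> np.ndarray:
        return self.zones == CANAL


def _zone_labels(cfg: PhantomConfig) -> np.ndarray:
    nx, ny, nz = cfg.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(xx - cx, yy - cy)
    ring_width = (cfg.outer_radius - cfg.canal_radius) / 3.0
    plane = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    plane[r <= cfg.outer_radius] = DECIDUA
    plane[r <= cfg.canal_radius + 2 * ring_width] = JUNCTIONAL
    plane[r <= cfg.canal_radius + ring_width] = LABYRINTH
    plane[r <= cfg.canal_radius] = CANAL
    return np.repeat(plane[:, :, None], nz, axis=2)


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal sample clipped to [lo, hi] and to +/- 2 SD."""
    lo_eff = max(lo, mean - 2 * sd)
    hi_eff = min(hi, mean + 2 * sd)
    if sd == 0 or lo_eff >= hi_eff:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo_eff - mean) / sd, (hi_eff - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _snap(values, grid_values):
    gv = np.asarray(grid_values, dtype=float)
    idx = np.argmin(np.abs(values[:, None] - gv[None, :]), axis=1)
    return gv[idx]


def _sample_parameters(cfg: PhantomConfig, rng, n: int) -> dict:
    """Draw per-voxel ground truth, optionally snapped to a fitting grid."""
    ref = ParameterGrid.default()
    k12 = _truncnorm(rng, cfg.k12_mean, cfg.k12_sd, min(ref.k12), max(ref.k12), n)
    k23 = _truncnorm(rng, cfg.k23_mean, cfg.k23_sd, min(ref.k23), max(ref.k23), n)
    v23 = _truncnorm(rng, cfg.v23_mean, cfg.v23_sd, min(ref.v23), max(ref.v23), n)

    def rate_from_t2(t2_mean_sd, rate_grid):
        m, sd = t2_mean_sd
        lo_t2, hi_t2 = 1000.0 / max(rate_grid), 1000.0 / min(rate_grid)
        t2 = _truncnorm(rng, m, sd, lo_t2, hi_t2, n)
        return 1000.0 / t2

    r_elev = rate_from_t2(cfg.t2star_elevation_ms, ref.r2agg_elevation)
    r_red = rate_from_t2(cfg.t2star_reduction_ms, ref.r2agg_reduction)
    r_rec = rate_from_t2(cfg.t2star_recovery_ms, ref.r2agg_recovery)
    # keep the reduction phase the most attenuated (matches the pruned grid)
    r_rec = np.minimum(r_rec, 0.9 * r_red)
    r_elev = np.minimum(r_elev, 0.9 * r_red)

    if cfg.snap_grid is not None:
        g = cfg.snap_grid
        k12 = _snap(k12, g.k12)
        k23 = _snap(k23, g.k23)
        v23 = _snap(v23, g.v23)
        r_red = _snap(r_red, g.r2agg_reduction)
        r_elev = _snap(r_elev, g.r2agg_elevation)
        r_rec = _snap(r_rec, g.r2agg_recovery)
        if g.prune:
            # snap could break the ordering; demote to the next valid value
            ev = np.asarray(g.r2agg_elevation)
            rv = np.asarray(g.r2agg_recovery)
            for i in range(k12.size):
                if r_elev[i] >= r_red[i]:
                    lower = ev[ev < r_red[i]]
                    if lower.size == 0:
                        raise ValueError("snap grid has no elevation value below reduction")
                    r_elev[i] = lower[-1]
                if r_rec[i] >= r_red[i]:
                    lower = rv[rv < r_red[i]]
                    if lower.size == 0:
                        raise ValueError("snap grid has no recovery value below reduction")
                    r_rec[i] = lower[-1]
    return {
        "k12": k12, "k23": k23, "v23": v23,
        "r2agg_elevation": r_elev, "r2agg_reduction": r_red, "r2agg_recovery": r_rec,
    }


def rician_noise(values, sigma, rng):
    """Rician magnitude noise: |(s + n1) + i n2| with Gaussian n1, n2."""
    n1 = rng.standard_normal(values.shape) * sigma
    n2 = rng.standard_normal(values.shape) * sigma
    return np.hypot(values + n1, n2)


def _phase_attenuation(r_elev, r_red, r_rec, tf, tc, te, n_frames):
    """Per-voxel, per-frame aggregate factor exp(-TE * r2agg(n))."""
    n = np.arange(n_frames)[None, :]
    tf = tf[:, None]
    tc = tc[:, None]
    rates = np.where(
        (tf >= 0) & (n >= tf),
        np.where((tc >= 0) & (n >= tc), r_rec[:, None], r_red[:, None]),
        r_elev[:, None],
    )
    return np.exp(-te * rates)


def generate_phantom(
    cfg: PhantomConfig = PhantomConfig(),
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    rel: Relaxivity = Relaxivity(),
    *,
    _competition: bool = False,
):
    """Generate a seeded 4-D DCE phantom with full ground truth.

    Returns ``(series, truth)`` where ``series`` has shape
    ``cfg.shape + (protocol.n_frames,)``.  Canal voxels carry the constant
    arterial signal; placental voxels follow the three-phase forward model
    with formation propagating decidua -> labyrinth and clearance in the
    reverse direction; background is pure noise floor.  Bit-for-bit
    reproducible for a given (config, protocol, relaxivity).
    """
    zones = _zone_labels(cfg)
    placenta = np.isin(zones, PLACENTAL_ZONES)
    n_plac = int(placenta.sum())
    if n_plac == 0:
        raise ValueError("phantom geometry contains no placental voxels")
    nf = protocol.n_frames
    rng = np.random.default_rng(cfg.seed)
    params = _sample_parameters(cfg, rng, n_plac)

    if _competition:
        params["k23"] = params["k23"] * cfg.competition_suppression
        for key in ("r2agg_elevation", "r2agg_reduction", "r2agg_recovery"):
            params[key] = np.zeros(n_plac)

    # phase boundaries from the zone-wise onset gradient
    zone_off = {DECIDUA: 0, JUNCTIONAL: 1, LABYRINTH: 2}
    offsets = np.zeros(n_plac, dtype=np.int32)
    zvals = zones[placenta]
    for z, off in zone_off.items():
        offsets[zvals == z] = off * cfg.phase_offset_frames
    max_off = 2 * cfg.phase_offset_frames
    if _competition:
        tf = np.full(n_plac, NEVER, dtype=np.int32)
        tc = np.full(n_plac, NEVER, dtype=np.int32)
    else:
        tf = (cfg.base_t_formation + offsets).astype(np.int32)
        tc = (cfg.base_t_clearance + (max_off - offsets)).astype(np.int32)
        if tf.max() >= tc.min() or tc.max() >= nf:
            raise ValueError("phase-onset gradient produces invalid boundaries")

    times = protocol.times
    c2, c3 = _solve_c2c3(params["k12"], params["k23"], cfg.c1, 0.0, 0.0, times)
    mix = _mixture_signal(c2, c3, params["v23"][:, None], protocol, rel)
    att = _phase_attenuation(
        params["r2agg_elevation"], params["r2agg_reduction"], params["r2agg_recovery"],
        tf, tc, protocol.te, nf,
    )
    plac_signal = cfg.m0 * att * mix

    canal_signal = cfg.m0 * np.exp(-protocol.te * 0.0) * _mixture_signal(
        np.full(nf, cfg.c1), np.full(nf, cfg.c1), 1.0, protocol, rel
    )

    series = np.zeros(cfg.shape + (nf,))
    series[placenta] = plac_signal
    series[zones == CANAL] = canal_signal

    if math.isfinite(cfg.snr):
        tissue = zones > 0
        sigma = float(series[tissue].mean()) / cfg.snr
        series = rician_noise(series, sigma, rng)

    def as_map(vec, fill=0.0, dtype=float):
        m = np.full(cfg.shape, fill, dtype=dtype)
        m[placenta] = vec
        return m

    truth = GroundTruth(
        k12=as_map(params["k12"]),
        k23=as_map(params["k23"]),
        v23=as_map(params["v23"]),
        r2agg_elevation=as_map(params["r2agg_elevation"]),
        r2agg_reduction=as_map(params["r2agg_reduction"]),
        r2agg_recovery=as_map(params["r2agg_recovery"]),
        t_formation=as_map(tf, fill=NEVER, dtype=np.int32),
        t_clearance=as_map(tc, fill=NEVER, dtype=np.int32),
        zones=zones,
        m0=np.where(zones > 0, cfg.m0, 0.0),
        config=cfg,
        seed=cfg.seed,
    )
    return series, truth


def generate_competition_phantom(
    cfg: PhantomConfig = PhantomConfig(),
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    rel: Relaxivity = Relaxivity(),
):
    """Phantom emulating transporter pre-saturation with native biotin.

    All aggregation rates are zero (no signal dip; phase maps sentinel)
    and k23 is scaled by ``cfg.competition_suppression``.  The random
    stream is consumed identically to :func:`generate_phantom`, so paired
    contrast/competition phantoms share geometry, sampling and noise draws.
    """
    return generate_phantom(cfg, protocol, rel, _competition=True)


# ---------------------------------------------------------------------------
# fluorescence fixtures
# ---------------------------------------------------------------------------

#: Per-phase aggregate populations: (count, (min radius px, max radius px)).
#: Densities mirror the reported ordering of relative aggregate area
#: (reduction densest, then recovery, then elevation) and the growth in
#: aggregate size from elevation to reduction.
PHASE_AGGREGATES = {
    "elevation": (60, (2.5, 4.0)),
    "reduction": (110, (4.0, 6.0)),
    "recovery": (50, (3.5, 5.5)),
}


@dataclass(frozen=True)
class FluorescenceFixtureConfig:
    """Geometry and intensity levels of the two-channel fixture.

    Tissue autofluorescence and bright structures carry multiplicative-like
    texture (per-pixel Gaussian around the nominal level, plus per-disk
    brightness variation) so the intensity histogram has realistic
    within-class spread; the nominal levels keep tissue and aggregates
    separated by a wide empty gap, so entropy thresholds recover the exact
    rendered disk footprints.
    """

    shape: tuple = (512, 512)
    pixel_size_um: float = 1.0
    ellipse_axes: tuple = (230.0, 180.0)  # semi-axes in px; ~50% coverage
    n_nuclei: int = 250
    nucleus_radius_px: tuple = (3.0, 5.0)
    outside_level: int = 8
    tissue_level: int = 60
    tissue_texture_sd: float = 5.0
    nucleus_level_range: tuple = (210.0, 245.0)
    aggregate_level_range: tuple = (200.0, 240.0)
    disk_texture_sd: float = 10.0
    noise_sd: float = 2.0
    min_separation_px: float = 4.0
    edge_margin_px: float = 30.0


def _inside_ellipse(cx, cy, center, axes, margin=0.0):
    return ((cx - center[0]) / (axes[0] - margin)) ** 2 + (
        (cy - center[1]) / (axes[1] - margin)
    ) ** 2 <= 1.0


def _place_disks(rng, n, r_range, center, axes, occupied, min_sep, edge_margin=2.0,
                 max_tries=40000):
    """Rejection-sample non-overlapping disk centres inside the ellipse."""
    placed = []
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        r = rng.uniform(*r_range)
        cx = rng.uniform(center[0] - axes[0], center[0] + axes[0])
        cy = rng.uniform(center[1] - axes[1], center[1] + axes[1])
        if not _inside_ellipse(cx, cy, center, axes, margin=r + edge_margin):
            continue
        ok = all(
            np.hypot(cx - px, cy - py) > r + pr + min_sep for px, py, pr in occupied + placed
        )
        if ok:
            placed.append((cx, cy, r))
    if len(placed) < n:
        raise RuntimeError(f"could not place {n} disks without overlap")
    return placed


def _render_disks(canvas, disks, levels, rng=None, texture_sd=0.0):
    """Paint disks (centre distance <= radius) and return pixel areas.

    ``levels`` is one nominal intensity per disk; optional per-pixel
    Gaussian texture is added inside each disk.
    """
    xx, yy = np.meshgrid(
        np.arange(canvas.shape[0]), np.arange(canvas.shape[1]), indexing="ij"
    )
    areas = []
    for (cx, cy, r), level in zip(disks, np.broadcast_to(levels, (len(disks),))):
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        vals = float(level)
        if rng is not None and texture_sd > 0:
            vals = level + rng.normal(0.0, texture_sd, int(m.sum()))
        canvas[m] = vals
        areas.append(int(m.sum()))
    return areas


def generate_fluorescence_fixture(
    phase: str,
    seed: int = 0,
    cfg: FluorescenceFixtureConfig = FluorescenceFixtureConfig(),
):
    """Two-channel fixture for one kinetic phase, with an aggregate truth table.

    Returns ``(FluorescenceImage, truth)`` where ``truth`` is a DataFrame of
    aggregate centres, radii, rendered pixel areas (um^2) and size classes,
    with the true placenta area in ``truth.attrs['placenta_area_um2']``.
    Aggregates are mutually separated and clear of nuclei, so segmentation
    should recover the exact count.
    """
    if phase not in PHASE_AGGREGATES:
        raise ValueError(f"phase must be one of {sorted(PHASE_AGGREGATES)}, got {phase!r}")
    rng = np.random.default_rng(seed)
    n_agg, r_range = PHASE_AGGREGATES[phase]
    shape = cfg.shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    axes = cfg.ellipse_axes

    green = np.full(shape, float(cfg.outside_level))
    blue = np.full(shape, float(cfg.outside_level))
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tissue = _inside_ellipse(xx, yy, center, axes)
    n_tissue = int(tissue.sum())
    green[tissue] = cfg.tissue_level + rng.normal(0, cfg.tissue_texture_sd, n_tissue)
    blue[tissue] = cfg.tissue_level + rng.normal(0, cfg.tissue_texture_sd, n_tissue)

    agg_disks = _place_disks(
        rng, n_agg, r_range, center, axes, [], cfg.min_separation_px,
        edge_margin=cfg.edge_margin_px,
    )
    nuc_disks = _place_disks(
        rng, cfg.n_nuclei, cfg.nucleus_radius_px, center, axes,
        occupied=list(agg_disks), min_sep=cfg.min_separation_px,
    )
    agg_levels = rng.uniform(*cfg.aggregate_level_range, n_agg)
    nuc_levels = rng.uniform(*cfg.nucleus_level_range, cfg.n_nuclei)
    agg_areas_px = _render_disks(green, agg_disks, agg_levels, rng, cfg.disk_texture_sd)
    _render_disks(blue, nuc_disks, nuc_levels, rng, cfg.disk_texture_sd)

    green = np.clip(green + rng.normal(0, cfg.noise_sd, shape), 0, 255).round().astype(np.uint8)
    blue = np.clip(blue + rng.normal(0, cfg.noise_sd, shape), 0, 255).round().astype(np.uint8)

    ps = cfg.pixel_size_um
    records = []
    for i, ((cx, cy, r), a_px) in enumerate(zip(agg_disks, agg_areas_px), start=1):
        area_um2 = a_px * ps * ps
        d_um = 2.0 * math.sqrt(area_um2 / math.pi)
        records.append(
            {
                "id": i, "center_x_px": cx, "center_y_px": cy, "radius_px": r,
                "area_um2": area_um2, "equivalent_diameter_um": d_um,
                "size_class": classify_diameter(d_um),
            }
        )
    truth = pd.DataFrame.from_records(records)
    truth.attrs["placenta_area_um2"] = float(tissue.sum()) * ps * ps
    truth.attrs["phase"] = phase
    truth.attrs["seed"] = seed
    return FluorescenceImage(green=green, blue=blue, pixel_size=ps), truth


def render_disk_fixture(
    diameters_um,
    pixel_size_um: float = 1.0,
    cfg: FluorescenceFixtureConfig | None = None,
    seed: int = 0,
):
    """Deterministic fixture with aggregate disks of exact given diameters.

    Disks are laid out on a horizontal line inside a large elliptical
    placenta scattered with nuclei; used to exercise the size-class
    boundaries (e.g. 20, 100 and 600 um diameters -> small, medium,
    large).
    """
    diameters_um = list(diameters_um)
    radii_px = [d / 2.0 / pixel_size_um for d in diameters_um]
    if cfg is None:
        width = int(max(768, (sum(2 * r for r in radii_px) + 100 * len(radii_px))))
        # gentler texture than the phase fixtures: this geometry probe is much
        # larger, and tail pixels must not form >= 5 um^2 clusters
        cfg = FluorescenceFixtureConfig(
            shape=(width, width),
            pixel_size_um=pixel_size_um,
            ellipse_axes=(0.46 * width, 0.40 * width),
            n_nuclei=150,
            tissue_texture_sd=3.0,
            noise_sd=1.0,
        )
    rng = np.random.default_rng(seed)
    shape = cfg.shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    green = np.full(shape, float(cfg.outside_level))
    blue = np.full(shape, float(cfg.outside_level))
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tissue = _inside_ellipse(xx, yy, center, cfg.ellipse_axes)
    n_tissue = int(tissue.sum())
    green[tissue] = cfg.tissue_level + rng.normal(0, cfg.tissue_texture_sd, n_tissue)
    blue[tissue] = cfg.tissue_level + rng.normal(0, cfg.tissue_texture_sd, n_tissue)

    # spread disk centres along the horizontal axis with generous gaps
    total = sum(2 * r for r in radii_px)
    gap = 30.0
    x = center[0] - (total + gap * (len(radii_px) - 1)) / 2.0
    disks = []
    for r in radii_px:
        disks.append((x + r, center[1], r))
        x += 2 * r + gap
    agg_levels = rng.uniform(*cfg.aggregate_level_range, len(disks))
    areas_px = _render_disks(green, disks, agg_levels, rng, cfg.disk_texture_sd)
    if cfg.n_nuclei:
        nuc_disks = _place_disks(
            rng, cfg.n_nuclei, cfg.nucleus_radius_px, center, cfg.ellipse_axes,
            occupied=list(disks), min_sep=cfg.min_separation_px,
        )
        nuc_levels = rng.uniform(*cfg.nucleus_level_range, cfg.n_nuclei)
        _render_disks(blue, nuc_disks, nuc_levels, rng, cfg.disk_texture_sd)

    green = np.clip(green + rng.normal(0, cfg.noise_sd, shape), 0, 255).round().astype(np.uint8)
    blue = np.clip(blue + rng.normal(0, cfg.noise_sd, shape), 0, 255).round().astype(np.uint8)
    ps = cfg.pixel_size_um
    records = []
    for i, ((cx, cy, r), a_px, d_nom) in enumerate(zip(disks, areas_px, diameters_um), start=1):
        area_um2 = a_px * ps * ps
        d_um = 2.0 * math.sqrt(area_um2 / math.pi)
        records.append(
            {
                "id": i, "center_x_px": cx, "center_y_px": cy, "radius_px": r,
                "nominal_diameter_um": d_nom, "area_um2": area_um2,
                "equivalent_diameter_um": d_um, "size_class": classify_diameter(d_um),
            }
        )
    truth = pd.DataFrame.from_records(records)
    truth.attrs["placenta_area_um2"] = float(tissue.sum()) * ps * ps
    return FluorescenceImage(green=green, blue=blue, pixel_size=ps), truth
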