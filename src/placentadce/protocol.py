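"""Acquisition protocol and contrast-agent relaxivity parameters.

All rates are carried in s^-1 and all times in seconds internally; helper
properties convert to the ms-scale units conventionally printed for T2*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionProtocol", "Relaxivity", "DEFAULT_FRAME_TIMES"]

#: Default dynamic schedule: 20 frames evenly covering a 54 min acquisition,
#: concentrations treated as stepwise-constant within each ~162 s frame and
#: evaluated at the frame-centre times.
DEFAULT_N_FRAMES = 20
DEFAULT_DURATION_S = 54.0 * 60.0
DEFAULT_FRAME_TIMES = tuple(
    (n + 0.5) * DEFAULT_DURATION_S / DEFAULT_N_FRAMES for n in range(DEFAULT_N_FRAMES)
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Spoiled gradient-echo acquisition parameters.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.
    te : float
        Echo time in seconds.
    flip_angle : float
        Excitation flip angle in radians.
    frame_times : tuple of float
        Frame-centre acquisition times in seconds, strictly increasing.
    voxel_dims : tuple of float
        Voxel dimensions (in-plane x, in-plane y, slice) in micrometres.
    """

    tr: float = 0.010
    te: float = 0.003
    flip_angle: float = float(np.deg2rad(15.0))
    frame_times: tuple = DEFAULT_FRAME_TIMES
    voxel_dims: tuple = (150.0, 150.0, 625.0)

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.te < 0:
            raise ValueError(f"te must be nonnegative, got {self.te}")
        if not 0 < self.flip_angle < np.pi:
            raise ValueError(f"flip_angle must lie in (0, pi), got {self.flip_angle}")
        ft = np.asarray(self.frame_times, dtype=float)
        if ft.size < 2:
            raise ValueError("at least 2 frames are required")
        if np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "frame_times", tuple(float(t) for t in ft))
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be 3 positive values, got {self.voxel_dims}")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def duration_s(self) -> float:
        """Total span of the dynamic acquisition in seconds (last frame end)."""
        ft = np.asarray(self.frame_times)
        # frame centres are mid-interval; the schedule spans n equal intervals
        dt = ft[1] - ft[0]
        return float(ft[-1] + dt / 2.0)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame_times, dtype=float)

    def fingerprint(self) -> str:
        """Stable string identifying the protocol for dictionary caching."""
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True)


@dataclass(frozen=True)
class Relaxivity:
    """Contrast-agent relaxivities and tissue baseline relaxation rates.

    ``r1`` and ``r2`` are the longitudinal and transverse relaxivities of the
    soluble agent in s^-1 mM^-1.  ``baseline_r1`` and ``baseline_r2star`` are
    the tissue relaxation rates without contrast (typical high-field values),
    added when composing the voxel signal so the pre-contrast signal is
    finite.
    """

    r1: float = 120.0
    r2: float = 17.0
    baseline_r1: float = 0.5
    baseline_r2star: float = 30.0

    def __post_init__(self):
        for name in ("r1", "r2", "baseline_r1", "baseline_r2star"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def load_config(path) -> dict:
    """Load a flat key-value configuration file (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return data


def protocol_from_config(cfg: dict) -> AcquisitionProtocol:
    """Build an :class:`AcquisitionProtocol` from a flat config mapping."""
    kwargs = {}
    if "tr" in cfg:
        kwargs["tr"] = float(cfg["tr"])
    if "te" in cfg:
        kwargs["te"] = float(cfg["te"])
    if "flip_angle_deg" in cfg:
        kwargs["flip_angle"] = float(np.deg2rad(cfg["flip_angle_deg"]))
    elif "flip_angle" in cfg:
        kwargs["flip_angle"] = float(cfg["flip_angle"])
    if "frame_times" in cfg:
        kwargs["frame_times"] = tuple(float(t) for t in cfg["frame_times"])
    if "voxel_dims" in cfg:
        kwargs["voxel_dims"] = tuple(float(d) for d in cfg["voxel_dims"])
    return AcquisitionProtocol(**kwargs)


def relaxivity_from_config(cfg: dict) -> Relaxivity:
    kwargs = {
        k: float(cfg[k])
        for k in ("r1", "r2", "baseline_r1", "baseline_r2star")
        if k in cfg
    }
    return Relaxivity(**kwargs)
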