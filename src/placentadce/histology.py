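"""Fluorescence-histology quantification of contrast-agent aggregates.

Re-implementation of a Fiji-style macro pipeline for two-channel sections
(green: labelled contrast-agent aggregates; blue: DAPI nuclear stain):

* nuclei: band-pass enhancement, Renyi-entropy auto-threshold, hole
  filling, binary watershed to split touching nuclei;
* aggregates: Kapur maximum-entropy auto-threshold on the green channel,
  nuclei excluded, 8-connected component labelling, sub-5-um^2 specks
  dropped, per-aggregate morphometry with small/medium/large size classes
  (equivalent circular diameter below 50 um, between 50 and 500 um, above
  500 um);
* whole placenta: channel average, Gaussian blur, mean-intensity
  threshold, morphological closing and hole filling;
* summary statistics normalised by placental area.

Entropy thresholds are computed from 256-bin histograms following the
ImageJ Auto-Threshold convention (first maximising bin wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_mean
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, disk, remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "FluorescenceImage",
    "PlacentaStats",
    "threshold_renyi_entropy",
    "threshold_max_entropy",
    "segment_nuclei",
    "segment_aggregates",
    "segment_placenta",
    "quantify",
    "classify_diameter",
]

#: Aggregates below this area (um^2) are treated as noise and dropped.
MIN_AGGREGATE_AREA_UM2 = 5.0
#: Size-class bounds on the equivalent circular diameter (um).  Boundary
#: values fold into the medium class.
SMALL_MAX_DIAMETER_UM = 50.0
LARGE_MIN_DIAMETER_UM = 500.0


@dataclass(frozen=True)
class FluorescenceImage:
    """Two-channel fluorescence section with physical pixel size.

    green : aggregate-label channel; blue : nuclear-stain channel
    (2-D arrays of equal shape, nonnegative); pixel_size : um per pixel.
    """

    green: np.ndarray
    blue: np.ndarray
    pixel_size: float

    def __post_init__(self):
        g = np.asarray(self.green)
        b = np.asarray(self.blue)
        if g.ndim != 2 or b.ndim != 2:
            raise ValueError("channels must be 2-D")
        if g.shape != b.shape:
            raise ValueError(f"channel shapes differ: {g.shape} vs {b.shape}")
        if np.any(g < 0) or np.any(b < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "blue", b)


@dataclass(frozen=True)
class PlacentaStats:
    """Placenta-normalised aggregate statistics (areas in um^2)."""

    total_count: int
    total_area_um2: float
    placenta_area_um2: float
    relative_area: float
    relative_count_per_um2: float
    count_by_class: dict
    area_by_class: dict
    relative_area_by_class: dict
    relative_count_by_class: dict


# ---------------------------------------------------------------------------
# histogram thresholds
# ---------------------------------------------------------------------------

def _histogram_256(image):
    """256-bin histogram with the bin-centre grey levels.

    Integer 8-bit images use the native 0..255 levels; anything else is
    min-max rescaled onto 256 bins first (the ImageJ convention for
    auto-thresholding non-8-bit data).
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        hist = np.bincount(img.ravel(), minlength=256).astype(float)
        centers = np.arange(256, dtype=float)
        return hist, centers
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        hist = np.zeros(256)
        hist[0] = img.size
        return hist, np.full(256, lo)
    scaled = np.clip(((img - lo) / (hi - lo) * 255.0).round().astype(int), 0, 255)
    hist = np.bincount(scaled.ravel(), minlength=256).astype(float)
    centers = lo + np.arange(256) * (hi - lo) / 255.0
    return hist, centers


def _renyi_criterion(hist, alpha):
    """Total Renyi entropy of background/foreground for every split point.

    Returns an array ``crit[t]`` = H_alpha(bg(<=t)) + H_alpha(fg(>t)); bins
    giving an empty class score -inf.  ``alpha`` -> 1 is the Shannon/Kapur
    limit.
    """
    total = hist.sum()
    p = hist / total
    counts = np.cumsum(hist)
    cum = np.cumsum(p)
    crit = np.full(256, -np.inf)
    for t in range(255):
        # classes must each contain pixels (exact integer check: the float
        # cumulative can leave a spurious epsilon "foreground")
        if counts[t] == 0 or counts[t] == total:
            continue
        w0, w1 = cum[t], 1.0 - cum[t]
        p0 = p[: t + 1] / w0
        p1 = p[t + 1:] / w1
        p0 = p0[p0 > 0]
        p1 = p1[p1 > 0]
        if abs(alpha - 1.0) < 1e-9:
            h0 = -np.sum(p0 * np.log(p0))
            h1 = -np.sum(p1 * np.log(p1))
        else:
            h0 = np.log(np.sum(p0**alpha)) / (1.0 - alpha)
            h1 = np.log(np.sum(p1**alpha)) / (1.0 - alpha)
        crit[t] = h0 + h1
    return crit


def _entropy_threshold(image, alpha):
    hist, centers = _histogram_256(image)
    if np.count_nonzero(hist) < 2:
        return None  # constant image: threshold undefined
    crit = _renyi_criterion(hist, alpha)
    if not np.any(np.isfinite(crit)):
        return None
    t = int(np.argmax(crit))  # first maximising bin
    return float(centers[t])


def threshold_renyi_entropy(image, alpha: float = 2.0):
    """Renyi-entropy threshold (order ``alpha``); None on constant images.

    Maximises the summed order-``alpha`` Renyi entropies of the background
    and foreground grey-level distributions over all split points of a
    256-bin histogram.  Foreground is ``image > threshold``.
    """
    return _entropy_threshold(image, alpha)


def threshold_max_entropy(image):
    """Kapur maximum-entropy threshold (Shannon limit of the Renyi family)."""
    return _entropy_threshold(image, 1.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(blue, sigma_low: float = 1.0, sigma_high: float = 15.0,
                   min_peak_distance: int = 5, min_size_px: int = 16):
    """Binary nuclei mask from the nuclear-stain channel.

    Difference-of-Gaussians band-pass (``sigma_low``, ``sigma_high`` in
    pixels), Renyi-entropy threshold, removal of sub-nuclear specks below
    ``min_size_px``, hole filling, then a watershed on the distance
    transform whose ridge lines are cut from the mask so touching nuclei
    separate into distinct connected components.
    """
    blue = np.asarray(blue, dtype=float)
    if blue.ndim != 2 or blue.size == 0:
        raise ValueError("blue channel must be a nonempty 2-D array")
    bandpassed = gaussian(blue, sigma_low, preserve_range=True) - gaussian(
        blue, sigma_high, preserve_range=True
    )
    t = threshold_renyi_entropy(bandpassed)
    if t is None:
        return np.zeros(blue.shape, dtype=bool)
    mask = bandpassed > t
    mask = remove_small_objects(mask, max_size=min_size_px - 1)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return mask
    distance = ndi.distance_transform_edt(mask)
    # light smoothing removes discretisation plateaus that would seed
    # spurious peaks inside a single convex nucleus
    distance_s = ndi.gaussian_filter(distance, sigma=1.0)
    peaks = peak_local_max(distance_s, min_distance=min_peak_distance, labels=mask)
    if peaks.shape[0] == 0:
        return mask
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = watershed(-distance_s, markers, mask=mask, watershed_line=True)
    return mask & (labels > 0)


def classify_diameter(diameter_um: float) -> str:
    """Size class of an equivalent circular diameter in um."""
    if diameter_um < SMALL_MAX_DIAMETER_UM:
        return "small"
    if diameter_um > LARGE_MIN_DIAMETER_UM:
        return "large"
    return "medium"


def segment_aggregates(green, nuclei_mask, pixel_size: float):
    """Label aggregates on the green channel and tabulate their morphometry.

    Kapur max-entropy threshold, nuclei pixels excluded, 8-connected
    components, components below 5 um^2 dropped.  Returns
    ``(label_image, table)`` where the table has one row per aggregate with
    label id, area (um^2), perimeter (um), equivalent diameter (um) and
    size class.
    """
    green = np.asarray(green)
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    if green.shape != nuclei_mask.shape:
        raise ValueError("green channel and nuclei mask shapes differ")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    columns = ["label", "area_um2", "perimeter_um", "equivalent_diameter_um", "size_class"]
    t = threshold_max_entropy(green)
    if t is None:
        return np.zeros(green.shape, dtype=int), pd.DataFrame(columns=columns)
    mask = (np.asarray(green, dtype=float) > t) & ~nuclei_mask
    labels = cc_label(mask, connectivity=2)  # 8-connectivity
    records = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    px_area = pixel_size * pixel_size
    for rp in regionprops(labels):
        area_um2 = rp.area * px_area
        if area_um2 < MIN_AGGREGATE_AREA_UM2:
            continue
        keep[rp.label] = True
        d_um = rp.equivalent_diameter_area * pixel_size
        records.append(
            {
                "label": rp.label,
                "area_um2": area_um2,
                "perimeter_um": rp.perimeter * pixel_size,
                "equivalent_diameter_um": d_um,
                "size_class": classify_diameter(d_um),
            }
        )
    labels = np.where(keep[labels], labels, 0)
    table = pd.DataFrame.from_records(records, columns=columns)
    return labels, table


def segment_placenta(green, blue, sigma: float = 10.0, closing_radius: int = 5):
    """Whole-placenta mask from the combined channels.

    Each channel is min-max rescaled to 8-bit range, averaged, Gaussian
    blurred, thresholded at the mean intensity, then closed and
    hole-filled.  Constant input yields an empty mask.
    """
    green = np.asarray(green, dtype=float)
    blue = np.asarray(blue, dtype=float)
    if green.shape != blue.shape:
        raise ValueError("channel shapes differ")

    def _rescale(ch):
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            return np.zeros_like(ch)
        return (ch - lo) / (hi - lo) * 255.0

    combined = 0.5 * (_rescale(green) + _rescale(blue))
    if combined.max() == combined.min():
        return np.zeros(green.shape, dtype=bool)
    blurred = gaussian(combined, sigma, preserve_range=True)
    mask = blurred > threshold_mean(blurred)
    mask = closing(mask, disk(closing_radius))
    return ndi.binary_fill_holes(mask)


def quantify(table: pd.DataFrame, placenta_mask, pixel_size: float) -> PlacentaStats:
    """Placenta-normalised aggregate statistics.

    Relative area is total aggregate area divided by placental area;
    relative count is the number of aggregates per um^2 of placenta.
    """
    placenta_mask = np.asarray(placenta_mask, dtype=bool)
    placenta_area = float(placenta_mask.sum()) * pixel_size * pixel_size
    if placenta_area <= 0:
        raise ZeroDivisionError("placenta mask is empty; cannot normalise")
    classes = ("small", "medium", "large")
    if len(table) == 0:
        zero = {c: 0 for c in classes}
        zerof = {c: 0.0 for c in classes}
        return PlacentaStats(
            total_count=0, total_area_um2=0.0, placenta_area_um2=placenta_area,
            relative_area=0.0, relative_count_per_um2=0.0,
            count_by_class=zero, area_by_class=zerof,
            relative_area_by_class=zerof, relative_count_by_class=dict(zerof),
        )
    total_area = float(table["area_um2"].sum())
    count_by_class = {c: int((table["size_class"] == c).sum()) for c in classes}
    area_by_class = {
        c: float(table.loc[table["size_class"] == c, "area_um2"].sum()) for c in classes
    }
    return PlacentaStats(
        total_count=int(len(table)),
        total_area_um2=total_area,
        placenta_area_um2=placenta_area,
        relative_area=total_area / placenta_area,
        relative_count_per_um2=len(table) / placenta_area,
        count_by_class=count_by_class,
        area_by_class=area_by_class,
        relative_area_by_class={c: area_by_class[c] / placenta_area for c in classes},
        relative_count_by_class={c: count_by_class[c] / placenta_area for c in classes},
    )
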