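"""Image analysis: preprocessing, compartment counting, colocalization.

Re-implements the quantification logic of the live-imaging and
immunofluorescence macros:

* median filter (1 px radius) then rolling-ball background subtraction
  (radius 10–50 px) per 2D plane;
* counting of small punctate compartments (connected component area below a
  size cutoff, default 15 px) via local-maxima detection;
* region intensity kinetics for Golgi-like (>= 20 px) and large (>= 15 px)
  compartments;
* Pearson correlation inside a cytoplasm mask, thresholded Mander's
  coefficients, and 3-channel mask-volume overlap fractions;
* whole-mount EV diameter estimation from bounding rectangles
  (diameter = (height + width) / 2).

Size thresholds are component areas in pixels (2D) or voxels (3D); the
alternative diameter reading can be obtained by converting before the call.
Coordinates are 0-based (z, y, x).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    stack: np.ndarray, median_radius: int = 1, rollball_radius: int = 25
) -> np.ndarray:
    """Median filter then rolling-ball background subtraction, per 2D plane.

    ``stack`` may be 2D (y, x) or have any number of leading axes (t, c, z)
    before the two spatial axes.  Output is clipped at zero.
    """
    if median_radius <= 0 or rollball_radius <= 0:
        raise ValueError("radii must be positive")
    ny, nx = stack.shape[-2:]
    if rollball_radius >= min(ny, nx):
        raise ValueError("rolling-ball radius must be smaller than the image extent")
    arr = np.asarray(stack, dtype=float)
    flat = arr.reshape(-1, ny, nx)
    footprint = morphology.disk(median_radius)
    out = np.empty_like(flat)
    for i, plane in enumerate(flat):
        med = ndimage.median_filter(plane, footprint=footprint)
        bg = rolling_ball(med, radius=rollball_radius)
        out[i] = np.clip(med - bg, 0.0, None)
    return out.reshape(arr.shape)


# ---------------------------------------------------------------------------
# compartment counting and kinetics
# ---------------------------------------------------------------------------

def _as_timeseries(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("expected (y, x) or (t, y, x) input")
    return frames


def count_small_compartments(
    frames: np.ndarray,
    prominence: float,
    max_size: int = 15,
    threshold: float | None = None,
) -> np.ndarray:
    """Count small punctate compartments per timepoint.

    Local maxima at least ``prominence`` above zero are detected inside the
    thresholded foreground (``threshold`` defaults to ``prominence``); each
    maximum is assigned to its connected component and counted when that
    component's area is strictly below ``max_size`` pixels.  At most one
    maximum per component is counted, so a plateau is a single compartment.
    """
    frames = _as_timeseries(frames)
    thr = prominence if threshold is None else threshold
    counts = np.zeros(len(frames), dtype=int)
    for t, img in enumerate(frames):
        labels = measure.label(img > thr, connectivity=2)
        if labels.max() == 0:
            continue
        peaks = peak_local_max(
            img,
            labels=labels,
            num_peaks_per_label=1,
            threshold_abs=float(prominence),
        )
        if len(peaks) == 0:
            continue
        areas = np.bincount(labels.ravel())
        comp = labels[tuple(peaks.T)]
        counts[t] = int(np.sum(areas[comp] < max_size))
    return counts


def region_intensity_kinetics(
    frames: np.ndarray,
    intensity_threshold: float,
    golgi_size_threshold: int = 20,
    large_size_threshold: int = 15,
    large_start: int = 0,
) -> pd.DataFrame:
    """Mean intensity in Golgi-like and large compartments per timepoint.

    Connected components above ``intensity_threshold`` qualify as Golgi-like
    when their area is >= ``golgi_size_threshold`` pixels and as large
    compartments when >= ``large_size_threshold`` pixels; the latter series
    is only measured from timepoint ``large_start`` on (the start of
    post-Golgi measurement is supplied by the caller).  Timepoints with no
    qualifying component are recorded as NaN, not 0.
    """
    frames = _as_timeseries(frames)
    rows = []
    for t, img in enumerate(frames):
        labels = measure.label(img > intensity_threshold, connectivity=2)
        areas = np.bincount(labels.ravel())
        golgi = np.nan
        large = np.nan
        if labels.max() > 0:
            golgi_ids = [i for i in range(1, len(areas)) if areas[i] >= golgi_size_threshold]
            if golgi_ids:
                golgi = float(img[np.isin(labels, golgi_ids)].mean())
            if t >= large_start:
                large_ids = [
                    i for i in range(1, len(areas)) if areas[i] >= large_size_threshold
                ]
                if large_ids:
                    large = float(img[np.isin(labels, large_ids)].mean())
        rows.append({"timepoint": t, "golgi_mean": golgi, "large_mean": large})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def pearson_in_mask(
    ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Sample Pearson correlation between two channels inside a mask.

    Returns NaN (with a warning) when either channel has zero variance
    within the mask.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs from channels")
        if not mask.any():
            raise ValueError("mask is empty")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance inside mask: Pearson undefined")
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def manders(
    ch1: np.ndarray, ch2: np.ndarray, threshold1: float, threshold2: float
) -> tuple[float, float]:
    """Thresholded Mander's coefficients (M1, M2).

    M1 is the fraction of above-threshold channel-1 intensity located where
    channel 2 is also above its threshold; M2 is symmetric.  Both lie in
    [0, 1].  A channel with no above-threshold signal yields NaN for its
    coefficient (flagged by warning).
    """
    if threshold1 < 0 or threshold2 < 0:
        raise ValueError("thresholds must be >= 0")
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    pos1 = a > threshold1
    pos2 = b > threshold2
    denom1 = a[pos1].sum()
    denom2 = b[pos2].sum()
    if denom1 > 0:
        m1 = float(a[pos1 & pos2].sum() / denom1)
    else:
        logger.warning("no channel-1 signal above threshold: M1 undefined")
        m1 = float("nan")
    if denom2 > 0:
        m2 = float(b[pos1 & pos2].sum() / denom2)
    else:
        logger.warning("no channel-2 signal above threshold: M2 undefined")
        m2 = float("nan")
    return m1, m2


def triple_overlap(masks: Sequence[np.ndarray]) -> pd.DataFrame:
    """Pairwise and three-way mask-volume overlap fractions.

    For ordered pair (i, j): |mask_i & mask_j| / |mask_i|; additionally
    |mask_0 & mask_1 & mask_2| / |mask_i| for each i.  Rows with an empty
    reference mask are NaN (warning logged).
    """
    if len(masks) != 3:
        raise ValueError("expected exactly three masks")
    ms = [np.asarray(m, dtype=bool) for m in masks]
    if not (ms[0].shape == ms[1].shape == ms[2].shape):
        raise ValueError("mask shapes differ")
    sizes = [int(m.sum()) for m in ms]
    inter_all = int((ms[0] & ms[1] & ms[2]).sum())
    rows = []
    for i in range(3):
        if sizes[i] == 0:
            logger.warning("mask %d is empty: its overlap row is undefined", i)
        for j in range(3):
            if i == j:
                continue
            frac = (
                float((ms[i] & ms[j]).sum() / sizes[i]) if sizes[i] else float("nan")
            )
            rows.append({"reference": i, "other": j, "overlap_fraction": frac})
        rows.append(
            {
                "reference": i,
                "other": -1,  # -1 = all three channels
                "overlap_fraction": float(inter_all / sizes[i]) if sizes[i] else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-mount EV sizing
# ---------------------------------------------------------------------------

def ev_diameter(
    bounding_rectangles: Sequence[tuple[float, float]],
    bin_width: float = 10.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """EV diameters from bounding rectangles, plus a frequency histogram.

    Each structure's diameter is the mean of the height and width of the
    rectangle drawn around it.  Rectangles with a non-positive dimension are
    rejected with a warning.  Histogram frequencies sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    diam = []
    for h, w in bounding_rectangles:
        if h <= 0 or w <= 0:
            logger.warning("rejected rectangle with non-positive dimension (%s, %s)", h, w)
            continue
        diam.append((h + w) / 2.0)
    diameters = np.asarray(diam, dtype=float)
    if len(diameters) == 0:
        return diameters, pd.DataFrame(
            columns=["bin_left", "bin_right", "count", "frequency"]
        )
    top = np.ceil(diameters.max() / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(diameters, bins=edges)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
    return diameters, hist
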