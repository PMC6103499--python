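"""Per-superpixel region descriptors: the node and edge feature vectors.

Four families of handcrafted features are computed for every region node:

* 14 first-order intensity statistics (mean, spread, shape of the gray-level
  distribution, entropy);
* 44 run-length-of-centralized-patterns (RLCP) texture features: the image is
  LBP-coded, codes are quantized to 16 levels, and 11 gray-level run-length
  statistics are computed along each of the four principal directions
  (0, 45, 90, 135 degrees);
* 1 curvature feature: the mean level-set curvature of the (smoothed)
  intensity surface over the region;
* 12 fractal features: a 4-threshold multi-Otsu quantization yields four
  binary channels, each summarized by (area fraction, mean intensity,
  box-counting fractal dimension).

Node vectors have 71 named columns; z-score standardization is fitted on
training nodes only and reapplied verbatim at test time.  Edge vectors are
[1, |delta mean intensity|, centroid distance] for each graph edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.filters import threshold_multiotsu

from .superpixels import RegionGraph, SuperpixelMap

__all__ = [
    "FeatureTable",
    "EdgeFeatures",
    "FIRST_ORDER_NAMES",
    "GLRL_NAMES",
    "NODE_FEATURE_NAMES",
    "first_order_stats",
    "lbp_image",
    "glrl_matrix",
    "glrl_features",
    "rlcp_features",
    "curvature_map",
    "mean_region_curvature",
    "box_counting_dimension",
    "fractal_features",
    "assemble_node_features",
    "assemble_edge_features",
    "fit_standardization",
]

FIRST_ORDER_NAMES = [
    "mean", "std", "variance", "mean_abs_dev", "median_abs_dev", "cv",
    "skewness", "kurtosis", "max", "mode", "third_central_moment", "range",
    "iqr", "entropy",
]

GLRL_NAMES = [
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
]

RLCP_DIRECTIONS = (0, 45, 90, 135)

NODE_FEATURE_NAMES = (
    FIRST_ORDER_NAMES
    + [f"rlcp_{d}_{s}" for d in RLCP_DIRECTIONS for s in GLRL_NAMES]
    + ["curvature_mean"]
    + [f"fractal_t{k}_{q}" for k in range(1, 5) for q in ("area", "mean_intensity", "box_dim")]
)

EDGE_FEATURE_NAMES = ["bias", "abs_dmean", "centroid_dist"]


@dataclass
class FeatureTable:
    """Node feature matrix with named columns and standardization state."""

    data: pd.DataFrame           # n_nodes x n_features
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def standardized(self, center: np.ndarray | None = None,
                     scale: np.ndarray | None = None) -> "FeatureTable":
        """Z-score the columns; with no arguments, fit on this table."""
        if center is None or scale is None:
            center, scale = fit_standardization([self])
        z = (self.values - center) / scale
        return FeatureTable(data=pd.DataFrame(z, columns=self.data.columns,
                                              index=self.data.index),
                            center=center, scale=scale)


def fit_standardization(tables: list["FeatureTable"]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column center/scale over the stacked training nodes.

    Columns with (numerically) zero spread get unit scale so standardization
    never produces NaN.
    """
    x = np.concatenate([t.values for t in tables], axis=0)
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return center, scale


@dataclass
class EdgeFeatures:
    """Per-edge feature vectors [1, |delta mean intensity|, centroid distance]."""

    data: np.ndarray            # n_edges x 3
    edges: np.ndarray           # n_edges x 2 node pairs

    def __post_init__(self) -> None:
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("edge features must be finite")


# ---------------------------------------------------------------------------
# first-order statistics

def first_order_stats(values: np.ndarray, entropy_bins: int = 32) -> np.ndarray:
    """The 14 first-order intensity statistics of a region, in fixed order.

    Population (biased) moment conventions throughout; for a constant region
    the scale-dependent shape statistics (cv, skewness, excess kurtosis) are
    defined as 0, and entropy is 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    mean = v.mean()
    var = v.var()
    std = np.sqrt(var)
    mad_mean = np.abs(v - mean).mean()
    mad_median = np.median(np.abs(v - np.median(v)))
    if std < 1e-12:
        cv = skew = kurt = 0.0
    else:
        cv = std / mean if abs(mean) > 1e-12 else 0.0
        skew = float(sps.skew(v))
        kurt = float(sps.kurtosis(v))  # Fisher: excess kurtosis
    vmax = v.max()
    mode = float(sps.mode(v, keepdims=False).mode)
    mu3 = float(sps.moment(v, order=3))
    vrange = vmax - v.min()
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    if vrange < 1e-12:
        entropy = 0.0
    else:
        hist, _ = np.histogram(v, bins=entropy_bins, range=(v.min(), vmax))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    return np.array([mean, std, var, mad_mean, mad_median, cv, skew, kurt,
                     vmax, mode, mu3, vrange, iqr, entropy])


# ---------------------------------------------------------------------------
# RLCP texture: LBP coding + gray-level run-length statistics

# 8-neighborhood offsets (row, col), counterclockwise from east; bit p has
# weight 2**p
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_image(image: np.ndarray, P: int = 8, R: int = 1) -> np.ndarray:
    """Classic local binary pattern code per pixel.

    Bit p is 1 iff the p-th neighbor is >= the center value; borders are
    handled by edge replication.  Only the classic square 8-neighborhood at
    radius 1 is supported.
    """
    if (P, R) != (8, 1):
        raise ValueError("only the classic P=8, R=1 neighborhood is supported")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    padded = np.pad(img, 1, mode="edge")
    code = np.zeros(img.shape, dtype=np.int32)
    for p, (dy, dx) in enumerate(_LBP_OFFSETS):
        neigh = padded[1 + dy : 1 + dy + img.shape[0], 1 + dx : 1 + dx + img.shape[1]]
        code |= (neigh >= img).astype(np.int32) << p
    return code


def _direction_lines(arr: np.ndarray, valid: np.ndarray, direction: int):
    """Yield (values, mask) 1-D lines of a bounding-box array along a
    run-length direction."""
    h, w = arr.shape
    if direction == 0:
        for r in range(h):
            yield arr[r], valid[r]
    elif direction == 90:
        for c in range(w):
            yield arr[:, c], valid[:, c]
    elif direction == 45:
        flipped, fvalid = arr[::-1], valid[::-1]
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=k), np.diagonal(fvalid, offset=k)
    elif direction == 135:
        for k in range(-(h - 1), w):
            yield np.diagonal(arr, offset=k), np.diagonal(valid, offset=k)
    else:
        raise ValueError("direction must be one of 0, 45, 90, 135")


def glrl_matrix(levels: np.ndarray, mask: np.ndarray, direction: int,
                n_levels: int = 16) -> np.ndarray:
    """Gray-level run-length matrix of a masked region along one direction.

    Entry (g, l-1) counts maximal runs of level g with length l; runs never
    cross pixels outside the region mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    levels = np.asarray(levels)
    rows = np.flatnonzero(np.any(mask, axis=1))
    cols = np.flatnonzero(np.any(mask, axis=0))
    rsl = slice(rows[0], rows[-1] + 1)   # contiguous bounding box: boolean
    csl = slice(cols[0], cols[-1] + 1)   # selection would glue runs together
    sub = levels[rsl, csl]
    subm = mask[rsl, csl]
    max_run = max(sub.shape)
    m = np.zeros((n_levels, max_run), dtype=np.int64)
    for vals, ok in _direction_lines(sub, subm, direction):
        run_level, run_len = -1, 0
        for v, o in zip(vals, ok):
            if not o:
                if run_len:
                    m[run_level, run_len - 1] += 1
                run_level, run_len = -1, 0
            elif v == run_level:
                run_len += 1
            else:
                if run_len:
                    m[run_level, run_len - 1] += 1
                run_level, run_len = int(v), 1
        if run_len:
            m[run_level, run_len - 1] += 1
    return m


def glrl_features(matrix: np.ndarray, n_pixels: int) -> np.ndarray:
    """The 11 extended run-length statistics of one run-length matrix.

    SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, with
    gray levels indexed 1..G and run lengths 1..L.
    """
    m = np.asarray(matrix, dtype=float)
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("run-length matrix has no runs")
    g = np.arange(1, m.shape[0] + 1)[:, None].astype(float)
    l = np.arange(1, m.shape[1] + 1)[None, :].astype(float)
    sre = (m / l**2).sum() / n_runs
    lre = (m * l**2).sum() / n_runs
    gln = (m.sum(axis=1) ** 2).sum() / n_runs
    rln = (m.sum(axis=0) ** 2).sum() / n_runs
    rp = n_runs / n_pixels
    lgre = (m / g**2).sum() / n_runs
    hgre = (m * g**2).sum() / n_runs
    srlge = (m / (g**2 * l**2)).sum() / n_runs
    srhge = (m * g**2 / l**2).sum() / n_runs
    lrlge = (m * l**2 / g**2).sum() / n_runs
    lrhge = (m * g**2 * l**2).sum() / n_runs
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


def rlcp_features(lbp_coded: np.ndarray, mask: np.ndarray,
                  n_levels: int = 16) -> np.ndarray:
    """Run length of centralized patterns: 44 = 11 x 4 texture features.

    LBP codes (0..255) are quantized into ``n_levels`` equal bins, then the
    11 run-length statistics are computed along 0, 45, 90 and 135 degrees
    within the region mask and concatenated in that direction order.
    """
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels < 4:
        raise ValueError("region too small for run-length texture")
    levels = (np.asarray(lbp_coded) * n_levels) // 256
    out = [glrl_features(glrl_matrix(levels, mask, d, n_levels), n_pixels)
           for d in RLCP_DIRECTIONS]
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# curvature

def curvature_map(image: np.ndarray, mode: str = "standard",
                  smooth_sigma: float = 1.0, grad_tol: float = 1e-8) -> np.ndarray:
    """Per-pixel 2-D curvature of the intensity surface's level sets.

    ``standard`` is the level-set curvature
    kappa = (f_xx f_y^2 - 2 f_xy f_x f_y + f_yy f_x^2) / (f_x^2 + f_y^2)^{3/2};
    ``as_printed`` is an alternative form without the mixed-derivative term,
    (f_xx f_y^2 + f_yy f_y^2 - 2 f_xx f_x f_y) / (f_x^2 + f_y^2)^{3/2}.
    Pixels with vanishing gradient get curvature 0.  The image is smoothed
    with a Gaussian of sd ``smooth_sigma`` before differentiation.
    """
    img = np.asarray(image, dtype=float)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma)
    f_y, f_x = np.gradient(img)
    f_yy, f_yx = np.gradient(f_y)
    f_xy, f_xx = np.gradient(f_x)
    g2 = f_x**2 + f_y**2
    if mode == "standard":
        num = f_xx * f_y**2 - 2.0 * f_xy * f_x * f_y + f_yy * f_x**2
    elif mode == "as_printed":
        num = f_xx * f_y**2 + f_yy * f_y**2 - 2.0 * f_xx * f_x * f_y
    else:
        raise ValueError("mode must be 'standard' or 'as_printed'")
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = num / g2**1.5
    kappa[g2 < grad_tol] = 0.0
    return kappa


def mean_region_curvature(curv: np.ndarray, mask: np.ndarray) -> float:
    """Region curvature feature: mean pixel curvature over the region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    return float(curv[mask].mean())


# ---------------------------------------------------------------------------
# fractal features

def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary foreground pattern.

    Boxes are dyadic (side 1, 2, 4, 8, 16 px, clipped to the foreground
    bounding box) on a grid anchored at the bounding-box corner; the
    dimension is minus the least-squares slope of log N(s) against log s.
    Degenerate patterns (fewer than two usable box sizes) return 0.
    """
    bw = np.asarray(binary, dtype=bool)
    if not bw.any():
        return 0.0
    rows = np.flatnonzero(np.any(bw, axis=1))
    cols = np.flatnonzero(np.any(bw, axis=0))
    sub = bw[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = sub.shape
    # clip to the larger bbox side so thin (line-like) patterns keep
    # multiple scales; partial boxes are padded
    sizes = [s for s in (1, 2, 4, 8, 16) if s <= max(h, w)]
    if len(sizes) < 2:
        return 0.0
    counts = []
    for s in sizes:
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(sub, ((0, ph), (0, pw)))
        boxes = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts.append(boxes.any(axis=(1, 3)).sum())
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def fractal_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """12 fractal features from 4 Otsu-thresholded binary channels.

    Region intensities are quantized by multi-level Otsu into 5 classes
    (4 thresholds); binary channel k is the indicator of intensity >=
    threshold k.  Each channel yields (area fraction, mean original intensity
    under the channel, box-counting dimension); empty channels yield
    (0, 0, 0).
    """
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels < 16:
        raise ValueError("region too small for fractal features")
    img = np.asarray(image, dtype=float)
    vals = img[mask]
    uniq = np.unique(vals)
    if uniq.size >= 5:
        # 32-bin histogram keeps the combinatorial threshold search cheap
        # for the 4-threshold case at negligible loss of precision
        try:
            thresholds = threshold_multiotsu(vals, classes=5, nbins=32)
        except ValueError:
            thresholds = _fallback_thresholds(uniq)
    else:
        thresholds = _fallback_thresholds(uniq)
    out = []
    for t in thresholds:
        chan = mask & (img >= t)
        area = chan.sum() / n_pixels
        if chan.any():
            mean_int = float(img[chan].mean())
            dim = box_counting_dimension(chan)
        else:
            mean_int, dim = 0.0, 0.0
        out.extend([area, mean_int, dim])
    return np.array(out)


def _fallback_thresholds(uniq: np.ndarray) -> np.ndarray:
    """Thresholds when a region has too few distinct values for multi-Otsu:
    midpoints between consecutive distinct values, padded with the maximum."""
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([], dtype=float)
    pad = np.full(max(0, 4 - mids.size), uniq[-1])
    return np.concatenate([mids, pad])[:4]


# ---------------------------------------------------------------------------
# assembly

def assemble_node_features(
    image: np.ndarray,
    sp: SuperpixelMap,
    curvature_mode: str = "standard",
    curvature_sigma: float = 1.0,
    entropy_bins: int = 32,
    glrl_levels: int = 16,
) -> FeatureTable:
    """All 71 node features for every superpixel of a slice (unstandardized)."""
    img = np.asarray(image, dtype=float)
    if img.shape != sp.labels.shape:
        raise ValueError("image and superpixel map shapes differ")
    coded = lbp_image(img)
    curv = curvature_map(img, mode=curvature_mode, smooth_sigma=curvature_sigma)
    rows = np.empty((sp.n_regions, len(NODE_FEATURE_NAMES)))
    for rid in range(sp.n_regions):
        mask = sp.labels == rid
        vals = img[mask]
        rows[rid] = np.concatenate([
            first_order_stats(vals, entropy_bins=entropy_bins),
            rlcp_features(coded, mask, n_levels=glrl_levels),
            [mean_region_curvature(curv, mask)],
            fractal_features(img, mask),
        ])
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite feature value produced")
    df = pd.DataFrame(rows, columns=NODE_FEATURE_NAMES)
    df.index.name = "region_id"
    return FeatureTable(data=df)


def assemble_edge_features(image: np.ndarray, sp: SuperpixelMap,
                           graph: RegionGraph) -> EdgeFeatures:
    """Pairwise features [1, |delta mean intensity|, centroid distance] per edge."""
    img = np.asarray(image, dtype=float)
    total = sp.region_sizes().astype(float)
    sums = np.bincount(sp.labels.ravel(), weights=img.ravel(), minlength=sp.n_regions)
    means = sums / total
    e = graph.edges
    if e.size == 0:
        return EdgeFeatures(data=np.empty((0, 3)), edges=e)
    dmean = np.abs(means[e[:, 0]] - means[e[:, 1]])
    dcent = np.linalg.norm(graph.centroids[e[:, 0]] - graph.centroids[e[:, 1]], axis=1)
    data = np.stack([np.ones(len(e)), dmean, dcent], axis=1)
    return EdgeFeatures(data=data, edges=e)
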