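"""Distribution-shape classification and conformational substates.

Tetranucleotide sequence effects show up as non-Gaussian, sometimes
multimodal, distributions of the inter-BP parameters shift, slide and twist.
This module provides an operational shape classifier (kernel-density peak
detection, skewness/kurtosis screens and a unimodality dip statistic),
3-D probability-density grids in (shift, slide, twist) with isolevel region
analysis, the shift-sign reading-direction convention, and the assignment of
snapshots to low-twist / canonical / high-twist substates conditioned on
backbone BI/BII states:

* RR steps: the Watson backbone of the central junction in BII marks the
  high-twist substate candidate (twist offset ≈ +5°);
* YR steps: at least one 3'-flanking junction (W3' or C3') in BII marks the
  low-twist substate candidate (twist offset ≈ −15°);
* RY steps: a single canonical substate.

Substate centres are estimated from the conditioned data themselves, so the
three-state picture is emergent rather than imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .sequence import canonical_reading, reverse_complement

__all__ = [
    "NEGATIVE_SHIFT_STEPS",
    "reading_direction",
    "ShapeConfig",
    "DistributionShape",
    "classify_shape",
    "peak_locations",
    "kde_grid",
    "dip_statistic",
    "DensityGrid3D",
    "density3d",
    "SubstateAssignment",
    "assign_substates",
]

#: Dinucleotide readings with negative average shift; they fix the direction
#: in which every non-self-complementary tetranucleotide is read.
NEGATIVE_SHIFT_STEPS = frozenset({"GG", "GA", "AG", "AA", "GT", "CA"})

_SELF_COMPLEMENTARY_STEPS = frozenset({"AT", "TA", "CG", "GC"})


def reading_direction(tetra: str) -> tuple[str, bool]:
    """Orient a tetranucleotide by the shift-sign convention.

    Returns ``(oriented sequence, flipped)``.  Non-self-complementary central
    steps are read in the direction that places the central dinucleotide in
    the negative-average-shift set {GG, GA, AG, AA, GT, CA}; self-
    complementary central steps keep the canonical class-name direction.
    Idempotent: reapplying to the result changes nothing.
    """
    up = tetra.upper()
    if len(up) != 4:
        raise ValueError("a tetranucleotide is a 4-letter sequence")
    central = up[1:3]
    if central in _SELF_COMPLEMENTARY_STEPS:
        oriented = canonical_reading(up)
        return oriented, oriented != up
    if central in NEGATIVE_SHIFT_STEPS:
        return up, False
    rc = reverse_complement(up)
    if rc[1:3] in NEGATIVE_SHIFT_STEPS:
        return rc, True
    raise ValueError(f"central step {central!r} in neither orientation set")


# ---------------------------------------------------------------------------
# Kernel density estimation and peak finding
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.349
    spread = min(sd, iqr) if iqr > 0 else sd
    if spread <= 0:
        return 1e-6
    return 0.9 * spread * x.size ** (-0.2)


def kde_grid(samples, bandwidth: float | None = None, grid_size: int = 1024,
             circular: bool = False):
    """Gaussian kernel density estimate on a uniform grid.

    Implemented as a fine histogram smoothed with a Gaussian filter (exact up
    to grid resolution, deterministic, O(n + grid)).  Circular data are
    estimated on the [0°, 360°) wheel with wrapped smoothing.  Returns
    ``(grid, density, bandwidth)``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if circular:
        x = x % 360.0
        edges = np.linspace(0.0, 360.0, grid_size + 1)
        counts, _ = np.histogram(x, bins=edges)
        step = 360.0 / grid_size
        density = ndimage.gaussian_filter1d(counts.astype(float), bandwidth / step, mode="wrap")
    else:
        lo, hi = np.min(x) - 3 * bandwidth, np.max(x) + 3 * bandwidth
        edges = np.linspace(lo, hi, grid_size + 1)
        counts, _ = np.histogram(x, bins=edges)
        step = (hi - lo) / grid_size
        density = ndimage.gaussian_filter1d(counts.astype(float), bandwidth / step, mode="constant")
    grid = 0.5 * (edges[:-1] + edges[1:])
    density /= density.sum() * step
    return grid, density, bandwidth


def _find_peaks(grid, density, bandwidth, prominence_frac=0.05, circular=False):
    step = grid[1] - grid[0]
    min_dist = max(1, int(round(2 * bandwidth / step)))
    if circular:
        k = int(np.argmin(density))
        rolled = np.roll(density, -k)
        idx, props = signal.find_peaks(
            rolled, prominence=prominence_frac * rolled.max(), distance=min_dist
        )
        idx = (idx + k) % len(density)
    else:
        padded = np.concatenate([[0.0], density, [0.0]])
        idx, props = signal.find_peaks(
            padded, prominence=prominence_frac * density.max(), distance=min_dist
        )
        idx = idx - 1
    locs = []
    for i in idx:
        # quadratic interpolation of the peak abscissa
        if 0 < i < len(density) - 1:
            y0, y1, y2 = density[i - 1], density[i], density[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-300 else 0.0
        else:
            delta = 0.0
        locs.append(grid[i] + delta * step)
    order = np.argsort(locs)
    return np.asarray(locs)[order], props["prominences"][order] if len(idx) else np.array([])


def peak_locations(samples, circular: bool = False, prominence_frac: float = 0.05,
                   bandwidth: float | None = None) -> np.ndarray:
    """Ordered KDE mode estimates above the prominence threshold."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 1000:
        raise ValueError("need at least 1000 samples for mode estimation")
    grid, density, bw = kde_grid(x, bandwidth, circular=circular)
    locs, _ = _find_peaks(grid, density, bw, prominence_frac, circular)
    return locs


# ---------------------------------------------------------------------------
# Dip (unimodality deviation) statistic
# ---------------------------------------------------------------------------

_DIP_SUBSAMPLE = 120
_DIP_NULL_REPS = 400
_dip_critical_cache: dict[tuple[int, float], float] = {}


def dip_statistic(x) -> float:
    """Hartigan-type unimodality deviation of a sample.

    Defined here as half the minimum, over candidate modes m, of the largest
    vertical deviation between the empirical CDF and its best unimodal
    envelope (greatest convex minorant left of m, least concave majorant
    right of m).  Zero for perfectly unimodal ECDFs; large for well-separated
    mixtures.  Calibrated by simulation (see :func:`dip_critical_value`).
    """
    xs = np.sort(np.asarray(x, dtype=float).ravel())
    n = xs.size
    if n < 4:
        raise ValueError("need at least 4 points")
    f = (np.arange(1, n + 1)) / n
    xs_l = xs.tolist()
    f_l = f.tolist()

    def prefix_dev(m):  # max deviation of ECDF above its convex minorant on [0..m]
        hull = [0]
        dev = 0.0
        for i in range(1, m + 1):
            while len(hull) >= 2:
                a, b = hull[-2], hull[-1]
                if (f_l[b] - f_l[a]) * (xs_l[i] - xs_l[b]) >= (f_l[i] - f_l[b]) * (xs_l[b] - xs_l[a]):
                    hull.pop()
                else:
                    break
            hull.append(i)
        # deviation of every prefix point above the hull
        j = 0
        for i in range(m + 1):
            while j < len(hull) - 1 and xs_l[hull[j + 1]] <= xs_l[i]:
                j += 1
            a = hull[j]
            b = hull[min(j + 1, len(hull) - 1)]
            if xs_l[b] > xs_l[a]:
                g = f_l[a] + (f_l[b] - f_l[a]) * (xs_l[i] - xs_l[a]) / (xs_l[b] - xs_l[a])
            else:
                g = f_l[a]
            if f_l[i] - g > dev:
                dev = f_l[i] - g
        return dev

    def suffix_dev(m):  # max deviation of ECDF below its concave majorant on [m..n-1]
        # mirror to reuse the convex-minorant logic: u = -x reversed,
        # G = survival of the ECDF lower steps reversed
        idxs = range(n - 1, m - 1, -1)
        rev_x = [-xs_l[i] for i in idxs]
        rev_f = [1.0 - i / n for i in idxs]
        hull = [0]
        dev = 0.0
        k = len(rev_x)
        for i in range(1, k):
            while len(hull) >= 2:
                a, b = hull[-2], hull[-1]
                if (rev_f[b] - rev_f[a]) * (rev_x[i] - rev_x[b]) >= (rev_f[i] - rev_f[b]) * (rev_x[b] - rev_x[a]):
                    hull.pop()
                else:
                    break
            hull.append(i)
        j = 0
        for i in range(k):
            while j < len(hull) - 1 and rev_x[hull[j + 1]] <= rev_x[i]:
                j += 1
            a = hull[j]
            b = hull[min(j + 1, len(hull) - 1)]
            if rev_x[b] > rev_x[a]:
                g = rev_f[a] + (rev_f[b] - rev_f[a]) * (rev_x[i] - rev_x[a]) / (rev_x[b] - rev_x[a])
            else:
                g = rev_f[a]
            if rev_f[i] - g > dev:
                dev = rev_f[i] - g
        return dev

    best = math.inf
    stride = max(1, n // 60)
    for m in range(0, n, stride):
        d = max(prefix_dev(m), suffix_dev(m))
        if d < best:
            best = d
    return 0.5 * best


def dip_critical_value(n: int, alpha: float = 0.01) -> float:
    """Simulated (1 − alpha) quantile of the dip statistic under a uniform
    (unimodal) null of size n; cached per (n, alpha)."""
    key = (n, alpha)
    if key not in _dip_critical_cache:
        rng = np.random.default_rng(202314)
        vals = [dip_statistic(rng.uniform(size=n)) for _ in range(_DIP_NULL_REPS)]
        _dip_critical_cache[key] = float(np.quantile(vals, 1.0 - alpha))
    return _dip_critical_cache[key]


# ---------------------------------------------------------------------------
# Shape classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeConfig:
    """Thresholds of the operational shape classifier (all configurable)."""

    prominence_frac: float = 0.05  # of the global KDE maximum
    min_separation_bw: float = 2.0  # peak separation in bandwidths
    skew_threshold: float = 0.5
    kurtosis_threshold: float = 1.0
    dip_alpha: float = 0.01
    min_n: int = 1000


@dataclass(frozen=True)
class DistributionShape:
    """Shape label plus the diagnostics that produced it."""

    label: str  # gaussian | non_gaussian | multi_peaked
    peaks: np.ndarray = field(compare=False)
    prominences: np.ndarray = field(compare=False)
    skewness: float = field(compare=False, default=float("nan"))
    excess_kurtosis: float = field(compare=False, default=float("nan"))
    dip: float = field(compare=False, default=float("nan"))
    dip_critical: float = field(compare=False, default=float("nan"))


def classify_shape(samples, circular: bool = False,
                   config: ShapeConfig = ShapeConfig()) -> DistributionShape:
    """Classify a parameter distribution as gaussian / non_gaussian /
    multi_peaked.

    Multi-peaked: the KDE shows ≥ 2 peaks, each with prominence ≥ 5% of the
    global maximum, separated by ≥ 2 bandwidths.  Otherwise non-Gaussian when
    |skewness| > 0.5, excess kurtosis > 1, or the dip statistic of a fixed
    subsample exceeds its simulated 1% critical value.  Else Gaussian.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < config.min_n:
        raise ValueError(f"need at least {config.min_n} samples, got {x.size}")
    grid, density, bw = kde_grid(x, circular=circular)
    locs, proms = _find_peaks(grid, density, bw, config.prominence_frac, circular)
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x))
    if len(locs) >= 2:
        return DistributionShape("multi_peaked", locs, proms, skew, kurt)
    sub_rng = np.random.default_rng(7)
    sub = x if x.size <= _DIP_SUBSAMPLE else sub_rng.choice(x, _DIP_SUBSAMPLE, replace=False)
    dip = dip_statistic(sub)
    crit = dip_critical_value(len(sub), config.dip_alpha)
    if (
        abs(skew) > config.skew_threshold
        or kurt > config.kurtosis_threshold
        or dip > crit
    ):
        return DistributionShape("non_gaussian", locs, proms, skew, kurt, dip, crit)
    return DistributionShape("gaussian", locs, proms, skew, kurt, dip, crit)


# ---------------------------------------------------------------------------
# 3-D density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid3D:
    """Uniform-bin probability density over (shift, slide, twist).

    ``density`` sums to 1 over occupied bins; isolevels are expressed as
    fractions of the maximum density.
    """

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    counts: np.ndarray
    density: np.ndarray

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def regions(self, isolevel_frac: float):
        """Connected regions with density above ``isolevel_frac`` × max.

        Returns a list of ``{"size": bins, "peak": (shift, slide, twist),
        "peak_density": value}`` sorted by descending peak density.
        """
        thr = isolevel_frac * self.density.max()
        labels, n = ndimage.label(self.density > thr)
        out = []
        for lab in range(1, n + 1):
            mask = labels == lab
            sub = np.where(mask, self.density, 0.0)
            peak_idx = np.unravel_index(np.argmax(sub), sub.shape)
            peak = tuple(self.centers(ax)[peak_idx[ax]] for ax in range(3))
            out.append(
                {"size": int(mask.sum()), "peak": peak, "peak_density": float(sub.max())}
            )
        out.sort(key=lambda r: -r["peak_density"])
        return out


def density3d(shift, slide, twist, bin_widths=(0.25, 0.25, 2.0)) -> DensityGrid3D:
    """Uniform-bin 3-D histogram density in (shift Å, slide Å, twist °)."""
    arrs = [np.asarray(a, dtype=float).ravel() for a in (shift, slide, twist)]
    if arrs[0].size == 0:
        raise ValueError("empty input")
    if not (arrs[0].size == arrs[1].size == arrs[2].size):
        raise ValueError("series must be aligned")
    edges = []
    for a, w in zip(arrs, bin_widths):
        lo = math.floor(a.min() / w) * w
        hi = math.ceil(a.max() / w) * w
        if hi <= lo:
            hi = lo + w
        edges.append(lo + np.arange(int(round((hi - lo) / w)) + 1) * w)
    counts, _ = np.histogramdd(np.column_stack(arrs), bins=edges)
    density = counts / counts.sum()
    return DensityGrid3D(tuple(edges), counts, density)


# ---------------------------------------------------------------------------
# Substate assignment
# ---------------------------------------------------------------------------

_TAG_TO_CANDIDATE = {
    "BI": "canonical",
    "BII": "high_twist",
    "BI3'": "canonical",
    "BII3'": "low_twist",
    "canonical": "canonical",
}


@dataclass
class SubstateAssignment:
    labels: np.ndarray  # low_twist | canonical | high_twist per snapshot
    tags: np.ndarray  # backbone conditioning tag per snapshot
    centers: dict[str, tuple[float, float, float]]

    def fractions(self) -> dict[str, float]:
        n = self.labels.size
        return {lab: float(np.mean(self.labels == lab)) for lab in np.unique(self.labels)}


def assign_substates(
    shift,
    slide,
    twist,
    step_family: str,
    watson_bii=None,
    w3_bii=None,
    c3_bii=None,
) -> SubstateAssignment:
    """Assign snapshots of a central step to conformational substates.

    ``step_family`` is the purine/pyrimidine family of the central step after
    the reading-direction convention ("RR", "RY" or "YR").  RR steps require
    ``watson_bii`` (BII flag of the central junction's Watson backbone); YR
    steps require ``w3_bii`` and ``c3_bii`` (BII flags of the two 3'-flanking
    junctions).  Snapshots are first tagged by backbone state, substate
    centres in (shift, slide, twist) are estimated from each tagged
    population, and the final label is the nearest centre (coordinates scaled
    by their pooled SDs).
    """
    sh, sl, tw = (np.asarray(a, dtype=float).ravel() for a in (shift, slide, twist))
    n = sh.size
    fam = step_family.upper()
    if fam == "RR":
        if watson_bii is None:
            raise ValueError("RR steps require the Watson-strand BII series")
        b = np.asarray(watson_bii, dtype=bool)
        tags = np.where(b, "BII", "BI")
    elif fam == "YR":
        if w3_bii is None or c3_bii is None:
            raise ValueError("YR steps require both 3'-junction BII series")
        b = np.asarray(w3_bii, dtype=bool) | np.asarray(c3_bii, dtype=bool)
        tags = np.where(b, "BII3'", "BI3'")
    elif fam == "RY":
        tags = np.full(n, "canonical", dtype=object)
    else:
        raise ValueError(f"unknown step family {step_family!r}")
    tags = np.asarray(tags, dtype=object)

    coords = np.column_stack([sh, sl, tw])
    scale = coords.std(axis=0)
    scale[scale < 1e-12] = 1.0
    centers: dict[str, tuple[float, float, float]] = {}
    for tag in np.unique(tags):
        mask = tags == tag
        centers[_TAG_TO_CANDIDATE[str(tag)]] = tuple(coords[mask].mean(axis=0))
    cand_labels = list(centers)
    cand = np.array([centers[c] for c in cand_labels]) / scale
    d2 = ((coords / scale)[:, None, :] - cand[None, :, :]) ** 2
    nearest = np.argmin(d2.sum(axis=2), axis=1)
    labels = np.asarray([cand_labels[i] for i in nearest], dtype=object)
    return SubstateAssignment(labels, tags, centers)
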