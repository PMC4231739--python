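"""Single-pass circular statistics and Fisher T-linear association.

MD trajectories are long, so all descriptive statistics and correlations are
computed from sufficient statistics that can be accumulated in one pass over
the data and merged exactly across chunks.  Backbone dihedrals (and, for
safety, rotational helical parameters) are treated as circular variables;
linear variables x (Å) entering a circular correlation are first mapped to
angles θ_x = atan(x / 5 Å), with the 5 Å length scale configurable.

Fisher's T-linear association for paired angles (θ_i, φ_i),

    ρ̂_T = Σ_{i<j} sin(θ_i−θ_j) sin(φ_i−φ_j)
           / sqrt( Σ_{i<j} sin²(θ_i−θ_j) · Σ_{i<j} sin²(φ_i−φ_j) ),

is evaluated through its algebraic expansion into per-sample trigonometric
sums (Fisher–Lee identity),

    Σ_{i<j} sin(θ_i−θ_j) sin(φ_i−φ_j) = A·B − C·D,
    Σ_{i<j} sin²(θ_i−θ_j) = (n² − E² − F²) / 4,

with A = Σ cosθcosφ, B = Σ sinθsinφ, C = Σ cosθsinφ, D = Σ sinθcosφ,
E = Σ cos2θ, F = Σ sin2θ — so the data are touched exactly once.  The
equivalence with the O(n²) pairwise definition is verified in the test
suite before the single-pass form is trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "lin_to_angle",
    "CircAccumulator",
    "PairedCircAccumulator",
    "SummaryStats",
    "circ_moments",
    "linear_moments",
    "fisher_T",
    "pearson",
    "corr_matrix",
    "histogram",
]

DEFAULT_LINEAR_SCALE = 5.0  # Å per 45° when mapping linear values to angles


def lin_to_angle(x, scale: float = DEFAULT_LINEAR_SCALE):
    """Map a linear variable (Å) to an angle θ_x = atan(x/scale), degrees.

    Odd, bounded in (−90°, 90°); 5 Å maps to 45° at the default scale.
    """
    return np.degrees(np.arctan(np.asarray(x, dtype=float) / scale))


def _rad(deg):
    return np.radians(np.asarray(deg, dtype=float))


@dataclass
class CircAccumulator:
    """Mergeable single-pass sufficient statistics for one angular series.

    Accumulates n, Σsinθ, Σcosθ, Σsin2θ, Σcos2θ; merging two accumulators is
    exact addition, so chunked accumulation equals whole-series accumulation.
    """

    n: int = 0
    sum_sin: float = 0.0
    sum_cos: float = 0.0
    sum_sin2: float = 0.0
    sum_cos2: float = 0.0

    def add(self, theta_deg) -> "CircAccumulator":
        t = _rad(theta_deg).ravel()
        self.n += t.size
        self.sum_sin += float(np.sum(np.sin(t)))
        self.sum_cos += float(np.sum(np.cos(t)))
        self.sum_sin2 += float(np.sum(np.sin(2 * t)))
        self.sum_cos2 += float(np.sum(np.cos(2 * t)))
        return self

    def merge(self, other: "CircAccumulator") -> "CircAccumulator":
        out = CircAccumulator()
        for f in ("n", "sum_sin", "sum_cos", "sum_sin2", "sum_cos2"):
            setattr(out, f, getattr(self, f) + getattr(other, f))
        return out

    @property
    def resultant_length(self) -> float:
        if self.n == 0:
            raise ValueError("empty accumulator")
        return math.hypot(self.sum_sin, self.sum_cos) / self.n

    @property
    def mean(self) -> float | None:
        """Circular mean in degrees on (−180°, 180°]; None when undefined."""
        if self.n == 0:
            raise ValueError("empty accumulator")
        if self.resultant_length < 1e-12:
            return None
        return math.degrees(math.atan2(self.sum_sin, self.sum_cos))

    @property
    def sd(self) -> float:
        """Circular standard deviation sqrt(−2 ln R̄), degrees."""
        r = min(1.0, max(self.resultant_length, 1e-300))
        return math.degrees(math.sqrt(-2.0 * math.log(r)))


@dataclass
class PairedCircAccumulator:
    """Single-pass sufficient statistics for ρ̂_T of a paired angular series."""

    n: int = 0
    # cross products
    s_cc: float = 0.0  # Σ cosθ cosφ
    s_ss: float = 0.0  # Σ sinθ sinφ
    s_cs: float = 0.0  # Σ cosθ sinφ
    s_sc: float = 0.0  # Σ sinθ cosφ
    # double-angle sums per series
    s_c2t: float = 0.0
    s_s2t: float = 0.0
    s_c2p: float = 0.0
    s_s2p: float = 0.0

    _FIELDS = ("n", "s_cc", "s_ss", "s_cs", "s_sc", "s_c2t", "s_s2t", "s_c2p", "s_s2p")

    def add(self, theta_deg, phi_deg) -> "PairedCircAccumulator":
        t = _rad(theta_deg).ravel()
        p = _rad(phi_deg).ravel()
        if t.size != p.size:
            raise ValueError("paired series must have equal length")
        st, ct = np.sin(t), np.cos(t)
        sp, cp = np.sin(p), np.cos(p)
        self.n += t.size
        self.s_cc += float(np.sum(ct * cp))
        self.s_ss += float(np.sum(st * sp))
        self.s_cs += float(np.sum(ct * sp))
        self.s_sc += float(np.sum(st * cp))
        self.s_c2t += float(np.sum(np.cos(2 * t)))
        self.s_s2t += float(np.sum(np.sin(2 * t)))
        self.s_c2p += float(np.sum(np.cos(2 * p)))
        self.s_s2p += float(np.sum(np.sin(2 * p)))
        return self

    def merge(self, other: "PairedCircAccumulator") -> "PairedCircAccumulator":
        out = PairedCircAccumulator()
        for f in self._FIELDS:
            setattr(out, f, getattr(self, f) + getattr(other, f))
        return out

    @property
    def rho_t(self) -> float | None:
        """ρ̂_T in [−1, 1], or None when a denominator vanishes (a series
        concentrated on an antipodal-degenerate configuration)."""
        if self.n < 3:
            raise ValueError("need at least 3 paired samples")
        num = self.s_cc * self.s_ss - self.s_cs * self.s_sc
        d_t = self.n**2 - self.s_c2t**2 - self.s_s2t**2
        d_p = self.n**2 - self.s_c2p**2 - self.s_s2p**2
        den = math.sqrt(max(d_t, 0.0) * max(d_p, 0.0)) / 4.0
        if den < 1e-12 * self.n**2:
            return None
        return float(np.clip(num / den, -1.0, 1.0))


@dataclass(frozen=True)
class SummaryStats:
    """Mean / SD / min / max / range of a series.

    For angular series these are circular: the mean comes from the resultant
    vector, the SD from its length, and min/max/range describe the smallest
    arc containing all of the data, reported unwrapped around the mean so
    that min ≤ mean ≤ max and range = max − min ≤ 360°.
    """

    mean: float | None
    sd: float
    minimum: float
    maximum: float
    range: float
    n: int
    circular: bool = field(default=False, compare=False)


def circ_moments(series_deg) -> SummaryStats:
    """Circular summary statistics of an angular series (degrees)."""
    x = np.asarray(series_deg, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    acc = CircAccumulator().add(x)
    mean = acc.mean
    # smallest enclosing arc: sort on the wheel, find the largest gap
    w = np.sort(x % 360.0)
    gaps = np.diff(np.concatenate([w, [w[0] + 360.0]]))
    if w.size == 1:
        lo = hi = w[0]
    else:
        k = int(np.argmax(gaps))
        if k == w.size - 1:  # largest gap is the wraparound one
            lo, hi = w[0], w[-1]
        else:
            lo, hi = w[k + 1], w[k] + 360.0
    rng = min(hi - lo, 360.0)
    # unwrap the arc around the mean representative
    if mean is not None:
        center = mean
        while lo > center:
            lo -= 360.0
            hi -= 360.0
        while hi < center:
            lo += 360.0
            hi += 360.0
    return SummaryStats(mean, acc.sd if mean is not None else float("nan"), float(lo), float(hi), float(rng), x.size, True)


def linear_moments(series) -> SummaryStats:
    """Plain summary statistics of a linear series."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    return SummaryStats(
        float(np.mean(x)),
        float(np.std(x, ddof=0)),
        float(np.min(x)),
        float(np.max(x)),
        float(np.max(x) - np.min(x)),
        x.size,
        False,
    )


def fisher_T(theta, phi, theta_circular: bool = True, phi_circular: bool = True,
             scale: float = DEFAULT_LINEAR_SCALE) -> float | None:
    """Fisher's T-linear association ρ̂_T between two series.

    Series flagged non-circular are linear (Å) and are mapped through
    :func:`lin_to_angle` first (circular–linear and linear–linear T cases).
    """
    t = np.asarray(theta, dtype=float)
    p = np.asarray(phi, dtype=float)
    if not theta_circular:
        t = lin_to_angle(t, scale)
    if not phi_circular:
        p = lin_to_angle(p, scale)
    return PairedCircAccumulator().add(t, p).rho_t


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = np.std(x), np.std(y)
    if sx < 1e-300 or sy < 1e-300:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def corr_matrix(
    series_map: dict[str, np.ndarray],
    circular_flags: dict[str, bool],
    threshold: float = 0.4,
    scale: float = DEFAULT_LINEAR_SCALE,
):
    """Pairwise correlation matrix with a significance mask.

    Pearson for linear–linear pairs; ρ̂_T when at least one variable is
    circular (the linear member mapped through θ_x = atan(x/scale)).  Returns
    ``(names, matrix, mask)`` where mask is +1 / −1 where |r| > threshold and
    0 elsewhere (undefined correlations propagate as NaN, mask 0).
    """
    names = list(series_map)
    k = len(names)
    mat = np.full((k, k), np.nan)
    mask = np.zeros((k, k), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            ca, cb = circular_flags.get(a, False), circular_flags.get(b, False)
            if i == j:
                r = 1.0
            elif not ca and not cb:
                r = pearson(series_map[a], series_map[b])
            else:
                r = fisher_T(series_map[a], series_map[b], ca, cb, scale)
            r = np.nan if r is None else r
            mat[i, j] = mat[j, i] = r
            if i != j and np.isfinite(r) and abs(r) > threshold:
                mask[i, j] = mask[j, i] = int(np.sign(r))
    return names, mat, mask


def histogram(series, bin_width: float, circular: bool = False,
              origin: float = 0.0):
    """Fixed-origin histogram with normalized density.

    Circular variables are binned on the [0°, 360°) wheel (origin 0); the
    returned density integrates to 1 over the binned support.
    Returns ``(edges, counts, density)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(series, dtype=float).ravel()
    if circular:
        x = x % 360.0
        nbins = max(1, int(round(360.0 / bin_width)))
        edges = np.linspace(0.0, 360.0, nbins + 1)
    else:
        lo = origin + math.floor((np.min(x) - origin) / bin_width) * bin_width
        hi = origin + math.ceil((np.max(x) - origin) / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        nbins = int(round((hi - lo) / bin_width))
        edges = lo + np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    total = counts.sum()
    density = counts / (total * np.diff(edges)) if total else counts.astype(float)
    return edges, counts, density
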