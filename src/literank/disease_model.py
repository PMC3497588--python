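"""Tri-modal Gaussian disease model, thresholds and association bands.

The cosine scores of all factors against one disease query are assumed to
form three modes: factors known to be unassociated (negative scores),
factors of uncertain status (low positive scores), and established
associations (high scores). The score histogram is fitted with a sum of
three unnormalized Gaussian-shaped curves

    f(x) = sum_i alpha_i * exp(-((x - mu_i) / sigma_i)^2)

(amplitudes alpha_i, peak centers mu_i, width parameters sigma_i; note the
exponent carries no 1/2, so each component has variance sigma_i^2 / 2 —
this is a curve-fit model, not a probability density). Cutoffs between
adjacent components are placed where the weighted curves intersect, giving
data-driven thresholds; manual thresholds reproduce published band
configurations. Scores are then partitioned into unknown / (low /)
potential / established bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError, ThresholdError, UndefinedScoreError

__all__ = [
    "TriModalParams",
    "TriModalFit",
    "Thresholds",
    "AssociationCategories",
    "trimodal_density",
    "score_histogram",
    "fit_trimodal",
    "r_square",
    "derive_thresholds",
    "categorize",
]

DEFAULT_BINS = 20
_SIGMA_MIN = 1e-3


@dataclass(frozen=True)
class TriModalParams:
    """Nine parameters of the tri-modal curve, components sorted by center."""

    alpha: tuple[float, float, float]
    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]

    def __post_init__(self):
        if len(self.alpha) != 3 or len(self.mu) != 3 or len(self.sigma) != 3:
            raise InputError("tri-modal parameters need exactly 3 components")
        if any(a < 0 for a in self.alpha):
            raise InputError("amplitudes must be non-negative")
        if any(s <= 0 for s in self.sigma):
            raise InputError("width parameters must be positive")
        if not (self.mu[0] <= self.mu[1] <= self.mu[2]):
            raise InputError("peak centers must be sorted ascending")

    @classmethod
    def from_flat(cls, theta: Sequence[float]) -> "TriModalParams":
        """From (a1,a2,a3, m1,m2,m3, s1,s2,s3), relabeling so mu ascends."""
        a, m, s = np.asarray(theta[0:3]), np.asarray(theta[3:6]), np.asarray(theta[6:9])
        order = np.argsort(m, kind="stable")
        return cls(
            alpha=tuple(float(x) for x in a[order]),
            mu=tuple(float(x) for x in m[order]),
            sigma=tuple(float(x) for x in s[order]),
        )

    def as_flat(self) -> np.ndarray:
        return np.array(list(self.alpha) + list(self.mu) + list(self.sigma))


def trimodal_density(x, params: TriModalParams):
    """Evaluate f(x); vectorized, non-negative everywhere."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for a, m, s in zip(params.alpha, params.mu, params.sigma):
        out += a * np.exp(-(((x - m) / s) ** 2))
    return out if out.ndim else float(out)


def score_histogram(
    scores: Sequence[float], n_bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width count histogram spanning [-1, 1]."""
    scores = np.asarray(scores, dtype=float)
    if n_bins < 3:
        raise InputError(f"n_bins must be >= 3, got {n_bins}")
    if scores.size and (scores.min() < -1 or scores.max() > 1):
        raise InputError("cosine scores must lie within [-1, 1]")
    heights, edges = np.histogram(scores, bins=n_bins, range=(-1.0, 1.0))
    return edges, heights.astype(float)


def r_square(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InputError("observed/predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedScoreError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class TriModalFit:
    """Fitted parameters with goodness of fit and the histogram they explain."""

    params: TriModalParams
    r_square: float
    bins: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        if len(self.heights) != len(self.bins) - 1:
            raise InputError("need len(heights) == len(bins) - 1")
        if np.any(np.asarray(self.heights) < 0):
            raise InputError("histogram heights must be non-negative")


def _weighted_quantile(centers, heights, q):
    cum = np.cumsum(heights)
    total = cum[-1]
    return float(centers[np.searchsorted(cum, q * total, side="left")])


def _auto_inits(centers, heights, rng, n_restarts):
    """Deterministic percentile-based init plus seeded random restarts."""
    mus = [_weighted_quantile(centers, heights, q) for q in (0.10, 0.50, 0.90)]
    gaps = [max(mus[1] - mus[0], 0.05), max(mus[2] - mus[1], 0.05)]
    sigmas = [gaps[0] / 2, (gaps[0] + gaps[1]) / 4, gaps[1] / 2]
    sigmas = [max(s, 0.02) for s in sigmas]
    alphas = [
        max(float(heights[np.argmin(np.abs(centers - m))]), 1e-3) for m in mus
    ]
    inits = [np.array(alphas + mus + sigmas)]
    hmax = max(float(heights.max()), 1e-3)
    for _ in range(n_restarts):
        m = np.sort(rng.uniform(-1, 1, size=3))
        a = rng.uniform(0.1, 1.5, size=3) * hmax
        s = rng.uniform(0.03, 0.5, size=3)
        inits.append(np.concatenate([a, m, s]))
    return inits


def fit_trimodal(
    histogram: tuple[np.ndarray, np.ndarray],
    init: TriModalParams | str = "auto",
    n_restarts: int = 20,
    seed: int = 0,
) -> TriModalFit:
    """Nonlinear least squares of the tri-modal curve against bin heights.

    Fits (bin center, height) pairs under alpha >= 0, sigma > 0,
    mu in [-1, 1]; components are relabeled so mu ascends. ``init="auto"``
    starts from histogram percentiles and adds ``n_restarts`` seeded random
    restarts, keeping the best R². Non-convergence raises :class:`FitError`
    carrying the best parameters and residual seen.
    """
    edges, heights = np.asarray(histogram[0]), np.asarray(histogram[1], dtype=float)
    if len(heights) != len(edges) - 1:
        raise InputError("histogram must be (edges, heights) with len match")
    if len(heights) < 9:
        raise InputError(
            f"need >= 9 bins (9 free parameters), got {len(heights)}"
        )
    if not heights.any():
        raise FitError("degenerate histogram: all heights are zero")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def residuals(theta):
        p = np.asarray(theta)
        model = np.zeros_like(centers)
        for i in range(3):
            model += p[i] * np.exp(-(((centers - p[3 + i]) / p[6 + i]) ** 2))
        return model - heights

    lower = [0, 0, 0, -1, -1, -1, _SIGMA_MIN, _SIGMA_MIN, _SIGMA_MIN]
    upper = [np.inf] * 3 + [1, 1, 1] + [4.0] * 3

    rng = np.random.default_rng(seed)
    if isinstance(init, TriModalParams):
        inits = [init.as_flat()]
    else:
        inits = _auto_inits(centers, heights, rng, n_restarts)

    best_theta, best_cost = None, np.inf
    for theta0 in inits:
        theta0 = np.clip(theta0, lower, upper)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf"
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_theta = sol.cost, sol.x
    if best_theta is None:
        raise FitError("tri-modal fit failed from every initialization")
    params = TriModalParams.from_flat(best_theta)
    r2 = r_square(heights, trimodal_density(centers, params))
    return TriModalFit(params=params, r_square=r2, bins=edges, heights=heights)


@dataclass(frozen=True)
class Thresholds:
    """Ascending score cutoffs: 2 for three bands, 3 for the four-band variant."""

    cutoffs: tuple[float, ...]
    source: str = "manual"  # "fitted" | "manual"

    def __post_init__(self):
        if len(self.cutoffs) not in (2, 3):
            raise InputError("need 2 cutoffs (three bands) or 3 (four bands)")
        if any(not (-1 < c < 1) for c in self.cutoffs):
            raise InputError("cutoffs must lie strictly inside (-1, 1)")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise InputError("cutoffs must be strictly ascending")
        if self.source not in ("fitted", "manual"):
            raise InputError(f"unknown threshold source {self.source!r}")


def _component_intersection(a1, m1, s1, a2, m2, s2) -> float:
    """x in (m1, m2) where a1·exp(-((x-m1)/s1)²) = a2·exp(-((x-m2)/s2)²).

    Taking logs gives a quadratic A·x² + B·x + C = 0; the root inside the
    open interval where dominance passes from the left to the right
    component is selected.
    """
    if a1 <= 0 or a2 <= 0:
        raise ThresholdError(
            "component with zero amplitude has no intersection; "
            "use manual thresholds"
        )
    A = 1.0 / s1**2 - 1.0 / s2**2
    B = -2.0 * (m1 / s1**2 - m2 / s2**2)
    C = m1**2 / s1**2 - m2**2 / s2**2 - np.log(a1 / a2)
    if abs(A) < 1e-14:
        if abs(B) < 1e-14:
            raise ThresholdError("curves are parallel; no unique intersection")
        roots = [-C / B]
    else:
        disc = B**2 - 4 * A * C
        if disc < 0:
            raise ThresholdError(
                "weighted components never intersect; use manual thresholds"
            )
        sq = np.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]

    def g_deriv(x):  # d/dx [log f1 - log f2]
        return -2 * (x - m1) / s1**2 + 2 * (x - m2) / s2**2

    inside = sorted(r for r in roots if m1 < r < m2)
    crossing = [r for r in inside if g_deriv(r) < 0]
    if crossing:
        return float(crossing[0])
    if inside:
        return float(inside[0])
    raise ThresholdError(
        "no intersection between adjacent peaks (heavy overlap); "
        "use manual thresholds"
    )


def derive_thresholds(fit: TriModalFit | TriModalParams) -> Thresholds:
    """Data-driven cutoffs at the intersections of adjacent weighted curves."""
    params = fit.params if isinstance(fit, TriModalFit) else fit
    a, m, s = params.alpha, params.mu, params.sigma
    if not (m[0] < m[1] < m[2]):
        raise ThresholdError("peak centers must be strictly ordered to derive cutoffs")
    c1 = _component_intersection(a[0], m[0], s[0], a[1], m[1], s[1])
    c2 = _component_intersection(a[1], m[1], s[1], a[2], m[2], s[2])
    return Thresholds(cutoffs=(c1, c2), source="fitted")


@dataclass
class AssociationCategories:
    """Partition of ranked factors into association bands."""

    established: set[str]
    potential: set[str]
    unknown: set[str]
    thresholds: Thresholds
    low: set[str] | None = None  # four-band variant only

    def __post_init__(self):
        bands = [self.established, self.potential, self.unknown]
        if self.low is not None:
            bands.append(self.low)
        total = sum(len(b) for b in bands)
        union = set().union(*bands)
        if len(union) != total:
            raise InputError("association bands overlap")

    def band_of(self, factor: str) -> str:
        for name in ("established", "potential", "low", "unknown"):
            band = getattr(self, name)
            if band is not None and factor in band:
                return name
        raise KeyError(factor)

    def all_factors(self) -> set[str]:
        extra = self.low or set()
        return self.established | self.potential | self.unknown | extra


def categorize(result, thresholds: Thresholds) -> AssociationCategories:
    """Partition factors into bands by their cosine scores.

    Bands are left-open / right-closed, matching the published reading
    ("highly associated if greater than" the top cutoff): with cutoffs
    (c1, c2), established = score > c2, potential = c1 < score <= c2,
    unknown = score <= c1. A third cutoff (c1, c2, c3) inserts a "low"
    band (c1 < score <= c2) below potential.

    ``result`` may be a :class:`~literank.engine.QueryResult` or any
    iterable of (factor, score) pairs.
    """
    pairs = list(result.scores) if hasattr(result, "scores") else list(result)
    cuts = thresholds.cutoffs
    established, potential, unknown = set(), set(), set()
    low: set[str] | None = set() if len(cuts) == 3 else None
    for name, score in pairs:
        if score > cuts[-1]:
            established.add(name)
        elif score <= cuts[0]:
            unknown.add(name)
        elif len(cuts) == 3 and score <= cuts[1]:
            low.add(name)
        else:
            potential.add(name)
    return AssociationCategories(
        established=established,
        potential=potential,
        unknown=unknown,
        low=low,
        thresholds=thresholds,
    )
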