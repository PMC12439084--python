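"""Allele turnover between consecutive dated layers and its smooth trend.

Turnover for one interval is the number of loci whose pooled allele frequency
changed by strictly more than a threshold (default 1%), divided by the elapsed
generations — and by the number of comparable loci when per-locus
normalization is on (the default, so intervals with different missingness are
comparable; the raw ratio is available by flag).  Layers from both sites are
merged into a single series sorted oldest to youngest, treating the two sites
as one population (justified when between-site FST is low).

The temporal trend is a penalized cubic regression spline (P-spline): a
B-spline basis on equally spaced knots with a second-order difference penalty
on the coefficients, smoothing parameter chosen by generalized
cross-validation.  The penalty null space is the straight line in age, so
lambda -> infinity recovers ordinary least squares on age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import AnalysisError, ValidationError
from .io_core import AlleleFrequencyMatrix, SedimentSample


@dataclass
class TurnoverConfig:
    """Threshold and time-scaling for the turnover statistic.

    ``gens_per_year`` converts elapsed calendar years to generations; the
    organism's generation time is not established, so the default 1.0 makes
    turnover "per year" unless the caller configures otherwise.
    """

    change_threshold: float = 0.01
    gens_per_year: float = 1.0
    per_locus_normalized: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.change_threshold < 1.0):
            raise ValidationError("change_threshold must be in (0,1)")
        if self.gens_per_year <= 0:
            raise ValidationError("gens_per_year must be positive")


@dataclass
class TurnoverInterval:
    """Turnover between one consecutive pair of dated layers."""

    age_older: float
    age_younger: float
    mid_age: float
    n_changes: int
    n_loci_compared: int
    generations: float
    turnover: float


@dataclass
class GamFit:
    """Penalized-spline fit of turnover against age."""

    ages_grid: np.ndarray
    fitted: np.ndarray
    lam: float
    edf: float
    basis_dim: int
    gcv: float
    knots: np.ndarray
    coefficients: np.ndarray

    def predict(self, ages) -> np.ndarray:
        b = _design(np.asarray(ages, dtype=float), self.knots)
        return b @ self.coefficients


def turnover_series(
    matrix: AlleleFrequencyMatrix,
    samples: list[SedimentSample],
    config: TurnoverConfig | None = None,
) -> list[TurnoverInterval]:
    """Per-interval turnover over all layers merged and sorted by age.

    Layers with identical ages are averaged into one pseudo-layer first.  For
    each consecutive (older, younger) pair, a locus counts as changed when
    both frequencies are observed and |delta p| strictly exceeds the
    threshold.
    """
    config = config or TurnoverConfig()
    cols: dict[float, list[int]] = {}
    for s in samples:
        if s.sample_id in matrix.samples:
            cols.setdefault(s.age_calBP, []).append(
                matrix.samples.index(s.sample_id)
            )
    if sum(len(v) for v in cols.values()) < 2:
        raise AnalysisError("turnover needs at least 2 dated samples")
    ages = sorted(cols, reverse=True)  # oldest first
    merged = np.empty((matrix.n_loci, len(ages)))
    for j, age in enumerate(ages):
        block = matrix.freq[:, cols[age]]
        if block.shape[1] > 1:
            warnings.warn(
                f"{block.shape[1]} samples share age {age}; averaged into one "
                "pseudo-sample",
                stacklevel=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                merged[:, j] = np.nanmean(block, axis=1)
        else:
            merged[:, j] = block[:, 0]

    intervals: list[TurnoverInterval] = []
    for j in range(len(ages) - 1):
        older, younger = ages[j], ages[j + 1]
        dt = older - younger
        if dt <= 0:
            warnings.warn(
                f"zero elapsed time between ages {older} and {younger}; "
                "interval skipped",
                stacklevel=2,
            )
            continue
        a, b = merged[:, j], merged[:, j + 1]
        both = ~(np.isnan(a) | np.isnan(b))
        n_compared = int(both.sum())
        # strict inequality with a guard against float noise, so a change of
        # exactly the threshold (e.g. 0.51 - 0.50 vs 0.01) is never counted
        n_changes = int(
            np.sum(np.abs(a[both] - b[both]) > config.change_threshold + 1e-12)
        )
        generations = dt * config.gens_per_year
        rate = n_changes / n_compared if config.per_locus_normalized else n_changes
        intervals.append(
            TurnoverInterval(
                age_older=older,
                age_younger=younger,
                mid_age=(older + younger) / 2.0,
                n_changes=n_changes,
                n_loci_compared=n_compared,
                generations=generations,
                turnover=rate / generations,
            )
        )
    return intervals


def _pspline_knots(lo: float, hi: float, basis_dim: int) -> np.ndarray:
    """Equally spaced cubic B-spline knots with ``basis_dim`` basis functions."""
    n_int = basis_dim - 3
    h = (hi - lo) / n_int if n_int > 0 else (hi - lo) or 1.0
    return lo + h * np.arange(-3, n_int + 4, dtype=float)


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # nudge points on the right boundary inward so the end basis evaluates
    lo, hi = knots[3], knots[-4]
    x = np.clip(x, lo, hi - 1e-12 * max(abs(hi), 1.0))
    return BSpline.design_matrix(x, knots, k=3).toarray()


def _second_difference(k: int) -> np.ndarray:
    d = np.zeros((k - 2, k))
    for i in range(k - 2):
        d[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d


def fit_gam(
    intervals: list[TurnoverInterval],
    basis_dim: int = 10,
    lam: float | str = "auto",
    grid_size: int = 200,
) -> GamFit:
    """Fit turnover ~ s(age) by penalized least squares.

    ``lam="auto"`` picks the smoothing parameter from a deterministic
    logarithmic grid (including the infinite-smoothness straight line) by
    generalized cross-validation, GCV = n*RSS/(n-edf)^2.
    """
    if len(intervals) < 4:
        raise AnalysisError("GAM needs at least 4 intervals")
    x = np.array([iv.mid_age for iv in intervals], dtype=float)
    y = np.array([iv.turnover for iv in intervals], dtype=float)
    if basis_dim > len(intervals):
        raise AnalysisError(
            f"basis_dim {basis_dim} exceeds the {len(intervals)} data points; "
            "use a smaller basis"
        )
    if basis_dim < 4:
        raise ValidationError("basis_dim must be >= 4 for cubic splines")
    span = x.max() - x.min()
    pad = 1e-6 * (span or 1.0)
    knots = _pspline_knots(x.min() - pad, x.max() + pad, basis_dim)
    b = _design(x, knots)
    d = _second_difference(basis_dim)
    btb = b.T @ b
    dtd = d.T @ d
    bty = b.T @ y
    n = len(y)

    def _solve(lmb: float) -> tuple[np.ndarray, float, float]:
        if np.isinf(lmb):
            # penalty null space: coefficients linear in knot index, i.e. the
            # ordinary least-squares straight line in age
            z = np.column_stack([np.ones(basis_dim), np.arange(basis_dim)])
            bz = b @ z
            alpha, *_ = np.linalg.lstsq(bz, y, rcond=None)
            beta = z @ alpha
            edf = 2.0
        else:
            a_mat = btb + lmb * dtd
            beta = np.linalg.solve(a_mat, bty)
            edf = float(np.trace(np.linalg.solve(a_mat, btb)))
        rss = float(np.sum((y - b @ beta) ** 2))
        return beta, edf, rss

    # RSS below numerical zero (relative to the response scale) is clamped so
    # exact fits rank by edf and GCV prefers the smoothest exact fit
    rss_floor = float(np.sum(y**2)) * 1e-24

    def _gcv(edf: float, rss: float) -> float:
        denom = max(n - edf, 1e-8)
        return n * max(rss, rss_floor) / denom**2

    if lam == "auto":
        scale = (np.trace(btb) / max(np.trace(dtd), 1e-300)) or 1.0
        # smoothest first: on (numerical) GCV ties keep the smoother fit
        candidates = [np.inf] + list(scale * np.logspace(8, -6, 29))
        best = None
        for lmb in candidates:
            beta, edf, rss = _solve(lmb)
            score = _gcv(edf, rss)
            if best is None or score < best[0] * (1.0 - 1e-10):
                best = (score, lmb, beta, edf, rss)
        gcv_score, lam_used, beta, edf, rss = best
    else:
        lam_used = float(lam)
        if lam_used < 0:
            raise ValidationError("lambda must be >= 0")
        beta, edf, rss = _solve(lam_used)
        gcv_score = _gcv(edf, rss)

    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = _design(grid, knots) @ beta
    return GamFit(
        ages_grid=grid,
        fitted=fitted,
        lam=float(lam_used),
        edf=float(edf),
        basis_dim=basis_dim,
        gcv=float(gcv_score),
        knots=knots,
        coefficients=beta,
    )


def era_contrast(fit: GamFit, boundary_age: float) -> tuple[float, float, float]:
    """(mean fitted turnover younger than boundary, mean older, their ratio).

    Ages are cal BP, so "recent" means age < boundary.  The ratio is
    recent/ancient; > 1 indicates accelerated turnover toward the present.
    """
    recent = fit.fitted[fit.ages_grid < boundary_age]
    ancient = fit.fitted[fit.ages_grid >= boundary_age]
    if recent.size == 0 or ancient.size == 0:
        raise AnalysisError(
            f"fitted grid does not span both sides of age {boundary_age}"
        )
    mean_recent = float(recent.mean())
    mean_ancient = float(ancient.mean())
    if mean_ancient == 0:
        ratio = float("inf") if mean_recent > 0 else 1.0
    else:
        ratio = mean_recent / mean_ancient
    return mean_recent, mean_ancient, ratio
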