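"""Spatial and temporal population structure from pooled allele frequencies.

FST here is Wright's variance form on pooled per-site frequencies: for one
locus with site frequencies p1, p2 and mean pbar, the between-site variance of
frequencies is (p1-p2)^2/4 and the total is pbar(1-pbar); multi-locus FST is
the ratio of sums of these components over usable loci.  No sample-size
correction is applied — the number of organisms pooled into a sediment layer
is unknowable, so the uncorrected pooled-frequency form is the honest choice.

The sliding-window variant sorts layers by age and recomputes FST from the
per-site mean frequencies within each window, tracing differentiation through
time.  PCA of the loci x samples frequency matrix summarizes allelic
composition, and a single-covariate PERMANOVA (McArdle-Anderson trace form,
raw-data permutation) asks how much PC-space variation a covariate such as
damage rate or TOC explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ValidationError
from .io_core import AlleleFrequencyMatrix, SedimentSample


@dataclass
class FstWindow:
    """Multi-locus FST between two sites within one age window."""

    window_start_age: float
    window_end_age: float
    mid_age: float
    fst: float | None
    n_loci_used: int
    n_samples_per_site: tuple[int, int]


@dataclass
class PcaResult:
    """Sample scores and explained-variance ratios of the allelic PCA."""

    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # loci x components
    sample_ids: list[str]
    imputed_loci: list[int]  # matrix row indices that had missing cells


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def per_locus_fst(p1: float, p2: float) -> tuple[float, float] | None:
    """(numerator, denominator) of Wright's variance FST for one locus.

    numerator = (p1-p2)^2/4, the between-population variance of the two
    frequencies; denominator = pbar(1-pbar).  Returns None (locus skipped)
    when the locus is monomorphic across both populations.
    """
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"allele frequency outside [0,1]: {p}")
    pbar = (p1 + p2) / 2.0
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return None
    return ((p1 - p2) ** 2 / 4.0, denom)


def multilocus_fst(freqs_site1, freqs_site2) -> float | None:
    """Ratio-of-sums multi-locus FST; None when every locus is unusable.

    Loci where either frequency is missing (NaN) are skipped, as are loci
    monomorphic across both sites.
    """
    p1 = np.asarray(freqs_site1, dtype=float)
    p2 = np.asarray(freqs_site2, dtype=float)
    if p1.shape != p2.shape:
        raise ValidationError("frequency vectors must have equal length")
    keep = ~(np.isnan(p1) | np.isnan(p2))
    p1, p2 = p1[keep], p2[keep]
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValidationError("allele frequency outside [0,1]")
    pbar = (p1 + p2) / 2.0
    denom = pbar * (1.0 - pbar)
    poly = denom > 0
    if not np.any(poly):
        return None
    num = (p1[poly] - p2[poly]) ** 2 / 4.0
    return float(num.sum() / denom[poly].sum())


def windowed_fst(
    matrix: AlleleFrequencyMatrix,
    samples: list[SedimentSample],
    window_years: float = 1000.0,
    step_years: float = 250.0,
) -> list[FstWindow]:
    """Two-site FST in sliding age windows, oldest to youngest.

    Windows are half-open [a, a+window) in cal BP age.  Start ages ``a``
    descend by ``step_years`` from the oldest sample age (whose window is
    [age_max, age_max+window)) until the youngest sample has been covered, so
    the emitted list runs oldest to youngest.  Within a window each site's
    frequency vector is the per-locus mean over that site's samples (missing
    cells ignored); a window missing either site is emitted with fst=None.
    """
    if window_years <= 0 or step_years <= 0:
        raise ValidationError("window_years and step_years must be positive")
    sites = sorted({s.site for s in samples})
    if len(sites) != 2:
        raise AnalysisError(f"windowed FST needs exactly 2 sites, got {len(sites)}")
    site_a, site_b = sites
    ages = {s.sample_id: s.age_calBP for s in samples if s.sample_id in matrix.samples}
    site_of = {s.sample_id: s.site for s in samples}
    if not ages:
        raise AnalysisError("no metadata samples present in the frequency matrix")
    age_max = max(ages.values())
    age_min = min(ages.values())

    windows: list[FstWindow] = []
    a = age_max
    while a + window_years > age_min:
        members = [
            sid for sid, age in ages.items() if a <= age < a + window_years
        ]
        ids_a = [sid for sid in members if site_of[sid] == site_a]
        ids_b = [sid for sid in members if site_of[sid] == site_b]
        n_a, n_b = len(ids_a), len(ids_b)
        fst = None
        n_loci = 0
        if n_a and n_b:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f_a = np.nanmean(
                    matrix.freq[:, [matrix.samples.index(s) for s in ids_a]], axis=1
                )
                f_b = np.nanmean(
                    matrix.freq[:, [matrix.samples.index(s) for s in ids_b]], axis=1
                )
            usable = ~(np.isnan(f_a) | np.isnan(f_b))
            pbar = (f_a + f_b) / 2.0
            n_loci = int(np.sum(usable & (pbar * (1 - pbar) > 0)))
            fst = multilocus_fst(f_a, f_b)
        windows.append(
            FstWindow(
                window_start_age=a,
                window_end_age=a + window_years,
                mid_age=a + window_years / 2.0,
                fst=fst,
                n_loci_used=n_loci,
                n_samples_per_site=(n_a, n_b),
            )
        )
        a -= step_years
    return windows


def global_fst(
    matrix: AlleleFrequencyMatrix, samples: list[SedimentSample]
) -> float | None:
    """Single multi-locus FST between the two sites over all layers pooled."""
    sites = sorted({s.site for s in samples})
    if len(sites) != 2:
        raise AnalysisError(f"global FST needs exactly 2 sites, got {len(sites)}")
    cols = {site: [] for site in sites}
    for s in samples:
        if s.sample_id in matrix.samples:
            cols[s.site].append(matrix.samples.index(s.sample_id))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_a = np.nanmean(matrix.freq[:, cols[sites[0]]], axis=1)
        f_b = np.nanmean(matrix.freq[:, cols[sites[1]]], axis=1)
    return multilocus_fst(f_a, f_b)


def pca_allelic(matrix: AlleleFrequencyMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples in allele-frequency space.

    Loci (columns after transposition) are mean-centered but not scaled;
    missing cells are imputed with the locus mean and the affected loci
    recorded.  Component signs are fixed so each component's largest-magnitude
    loading is positive, making score orientation deterministic.
    """
    if matrix.n_samples < 2 or matrix.n_loci < 2:
        raise AnalysisError("PCA needs at least 2 samples and 2 loci")
    X = matrix.freq.T.copy()  # samples x loci
    keep_cols: list[int] = []
    imputed: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        nan = np.isnan(col)
        if nan.all():
            warnings.warn(
                f"locus {matrix.loci[j]} has no observations; dropped from PCA",
                stacklevel=2,
            )
            continue
        if nan.any():
            col[nan] = col[~nan].mean()
            imputed.append(j)
        keep_cols.append(j)
    X = X[:, keep_cols]
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise AnalysisError("PCA undefined: matrix has zero variance")
    k = min(len(s), n_components) if n_components else len(s)
    # sign convention: largest-|loading| entry of each component is positive
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=scores,
        explained_variance_ratio=(s**2 / total)[:k],
        loadings=vt[:k].T,
        sample_ids=list(matrix.samples),
        imputed_loci=imputed,
    )


def permanova(
    coords: np.ndarray,
    covariate,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Single-covariate PERMANOVA on Euclidean distances in ``coords``.

    Gower-centered squared-distance matrix G = -1/2 J D^2 J; model matrix
    X = [1, covariate]; SS_model = tr(HGH) with hat matrix H; pseudo-F =
    (SS_model/1) / ((SS_total-SS_model)/(n-2)); the p-value permutes the
    covariate rows, p = (1 + #{F_perm >= F_obs}) / (B + 1).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1 and coords.shape[1] > 1:
        coords = coords.T
    x = np.asarray(covariate, dtype=float)
    n = coords.shape[0]
    if x.shape != (n,):
        raise ValidationError("covariate length must match number of samples")
    if np.isnan(coords).any() or np.isnan(x).any():
        raise ValidationError("PERMANOVA inputs must not contain missing values")
    if np.ptp(x) == 0:
        raise AnalysisError("constant covariate: PERMANOVA undefined")
    if n_permutations < 99:
        raise ValidationError("n_permutations must be >= 99")

    sq = np.sum(coords**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T
    np.fill_diagonal(d2, 0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise AnalysisError("zero total sum of squares in coordinate space")

    def _ss_model(xv: np.ndarray) -> float:
        X = np.column_stack([np.ones(n), xv])
        xtx = X.T @ X
        if abs(np.linalg.det(xtx)) < 1e-12:
            raise AnalysisError("singular design matrix (constant covariate?)")
        h = X @ np.linalg.solve(xtx, X.T)
        return float(np.trace(h @ g @ h))

    ss_model = _ss_model(x)
    f_obs = (ss_model / 1.0) / ((ss_total - ss_model) / (n - 2))

    # H is idempotent and G doubly centered, so tr(HGH) = tr(HG) =
    # xc' G xc / xc'xc with xc the centered covariate — one quadratic form
    # per permutation instead of an n x n hat matrix.
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    perms = np.empty((n_permutations, n), dtype=float)
    for b in range(n_permutations):
        perms[b] = rng.permutation(xc)
    qf = np.einsum("bi,ij,bj->b", perms, g, perms) / np.sum(xc**2)
    f_perm = qf / ((ss_total - qf) / (n - 2))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (n_permutations + 1.0)
    return PermanovaResult(
        r_squared=ss_model / ss_total,
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
    )
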