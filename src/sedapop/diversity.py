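"""Coverage-normalized diversity measures and between-site comparisons.

Nucleotide diversity for pooled sedaDNA is per-site expected heterozygosity,
pi = (1/L) * sum over loci of 2 p (1-p), computed from the pooled alternate
allele frequency of each layer; it and the distinct-variant (haplotype) count
are divided by mean mapping coverage so layers sequenced to different depths
are comparable.  Haplotype evenness is summarized by Shannon entropy (natural
log) and the Gini-Simpson index 1 - sum(p_i^2).

Site comparisons first restrict both cores to their overlapping time window,
then apply Welch t-tests (no equal-variance assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .damage import CorrelationResult, correlate
from .errors import AnalysisError, ValidationError
from .io_core import AlleleFrequencyMatrix, HaplotypeTable, SedimentSample


@dataclass
class DiversityRecord:
    """Per-sample diversity summary for one organelle or the combined genome."""

    sample_id: str
    organelle: str
    pi_raw: float | None = None
    pi_norm: float | None = None
    n_distinct_variants_norm: float | None = None
    shannon: float | None = None
    simpson: float | None = None


@dataclass
class TTestResult:
    """Welch two-sample t-test (Satterthwaite degrees of freedom)."""

    statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    degenerate_variance: bool = False


def nucleotide_diversity(
    matrix: AlleleFrequencyMatrix, sample_id: str, target_length: int
) -> float | None:
    """pi = (1/target_length) * sum over non-missing loci of 2 p (1-p)."""
    if target_length <= 0:
        raise ValidationError("target_length must be positive")
    if matrix.n_loci > target_length:
        raise ValidationError(
            f"target_length {target_length} smaller than locus count {matrix.n_loci}"
        )
    p = matrix.column(sample_id)
    p = p[~np.isnan(p)]
    if p.size == 0:
        warnings.warn(
            f"sample {sample_id!r}: no covered loci, pi undefined", stacklevel=2
        )
        return None
    return float(np.sum(2.0 * p * (1.0 - p)) / target_length)


def normalize_by_coverage(value: float, coverage: float) -> float:
    """Divide a diversity measure by mean mapping coverage."""
    if coverage <= 0:
        raise ValidationError(f"coverage must be > 0, got {coverage}")
    return value / coverage


def diversity_indices(
    haps: HaplotypeTable, sample_id: str
) -> tuple[float | None, float | None]:
    """(Shannon entropy in nats, Gini-Simpson 1 - sum p^2) of haplotype counts."""
    counts = haps.counts_for(sample_id)
    if counts.size == 0:
        warnings.warn(f"sample {sample_id!r} has no haplotypes", stacklevel=2)
        return None, None
    p = counts / counts.sum()
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(1.0 - np.sum(p**2))
    return shannon, simpson


def welch_t_test(group_a, group_b) -> TTestResult:
    """Welch t-test; degenerate zero-variance groups are flagged, not crashed."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs n >= 2 non-missing values")
    means = (float(a.mean()), float(b.mean()))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if means[0] == means[1]:
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0, means, True)
        return TTestResult(
            float(np.sign(means[0] - means[1]) * np.inf),
            float(a.size + b.size - 2), 0.0, means, True,
        )
    se2 = va / a.size + vb / b.size
    t = (means[0] - means[1]) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), means)


def diversity_table(
    matrix: AlleleFrequencyMatrix,
    haps: HaplotypeTable,
    samples: list[SedimentSample],
    target_lengths: dict[str, int],
) -> list[DiversityRecord]:
    """Per-sample records: pi per organelle plus combined haplotype indices.

    ``target_lengths`` maps each organelle (replicon id) to its genome length,
    the denominator of per-site diversity.
    """
    records: list[DiversityRecord] = []
    submatrices = {
        org: matrix.subset_replicon(org) for org in target_lengths
    }
    for s in samples:
        for org, sub in submatrices.items():
            if sub.n_loci == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pi = nucleotide_diversity(sub, s.sample_id, target_lengths[org])
            cov = s.coverage.get(org, 0.0)
            pi_norm = (
                normalize_by_coverage(pi, cov) if pi is not None and cov > 0 else None
            )
            records.append(
                DiversityRecord(
                    sample_id=s.sample_id, organelle=org, pi_raw=pi, pi_norm=pi_norm
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shannon, simpson = diversity_indices(haps, s.sample_id)
        n_distinct = len(haps.data[haps.data["sample_id"] == s.sample_id])
        mean_cov = s.mean_coverage
        records.append(
            DiversityRecord(
                sample_id=s.sample_id,
                organelle="combined",
                shannon=shannon,
                simpson=simpson,
                n_distinct_variants_norm=(
                    n_distinct / mean_cov if mean_cov > 0 else None
                ),
            )
        )
    return records


def overlapping_age_window(samples: list[SedimentSample]) -> tuple[float, float]:
    """[max of per-site minimum ages, min of per-site maximum ages]."""
    by_site: dict[str, list[float]] = {}
    for s in samples:
        by_site.setdefault(s.site, []).append(s.age_calBP)
    if len(by_site) < 2:
        raise AnalysisError("need samples from at least two sites")
    lo = max(min(v) for v in by_site.values())
    hi = min(max(v) for v in by_site.values())
    if lo > hi:
        raise AnalysisError("sites have no temporally overlapping samples")
    return lo, hi


def compare_sites(
    records: list[DiversityRecord], samples: list[SedimentSample]
) -> dict:
    """Between-site Welch tests on the temporally overlapping subset.

    Tests coverage-normalized pi (both organelles pooled into one vector per
    site), Shannon and Simpson; also reports the Pearson correlation between
    mitochondrial and chloroplast pi_norm across samples as a consistency
    check between the two replicons.
    """
    lo, hi = overlapping_age_window(samples)
    site_of = {s.sample_id: s.site for s in samples}
    in_window = {
        s.sample_id for s in samples if lo <= s.age_calBP <= hi
    }
    sites = sorted({s.site for s in samples})
    site_a, site_b = sites[0], sites[1]

    def _pool(predicate) -> dict[str, list[float]]:
        pools: dict[str, list[float]] = {site_a: [], site_b: []}
        for r in records:
            if r.sample_id not in in_window:
                continue
            val = predicate(r)
            if val is not None:
                pools[site_of[r.sample_id]].append(val)
        return pools

    pi_pool = _pool(lambda r: r.pi_norm if r.organelle != "combined" else None)
    sh_pool = _pool(lambda r: r.shannon if r.organelle == "combined" else None)
    si_pool = _pool(lambda r: r.simpson if r.organelle == "combined" else None)

    per_sample: dict[str, dict[str, float]] = {}
    for r in records:
        if r.organelle in ("chloroplast", "mitochondrion") and r.pi_norm is not None:
            per_sample.setdefault(r.sample_id, {})[r.organelle] = r.pi_norm
    paired = [
        (v["mitochondrion"], v["chloroplast"])
        for v in per_sample.values()
        if len(v) == 2
    ]
    organelle_consistency: CorrelationResult | None = None
    if len(paired) >= 3:
        mito, chloro = zip(*paired)
        try:
            organelle_consistency = correlate(mito, chloro)
        except AnalysisError:
            pass

    return {
        "sites": (site_a, site_b),
        "overlap_age_window": (lo, hi),
        "pi_norm": welch_t_test(pi_pool[site_a], pi_pool[site_b]),
        "shannon": welch_t_test(sh_pool[site_a], sh_pool[site_b]),
        "simpson": welch_t_test(si_pool[site_a], si_pool[site_b]),
        "organelle_consistency": organelle_consistency,
    }
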