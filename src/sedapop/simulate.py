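"""Synthetic sediment-core generator for the organellar sedaDNA pipeline.

The generator emulates the downstream data products of a two-core capture
study: two sites (an "EGB-like" basin core reaching ~8150 cal BP and a
"GOF-like" gulf core reaching ~4300 cal BP, ~13 dated layers each), biallelic
SNPs on a chloroplast and a mitochondrion replicon, long-term frequency
stability with punctuated *reversible* event shifts, accelerated drift in the
recent past, age-increasing terminal C-to-T damage, and the large
chloroplast/mitochondrion coverage contrast of organellar capture data.

Latent allele-frequency trajectories follow a Gaussian diffusion
approximation to Wright-Fisher drift: between layers separated by g
generations, p' = clip(p + N(0, sqrt(p(1-p) g / (2 Ne))), eps, 1-eps).
Observed data are binomial read sampling on Poisson depths, so every emitted
file is exactly what :mod:`sedapop.io_core` reads, and a truth record allows
recovery tests against the simulated ground truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import (
    HaplotypeTable,
    MisincorporationTable,
    SedimentSample,
    write_haplotypes,
    write_metadata,
    write_misincorporation,
)

_EPS = 1e-4  # clipping bound for the diffusion approximation

#: organelle genome lengths (nt) used for locus placement
REPLICON_LENGTHS = {"chloroplast": 127202, "mitochondrion": 43586}


def _default_ages() -> dict[str, list[float]]:
    # basin core spans the full record, gulf core the last ~4300 years
    egb = list(np.round(np.linspace(8148.0, -71.0, 13), 1))
    gof = list(np.round(np.linspace(4300.0, -71.0, 13), 1))
    return {"EGB-like": egb, "GOF-like": gof}


def _default_events() -> list[tuple[float, float, float, float]]:
    # (start_age, end_age, shift_sd, affected_fraction): a mid-Holocene warm
    # phase and a medieval-era excursion, both reversible
    return [(7000.0, 6000.0, 0.12, 0.25), (1100.0, 700.0, 0.12, 0.25)]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_loci: int = 500
    ages: dict[str, list[float]] = field(default_factory=_default_ages)
    ne: float = 1e5
    gens_per_year: float = 1.0
    event_windows: list[tuple[float, float, float, float]] = field(
        default_factory=_default_events
    )
    accel_age: float = 1500.0
    accel_factor: float = 5.0
    site_divergence_sd: float = 0.172
    depth_mean: dict[str, float] = field(
        default_factory=lambda: {"chloroplast": 575.5, "mitochondrion": 78.77}
    )
    damage_d0: float = 0.005
    damage_dmax: float = 0.05
    damage_tau: float = 2000.0
    n_haplotypes_latent: int = 20
    haplotype_reads: int = 200
    chloroplast_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValidationError("n_loci must be positive")
        if self.ne <= 0:
            raise ValidationError("ne must be positive")
        if self.gens_per_year <= 0:
            raise ValidationError("gens_per_year must be positive")
        if self.accel_factor < 1:
            raise ValidationError("accel_factor must be >= 1")
        if self.site_divergence_sd < 0:
            raise ValidationError("site_divergence_sd must be >= 0")
        if not (0 <= self.damage_d0 <= self.damage_dmax):
            raise ValidationError("need 0 <= d0 <= d_max")
        if self.damage_tau <= 0:
            raise ValidationError("damage tau must be positive")
        for site, ages in self.ages.items():
            diffs = np.diff(ages)
            if np.any(diffs >= 0):
                raise ValidationError(
                    f"ages for site {site!r} must be strictly decreasing "
                    "(oldest first)"
                )
        for start, end, sd, frac in self.event_windows:
            if start <= end:
                raise ValidationError("event start_age must be older than end_age")
            if sd < 0 or not (0 <= frac <= 1):
                raise ValidationError("bad event window parameters")

    def damage_rate(self, age: float) -> float:
        """Terminal C->T rate as a saturating function of sample age."""
        d = self.damage_d0 + (self.damage_dmax - self.damage_d0) * (
            1.0 - np.exp(-age / self.damage_tau)
        )
        return float(np.clip(d, 0.0, 1.0))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated core pair, for recovery tests."""

    baseline_freq: np.ndarray
    merged_ages: list[float]
    shared_latent: np.ndarray  # n_loci x n_merged_ages, before site offsets
    site_latent: dict[str, np.ndarray]  # per site: n_loci x n_layers
    site_offsets: dict[str, np.ndarray]
    event_affected: list[np.ndarray]  # locus indices per event window
    event_shifts: list[np.ndarray]  # additive shift per affected locus
    damage_rate: dict[str, float]  # per sample id
    config: SimulationConfig

    def to_json(self, path: str) -> None:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = {
            "baseline_freq": self.baseline_freq,
            "merged_ages": self.merged_ages,
            "shared_latent": self.shared_latent,
            "site_latent": self.site_latent,
            "site_offsets": self.site_offsets,
            "event_affected": self.event_affected,
            "event_shifts": self.event_shifts,
            "damage_rate": self.damage_rate,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(_clean(payload), fh)


def simulate_trajectories(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], SimulationTruth]:
    """Latent per-site, per-layer allele-frequency matrices plus ground truth.

    Both sites share one drift trajectory simulated over the union of their
    layer ages; each site then receives a constant per-locus offset
    ~N(0, site_divergence_sd).  Event windows add a reversible per-locus shift
    to the affected fraction of loci while a layer's age falls inside the
    window.
    """
    rng = np.random.default_rng([config.seed, 1])
    merged_ages = sorted({a for ages in config.ages.values() for a in ages},
                         reverse=True)
    n, m = config.n_loci, len(merged_ages)

    p0 = rng.beta(2.0, 2.0, size=n)
    shared = np.empty((n, m))
    shared[:, 0] = p0
    for j in range(1, m):
        dt_years = merged_ages[j - 1] - merged_ages[j]
        g = dt_years * config.gens_per_year
        var_mult = config.accel_factor if merged_ages[j] < config.accel_age else 1.0
        p = shared[:, j - 1]
        sd = np.sqrt(p * (1.0 - p) * g * var_mult / (2.0 * config.ne))
        shared[:, j] = np.clip(p + rng.normal(0.0, 1.0, size=n) * sd, _EPS, 1 - _EPS)

    event_affected: list[np.ndarray] = []
    event_shifts: list[np.ndarray] = []
    event_field = np.zeros((n, m))  # additive, zero outside windows (reversible)
    for start, end, shift_sd, frac in config.event_windows:
        k = int(round(frac * n))
        affected = rng.choice(n, size=k, replace=False)
        shifts = rng.normal(0.0, shift_sd, size=k)
        event_affected.append(np.sort(affected))
        event_shifts.append(shifts[np.argsort(affected)])
        in_window = [end <= age <= start for age in merged_ages]
        for j, inside in enumerate(in_window):
            if inside:
                event_field[affected, j] += shifts
    shared_with_events = np.clip(shared + event_field, _EPS, 1 - _EPS)

    site_latent: dict[str, np.ndarray] = {}
    site_offsets: dict[str, np.ndarray] = {}
    col_of = {age: j for j, age in enumerate(merged_ages)}
    for site, ages in config.ages.items():
        offset = rng.normal(0.0, config.site_divergence_sd, size=n) \
            if config.site_divergence_sd > 0 else np.zeros(n)
        cols = [col_of[a] for a in ages]
        site_latent[site] = np.clip(
            shared_with_events[:, cols] + offset[:, None], _EPS, 1 - _EPS
        )
        site_offsets[site] = offset

    damage = {
        _sample_id(site, i): config.damage_rate(age)
        for site, ages in config.ages.items()
        for i, age in enumerate(ages)
    }
    truth = SimulationTruth(
        baseline_freq=p0,
        merged_ages=merged_ages,
        shared_latent=shared_with_events,
        site_latent=site_latent,
        site_offsets=site_offsets,
        event_affected=event_affected,
        event_shifts=event_shifts,
        damage_rate=damage,
        config=config,
    )
    return site_latent, truth


def _sample_id(site: str, layer_index: int) -> str:
    short = site.split("-")[0]
    return f"{short}_{layer_index:02d}"


@dataclass
class SyntheticDataset:
    """File paths of one emitted synthetic core pair."""

    vcf: str
    metadata: str
    haplotypes: str
    misincorporation: str
    truth_json: str
    samples: list[SedimentSample]
    truth: SimulationTruth


def _assign_loci(config: SimulationConfig, rng: np.random.Generator):
    """Place loci on the two replicons with random positions and alleles."""
    n_chl = int(round(config.chloroplast_fraction * config.n_loci))
    bases = np.array(list("ACGT"))
    loci = []
    for replicon, count in (
        ("chloroplast", n_chl),
        ("mitochondrion", config.n_loci - n_chl),
    ):
        length = REPLICON_LENGTHS[replicon]
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=count, replace=False)
        )
        for p in pos:
            ref = rng.choice(bases)
            alt = rng.choice(bases[bases != ref])
            loci.append((replicon, int(p), str(ref), str(alt)))
    return loci


def _sample_core(latent: dict[str, np.ndarray], config: SimulationConfig):
    """Draw the observed layer of one core pair, in memory.

    Per sample and locus: depth ~ Poisson(depth_mean[organelle]), alt reads ~
    Binomial(depth, p); for C>T loci an apparent excess of alt reads is added
    at the age-dependent damage rate.  Zero-depth cells become missing.
    Per-sample randomness uses substreams keyed by (seed, site, layer), so
    adding layers never perturbs existing ones.
    """
    rng = np.random.default_rng([config.seed, 2])
    loci = _assign_loci(config, rng)
    hap_base = rng.dirichlet(np.ones(config.n_haplotypes_latent))
    hap_keys = [
        "".join(rng.choice(list("ACGT"), size=12))
        for _ in range(config.n_haplotypes_latent)
    ]

    samples: list[SedimentSample] = []
    depth_obs: dict[str, dict[str, list[int]]] = {}
    ad_store: dict[str, np.ndarray] = {}
    hap_rows = []
    mis_rows = []
    site_index = {site: k for k, site in enumerate(sorted(config.ages))}

    for site, ages in config.ages.items():
        lat = latent[site]
        for i, age in enumerate(ages):
            sid = _sample_id(site, i)
            srng = np.random.default_rng(
                [config.seed, 3, site_index[site], i]
            )
            d_rate = config.damage_rate(age)
            mean_depth = np.array(
                [config.depth_mean[loc[0]] for loc in loci], dtype=float
            )
            ct_locus = np.array(
                [loc[2] == "C" and loc[3] == "T" for loc in loci], dtype=bool
            )
            depth = srng.poisson(mean_depth)
            alt_n = srng.binomial(depth, lat[:, i])
            extra = srng.binomial(depth - alt_n, d_rate)
            alt_n = np.where(ct_locus, alt_n + extra, alt_n)
            ad = np.column_stack([depth - alt_n, alt_n]).astype(int)
            ad_store[sid] = ad
            depth_obs[sid] = {
                org: depth[[k for k, loc in enumerate(loci) if loc[0] == org]]
                for org in config.depth_mean
            }

            # misincorporation tallies consistent with d(age) at 5' position 1
            n_ref_c = int(srng.poisson(2000))
            n_ct = int(srng.binomial(n_ref_c, d_rate)) if n_ref_c else 0
            n_p2 = int(srng.poisson(2000))
            n_ct2 = int(srng.binomial(n_p2, d_rate / 2.0)) if n_p2 else 0
            n_ga = int(srng.binomial(n_ref_c, d_rate * 0.3)) if n_ref_c else 0
            mis_rows += [
                (sid, "5p", 1, "C", "T", n_ct),
                (sid, "5p", 1, "C", "C", n_ref_c - n_ct),
                (sid, "5p", 2, "C", "T", n_ct2),
                (sid, "5p", 2, "C", "C", n_p2 - n_ct2),
                (sid, "3p", 1, "G", "A", n_ga),
                (sid, "3p", 1, "G", "G", n_ref_c - n_ga),
            ]

            # layer-specific haplotype mixture around the latent pool
            conc = 50.0
            w = srng.dirichlet(hap_base * conc * config.n_haplotypes_latent)
            counts = srng.multinomial(config.haplotype_reads, w)
            for key, c in zip(hap_keys, counts):
                if c > 0:
                    hap_rows.append((sid, key, int(c)))

            samples.append(
                SedimentSample(
                    sample_id=sid,
                    site=site,
                    depth_cm=float(32.0 + 15.0 * i),
                    age_calBP=float(age),
                    toc=float(srng.uniform(0.5, 8.0)),
                    coverage={
                        org: float(np.mean(depth_obs[sid][org]))
                        for org in config.depth_mean
                    },
                )
            )
    return samples, loci, ad_store, hap_rows, mis_rows


def observed_frequency_matrix(
    latent: dict[str, np.ndarray], config: SimulationConfig
):
    """Observed allele-frequency matrix without the file round trip.

    Same sampling model and random substreams as :func:`sample_observed_data`;
    useful for replicate-heavy recovery tests where VCF emission would only
    add I/O.
    """
    from .io_core import AlleleFrequencyMatrix

    samples, loci, ad_store, _haps, _mis = _sample_core(latent, config)
    order = sorted(range(len(loci)), key=lambda i: (loci[i][0], loci[i][1]))
    freq = np.full((len(loci), len(samples)), np.nan)
    for j, s in enumerate(samples):
        ad = ad_store[s.sample_id][order]
        tot = ad.sum(axis=1)
        nz = tot > 0
        freq[nz, j] = ad[nz, 1] / tot[nz]
    return (
        AlleleFrequencyMatrix(
            loci=[loci[i] for i in order],
            samples=[s.sample_id for s in samples],
            freq=freq,
        ),
        samples,
    )


def sample_observed_data(
    latent: dict[str, np.ndarray],
    config: SimulationConfig,
    outdir: str,
    truth: SimulationTruth | None = None,
) -> SyntheticDataset:
    """Emit VCF + metadata/haplotype/misincorporation TSVs from latent truth.

    The sampling model is :func:`_sample_core`; this function only writes the
    io_core file formats (VCF 4.2 with AD/DP, headered TSVs, truth JSON).
    """
    import pysam

    os.makedirs(outdir, exist_ok=True)
    samples, loci, ad_store, hap_rows, mis_rows = _sample_core(latent, config)

    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "haplotypes": os.path.join(outdir, "haplotypes.tsv"),
        "misincorporation": os.path.join(outdir, "misincorporation.tsv"),
        "truth_json": os.path.join(outdir, "truth.json"),
    }

    header = pysam.VariantHeader()
    header.add_line("##source=sedapop-simulate")
    for replicon, length in REPLICON_LENGTHS.items():
        header.add_line(f"##contig=<ID={replicon},length={length}>")
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    sample_ids = [s.sample_id for s in samples]
    for sid in sample_ids:
        header.add_sample(sid)
    qual_rng = np.random.default_rng([config.seed, 4])
    quals = qual_rng.gamma(shape=4.0, scale=20.0, size=config.n_loci)
    with pysam.VariantFile(paths["vcf"], "w", header=header) as vf:
        for j, (replicon, pos, ref, alt) in enumerate(loci):
            rec = vf.new_record(
                contig=replicon, start=pos - 1, stop=pos, alleles=(ref, alt)
            )
            rec.qual = float(round(quals[j], 2))
            for sid in sample_ids:
                ref_n, alt_n = (int(v) for v in ad_store[sid][j])
                rec.samples[sid]["AD"] = (ref_n, alt_n)
                rec.samples[sid]["DP"] = ref_n + alt_n
            vf.write(rec)

    write_metadata(samples, paths["metadata"])
    write_haplotypes(
        HaplotypeTable(
            data=pd.DataFrame(
                hap_rows, columns=["sample_id", "variant_combination", "count"]
            )
        ),
        paths["haplotypes"],
    )
    write_misincorporation(
        MisincorporationTable(
            data=pd.DataFrame(
                mis_rows,
                columns=["sample_id", "end", "read_pos", "ref_base", "obs_base", "count"],
            )
        ),
        paths["misincorporation"],
    )
    if truth is not None:
        truth.to_json(paths["truth_json"])

    return SyntheticDataset(
        vcf=paths["vcf"],
        metadata=paths["metadata"],
        haplotypes=paths["haplotypes"],
        misincorporation=paths["misincorporation"],
        truth_json=paths["truth_json"],
        samples=samples,
        truth=truth,
    )


def generate_core(config: SimulationConfig, outdir: str) -> SyntheticDataset:
    """Simulate latent trajectories and emit the full synthetic dataset."""
    latent, truth = simulate_trajectories(config)
    return sample_observed_data(latent, config, outdir, truth=truth)
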