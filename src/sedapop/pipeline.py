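"""End-to-end orchestration: filter -> matrix -> damage -> diversity ->
structure -> turnover, with a reproducibility manifest.

Every stage writes plain-text tables/JSON under a fixed run-directory layout
(``tables/``, ``manifest.json``); the manifest records the config echo, the
seed, and SHA-256 checksums of inputs and outputs, so two runs with the same
inputs, config and seed can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_core
from .damage import authenticate
from .diversity import compare_sites, diversity_table
from .errors import SedapopError
from .simulate import REPLICON_LENGTHS
from .structure import global_fst, pca_allelic, permanova, windowed_fst
from .turnover import TurnoverConfig, era_contrast, fit_gam, turnover_series

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location of one pipeline run.

    Defaults follow the analysis conventions: inclusive Q>=30 variant filter,
    1000-year FST windows stepped by 250 years, a strict >1% turnover
    threshold, 999 PERMANOVA permutations.
    """

    vcf: str = ""
    metadata: str = ""
    haplotypes: str = ""
    misincorporation: str = ""
    outdir: str = "sedapop_run"
    min_qual: float = 30.0
    window_years: float = 1000.0
    step_years: float = 250.0
    turnover: TurnoverConfig = field(default_factory=TurnoverConfig)
    n_permutations: int = 999
    seed: int = 0
    gam_basis_dim: int = 10
    era_boundary_age: float = 1500.0
    target_lengths: dict[str, int] = field(
        default_factory=lambda: dict(REPLICON_LENGTHS)
    )

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides win over file values."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        turnover_raw = raw.pop("turnover", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if turnover_raw:
            cfg.turnover = TurnoverConfig(**turnover_raw)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the result bundle (also written to disk)."""
    tables = os.path.join(config.outdir, "tables")
    os.makedirs(tables, exist_ok=True)
    outputs: list[str] = []
    results: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except SedapopError:
            raise
        except Exception as exc:
            raise SedapopError(f"stage {name!r} failed: {exc}") from exc

    # --- io: filter variants, assemble matrix -------------------------------
    samples = _stage("metadata", lambda: io_core.read_metadata(config.metadata))
    records, report = _stage(
        "vcf",
        lambda: io_core.read_vcf(
            config.vcf, min_qual=config.min_qual, collect_report=True
        ),
    )
    matrix = _stage(
        "matrix", lambda: io_core.build_frequency_matrix(records, samples)
    )
    haps = _stage("haplotypes", lambda: io_core.read_haplotypes(config.haplotypes))
    mis = _stage(
        "misincorporation",
        lambda: io_core.read_misincorporation(config.misincorporation),
    )
    results["filter_report"] = dataclasses.asdict(report)
    logger.info(
        "variants: %d read, %d retained (Q>=%g)",
        report.n_read, report.n_retained, config.min_qual,
    )

    ages = {s.sample_id: s.age_calBP for s in samples}
    covs = {s.sample_id: s.mean_coverage for s in samples}

    # --- damage authentication ---------------------------------------------
    dmg = _stage("damage", lambda: authenticate(mis, ages, covs))
    results["damage"] = dmg
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "ct_rate_pos1": p.ct_rate_pos1,
                "n_ref_c_pos1": p.n_ref_c_pos1,
            }
            for p in dmg["profiles"]
        ]
    ).to_csv(os.path.join(tables, "damage.tsv"), sep="\t", index=False)
    _dump_json(
        {
            "age_correlation": dmg["age_correlation"],
            "coverage_correlation": dmg["coverage_correlation"],
        },
        os.path.join(tables, "damage_correlations.json"),
    )
    outputs += ["damage.tsv", "damage_correlations.json"]

    # --- diversity ----------------------------------------------------------
    div = _stage(
        "diversity",
        lambda: diversity_table(matrix, haps, samples, config.target_lengths),
    )
    results["diversity"] = div
    pd.DataFrame([dataclasses.asdict(r) for r in div]).to_csv(
        os.path.join(tables, "diversity.tsv"), sep="\t", index=False
    )
    outputs.append("diversity.tsv")
    comparison = _stage("compare_sites", lambda: compare_sites(div, samples))
    results["site_comparison"] = comparison
    _dump_json(comparison, os.path.join(tables, "site_comparison.json"))
    outputs.append("site_comparison.json")

    # --- structure: FST, PCA, PERMANOVA --------------------------------------
    fst_windows = _stage(
        "fst",
        lambda: windowed_fst(
            matrix, samples, window_years=config.window_years,
            step_years=config.step_years,
        ),
    )
    results["fst_windows"] = fst_windows
    results["fst_global"] = _stage("fst", lambda: global_fst(matrix, samples))
    pd.DataFrame([dataclasses.asdict(w) for w in fst_windows]).to_csv(
        os.path.join(tables, "fst_windows.tsv"), sep="\t", index=False
    )
    outputs.append("fst_windows.tsv")

    pca = _stage("pca", lambda: pca_allelic(matrix))
    results["pca"] = pca
    scores = pd.DataFrame(
        pca.scores[:, :2], columns=["PC1", "PC2"], index=pca.sample_ids
    )
    scores.index.name = "sample_id"
    scores.to_csv(os.path.join(tables, "pca_scores.tsv"), sep="\t")
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.explained_variance_ratio) + 1),
            "explained_variance_ratio": pca.explained_variance_ratio,
        }
    ).to_csv(os.path.join(tables, "pca_variance.tsv"), sep="\t", index=False)
    outputs += ["pca_scores.tsv", "pca_variance.tsv"]

    rate_of = {
        p.sample_id: p.ct_rate_pos1
        for p in dmg["profiles"]
        if p.ct_rate_pos1 is not None
    }
    coords = pca.scores[:, :2]
    perm_results = {}
    for label, vec in (
        ("ct_rate", [rate_of.get(sid, np.nan) for sid in pca.sample_ids]),
        ("toc", [next(s.toc for s in samples if s.sample_id == sid)
                 for sid in pca.sample_ids]),
    ):
        vec = np.asarray(vec, dtype=float)
        if np.isnan(vec).any():
            logger.warning("covariate %s has missing values; PERMANOVA skipped", label)
            continue
        perm_results[label] = _stage(
            "permanova",
            lambda v=vec: permanova(
                coords, v, n_permutations=config.n_permutations, seed=config.seed
            ),
        )
    results["permanova"] = perm_results
    _dump_json(perm_results, os.path.join(tables, "permanova.json"))
    outputs.append("permanova.json")

    # --- turnover + GAM -------------------------------------------------------
    intervals = _stage(
        "turnover", lambda: turnover_series(matrix, samples, config.turnover)
    )
    results["turnover"] = intervals
    pd.DataFrame([dataclasses.asdict(iv) for iv in intervals]).to_csv(
        os.path.join(tables, "turnover.tsv"), sep="\t", index=False
    )
    outputs.append("turnover.tsv")
    gam = _stage(
        "gam", lambda: fit_gam(intervals, basis_dim=min(config.gam_basis_dim,
                                                        len(intervals)))
    )
    results["gam"] = gam
    pd.DataFrame({"age": gam.ages_grid, "fitted": gam.fitted}).to_csv(
        os.path.join(tables, "gam_fit.tsv"), sep="\t", index=False
    )
    outputs.append("gam_fit.tsv")
    recent, ancient, ratio = _stage(
        "era_contrast", lambda: era_contrast(gam, config.era_boundary_age)
    )
    results["era_contrast"] = {
        "boundary_age": config.era_boundary_age,
        "mean_recent": recent,
        "mean_ancient": ancient,
        "ratio": ratio,
    }
    _dump_json(results["era_contrast"], os.path.join(tables, "era_contrast.json"))
    outputs.append("era_contrast.json")

    # --- manifest -------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "turnover"
            },
            "turnover": dataclasses.asdict(config.turnover),
        },
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("vcf", config.vcf),
                ("metadata", config.metadata),
                ("haplotypes", config.haplotypes),
                ("misincorporation", config.misincorporation),
            )
            if path
        },
        "outputs": {
            name: _sha256(os.path.join(tables, name)) for name in outputs
        },
        "filter_report": dataclasses.asdict(report),
    }
    _dump_json(manifest, os.path.join(config.outdir, "manifest.json"))
    results["manifest"] = manifest
    return results
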