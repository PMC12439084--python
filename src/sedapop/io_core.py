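"""Domain types and file I/O for the sedaDNA organellar pipeline.

The pipeline works on pooled sedimentary DNA: each dated sediment layer is one
"sample" containing many individuals, so the natural per-locus observation is
an alternate-read fraction, not a genotype call.  Positions are kept 1-based
(VCF convention) throughout; a locus is keyed by ``(replicon, pos)``.

Readers cover the standard formats the pipeline touches: VCF 4.x (via cyvcf2),
softmasked FASTA (via Biopython, case preserved), and headered TSV tables for
sample metadata, haplotype counts, and misincorporation tallies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import EmptyDataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Mandatory metadata columns; extra columns are preserved as annotations.
METADATA_COLUMNS = (
    "sample_id",
    "site",
    "depth_cm",
    "age_calBP",
    "toc",
    "cov_chloroplast",
    "cov_mitochondrion",
)
HAPLOTYPE_COLUMNS = ("sample_id", "variant_combination", "count")
MISINCORPORATION_COLUMNS = (
    "sample_id",
    "end",
    "read_pos",
    "ref_base",
    "obs_base",
    "count",
)

_FASTA_ALPHABET = frozenset("ACGTNacgtn")


@dataclass
class SedimentSample:
    """One dated sediment layer.

    ``age_calBP`` is in calibrated years before present (present = 1950 CE);
    larger is older, negative means post-1950.  ``coverage`` maps an organelle
    label (``chloroplast`` / ``mitochondrion``) to mean mapping depth.
    """

    sample_id: str
    site: str
    depth_cm: float
    age_calBP: float
    toc: float
    coverage: dict[str, float]
    extra: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_calBP):
            raise ValidationError(
                f"sample {self.sample_id!r}: age_calBP must be finite"
            )
        if self.depth_cm < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: depth_cm must be >= 0"
            )
        for organelle, cov in self.coverage.items():
            if cov < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: coverage[{organelle!r}] < 0"
                )

    @property
    def mean_coverage(self) -> float:
        """Mean mapping depth across organelles."""
        return float(np.mean(list(self.coverage.values())))


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample pooled allele frequencies."""

    replicon: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float
    per_sample_freq: dict[str, float]
    per_sample_depth: dict[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValidationError(f"quality must be >= 0, got {self.qual}")
        for sid, f in self.per_sample_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(
                    f"frequency for sample {sid!r} outside [0,1]: {f}"
                )

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.replicon, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class AlleleFrequencyMatrix:
    """Loci x samples matrix of alternate-allele frequencies.

    Missing observations (zero depth) are NaN, never 0: a layer where a locus
    was not covered carries no information about its frequency.
    """

    loci: list[tuple[str, int, str, str]]
    samples: list[str]
    freq: np.ndarray  # shape (n_loci, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.loci), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.freq.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        observed = self.freq[~np.isnan(self.freq)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValidationError("allele frequencies must lie in [0,1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, sample_id: str) -> np.ndarray:
        """Frequency vector for one sample (NaN where missing)."""
        return self.freq[:, self.samples.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "AlleleFrequencyMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return AlleleFrequencyMatrix(
            loci=list(self.loci),
            samples=list(sample_ids),
            freq=self.freq[:, idx].copy(),
        )

    def subset_replicon(self, replicon: str) -> "AlleleFrequencyMatrix":
        keep = [i for i, loc in enumerate(self.loci) if loc[0] == replicon]
        return AlleleFrequencyMatrix(
            loci=[self.loci[i] for i in keep],
            samples=list(self.samples),
            freq=self.freq[keep, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(
            self.loci, names=["replicon", "pos", "ref", "alt"]
        )
        return pd.DataFrame(self.freq, index=index, columns=self.samples)


@dataclass
class HaplotypeTable:
    """Per-sample counts of distinct phased allele combinations.

    A "distinct variant" is a unique combination of alleles across the variant
    sites of an organellar genome; counts are how often each combination was
    observed in a sample.
    """

    data: pd.DataFrame  # columns: sample_id, variant_combination, count

    def __post_init__(self) -> None:
        missing = set(HAPLOTYPE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"haplotype table missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["count"] <= 0).any():
            raise ValidationError("haplotype counts must be > 0")

    def counts_for(self, sample_id: str) -> np.ndarray:
        sub = self.data[self.data["sample_id"] == sample_id]
        return sub["count"].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))


@dataclass
class MisincorporationTable:
    """Substitution counts by read position and read end (mapDamage-style).

    ``read_pos`` is 1-based from the given end (1 = terminal base); ``end`` is
    ``5p`` or ``3p``.  Compatible with mapDamage2 ``misincorporation.txt``
    after mapping its (End, Pos, mutation-count) columns onto this layout.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MISINCORPORATION_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(
                f"misincorporation table missing columns: {sorted(missing)}"
            )
        if len(self.data):
            if (self.data["count"] < 0).any():
                raise ValidationError("misincorporation counts must be >= 0")
            if (self.data["read_pos"] < 1).any():
                raise ValidationError("read_pos must be >= 1")
            bad_end = set(self.data["end"]) - {"5p", "3p"}
            if bad_end:
                raise ValidationError(f"unknown read end labels: {sorted(bad_end)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))


@dataclass
class MaskedGenome:
    """Softmasked genome: lowercase = masked, uppercase = unmasked."""

    contigs: dict[str, str]

    def masked_fraction(self, contig_id: str) -> float:
        seq = self.contigs[contig_id]
        return sum(c.islower() for c in seq) / len(seq)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class VcfSkipReport:
    """Counts of records excluded while reading a VCF."""

    n_read: int = 0
    n_retained: int = 0
    n_below_qual: int = 0
    n_not_snp: int = 0
    n_multiallelic: int = 0


def read_vcf(
    path: str,
    min_qual: float = 30.0,
    *,
    collect_report: bool = False,
):
    """Read biallelic SNPs with qual >= ``min_qual`` from a VCF 4.x file.

    Per-sample frequencies come from the AD field (alt / (ref+alt)) when
    present, else from an AF FORMAT field; zero-depth cells are missing.
    The quality filter is inclusive (Q >= min_qual).

    Returns a list of :class:`VariantRecord`, or ``(records, VcfSkipReport)``
    when ``collect_report`` is true.
    """
    from cyvcf2 import VCF

    if min_qual < 0:
        raise ValidationError("min_qual must be >= 0")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyDataError(f"VCF {path!r} declares no samples")

    report = VcfSkipReport()
    records: list[VariantRecord] = []
    for lineno, var in enumerate(vcf, start=1):
        report.n_read += 1
        try:
            if not var.is_snp or var.var_type != "snp":
                report.n_not_snp += 1
                continue
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                report.n_multiallelic += 1
                continue
            qual = var.QUAL if var.QUAL is not None else 0.0
            if qual < min_qual:
                report.n_below_qual += 1
                continue
            freqs: dict[str, float] = {}
            depths: dict[str, int] = {}
            ad = _format_field(var, "AD")
            if ad is not None:
                for i, sid in enumerate(samples):
                    ref_n, alt_n = int(ad[i, 0]), int(ad[i, 1])
                    if ref_n < 0 or alt_n < 0:  # cyvcf2 encodes missing as <0
                        continue
                    total = ref_n + alt_n
                    depths[sid] = total
                    if total > 0:
                        freqs[sid] = alt_n / total
            else:
                af = _format_field(var, "AF")
                if af is None:
                    raise FormatError(
                        f"VCF record at data line {lineno} ({var.CHROM}:{var.POS}) "
                        "has neither AD nor AF FORMAT fields"
                    )
                for i, sid in enumerate(samples):
                    val = float(af[i, 0]) if af.ndim == 2 else float(af[i])
                    if np.isnan(val):
                        continue
                    freqs[sid] = val
            records.append(
                VariantRecord(
                    replicon=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=var.ALT[0],
                    qual=float(qual),
                    per_sample_freq=freqs,
                    per_sample_depth=depths,
                )
            )
            report.n_retained += 1
        except (ValidationError, FormatError):
            raise
        except Exception as exc:
            raise FormatError(
                f"malformed VCF record at data line {lineno} in {path!r}: {exc}"
            ) from exc
    logger.info(
        "read_vcf %s: %d read, %d retained, %d below Q%g, %d non-SNP, %d multiallelic",
        path, report.n_read, report.n_retained, report.n_below_qual,
        min_qual, report.n_not_snp, report.n_multiallelic,
    )
    if collect_report:
        return records, report
    return records


def _format_field(var, key: str):
    try:
        return var.format(key)
    except KeyError:
        return None


def build_frequency_matrix(
    records: list[VariantRecord], samples: list[SedimentSample]
) -> AlleleFrequencyMatrix:
    """Assemble records into a loci x samples matrix ordered by (replicon, pos)."""
    if not records:
        raise EmptyDataError("no variant records to build a matrix from")
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample ids in metadata")
    known = set(sample_ids)
    seen: set[tuple[str, int]] = set()
    ordered = sorted(records, key=lambda r: (r.replicon, r.pos))
    loci = []
    freq = np.full((len(ordered), len(sample_ids)), np.nan)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    for i, rec in enumerate(ordered):
        key = (rec.replicon, rec.pos)
        if key in seen:
            raise ValidationError(f"duplicate locus {key[0]}:{key[1]}")
        seen.add(key)
        loci.append(rec.locus)
        for sid, f in rec.per_sample_freq.items():
            if sid not in known:
                raise ValidationError(
                    f"VCF sample {sid!r} absent from metadata"
                )
            if rec.per_sample_depth.get(sid, 1) == 0:
                continue  # zero depth carries no frequency information
            freq[i, col[sid]] = f
    return AlleleFrequencyMatrix(loci=loci, samples=sample_ids, freq=freq)


def read_masked_fasta(path: str) -> MaskedGenome:
    """Read a softmasked FASTA, preserving case and contig order exactly."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig id {rec.id!r} in {path!r}")
        seq = str(rec.seq)
        for offset, ch in enumerate(seq):
            if ch not in _FASTA_ALPHABET:
                raise FormatError(
                    f"illegal character {ch!r} in contig {rec.id!r} "
                    f"at offset {offset}"
                )
        contigs[rec.id] = seq
    if not contigs:
        raise EmptyDataError(f"no sequences found in FASTA {path!r}")
    return MaskedGenome(contigs=contigs)


def _read_tsv(path: str, mandatory: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(mandatory))
    except Exception as exc:
        raise FormatError(f"cannot parse TSV {path!r}: {exc}") from exc
    missing = set(mandatory) - set(df.columns)
    if missing:
        raise FormatError(
            f"TSV {path!r} is missing mandatory column(s): {sorted(missing)}"
        )
    return df


def read_metadata(path: str) -> list[SedimentSample]:
    """Read the sample metadata TSV into validated :class:`SedimentSample` rows."""
    df = _read_tsv(path, METADATA_COLUMNS)
    if df.empty:
        raise EmptyDataError(f"metadata table {path!r} has no rows")
    numeric = ("depth_cm", "age_calBP", "toc", "cov_chloroplast", "cov_mitochondrion")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric value in column {col!r}") from exc
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    extra_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SedimentSample(
                sample_id=str(row["sample_id"]),
                site=str(row["site"]),
                depth_cm=float(row["depth_cm"]),
                age_calBP=float(row["age_calBP"]),
                toc=float(row["toc"]),
                coverage={
                    "chloroplast": float(row["cov_chloroplast"]),
                    "mitochondrion": float(row["cov_mitochondrion"]),
                },
                extra={c: row[c] for c in extra_cols},
            )
        )
    return samples


def read_haplotypes(path: str) -> HaplotypeTable:
    """Read the distinct-variant (haplotype) count TSV."""
    df = _read_tsv(path, HAPLOTYPE_COLUMNS)
    if df.empty:
        warnings.warn(f"haplotype table {path!r} is empty", stacklevel=2)
        df = pd.DataFrame(columns=list(HAPLOTYPE_COLUMNS))
    else:
        df["count"] = pd.to_numeric(df["count"]).astype(int)
    return HaplotypeTable(data=df)


def read_misincorporation(path: str) -> MisincorporationTable:
    """Read the misincorporation count TSV (mapDamage-like layout)."""
    df = _read_tsv(path, MISINCORPORATION_COLUMNS)
    if not df.empty:
        df["count"] = pd.to_numeric(df["count"]).astype(int)
        df["read_pos"] = pd.to_numeric(df["read_pos"]).astype(int)
    return MisincorporationTable(data=df)


def write_metadata(samples: list[SedimentSample], path: str) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "site": s.site,
            "depth_cm": s.depth_cm,
            "age_calBP": s.age_calBP,
            "toc": s.toc,
            "cov_chloroplast": s.coverage.get("chloroplast", 0.0),
            "cov_mitochondrion": s.coverage.get("mitochondrion", 0.0),
        }
        row.update(s.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_haplotypes(table: HaplotypeTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_misincorporation(table: MisincorporationTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_masked_bed(genome: MaskedGenome, path: str) -> None:
    """Write softmasked intervals as 0-based half-open BED records."""
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            start = None
            for i, ch in enumerate(seq):
                if ch.islower() and start is None:
                    start = i
                elif not ch.islower() and start is not None:
                    fh.write(f"{cid}\t{start}\t{i}\n")
                    start = None
            if start is not None:
                fh.write(f"{cid}\t{start}\t{len(seq)}\n")
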