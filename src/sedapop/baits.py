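"""Hybridization-capture bait design over softmasked target genomes.

Baits are fixed-length probes tiled across each contig at a step of
``bait_length / tiling_coverage``, so that on average every target base is
covered by ``tiling_coverage`` different baits (80 nt at 4x -> 20 nt step).
Baits overlapping too much softmasked (lowercase) sequence are discarded,
since simple and low-complexity repeats hybridize promiscuously.

An extra end-anchored bait is placed flush with the 3' end of a contig when
the regular grid does not reach it, so contig ends are never left uncovered;
the design report records how many baits are end-anchored so tiling counts
stay interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyDataError, ValidationError
from .io_core import MaskedGenome


@dataclass
class BaitDesignConfig:
    """Tiling and filtering parameters.

    Defaults: 80 nt baits at 4x tiling, keeping baits with at most 35%
    softmasked bases (boundary inclusive: exactly 35% is retained).
    """

    bait_length: int = 80
    tiling_coverage: int = 4
    max_masked_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.bait_length <= 0 or self.tiling_coverage <= 0:
            raise ValidationError("bait_length and tiling_coverage must be positive")
        if not (0.0 <= self.max_masked_fraction <= 1.0):
            raise ValidationError("max_masked_fraction must be in [0,1]")

    @property
    def step(self) -> int:
        """Tiling step; rounded when bait_length is not divisible by coverage."""
        if self.bait_length % self.tiling_coverage == 0:
            return self.bait_length // self.tiling_coverage
        step = round(self.bait_length / self.tiling_coverage)
        warnings.warn(
            f"bait_length {self.bait_length} not divisible by tiling_coverage "
            f"{self.tiling_coverage}; using rounded step {step}",
            stacklevel=2,
        )
        return step


@dataclass
class Bait:
    """One probe: 0-based half-open interval on a contig, case preserved."""

    contig_id: str
    start: int
    end: int
    sequence: str
    end_anchored: bool = False  # placed flush with the contig end, off-grid
    masked_fraction: float = field(init=False)
    gc: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad bait interval [{self.start},{self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValidationError("bait sequence length does not match interval")
        self.masked_fraction = (
            sum(c.islower() for c in self.sequence) / len(self.sequence)
        )
        self.gc = gc_fraction(self.sequence)

    @property
    def bait_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"


def gc_fraction(sequence: str) -> float | None:
    """GC fraction over non-N bases; None when the sequence is all N."""
    if not sequence:
        raise ValidationError("empty sequence")
    upper = sequence.upper()
    non_n = len(upper) - upper.count("N")
    if non_n == 0:
        return None
    return (upper.count("G") + upper.count("C")) / non_n


def tile_baits(genome: MaskedGenome, config: BaitDesignConfig | None = None) -> list[Bait]:
    """Tile fixed-length baits across every contig of a softmasked genome.

    Starts run 0, step, 2*step, ... while the bait still fits; if the last
    regular start leaves the contig tail uncovered, one end-anchored bait at
    ``length - bait_length`` is appended.  Contigs shorter than one bait are
    skipped with a warning.  Tiling never spans contigs.
    """
    config = config or BaitDesignConfig()
    if not genome.contigs:
        raise EmptyDataError("genome has no contigs")
    L, step = config.bait_length, config.step
    baits: list[Bait] = []
    for cid, seq in genome.contigs.items():
        n = len(seq)
        if n < L:
            warnings.warn(
                f"contig {cid!r} (length {n}) shorter than bait length {L}; skipped",
                stacklevel=2,
            )
            continue
        starts = list(range(0, n - L + 1, step))
        anchored = {}
        if starts[-1] != n - L:
            starts.append(n - L)  # end-anchored terminal bait
            anchored[n - L] = True
        for s in starts:
            baits.append(
                Bait(contig_id=cid, start=s, end=s + L, sequence=seq[s : s + L],
                     end_anchored=anchored.get(s, False))
            )
    return baits


def filter_baits(
    baits: list[Bait], config: BaitDesignConfig | None = None
) -> tuple[list[Bait], list[tuple[Bait, str]]]:
    """Split baits into (retained, rejected-with-reason) by masked fraction."""
    config = config or BaitDesignConfig()
    retained: list[Bait] = []
    rejected: list[tuple[Bait, str]] = []
    for b in baits:
        if b.masked_fraction <= config.max_masked_fraction:
            retained.append(b)
        else:
            rejected.append(
                (b, f"masked_fraction {b.masked_fraction:.4f} > "
                    f"{config.max_masked_fraction}")
            )
    return retained, rejected


def design_report(
    retained: list[Bait], rejected: list[tuple[Bait, str]]
) -> pd.DataFrame:
    """Per-bait TSV-ready report: id, interval, masked/GC fractions, retained flag."""
    rows = []
    for b in retained:
        rows.append(_report_row(b, True))
    for b, _reason in rejected:
        rows.append(_report_row(b, False))
    df = pd.DataFrame(
        rows,
        columns=[
            "bait_id", "contig_id", "start", "end",
            "masked_fraction", "gc_fraction", "retained", "end_anchored",
        ],
    )
    return df.sort_values(["contig_id", "start"], kind="stable").reset_index(drop=True)


def _report_row(b: Bait, retained: bool) -> dict:
    return {
        "bait_id": b.bait_id,
        "contig_id": b.contig_id,
        "start": b.start,
        "end": b.end,
        "masked_fraction": b.masked_fraction,
        "gc_fraction": b.gc if b.gc is not None else float("nan"),
        "retained": retained,
        "end_anchored": b.end_anchored,
    }


def write_bait_fasta(baits: list[Bait], path: str) -> None:
    with open(path, "w") as fh:
        for b in baits:
            fh.write(f">{b.bait_id}\n{b.sequence}\n")


def write_bait_bed(baits: list[Bait], path: str) -> None:
    with open(path, "w") as fh:
        for b in baits:
            fh.write(f"{b.contig_id}\t{b.start}\t{b.end}\t{b.bait_id}\n")
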