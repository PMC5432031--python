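"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open genomic throughout.  A transcript with
``strand='+'`` occupies ``[tss, tss + length)``; on the minus strand the TSS
is the *larger* coordinate and the transcript occupies
``(end3, tss] == [tss - length + 1, tss + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: canonical long-format columns of a time-course table
TC_COLUMNS = ["gene_id", "condition", "replicate", "timepoint_min", "value"]


@dataclass
class Alignment:
    """One genomic placement of a read (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    soft_clip_3prime: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"alignment start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ReadRecord:
    """A sequencing read, optionally demultiplexed and aligned.

    ``umi`` is the random-barcode portion of the in-read barcode used for
    PCR-duplicate collapsing; it may be empty only before demultiplexing.
    """

    read_id: str
    sequence: str
    umi: str = ""
    sample_barcode: str = ""
    alignments: list[Alignment] = field(default_factory=list)
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")

    @property
    def alignment(self) -> Alignment:
        """The unique alignment of a single-placement read."""
        if len(self.alignments) != 1:
            raise ValueError(
                f"read {self.read_id} has {len(self.alignments)} alignments, "
                "expected exactly 1"
            )
        return self.alignments[0]


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcript coordinates anchoring promoter-proximal / body regions
    and profile windows.

    ``tss`` and ``end3`` are 0-based genomic positions of the 5' and 3'
    anchors; ``length_nt == |end3 - tss|``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    end3: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.end3:
            raise ValueError(f"{self.gene_id}: + strand requires tss < end3")
        if self.strand == "-" and not self.tss > self.end3:
            raise ValueError(f"{self.gene_id}: - strand requires tss > end3")

    @property
    def length_nt(self) -> int:
        return abs(self.end3 - self.tss)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic half-open interval occupied by the transcript."""
        if self.strand == "+":
            return self.tss, self.end3
        return self.end3 + 1, self.tss + 1

    def genomic_position(self, rel: int) -> int:
        """Map a transcript-frame offset (0 = TSS, increasing 5'->3') to a
        genomic coordinate.  Negative offsets address upstream sequence."""
        return self.tss + rel if self.strand == "+" else self.tss - rel

    def relative_position(self, genomic: int) -> int:
        """Inverse of :meth:`genomic_position`."""
        return genomic - self.tss if self.strand == "+" else self.tss - genomic


@dataclass
class PileupTrack:
    """Strand-aware per-nucleotide read coverage over one region.

    If ``oriented`` is True the coverage vector runs 5'->3' along the
    transcript (index 0 = TSS); otherwise it runs in genomic order starting
    at genomic coordinate ``start``.
    """

    scope: str
    strand: str
    coverage: np.ndarray
    library_size: int = 1
    start: int = 0
    oriented: bool = False
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.ndim != 1:
            raise ValueError("coverage must be a 1-D vector")
        if np.any(self.coverage < 0):
            raise ValueError("coverage entries must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError("strand must be '+' or '-'")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def __len__(self) -> int:
        return self.coverage.size


class TimeCourseMatrix:
    """Per-transcript FPKM series indexed by condition, replicate and
    timepoint — the substrate of normalization and the GP test.

    Stored as a long-format DataFrame with columns ``gene_id, condition,
    replicate, timepoint_min, value``.  The timepoint grid must be identical
    across every (condition, replicate) pair.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        missing = [c for c in TC_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"time-course table missing columns: {missing}")
        self.data = data.loc[:, TC_COLUMNS].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.data.empty:
            raise ValueError("empty time-course table")
        grids = {
            key: tuple(sorted(g["timepoint_min"].unique()))
            for key, g in self.data.groupby(["condition", "replicate"])
        }
        if len(set(grids.values())) != 1:
            raise ValueError(
                f"timepoint grid differs across condition/replicate: {grids}"
            )
        if (self.data["value"] < 0).any():
            bad = self.data.loc[self.data["value"] < 0, "gene_id"].iloc[0]
            raise ValueError(f"negative FPKM for gene {bad}")

    @property
    def transcripts(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["timepoint_min"].unique())

    def wide(self) -> pd.DataFrame:
        """Genes x (condition, replicate, timepoint) pivot."""
        return self.data.pivot_table(
            index="gene_id",
            columns=["condition", "replicate", "timepoint_min"],
            values="value",
            aggfunc="first",
        )

    def copy_with(self, data: pd.DataFrame) -> "TimeCourseMatrix":
        return TimeCourseMatrix(data, validate=False)

    def __repr__(self) -> str:
        return (
            f"TimeCourseMatrix({len(self.transcripts)} transcripts, "
            f"conditions={self.conditions}, replicates={self.replicates}, "
            f"timepoints={list(self.timepoints)})"
        )
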