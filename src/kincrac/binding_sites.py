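"""Binding-interval (peak) calling and oligo(A) tail detection.

Peaks are maximal contiguous pileup intervals whose height reaches a
minimum read count (default 5) over a minimum width (default 20 nt).  An
empirical FDR is attached by a seeded within-gene permutation null that
redistributes the observed reads uniformly over the region and counts how
many qualifying peaks arise by chance.

Oligo(A) tails are non-genome-encoded adenosine runs at a read's 3' end —
a hallmark of NNS/exosome degradation intermediates.  A read is reported
when its strand-oriented 3' soft-clip is an A-run of at least ``min_tail``
bases and the reference immediately downstream of the alignment is *not*
an A-run of the same length (the non-encoded test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .crac_io import _revcomp
from .types import Alignment, GeneAnnotation, PileupTrack, ReadRecord


@dataclass
class Peak:
    """Significant binding interval (0-based half-open)."""

    scope: str
    strand: str
    start: int
    end: int
    max_height: float
    total_reads: int | None = None
    fdr: float = float("nan")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class OligoATail:
    """A read ending in a non-encoded oligo-A run."""

    read_id: str
    chrom: str
    genomic_end: int  # 0-based position of the 3'-most aligned base
    strand: str
    tail_seq: str
    encoded: bool = False

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)


def _scan_intervals(
    coverage: np.ndarray, min_reads: float, min_width: int
) -> list[tuple[int, int]]:
    """Maximal runs with coverage >= min_reads and width >= min_width."""
    above = coverage >= min_reads
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_width]


def call_peaks(
    pileup: PileupTrack,
    min_reads: float = 5,
    min_width: int = 20,
    fdr_threshold: float | None = None,
    seed: int = 0,
    n_permutations: int = 100,
    reads: list[ReadRecord] | None = None,
    count_mode: str = "height",
) -> list[Peak]:
    """Call maximal binding intervals from a pileup.

    With ``count_mode='height'`` (default) an interval qualifies when its
    coverage stays at or above ``min_reads``; ``count_mode='total'``
    instead requires at least ``min_reads`` distinct reads overlapping a
    coverage>=1 run, and needs the ``reads`` argument.

    FDR is estimated only when ``reads`` are supplied: each permutation
    replaces every read by a same-length interval placed uniformly within
    the region, and FDR = (mean qualifying-peak count under the null) /
    (observed count), clipped to [0, 1].  Without reads the FDR is NaN and
    ``fdr_threshold`` must be None.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if count_mode not in ("height", "total"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if count_mode == "total" and reads is None:
        raise ValueError("count_mode='total' requires the reads argument")

    read_spans: list[int] | None = None
    if reads is not None:
        read_spans = []
        for r in reads:
            aln = r.alignment
            if aln.strand == pileup.strand:
                read_spans.append(aln.end - aln.start)

    def qualify(cov: np.ndarray) -> list[tuple[int, int]]:
        if count_mode == "height":
            return _scan_intervals(cov, min_reads, min_width)
        runs = _scan_intervals(cov, 1, min_width)
        out = []
        for s, e in runs:
            n_over = sum(
                1
                for r in reads  # type: ignore[union-attr]
                if r.alignment.strand == pileup.strand
                and r.alignment.end - pileup.start > s
                and r.alignment.start - pileup.start < e
            )
            if n_over >= min_reads:
                out.append((s, e))
        return out

    observed = qualify(pileup.coverage)
    peaks = [
        Peak(
            scope=pileup.scope,
            strand=pileup.strand,
            start=pileup.start + s,
            end=pileup.start + e,
            max_height=float(pileup.coverage[s:e].max()),
        )
        for s, e in observed
    ]
    if reads is not None:
        for pk, (s, e) in zip(peaks, observed):
            pk.total_reads = sum(
                1
                for r in reads
                if r.alignment.strand == pileup.strand
                and r.alignment.end - pileup.start > s
                and r.alignment.start - pileup.start < e
            )
    if reads is not None and peaks:
        rng = np.random.default_rng(seed)
        region_len = len(pileup)
        null_counts = np.empty(n_permutations)
        for p in range(n_permutations):
            cov = np.zeros(region_len)
            for span in read_spans:  # type: ignore[union-attr]
                span = min(span, region_len)
                s = int(rng.integers(0, region_len - span + 1))
                cov[s : s + span] += 1
            null_counts[p] = len(_scan_intervals(cov, min_reads, min_width))
        fdr = float(np.clip(null_counts.mean() / len(peaks), 0.0, 1.0))
        for pk in peaks:
            pk.fdr = fdr
    if fdr_threshold is not None:
        if reads is None:
            raise ValueError("fdr_threshold requires the reads argument")
        peaks = [pk for pk in peaks if pk.fdr <= fdr_threshold]
    return peaks


def detect_oligoA(
    reads: Iterable[ReadRecord],
    genome: Mapping[str, str],
    min_tail: int = 3,
) -> list[OligoATail]:
    """Report reads whose 3' soft-clip is a non-encoded oligo-A run.

    ``genome`` maps contig name to sequence (a dict or any mapping, e.g. a
    pyfaidx.Fasta).  The soft-clip is taken in transcript orientation; the
    reference comparison window lies immediately 3' of the alignment on
    the transcribed strand.  Tails matched by an equally long genomic
    A-run are suppressed as encoded.
    """
    out = []
    for read in reads:
        aln = read.alignment
        clip = aln.soft_clip_3prime.upper()
        if len(clip) < min_tail or set(clip) != {"A"}:
            continue
        if aln.chrom not in genome:
            raise KeyError(f"reference contig {aln.chrom!r} unavailable")
        ref = genome[aln.chrom]
        tail_len = len(clip)
        if aln.strand == "+":
            lo, hi = aln.end, aln.end + tail_len
            if hi > len(ref):
                raise ValueError(
                    f"reference window [{lo},{hi}) beyond end of {aln.chrom}"
                )
            downstream = str(ref[lo:hi]).upper()
            genomic_end = aln.end - 1
        else:
            lo, hi = aln.start - tail_len, aln.start
            if lo < 0:
                raise ValueError(
                    f"reference window [{lo},{hi}) before start of {aln.chrom}"
                )
            downstream = _revcomp(str(ref[lo:hi])).upper()
            genomic_end = aln.start
        encoded = downstream == "A" * tail_len
        if encoded:
            continue
        out.append(
            OligoATail(
                read_id=read.read_id,
                chrom=aln.chrom,
                genomic_end=genomic_end,
                strand=aln.strand,
                tail_seq=clip,
                encoded=False,
            )
        )
    return out


def oligoA_track(
    tails: Iterable[OligoATail],
    region: GeneAnnotation | tuple[str, int, int, str],
) -> PileupTrack:
    """Per-nucleotide count of oligo-A tail 3' termini over a region."""
    if isinstance(region, GeneAnnotation):
        chrom, strand = region.chrom, region.strand
        start, end = region.span
        oriented, scope = True, region.gene_id
    else:
        chrom, start, end, strand = region
        oriented, scope = False, chrom
    cov = np.zeros(end - start)
    for tail in tails:
        if tail.chrom != chrom or tail.strand != strand:
            continue
        if start <= tail.genomic_end < end:
            cov[tail.genomic_end - start] += 1
    if oriented and strand == "-":
        cov = cov[::-1].copy()
    return PileupTrack(
        scope=scope, strand=strand, coverage=cov, start=start, oriented=oriented
    )
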