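"""Read-level procedures and format I/O for the kinetic CRAC pipeline.

Covers demultiplexing by in-read barcodes, PCR-duplicate collapsing on the
random-barcode (UMI), random placement of multimapping reads, strand-aware
pileups, FPKM computation and the all-timepoint detection filter.  Adapter
trimming and genomic alignment are upstream concerns: aligned reads are
consumed from SAM/BAM or BED, never produced here.

Barcode layouts are strings over ``{A, C, G, T, N}`` read 5'->3': ``N``
positions hold random (UMI) bases, fixed letters form the sample code.  For
example ``"NNNAGC"`` declares a 3-nt UMI followed by sample code ``AGC``.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np
import pandas as pd

from .types import TC_COLUMNS, Alignment, GeneAnnotation, PileupTrack, ReadRecord, TimeCourseMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
_DNA = set("ACGT")


class BarcodeConfigError(ValueError):
    """Raised for malformed or conflicting barcode tables."""


def _parse_layout(name: str, layout: str) -> tuple[list[int], list[int], str]:
    """Split a layout string into UMI positions, code positions and code."""
    layout = layout.upper()
    if not layout or any(c not in _DNA | {"N"} for c in layout):
        raise BarcodeConfigError(
            f"sample {name}: malformed barcode layout {layout!r} "
            "(expected characters A/C/G/T/N)"
        )
    umi_pos = [i for i, c in enumerate(layout) if c == "N"]
    code_pos = [i for i, c in enumerate(layout) if c != "N"]
    if not code_pos:
        raise BarcodeConfigError(f"sample {name}: layout {layout!r} has no sample code")
    code = "".join(layout[i] for i in code_pos)
    return umi_pos, code_pos, code


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
) -> dict[str, list[ReadRecord]]:
    """Assign reads to sample bins by their in-read 5' barcode.

    Parameters
    ----------
    reads
        Raw reads carrying the barcode at the 5' end of ``sequence``.
    barcode_table
        Sample name -> layout string (see module docstring).  All layouts
        must have equal length and unique sample codes.
    max_mismatch
        0 for exact matching (default) or 1 to tolerate a single Hamming
        mismatch within the sample-code positions.

    Returns
    -------
    dict mapping each sample name (plus :data:`UNASSIGNED`) to its reads,
    with ``umi`` / ``sample_barcode`` populated and barcode bases stripped
    from the sequence.  Unmatched reads are kept, never dropped silently.
    """
    if max_mismatch not in (0, 1):
        raise BarcodeConfigError("max_mismatch must be 0 or 1")
    parsed = {name: _parse_layout(name, lay) for name, lay in barcode_table.items()}
    lengths = {len(barcode_table[name]) for name in parsed}
    if len(lengths) != 1:
        raise BarcodeConfigError(f"barcode layouts have unequal lengths: {lengths}")
    (bc_len,) = lengths
    codes = Counter(code for _, _, code in parsed.values())
    dupes = [c for c, n in codes.items() if n > 1]
    if dupes:
        raise BarcodeConfigError(f"duplicate sample codes in barcode table: {dupes}")

    bins: dict[str, list[ReadRecord]] = {name: [] for name in parsed}
    bins[UNASSIGNED] = []
    for read in reads:
        prefix = read.sequence[:bc_len].upper()
        assigned = None
        if len(prefix) == bc_len:
            best = None
            for name, (umi_pos, code_pos, code) in parsed.items():
                dist = sum(prefix[i] != c for i, c in zip(code_pos, code))
                if dist <= max_mismatch and (best is None or dist < best[1]):
                    best = (name, dist)
                    if dist == 0:
                        break
            if best is not None:
                assigned = best[0]
        if assigned is None:
            bins[UNASSIGNED].append(read)
            continue
        umi_pos, _, code = parsed[assigned]
        bins[assigned].append(
            ReadRecord(
                read_id=read.read_id,
                sequence=read.sequence[bc_len:],
                umi="".join(prefix[i] for i in umi_pos),
                sample_barcode=code,
                alignments=list(read.alignments),
                quality=read.quality[bc_len:] if read.quality else "",
            )
        )
    return bins


def collapse_duplicates(
    reads: Iterable[ReadRecord], mode: str = "sequence"
) -> tuple[list[ReadRecord], dict[tuple, int]]:
    """Collapse PCR duplicates on the random barcode.

    ``mode='sequence'`` keys on ``(umi, sequence)`` (pre-alignment, the
    pipeline default); ``mode='position'`` keys on
    ``(umi, chrom, start, end, strand)`` and requires aligned reads.
    Returns the retained representatives (first seen per key) and the
    per-key multiplicities.
    """
    if mode not in ("sequence", "position"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    kept: dict[tuple, ReadRecord] = {}
    counts: Counter[tuple] = Counter()
    for read in reads:
        if not read.umi:
            raise ValueError(f"read {read.read_id} has no UMI; demultiplex first")
        if mode == "sequence":
            key = (read.umi, read.sequence)
        else:
            aln = read.alignment
            key = (read.umi, aln.chrom, aln.start, aln.end, aln.strand)
        counts[key] += 1
        kept.setdefault(key, read)
    return list(kept.values()), dict(counts)


def assign_multimappers(
    reads: Iterable[ReadRecord], seed: int
) -> list[ReadRecord]:
    """Randomly distribute multimapping reads over their candidate
    locations, one uniform draw per read.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        if not read.alignments:
            raise ValueError(f"read {read.read_id} has no alignments")
        if len(read.alignments) == 1:
            chosen = read.alignments[0]
        else:
            chosen = read.alignments[int(rng.integers(len(read.alignments)))]
        out.append(
            ReadRecord(
                read_id=read.read_id,
                sequence=read.sequence,
                umi=read.umi,
                sample_barcode=read.sample_barcode,
                alignments=[chosen],
                quality=read.quality,
            )
        )
    return out


def build_pileup(
    reads: Iterable[ReadRecord],
    region: GeneAnnotation | tuple[str, int, int, str],
    library_size: int | None = None,
) -> PileupTrack:
    """Per-nucleotide coverage of single-alignment reads over a region.

    Only reads on the region's strand contribute (strand-specific
    contract); alignments falling entirely outside are tallied in
    ``skipped_reads``.  With a :class:`GeneAnnotation` region the returned
    track is transcript-oriented (index 0 = TSS, running 5'->3'); with a
    ``(chrom, start, end, strand)`` window it is in genomic order.
    """
    if isinstance(region, GeneAnnotation):
        chrom, strand = region.chrom, region.strand
        g_start, g_end = region.span
        oriented, scope = True, region.gene_id
    else:
        chrom, g_start, g_end, strand = region
        oriented, scope = False, chrom
    if g_start >= g_end:
        raise ValueError("empty region")
    cov = np.zeros(g_end - g_start)
    n_reads, skipped = 0, 0
    for read in reads:
        aln = read.alignment
        n_reads += 1
        if aln.chrom != chrom or aln.strand != strand:
            skipped += 1
            continue
        lo, hi = max(aln.start, g_start), min(aln.end, g_end)
        if lo >= hi:
            skipped += 1
            continue
        cov[lo - g_start : hi - g_start] += 1
    if oriented and strand == "-":
        cov = cov[::-1].copy()
    return PileupTrack(
        scope=scope,
        strand=strand,
        coverage=cov,
        library_size=library_size if library_size is not None else max(n_reads, 1),
        start=g_start,
        oriented=oriented,
        skipped_reads=skipped,
    )


def compute_fpkm(
    counts: dict[str, int], lengths: dict[str, int], library_size: int
) -> dict[str, float]:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM = count / (length_kb * library_size_millions)``.  Genes present
    in ``lengths`` but absent from ``counts`` get 0.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = {}
    for gene, length in lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene}: non-positive length {length}")
        count = counts.get(gene, 0)
        out[gene] = count / ((length / 1e3) * (library_size / 1e6))
    return out


def filter_detected_all_timepoints(
    matrix: TimeCourseMatrix,
) -> tuple[TimeCourseMatrix, list[str]]:
    """Keep only transcripts detected (FPKM > 0, non-missing) at every
    condition, replicate and timepoint; return the removal list."""
    wide = matrix.wide()
    n_cols = (
        len(matrix.conditions) * len(matrix.replicates) * len(matrix.timepoints)
    )
    ok = (wide.notna() & (wide > 0)).sum(axis=1) == n_cols
    removed = sorted(wide.index[~ok])
    kept = matrix.data[~matrix.data["gene_id"].isin(removed)]
    if kept.empty:
        raise ValueError("no transcript detected at all timepoints")
    return matrix.copy_with(kept), removed


# ---------------------------------------------------------------------------
# format I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file as ReadRecords (no barcode interpretation)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield ReadRecord(read_id=rec.id, sequence=str(rec.seq), quality=qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_alignments_sam(path: str | Path) -> list[ReadRecord]:
    """Load aligned reads from SAM/BAM via pysam.

    Secondary alignments of the same query are merged into one ReadRecord
    with multiple candidate placements.  The 3' soft-clip (strand-oriented)
    is retained for oligo(A) detection.  The UMI is recovered from a
    trailing ``##<umi>`` tag on the query name when present.
    """
    import pysam

    by_name: dict[str, ReadRecord] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            cigar = seg.cigartuples or []
            # soft clip at the read's 3' end in transcript orientation
            if strand == "+":
                clip_len = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
                clip = seg.query_sequence[-clip_len:] if clip_len else ""
            else:
                clip_len = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
                clip = _revcomp(seg.query_sequence[:clip_len]) if clip_len else ""
            aln = Alignment(
                chrom=seg.reference_name,
                start=seg.reference_start,
                end=seg.reference_end,
                strand=strand,
                soft_clip_3prime=clip,
            )
            name = seg.query_name
            umi = ""
            if "##" in name:
                name, umi = name.rsplit("##", 1)
            if name in by_name:
                by_name[name].alignments.append(aln)
            else:
                seq = seg.query_sequence or "N"
                by_name[name] = ReadRecord(
                    read_id=name, sequence=seq, umi=umi, alignments=[aln]
                )
    return list(by_name.values())


def write_sam(
    reads: Iterable[ReadRecord],
    path: str | Path,
    contig_lengths: dict[str, int],
    tag_umi: bool = True,
) -> int:
    """Write single- or multi-alignment reads as headered SAM text.

    Additional placements beyond the first are emitted as secondary
    alignments (flag 0x100) under the same query name.  The UMI is carried
    in a trailing ``##<umi>`` tag on the name when ``tag_umi`` is set, so
    :func:`read_alignments_sam` can recover it.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for read in reads:
            if not read.alignments:
                raise ValueError(f"read {read.read_id} has no alignments")
            name = read.read_id
            if tag_umi and read.umi:
                name = f"{name}##{read.umi}"
            for i, aln in enumerate(read.alignments):
                alen = aln.end - aln.start
                clip = aln.soft_clip_3prime
                flag = (16 if aln.strand == "-" else 0) | (0x100 if i else 0)
                body = read.sequence[:alen].ljust(alen, "N")
                if aln.strand == "+":
                    seq = body + clip
                    cigar = f"{alen}M{len(clip)}S" if clip else f"{alen}M"
                else:
                    seq = _revcomp(clip) + _revcomp(body)
                    cigar = f"{len(clip)}S{alen}M" if clip else f"{alen}M"
                fh.write(
                    f"{name}\t{flag}\t{aln.chrom}\t{aln.start + 1}\t255\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
            n += 1
    return n


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


def read_annotation_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED6 -> GeneAnnotation (0-based half-open, strand-aware anchors)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    out = []
    for row in df.itertuples():
        if row.strand == "+":
            tss, end3 = row.start, row.end
        else:
            tss, end3 = row.end - 1, row.start - 1
        out.append(
            GeneAnnotation(
                gene_id=row.name, chrom=row.chrom, strand=row.strand, tss=tss, end3=end3
            )
        )
    return out


def read_annotation_gtf(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """GTF/GFF3 (1-based closed) -> GeneAnnotation via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature):
        start0, end_excl = feat.start - 1, feat.end  # convert to half-open
        if feat.strand == "+":
            tss, end3 = start0, end_excl
        else:
            tss, end3 = end_excl - 1, start0 - 1
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        out.append(
            GeneAnnotation(
                gene_id=gid, chrom=feat.seqid, strand=feat.strand, tss=tss, end3=end3
            )
        )
    return out


def read_timecourse_tsv(path: str | Path) -> TimeCourseMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeCourseMatrix(df)


def write_timecourse_tsv(matrix: TimeCourseMatrix, path: str | Path) -> None:
    matrix.data.loc[:, TC_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bedgraph(track: PileupTrack, path: str | Path, chrom: str | None = None) -> None:
    """Write a genomic-order pileup as bedGraph (zero runs omitted)."""
    if track.oriented:
        raise ValueError("bedGraph output requires a genomic-order track")
    chrom = chrom or track.scope
    cov = track.coverage
    with open(path, "w") as fh:
        i = 0
        while i < cov.size:
            j = i
            while j < cov.size and cov[j] == cov[i]:
                j += 1
            if cov[i] != 0:
                fh.write(
                    f"{chrom}\t{track.start + i}\t{track.start + j}\t{cov[i]:g}\n"
                )
            i = j


def read_bedgraph(
    path: str | Path, chrom: str, start: int, end: int, strand: str = "+",
    library_size: int = 1,
) -> PileupTrack:
    """Load bedGraph coverage for one genomic window."""
    cov = np.zeros(end - start)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split()[:4]
            if c != chrom:
                continue
            lo, hi = max(int(s), start), min(int(e), end)
            if lo < hi:
                cov[lo - start : hi - start] = float(v)
    return PileupTrack(
        scope=chrom, strand=strand, coverage=cov, start=start,
        library_size=library_size,
    )
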