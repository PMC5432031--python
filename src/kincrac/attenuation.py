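"""Escape-index screening for transcriptionally attenuated genes.

The escape index (EI) quantifies how strongly polymerase accumulates over
the promoter-proximal region (PPR, -100 to +250 nt around the 5' anchor)
relative to the gene body (+251 nt to the 3' end), and how that ratio
changes between a pre-shift (t = 0) sample and a later timepoint:

    EI(t) = [ppr_density(t) / body_density(t)] / [ppr_density(0) / body_density(0)]

An EI above 1 means relatively stronger 5'-proximal pileup at time t,
interpreted as increased termination/attenuation.  The accompanying
transcription change is whole-gene density(t) / density(0).  Candidate
attenuated genes must show transcription change >= 1.5, coverage >= 10
FPKM and EI >= 2 (all boundary-inclusive), optionally also a called
binding peak overlapping the PPR and a reproducible EI in a replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .binding_sites import Peak
from .types import GeneAnnotation, PileupTrack

logger = logging.getLogger(__name__)

PPR_UPSTREAM = 100  # nt upstream of the 5' anchor
PPR_DOWNSTREAM = 250  # last PPR offset, inclusive
BODY_START = 251  # first gene-body offset

REGIONS = ("ppr", "body", "whole")


@dataclass
class EscapeIndexResult:
    """Escape index of one gene between two samples."""

    gene_id: str
    ppr_density_t0: float
    ppr_density_t: float
    body_density_t0: float
    body_density_t: float
    whole_density_t0: float
    whole_density_t: float
    ei: float
    transcription_change: float
    fpkm: float | None = None
    chrom: str = ""
    strand: str = "+"
    ppr_interval: tuple[int, int] = (0, 0)  # genomic half-open
    unresolved: str | None = None
    selected: bool = field(default=False)


def _region_bounds(annotation: GeneAnnotation, region: str) -> tuple[int, int]:
    """Transcript-frame half-open offset interval for a named region."""
    length = annotation.length_nt
    if region == "ppr":
        return -PPR_UPSTREAM, PPR_DOWNSTREAM + 1
    if region == "body":
        if length <= BODY_START:
            raise ValueError(
                f"{annotation.gene_id}: length {length} nt leaves no gene body"
            )
        return BODY_START, length
    if region == "whole":
        return 0, length
    raise ValueError(f"unknown region {region!r}")


def ppr_genomic_interval(annotation: GeneAnnotation) -> tuple[int, int]:
    """Genomic half-open interval of the promoter-proximal region."""
    lo_rel, hi_rel = _region_bounds(annotation, "ppr")
    a = annotation.genomic_position(lo_rel)
    b = annotation.genomic_position(hi_rel - 1)
    lo, hi = (a, b + 1) if a <= b else (b, a + 1)
    return max(lo, 0), hi


def region_density(
    pileup: PileupTrack, annotation: GeneAnnotation, region: str
) -> float:
    """Library-normalized read density (reads/nt per million mapped reads)
    over the PPR, gene body or whole gene.

    The pileup must be a genomic-order track containing the gene (with 100
    nt upstream margin for the PPR); offsets outside the track are
    truncated with a warning and the density uses the positions actually
    covered.
    """
    if pileup.oriented:
        raise ValueError("region_density requires a genomic-order track")
    lo_rel, hi_rel = _region_bounds(annotation, region)
    offsets = np.arange(lo_rel, hi_rel)
    genomic = (
        annotation.tss + offsets if annotation.strand == "+" else annotation.tss - offsets
    )
    idx = genomic - pileup.start
    ok = (idx >= 0) & (idx < len(pileup))
    if not ok.all():
        logger.warning(
            "%s %s region extends past track bounds; truncated (%d of %d nt kept)",
            annotation.gene_id, region, int(ok.sum()), offsets.size,
        )
    if not ok.any():
        raise ValueError(f"{annotation.gene_id}: {region} region outside track")
    total = float(pileup.coverage[idx[ok]].sum())
    density = total / int(ok.sum())
    return density * 1e6 / pileup.library_size


def escape_index(
    pileup_t0: PileupTrack,
    pileup_t: PileupTrack,
    annotation: GeneAnnotation,
    fpkm: float | None = None,
) -> EscapeIndexResult:
    """Escape index and transcription change between t = 0 and a later
    sample.  A zero body or whole-gene density at t = 0 makes the gene
    unresolved (flagged, not silently dropped)."""
    dens = {
        (name, reg): region_density(track, annotation, reg)
        for name, track in (("t0", pileup_t0), ("t", pileup_t))
        for reg in REGIONS
    }
    unresolved = None
    ei = tc = float("nan")
    if dens[("t0", "body")] <= 0 or dens[("t", "body")] <= 0:
        unresolved = "zero body density"
    elif dens[("t0", "ppr")] <= 0:
        unresolved = "zero baseline PPR density"
    else:
        ratio0 = dens[("t0", "ppr")] / dens[("t0", "body")]
        ratio_t = dens[("t", "ppr")] / dens[("t", "body")]
        ei = ratio_t / ratio0
    if dens[("t0", "whole")] > 0:
        tc = dens[("t", "whole")] / dens[("t0", "whole")]
    elif unresolved is None:
        unresolved = "zero baseline whole-gene density"
    return EscapeIndexResult(
        gene_id=annotation.gene_id,
        ppr_density_t0=dens[("t0", "ppr")],
        ppr_density_t=dens[("t", "ppr")],
        body_density_t0=dens[("t0", "body")],
        body_density_t=dens[("t", "body")],
        whole_density_t0=dens[("t0", "whole")],
        whole_density_t=dens[("t", "whole")],
        ei=ei,
        transcription_change=tc,
        fpkm=fpkm,
        chrom=annotation.chrom,
        strand=annotation.strand,
        ppr_interval=ppr_genomic_interval(annotation),
        unresolved=unresolved,
    )


def select_attenuated(
    results: list[EscapeIndexResult],
    min_fpkm: float | None = 10.0,
    min_change: float = 1.5,
    min_ei: float = 2.0,
    peaks: list[Peak] | None = None,
    replicate_results: list[EscapeIndexResult] | None = None,
) -> list[EscapeIndexResult]:
    """Apply the attenuated-gene selection thresholds (boundary values at
    the threshold pass).

    When ``peaks`` are supplied a gene must additionally have at least one
    peak overlapping its PPR; when ``replicate_results`` are supplied the
    replicate's EI must also reach ``min_ei``.  Genes without an FPKM
    value are excluded whenever an FPKM threshold is active.  Returns the
    selected subset with ``selected=True`` set on those results.
    """
    rep_ei = (
        {r.gene_id: r.ei for r in replicate_results}
        if replicate_results is not None
        else None
    )
    selected = []
    for res in results:
        if res.unresolved is not None or not np.isfinite(res.ei):
            continue
        if res.ei < min_ei or res.transcription_change < min_change:
            continue
        if min_fpkm is not None and (res.fpkm is None or res.fpkm < min_fpkm):
            continue
        if peaks is not None:
            lo, hi = res.ppr_interval
            hit = any(
                pk.strand == res.strand and pk.start < hi and pk.end > lo
                for pk in peaks
                if pk.scope in (res.chrom, res.gene_id)
            )
            if not hit:
                continue
        if rep_ei is not None:
            other = rep_ei.get(res.gene_id, float("nan"))
            if not (np.isfinite(other) and other >= min_ei):
                continue
        res.selected = True
        selected.append(res)
    return selected
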