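"""Synthetic data with the statistical structure the pipeline assumes.

Two generators make every stage testable without any external download:

* :func:`simulate_timecourse` draws per-transcript latent log2 binding
  dynamics from a squared-exponential GP on the experimental timepoint
  grid (default {0, 1, 2, 4, 8, 14, 20} minutes, two replicates per
  condition), adds iid Gaussian observation noise in log2 space and
  exponentiates against a log-normal baseline abundance so the raw output
  mimics FPKM series.  Under H0 both conditions share one latent; under
  H1 each condition gets an independent latent and the treated condition
  is additionally offset by the effect size at t > 0 (a constant offset
  would cancel under baseline anchoring).

* :func:`simulate_gene_reads` builds toy gene read sets with 5'-proximal
  binding peaks, PCR duplicates sharing (UMI, sequence), multimapping
  decoy placements and planted non-encoded oligo-A tails, together with a
  synthetic reference sequence and ground-truth labels for every
  downstream detector.

Everything is reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpdiff import GPHyperparams, se_covariance
from .types import Alignment, GeneAnnotation, ReadRecord, TimeCourseMatrix

DEFAULT_TIMEPOINTS = (0.0, 1.0, 2.0, 4.0, 8.0, 14.0, 20.0)
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    """Design of a synthetic binding time course."""

    n_transcripts: int
    seed: int
    hypothesis: str = "H0"
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    alpha_sq: float = 1.0  # latent signal variance, (log2 a.u.)^2
    control_alpha_sq: float = 0.01  # mock-shift latent variance (near-flat)
    lengthscale_min: float = 1.0
    noise_sd: float = 0.1  # observation noise in log2 a.u.
    effect_size: float = 0.0  # latent separation at t > 0, log2 a.u.
    baseline_log10_mean: float = 1.5  # median baseline ~ 30 FPKM
    baseline_log10_sd: float = 0.5
    conditions: tuple[str, str] = ("control", "treated")

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1"):
            raise ValueError("hypothesis must be 'H0' or 'H1'")
        if self.n_transcripts < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 transcript and replicate")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        tp = np.asarray(self.timepoints, float)
        if tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must ascend from 0")


def simulate_timecourse(spec: SimulationSpec) -> tuple[TimeCourseMatrix, pd.DataFrame]:
    """Draw a synthetic FPKM time-course matrix plus truth labels.

    Returns the matrix and a truth table (gene_id, hypothesis,
    effect_size, baseline) sufficient to score any downstream detector.
    """
    rng = np.random.default_rng(spec.seed)
    tp = np.asarray(spec.timepoints, float)
    n_t = tp.size
    def _chol(alpha_sq: float) -> np.ndarray | None:
        if alpha_sq <= 0:
            return None
        hyper = GPHyperparams(
            alpha_sq=alpha_sq,
            lengthscale_min=spec.lengthscale_min,
            noise_sq=1e-6,
        )
        kern = se_covariance(tp[:, None], tp[None, :], hyper) + 1e-10 * np.eye(n_t)
        return np.linalg.cholesky(kern)

    chol_treated = _chol(spec.alpha_sq)
    chol_control = _chol(spec.control_alpha_sq)
    step = (tp > 0).astype(float)

    def _draw(chol: np.ndarray | None) -> np.ndarray:
        return np.zeros(n_t) if chol is None else chol @ rng.standard_normal(n_t)

    rows = []
    truth = []
    for i in range(spec.n_transcripts):
        gene = f"GENE{i:05d}"
        baseline = 10.0 ** rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd)
        effect = 0.0
        control_name, treated_name = spec.conditions
        if spec.hypothesis == "H0":
            # both arms respond identically: one shared latent drawn from
            # the main kernel
            shared = _draw(chol_treated)
            latents = {control_name: shared, treated_name: shared}
        else:
            # random per-transcript sign: responses go either way, so the
            # equal-column-sum scaling step is not degenerate
            effect = spec.effect_size * (1.0 if rng.random() < 0.5 else -1.0)
            latents = {
                control_name: _draw(chol_control),
                treated_name: _draw(chol_treated) + effect * step,
            }
        for cond in spec.conditions:
            f = latents[cond] - latents[cond][0]  # anchor latent at its t=0
            for rep in range(1, spec.n_replicates + 1):
                eps = rng.normal(0.0, spec.noise_sd, n_t)
                fpkm = baseline * np.exp2(f + eps)
                for t, v in zip(tp, fpkm):
                    rows.append((gene, cond, rep, float(t), float(v)))
        truth.append(
            {
                "gene_id": gene,
                "hypothesis": spec.hypothesis,
                "effect_size": effect,
                "baseline": baseline,
            }
        )
    matrix = TimeCourseMatrix(
        pd.DataFrame(
            rows, columns=["gene_id", "condition", "replicate", "timepoint_min", "value"]
        )
    )
    return matrix, pd.DataFrame(truth)


@dataclass
class ReadSimTruth:
    """Ground truth accompanying a simulated read set."""

    peaks: list[tuple[int, int]]  # genomic half-open intervals
    tail_read_ids: list[str] = field(default_factory=list)  # non-encoded
    encoded_tail_read_ids: list[str] = field(default_factory=list)
    duplicate_keys: dict[tuple, int] = field(default_factory=dict)
    multimapper_ids: list[str] = field(default_factory=list)
    genome: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_gene_reads(
    annotation: GeneAnnotation,
    peak_spec: list[tuple[int, int, float]],
    oligoa_fraction: float = 0.0,
    duplicate_rate: float = 0.0,
    multimap_rate: float = 0.0,
    seed: int = 0,
    encoded_fraction: float = 0.0,
    read_length: tuple[int, int] = (20, 40),
    umi_length: int = 6,
    contig_length: int | None = None,
) -> tuple[list[ReadRecord], ReadSimTruth]:
    """Simulate a toy gene read set with known structure.

    ``peak_spec`` lists (genomic_start, width, rate): each peak receives a
    Poisson(rate) number of reads placed inside its interval.  A fraction
    of reads carries a planted non-encoded oligo-A soft-clip; a further
    ``encoded_fraction`` carries tails that *are* genome-encoded (A-run
    decoys planted in the reference) and must be suppressed by a correct
    detector.  Duplicates copy (UMI, sequence, placement); multimappers
    gain extra decoy alignments.  The synthetic reference guarantees that
    genuine tails are followed by a non-A base.
    """
    for rate_name, value in (
        ("oligoa_fraction", oligoa_fraction),
        ("duplicate_rate", duplicate_rate),
        ("multimap_rate", multimap_rate),
        ("encoded_fraction", encoded_fraction),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{rate_name} must be in [0, 1]")
    span_lo, span_hi = annotation.span
    for p_start, p_width, _ in peak_spec:
        if p_start < span_lo or p_start + p_width > span_hi:
            raise ValueError(
                f"peak [{p_start}, {p_start + p_width}) outside gene span "
                f"[{span_lo}, {span_hi})"
            )
    rng = np.random.default_rng(seed)
    contig_length = contig_length or span_hi + 200
    genome = list(_random_seq(rng, contig_length))

    reads: list[ReadRecord] = []
    truth = ReadSimTruth(
        peaks=[(s, s + w) for s, w, _ in peak_spec],
    )
    serial = 0
    for p_start, p_width, rate in peak_spec:
        n = rng.poisson(rate)
        for _ in range(n):
            length = int(rng.integers(read_length[0], read_length[1] + 1))
            length = min(length, p_width)
            start = int(rng.integers(p_start, p_start + p_width - length + 1))
            serial += 1
            read_id = f"read{serial:06d}"
            aln = Alignment(
                chrom=annotation.chrom,
                start=start,
                end=start + length,
                strand=annotation.strand,
            )
            seq = "".join(genome[start : start + length])
            if annotation.strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            reads.append(
                ReadRecord(
                    read_id=read_id,
                    sequence=seq,
                    umi=_random_seq(rng, umi_length),
                    alignments=[aln],
                )
            )

    # plant oligo-A tails: non-encoded (guarded by a non-A base) and
    # encoded decoys (genomic A-run of the full tail length)
    n_reads = len(reads)
    if n_reads and (oligoa_fraction > 0 or encoded_fraction > 0):
        n_tail = int(round(oligoa_fraction * n_reads))
        n_enc = int(round(encoded_fraction * n_reads))
        chosen = rng.choice(n_reads, size=min(n_tail + n_enc, n_reads), replace=False)
        tailed: list[ReadRecord] = []
        for j, idx in enumerate(chosen):
            read = reads[int(idx)]
            aln = read.alignment
            tail_len = int(rng.integers(3, 9))
            aln.soft_clip_3prime = "A" * tail_len
            tailed.append(read)
            if aln.strand == "+":
                window = range(aln.end, min(aln.end + tail_len, contig_length))
                guard_pos = aln.end
            else:
                window = range(max(aln.start - tail_len, 0), aln.start)
                guard_pos = aln.start - 1
            if j < n_tail:  # intended genuine: guard first downstream base
                if 0 <= guard_pos < contig_length:
                    base = genome[guard_pos]
                    if (aln.strand == "+" and base == "A") or (
                        aln.strand == "-" and base == "T"
                    ):
                        genome[guard_pos] = "C"
            else:  # encoded decoy: plant a genomic A-run (strand-aware)
                for pos in window:
                    genome[pos] = "A" if aln.strand == "+" else "T"
        # overlapping windows can override an intent, so truth labels are
        # derived from the final reference state, not the intent
        for read in tailed:
            aln = read.alignment
            tail_len = len(aln.soft_clip_3prime)
            if aln.strand == "+":
                down = "".join(genome[aln.end : aln.end + tail_len])
                encoded = down == "A" * len(down) and len(down) == tail_len
            else:
                win = "".join(genome[max(aln.start - tail_len, 0) : aln.start])
                encoded = win == "T" * len(win) and len(win) == tail_len
            if encoded:
                truth.encoded_tail_read_ids.append(read.read_id)
            else:
                truth.tail_read_ids.append(read.read_id)

    # PCR duplicates: copies sharing (umi, sequence, placement)
    if reads and duplicate_rate > 0:
        n_dup = int(round(duplicate_rate * len(reads)))
        for idx in rng.choice(len(reads), size=n_dup, replace=True):
            src = reads[int(idx)]
            serial += 1
            reads.append(
                ReadRecord(
                    read_id=f"read{serial:06d}",
                    sequence=src.sequence,
                    umi=src.umi,
                    alignments=[
                        Alignment(
                            chrom=a.chrom, start=a.start, end=a.end,
                            strand=a.strand, soft_clip_3prime=a.soft_clip_3prime,
                        )
                        for a in src.alignments
                    ],
                )
            )
            truth.duplicate_keys[(src.umi, src.sequence)] = (
                truth.duplicate_keys.get((src.umi, src.sequence), 1) + 1
            )

    # multimappers: extra decoy placements elsewhere on the contig
    if reads and multimap_rate > 0:
        n_mm = int(round(multimap_rate * len(reads)))
        for idx in rng.choice(len(reads), size=min(n_mm, len(reads)), replace=False):
            read = reads[int(idx)]
            aln = read.alignments[0]
            length = aln.end - aln.start
            for _ in range(int(rng.integers(1, 4))):
                start = int(rng.integers(0, contig_length - length))
                read.alignments.append(
                    Alignment(
                        chrom=aln.chrom, start=start, end=start + length,
                        strand=aln.strand,
                    )
                )
            truth.multimapper_ids.append(read.read_id)

    truth.genome = {annotation.chrom: "".join(genome)}
    return reads, truth
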