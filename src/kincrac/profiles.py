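"""Temporal-profile clustering and positional meta-profiles.

Two families of summaries live here.  Along *time*: filtering of
baseline-normalized binding profiles by fold-change and replicate
reproducibility, followed by K-means clustering of the replicate-averaged
log2 profiles.  Along *position*: TSS-aligned coverage matrices, summed
TSS-centered binding-site distributions with a two-sample KS comparison,
and length-normalized meta-profiles where each transcript is divided into
a fixed number of bins and contributes its read-mass fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedTimeCourse
from .types import GeneAnnotation, PileupTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Replicate-averaged log2 profiles of transcripts passing the
    fold-change and replicate-correlation filters."""

    timepoints: np.ndarray
    profiles: pd.DataFrame  # genes x timepoints, replicate-averaged log2
    max_fold: pd.Series  # per-gene max over timepoints of max(r, 1/r)
    mean_corr: pd.Series  # per-gene mean pairwise replicate Pearson r

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene_id -> cluster id
    centroids: np.ndarray  # k x n_timepoints
    inertia: float
    converged: bool


@dataclass
class MetaProfile:
    """Length-normalized binding profile summed over transcripts."""

    n_bins: int
    fractions: pd.DataFrame  # transcripts x bins, each row sums to 1
    summed: np.ndarray  # length n_bins
    excluded: list[str]  # zero-coverage transcripts


def _fold_and_corr(
    ntc: NormalizedTimeCourse, condition: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-gene replicate-averaged log2 profile, max fold-change and mean
    pairwise replicate correlation for one condition."""
    sub = ntc.data[ntc.data["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present")
    wide = sub.pivot_table(
        index="gene_id", columns=["replicate", "timepoint_min"],
        values="value", aggfunc="first",
    )
    reps = sorted({r for r, _ in wide.columns})
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates for the correlation filter")
    per_rep = {r: wide[r] for r in reps}  # genes x timepoints each
    if ntc.scale == "log2":
        linear = {r: np.exp2(df) for r, df in per_rep.items()}
        log2p = per_rep
    else:
        linear = per_rep
        log2p = {r: np.log2(df) for r, df in per_rep.items()}
    avg_linear = sum(linear.values()) / len(reps)
    with np.errstate(divide="ignore"):
        fold = np.maximum(avg_linear, 1.0 / avg_linear).max(axis=1)
    corrs = []
    for ra, rb in combinations(reps, 2):
        a, b = log2p[ra], log2p[rb]
        am, bm = a.sub(a.mean(axis=1), axis=0), b.sub(b.mean(axis=1), axis=0)
        denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corrs.append((am * bm).sum(axis=1) / denom)
    mean_corr = pd.concat(corrs, axis=1).mean(axis=1)
    avg_log2 = sum(log2p.values()) / len(reps)
    return avg_log2, fold, mean_corr


def filter_profiles(
    ntc: NormalizedTimeCourse,
    min_fold: float = 1.5,
    min_corr: float = 0.7,
    condition: str = "treated",
) -> ProfileSet:
    """Retain transcripts with a maximum fold-change of at least
    ``min_fold`` and a mean pairwise replicate Pearson correlation of at
    least ``min_corr`` (both boundary-inclusive).

    Fold-change is evaluated on replicate-averaged linear values as the
    max over timepoints of max(ratio, 1/ratio); correlation on the
    per-replicate log2 profiles.  Constant profiles have undefined
    correlation and are excluded.
    """
    avg_log2, fold, mean_corr = _fold_and_corr(ntc, condition)
    keep = (fold >= min_fold) & (mean_corr >= min_corr) & mean_corr.notna()
    kept = sorted(avg_log2.index[keep])
    return ProfileSet(
        timepoints=np.asarray(avg_log2.columns, dtype=float),
        profiles=avg_log2.loc[kept],
        max_fold=fold,
        mean_corr=mean_corr,
    )


def kmeans_cluster(profiles: ProfileSet, k: int, seed: int) -> ClusterResult:
    """K-means (k-means++ seeding, Lloyd iterations, Euclidean distance on
    log2 profiles) with a fixed seed for reproducibility."""
    from sklearn.cluster import KMeans

    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    x = profiles.profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=profiles.profiles.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        converged=km.n_iter_ < km.max_iter,
    )


def tss_aligned_matrix(
    pileups: dict[str, PileupTrack],
    annotations: list[GeneAnnotation],
    window: int,
) -> pd.DataFrame:
    """Genes x positions coverage matrix aligned at the TSS.

    Columns run from -window (upstream on the coding strand) to +window;
    rows are sorted by transcript length.  Cells outside the supplied
    track are missing (NaN), distinct from zero coverage.  Tracks must be
    in genomic order (``oriented=False``).
    """
    positions = np.arange(-window, window + 1)
    rows = {}
    for ann in sorted(annotations, key=lambda a: a.length_nt):
        track = pileups.get(ann.gene_id)
        row = np.full(positions.size, np.nan)
        if track is None:
            logger.warning("no pileup for %s; row left missing", ann.gene_id)
        else:
            if track.oriented:
                raise ValueError(f"{ann.gene_id}: genomic-order track required")
            genomic = (
                ann.tss + positions if ann.strand == "+" else ann.tss - positions
            )
            idx = genomic - track.start
            ok = (idx >= 0) & (idx < len(track))
            row[ok] = track.coverage[idx[ok]]
        rows[ann.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=positions)


def tss_site_distribution(
    sites: dict[str, list[int]],
    annotations: list[GeneAnnotation],
    window: int,
) -> np.ndarray:
    """Summed per-gene binding-site frequency around the TSS.

    ``sites`` maps gene_id to genomic site positions.  Within each gene,
    sites falling inside the window are converted to TSS-relative
    (strand-aware) positions and normalized to frequencies; the per-gene
    frequency vectors are summed across genes.  Genes without sites in the
    window contribute zeros.
    """
    ann_by_id = {a.gene_id: a for a in annotations}
    total = np.zeros(2 * window + 1)
    for gene, positions in sites.items():
        ann = ann_by_id.get(gene)
        if ann is None:
            raise KeyError(f"no annotation for gene {gene}")
        rel = np.array([ann.relative_position(p) for p in positions], dtype=int)
        rel = rel[(rel >= -window) & (rel <= window)]
        if rel.size == 0:
            continue
        freq = np.zeros(2 * window + 1)
        np.add.at(freq, rel + window, 1.0)
        total += freq / rel.size
    return total


def compare_site_distributions(
    dist_a: np.ndarray, dist_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of relative-position
    samples: D = max |ECDF_a - ECDF_b| with the asymptotic p-value."""
    a, b = np.asarray(dist_a, float), np.asarray(dist_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _bin_fractions(coverage: np.ndarray, n_bins: int) -> np.ndarray:
    """Mass-conserving apportionment of per-nucleotide coverage into
    n_bins equal-width bins, with fractional-overlap weighting when the
    length does not divide evenly."""
    length = coverage.size
    # cumulative mass, treating each nucleotide's mass as uniform on its
    # unit interval; bin mass = F(edge_{i+1}) - F(edge_i)
    cum = np.concatenate([[0.0], np.cumsum(coverage)])
    edges = np.linspace(0.0, length, n_bins + 1)
    at_edges = np.interp(edges, np.arange(length + 1), cum)
    mass = np.diff(at_edges)
    return mass / mass.sum()


def metaprofile_bins(
    pileups: dict[str, PileupTrack],
    n_bins: int = 1000,
) -> MetaProfile:
    """Length-normalized meta-profile over transcripts.

    Each transcript-oriented pileup is divided into ``n_bins`` equal-width
    bins along the transcript; coverage mass is apportioned with
    fractional-overlap weighting and converted to fractions summing to 1.
    Fraction vectors are then summed across transcripts.  Zero-coverage
    transcripts are excluded and reported.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows, excluded = {}, []
    for gene, track in sorted(pileups.items()):
        if len(track) < 1:
            raise ValueError(f"{gene}: empty transcript")
        if track.coverage.sum() <= 0:
            excluded.append(gene)
            continue
        rows[gene] = _bin_fractions(track.coverage, n_bins)
    if not rows:
        fractions = pd.DataFrame(columns=range(n_bins))
    else:
        fractions = pd.DataFrame.from_dict(rows, orient="index")
    summed = (
        fractions.to_numpy(dtype=float).sum(axis=0)
        if len(fractions)
        else np.zeros(n_bins)
    )
    return MetaProfile(
        n_bins=n_bins, fractions=fractions, summed=summed, excluded=excluded
    )
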