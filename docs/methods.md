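# Methods

This note documents the models and procedures implemented in `kincrac`,
the assumptions behind them, the tunable parameters and their defaults,
and the choices made where the design was genuinely open.

## Gaussian-process test for differential binding dynamics

### Model

For one transcript, let y_j,r(t) be the normalized binding signal in
condition j ∈ {control, treated}, replicate r, at time t (minutes). The
latent binding response f_j(t) is assumed smooth in time and is given a
zero-mean GP prior with squared-exponential covariance

    cov(f(s), f(t)) = a² · exp(−(s − t)² / (2λ²)),

with a² the signal variance ((a.u.)², log2 scale by default), λ the
lengthscale in minutes. Observations add iid Gaussian noise with variance
σ². Replicates at the same timepoint share the latent value (their prior
covariance is exactly a²) but carry independent noise.

The evidence of a set of observations sharing one latent is the zero-mean
multivariate normal density with covariance C = K + σ²I, where K is the
kernel matrix over the observation times. It is evaluated by Cholesky
factorization; if C is numerically indefinite, a jitter escalating from
1e−9 to 1e−5 of the mean diagonal is added, and failure beyond that raises
an error with the condition number — never a silent fallback.

### Hypotheses and decision

* H0: control and treated series are noise-corrupted observations of one
  shared latent function. Evidence = one joint density over all stacked
  observations.
* H1: each condition has its own latent. Evidence factorizes into the
  product of the two per-condition densities.

The log Bayes factor is log p(y|H1) − log p(y|H0); a transcript is flagged
when BF ≥ 10 (the conventional "strong evidence" cut). Working precision
is natural log throughout; the threshold constant is ln 10. The test runs
independently per transcript; being Bayesian, the marginalization already
accounts for sampling variability, so no multiplicity correction is
applied.

### Empirical-Bayes hyperparameters

Fit hyperparameters per transcript, shared between both hypotheses to
avoid favouring the more flexible one:

* a² = 0.5 × population variance (ddof = 0) of all of the transcript's
  values, pooled across conditions, replicates and timepoints;
* λ = 1 min, globally;
* σ² = population variance of the control-condition values, floored at
  ε = 1e−6 (a.u.)² with a warning (a constant control series would
  otherwise give σ² = 0).

The σ² rule presumes the control arm is a mock shift whose series
variance is essentially measurement noise. It deliberately breaks the
control/treated symmetry of the likelihood: swapping condition labels
changes the result under automatic hyperparameters (tested), though not
when hyperparameters are supplied explicitly.

### Modeled scale and t = 0

The default input is the log2 of the baseline-normalized series, matching
the zero-mean prior (the series starts at exactly 0 and moves are fold
changes). Linear-scale input is supported by centering at the 1 a.u.
baseline. t = 0 observations are included in the likelihood by default
(`include_t0=False` excludes them). Replicate series are stacked into one
likelihood per condition rather than averaged — averaging would discard
the replicate-noise information that σ² is meant to describe.

### Known limitations

* Because the baseline division pins t = 0 at exactly zero and subtracts
  each series' own t = 0 noise draw, the effective noise on later points
  is correlated within a series; the model treats it as iid. Under the
  simulated conditions this costs nothing detectable (the null
  calibration below), but it is an approximation.
* Under a worst-case null in which both arms are *flat* (no latent
  dynamics at all, pure noise), the empirical-Bayes σ² is itself a noisy
  estimate from ~14 points, and the BF ≥ 10 rule flags ≈ 8% of
  transcripts rather than ≲ 5%. With any genuine shared dynamics the rule
  is conservative (σ² absorbs the latent variance and the measured
  false-flag rate drops to 0 at 500 nulls). This is a property of the
  variance-matching hyperparameter rule, not of the evidence computation,
  which matches an independent dense-inverse oracle to < 1e−12.

## Normalization

Two steps, in order:

1. **Equal column sums.** Each (condition, replicate, timepoint) sample
   column is multiplied by a constant so that all column sums equal a
   target (default: the mean of the observed sums; any positive number
   may be supplied). Within-column ratios are preserved exactly; zero-sum
   columns are an error.
2. **Baseline division.** Each replicate series is divided by its own
   value at t = 0. Transcripts with any non-finite normalized value
   (e.g. a zero baseline) are dropped and reported, never imputed.

An optional log2 transform follows; t = 0 values are set to exactly 0
rather than log2(1.0 + rounding). The composition is invariant under any
global rescaling of the raw input.

## Escape index

Regions are resolved strand-aware in the transcript frame anchored at the
5′ end (offset 0 = TSS):

* PPR (promoter-proximal region): offsets −100 … +250, i.e. 351 nt;
* body: offsets +251 … L−1 (genes with L ≤ 251 nt of body are skipped);
* whole gene: offsets 0 … L−1.

Density = Σ coverage / region length, scaled per million mapped reads.
Regions truncated by the track bounds use the positions actually covered
(with a warning). Then

    EI = [ppr(t)/body(t)] / [ppr(0)/body(0)],
    transcription change = whole(t) / whole(0).

Library-size scaling cancels in both ratios (tested). Genes with a zero
body or baseline density are flagged unresolved, not dropped silently.
Candidate attenuated genes require EI ≥ 2, transcription change ≥ 1.5 and
coverage ≥ 10 FPKM — all boundary-inclusive — optionally plus a called
peak overlapping the PPR and a replicate EI also ≥ 2.

The 5′ anchor is the annotated TSS; annotations whose 5′ field denotes
the start codon instead will shift the PPR accordingly (the anchor is
whatever the `GeneAnnotation.tss` field holds, so callers can re-anchor).

## Peak calling and oligo(A) tails

Peaks are maximal contiguous intervals with coverage ≥ 5 reads (height
semantics; a `total` mode instead counts distinct overlapping reads) and
width ≥ 20 nt. The empirical FDR redistributes the observed reads
(preserving their lengths) uniformly over the region N times (default
100, seeded) and reports mean null qualifying-peak count / observed
count, clipped to [0, 1]. This requires the read list; from a bare pileup
the FDR is NaN and no FDR filtering is possible. The null is deliberately
simple, stated, and reproducible; it is conservative for strongly
localized signal.

A read carries an oligo(A) tail when its strand-oriented 3′ soft-clip is
an adenosine run of ≥ 3 nt (configurable). The tail is reported only when
the reference immediately 3′ of the alignment (on the transcribed strand)
is *not* an A-run of the same length — equally long genomic A-runs are
suppressed as encoded. Partial genomic A-runs shorter than the tail do
not suppress.

## Temporal profiles and positional summaries

* **Filtering:** a transcript is kept when (i) the max over timepoints of
  max(ratio, 1/ratio) on the replicate-averaged linear profile is ≥ 1.5
  and (ii) the mean pairwise Pearson correlation of the per-replicate
  log2 profiles is ≥ 0.7. Constant profiles (undefined correlation) are
  excluded. The fold-change is evaluated on replicate-averaged values;
  applying it per replicate and requiring all replicates to pass is
  stricter and was not chosen.
* **Clustering:** plain K-means (k-means++ seeding, Lloyd iterations,
  Euclidean distance on the averaged log2 profiles) with an explicit
  seed. The cluster count is a parameter (4 is a typical choice for
  stress-response profiles), not an inference.
* **TSS-aligned matrices:** rows sorted by transcript length, columns are
  strand-aware TSS-relative positions; cells outside the supplied track
  are missing (NaN), distinct from zero coverage.
* **Site distributions:** per gene, sites within the window are
  normalized to frequencies before summing across genes, so every gene
  contributes equal weight; distributions are compared with the
  asymptotic two-sample Kolmogorov–Smirnov test.
* **Meta-profiles:** each transcript is divided into 1000 equal-width
  bins along its 5′→3′ axis; per-nucleotide coverage mass is apportioned
  by fractional overlap (each nucleotide's mass is uniform over its unit
  interval, so bin mass is an exact integral — mass-conserving for any
  length, including lengths not divisible by the bin count). Fractions
  sum to 1 per transcript; the summed profile totals the number of
  contributing transcripts. Zero-coverage transcripts are excluded and
  reported.

## Synthetic data generator

`simulate_timecourse` emulates the structure of a two-condition,
two-replicate kinetic binding experiment on the grid
{0, 1, 2, 4, 8, 14, 20} min:

* a latent log2 profile per condition drawn from the squared-exponential
  GP (defaults a² = 1, λ = 1 min, matching the analysis assumptions);
* under H0 both conditions share one latent; under H1 the control arm is
  drawn at a small mock-shift amplitude (`control_alpha_sq` = 0.01,
  emulating a quiescent control shift) and the treated arm gets its own
  full-amplitude latent plus a sustained offset at t > 0 of magnitude
  `effect_size` with a random per-transcript sign. The offset starts at
  t > 0 because a constant offset would cancel under baseline anchoring;
  the sign is random because an identical offset on every transcript
  would be absorbed by the equal-column-sum scaling step.
* iid Gaussian noise (σ = 0.1 log2 a.u.) is added per observation, the
  latent is anchored at its own t = 0 value, and the series is
  exponentiated against a per-transcript log-normal baseline abundance
  (median ≈ 30 FPKM, 0.5 dex spread) so the raw output mimics FPKM
  tables.

`simulate_gene_reads` builds toy gene read sets: Poisson read counts per
specified peak, random read lengths of 20–40 nt, random 6-nt UMIs, PCR
duplicates sharing (UMI, sequence, placement), multimapper decoy
placements, and planted oligo-A soft-clips. A synthetic reference
sequence is produced alongside: genuine tails are guarded by a non-A base
downstream, and an `encoded_fraction` of tails sits on planted genomic
A-runs that a correct detector must suppress. Truth labels are derived
from the final reference state, so they remain exact even when guard and
decoy windows collide.

What the generator does **not** emulate: realistic sequence composition,
sequencing errors, cross-link-induced mutations, ligation biases,
non-Gaussian (count) noise at low coverage, or correlated dynamics across
transcripts. Tests passing on this generator therefore demonstrate the
correctness and calibration of the algorithms under their stated
assumptions, not robustness to every artefact of real libraries.

## Problem sizes and numerical conventions

The verification script (`scripts/acceptance.py`) uses: 200 random
instances (n ≤ 8) for evidence exactness; 10⁶ latent draws for the
Monte-Carlo consistency check at n = 3; 500 transcripts each for null
calibration and recovery (recovery at effect size 0.3 = 3× the noise sd);
100 random pileups/coverage vectors for the escape-index and peak-calling
oracles; ~500 reads with 20% planted tails and 5% encoded decoys for
oligo(A) accuracy; 20 transcripts of non-divisible lengths for
meta-profile conservation; 40 profiles in two separable groups for
clustering recovery. These sizes give stable statistics in seconds on one
CPU.

Coordinates are 0-based half-open internally and in BED/bedGraph;
GTF/GFF (1-based closed) is converted on ingest. On the minus strand the
TSS is the larger coordinate and transcript offsets run against the
genomic axis. All stochastic operations take an explicit integer seed and
use numpy's `default_rng`; identical seeds reproduce identical outputs
bit for bit.
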