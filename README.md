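# kincrac

Quantitative analysis of **kinetic CRAC** (UV cross-linking and analysis of
cDNA) time courses: given binding measurements for an RNA-binding protein or
RNA polymerase sampled at minute resolution after a stress shift, decide —
per transcript — whether the binding dynamics under stress differ from a
mock-shift control, and characterise *where* on each transcript the protein
acts.

It is written for people analysing time-resolved CLIP/CRAC experiments in
yeast or similar systems: two conditions (control shift, stress shift), a
handful of timepoints (default grid 0, 1, 2, 4, 8, 14, 20 min), two
biological replicates, and FPKM tables per transcript.

## What it computes

**Differential binding dynamics (Gaussian-process Bayes factor).**
The binding response f_j(t) of condition j is modelled as a smooth latent
function with a zero-mean GP prior under a squared-exponential covariance

    cov(f(s), f(t)) = a² · exp(−(s − t)² / (2λ²)),

observed through iid Gaussian noise σ². Because everything is Gaussian, the
latent marginalises exactly and the evidence p(y(0), …, y(T) | a, λ, σ) is a
closed-form multivariate normal density. Two hypotheses are compared per
transcript: H0 — all series are noisy observations of one shared function —
versus H1 — control and stress have distinct latent dynamics. A Bayes
factor ≥ 10 flags the transcript. Hyperparameters are set empirically:
a² = half the variance of all the transcript's series, λ = 1 min, σ² = the
variance of the control series, shared between both hypotheses.

**Normalization.** Per-sample FPKM columns are scaled to a common sum, then
each replicate series is divided by its own t = 0 baseline, so every series
starts at 1 a.u. (0 in log2) and later values are relative binding changes.
Transcripts without finite values at all timepoints are dropped and
reported.

**Escape index (EI).** The ratio of promoter-proximal (−100 to +250 nt
around the 5′ anchor) to gene-body (+251 nt to the 3′ end) read density,
compared between t = 0 and a later sample. EI ≥ 2 together with a ≥ 1.5
transcription increase and ≥ 10 FPKM marks candidate attenuated genes.

**Binding sites and oligo(A) tails.** Peak calling (coverage ≥ 5 reads over
≥ 20 nt, seeded permutation FDR) and detection of reads ending in
non-genome-encoded oligo-A runs, a hallmark of NNS/exosome degradation
intermediates.

**Profiles.** Fold-change/replicate-correlation filtering with K-means
clustering of temporal log2 profiles; TSS-aligned coverage matrices;
length-normalized 1000-bin meta-profiles.

**Synthetic data.** A seeded generator producing FPKM time courses with the
exact generative structure the GP test assumes, and toy gene read sets with
planted peaks, PCR duplicates, multimappers and oligo-A tails plus ground
truth, so the entire pipeline is testable offline.

## Worked example

Simulate a mixture of 80 null and 20 differentially responding transcripts,
normalise, and test:

```python
import pandas as pd
from kincrac import SimulationSpec, simulate_timecourse, normalize_pipeline, test_all

null_spec = SimulationSpec(n_transcripts=80, seed=10, hypothesis="H0")
diff_spec = SimulationSpec(n_transcripts=20, seed=11, hypothesis="H1", effect_size=1.0)
m0, _ = simulate_timecourse(null_spec)
m1, _ = simulate_timecourse(diff_spec)
m1.data["gene_id"] = "DIFF_" + m1.data["gene_id"]
matrix = m0.copy_with(pd.concat([m0.data, m1.data], ignore_index=True))

ntc, report = normalize_pipeline(matrix)       # scale columns, divide by t=0, log2
results = test_all(ntc)                        # one Bayes factor per transcript
flagged = results[results["flagged"]]
print(f"{len(results)} transcripts tested, {len(flagged)} flagged (BF >= 10)")
print(f"flagged among true differential: "
      f"{flagged['gene_id'].str.startswith('DIFF_').sum()} / 20")
```

Output:

```
100 transcripts tested, 19 flagged (BF >= 10)
flagged among true differential: 19 / 20
```

All 19 flags land on truly differential transcripts (one weak responder is
missed; no false positives among the 80 nulls). `results` also carries the
per-transcript log evidences, the Bayes factor and the hyperparameters
used, e.g. the top hit here has log BF ≈ 681 (a 2-fold sustained change
with σ = 0.1 noise is overwhelming evidence at 28 observations).

The same stages are available from the shell:

```bash
kincrac simulate timecourse --seed 5 --out-prefix sim --n-transcripts 100
kincrac normalize sim.timecourse.tsv --out norm.tsv
kincrac gp-test norm.tsv --out gp.tsv
kincrac cluster norm.tsv --out-prefix clusters --k 4 --seed 0
```

plus `demux`, `collapse`, `pileup`, `fpkm`, `peaks`, `oligoa`, `ei`,
`metaprofile` and `tssmap` for the read-level stages (see `kincrac --help`).

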