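import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from kincrac.normalize import NormalizedTimeCourse
from kincrac.profiles import (
    compare_site_distributions,
    filter_profiles,
    kmeans_cluster,
    metaprofile_bins,
    tss_aligned_matrix,
    tss_site_distribution,
)
from kincrac.types import GeneAnnotation, PileupTrack

TP = [0.0, 1.0, 2.0, 4.0, 8.0]


def make_ntc(series_by_gene, timepoints=TP):
    """Linear-scale normalized time course for the treated condition with
    two replicates; series_by_gene[gene] = {rep: values}."""
    rows = []
    for gene, reps in series_by_gene.items():
        for rep, vals in reps.items():
            for t, v in zip(timepoints, vals):
                rows.append((gene, "treated", rep, t, float(v)))
    df = pd.DataFrame(rows, columns=["gene_id", "condition", "replicate",
                                     "timepoint_min", "value"])
    return NormalizedTimeCourse(df, scale="linear")


def correlated_pair(base, noise, rng):
    return {1: base + rng.normal(0, noise, len(base)),
            2: base + rng.normal(0, noise, len(base))}


class TestFilterProfiles:
    def test_fold_below_threshold_excluded(self):
        # max fold-change 1.4 in both replicates -> excluded at 1.5
        up = [1.0, 1.2, 1.4, 1.2, 1.1]
        ntc = make_ntc({"g": {1: up, 2: up}})
        pset = filter_profiles(ntc)
        assert len(pset) == 0
        assert pset.max_fold["g"] == pytest.approx(1.4)

    def test_fold_at_threshold_included(self):
        up = [1.0, 1.5, 1.2, 1.1, 1.0]
        pset = filter_profiles(make_ntc({"g": {1: up, 2: up}}))
        assert list(pset.profiles.index) == ["g"]

    def test_downward_fold_counts_via_inverse_ratio(self):
        down = [1.0, 0.9, 0.5, 0.6, 0.8]  # 1/0.5 = 2-fold
        pset = filter_profiles(make_ntc({"g": {1: down, 2: down}}))
        assert list(pset.profiles.index) == ["g"]
        assert pset.max_fold["g"] == pytest.approx(2.0)

    def test_low_replicate_correlation_excluded(self, rng):
        a = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        b = np.array([1.0, 1.1, 0.7, 2.5, 0.4])  # discordant replicate
        ntc = make_ntc({"g": {1: a, 2: b}})
        pset = filter_profiles(ntc)
        assert pset.mean_corr["g"] < 0.7
        assert len(pset) == 0

    def test_retained_set_equals_brute_force(self, rng):
        genes = {}
        for i in range(20):
            fold = rng.uniform(1.0, 3.0)
            shape = np.array([1.0, fold, fold / 2, 1.2, 1.0])
            noise = rng.choice([0.01, 1.0])
            genes[f"g{i:02d}"] = correlated_pair(shape, noise, rng)
        genes = {
            g: {r: np.clip(v, 0.05, None) for r, v in reps.items()}
            for g, reps in genes.items()
        }
        ntc = make_ntc(genes)
        pset = filter_profiles(ntc, min_fold=1.5, min_corr=0.7)
        # brute force on the same definition
        expected = []
        for g, reps in genes.items():
            avg = (np.asarray(reps[1]) + np.asarray(reps[2])) / 2
            fold = max(max(avg), max(1 / avg))
            r = np.corrcoef(np.log2(reps[1]), np.log2(reps[2]))[0, 1]
            if fold >= 1.5 and r >= 0.7:
                expected.append(g)
        assert list(pset.profiles.index) == sorted(expected)

    def test_single_replicate_is_error(self):
        ntc = make_ntc({"g": {1: [1.0, 2.0, 1.0, 1.0, 1.0]}})
        with pytest.raises(ValueError, match="replicates"):
            filter_profiles(ntc)

    def test_idempotent_and_order_independent(self, rng):
        genes = {
            f"g{i}": correlated_pair(
                np.array([1.0, rng.uniform(1, 3), 1.5, 1.2, 1.0]), 0.02, rng
            )
            for i in range(8)
        }
        ntc = make_ntc(genes)
        first = filter_profiles(ntc)
        shuffled = NormalizedTimeCourse(
            ntc.data.sample(frac=1.0, random_state=5).reset_index(drop=True),
            scale="linear",
        )
        second = filter_profiles(shuffled)
        assert list(first.profiles.index) == list(second.profiles.index)


class TestKmeans:
    def _pset(self, profiles_df):
        from kincrac.profiles import ProfileSet

        return ProfileSet(
            timepoints=np.asarray(profiles_df.columns, dtype=float),
            profiles=profiles_df,
            max_fold=pd.Series(2.0, index=profiles_df.index),
            mean_corr=pd.Series(1.0, index=profiles_df.index),
        )

    def test_k1_centroid_is_mean_profile(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (5, 4)),
                          index=[f"g{i}" for i in range(5)], columns=TP[:4])
        res = kmeans_cluster(self._pset(df), k=1, seed=0)
        assert set(res.assignments) == {0}
        assert np.allclose(res.centroids[0], df.mean(axis=0))

    def test_separable_groups_recovered(self, rng):
        up = np.array([0.0, 1.0, 2.0, 2.0])
        down = -up
        rows, labels = {}, {}
        for i in range(20):
            truth = i % 2
            base = up if truth else down
            rows[f"g{i:02d}"] = base + rng.normal(0, 0.05, 4)
            labels[f"g{i:02d}"] = truth
        df = pd.DataFrame(rows).T
        df.columns = TP[:4]
        res = kmeans_cluster(self._pset(df), k=2, seed=1)
        ari = adjusted_rand_score(
            [labels[g] for g in df.index], res.assignments[df.index]
        )
        assert ari == 1.0

    def test_reproducible_given_seed(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (12, 4)),
                          index=[f"g{i}" for i in range(12)], columns=TP[:4])
        a = kmeans_cluster(self._pset(df), k=3, seed=9)
        b = kmeans_cluster(self._pset(df), k=3, seed=9)
        assert (a.assignments == b.assignments).all()
        assert a.inertia == b.inertia

    def test_bad_k_is_error(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (3, 4)), columns=TP[:4])
        with pytest.raises(ValueError):
            kmeans_cluster(self._pset(df), k=0, seed=0)
        with pytest.raises(ValueError):
            kmeans_cluster(self._pset(df), k=4, seed=0)


def genomic_track(start, coverage, strand="+"):
    return PileupTrack(scope="chrI", strand=strand, coverage=coverage,
                       start=start, oriented=False)


class TestTssAlignedMatrix:
    def test_plus_strand_coordinate_mapping(self):
        ann = GeneAnnotation("gp", "chrI", "+", tss=100, end3=300)
        cov = np.zeros(400)
        cov[50] = 7.0  # genomic 50 == relative -50
        mat = tss_aligned_matrix({"gp": genomic_track(0, cov)}, [ann], window=50)
        assert mat.loc["gp", -50] == 7.0
        assert mat.loc["gp", 0] == 0.0

    def test_minus_strand_axis_reversed(self):
        ann = GeneAnnotation("gm", "chrI", "-", tss=100, end3=20)
        cov = np.zeros(200)
        cov[90] = 3.0  # genomic 90 == relative +10 on the minus strand
        mat = tss_aligned_matrix({"gm": genomic_track(0, cov)}, [ann], window=20)
        assert mat.loc["gm", 10] == 3.0
        assert mat.loc["gm", -10] == 0.0

    def test_uniform_coverage_gives_flat_field(self):
        anns = [
            GeneAnnotation("a", "chrI", "+", tss=100, end3=200),
            GeneAnnotation("b", "chrI", "-", tss=250, end3=210),
        ]
        tracks = {g.gene_id: genomic_track(0, np.full(400, 2.5)) for g in anns}
        mat = tss_aligned_matrix(tracks, anns, window=30)
        assert (mat.to_numpy() == 2.5).all()

    def test_out_of_bounds_cells_missing_not_zero(self):
        ann = GeneAnnotation("g", "chrI", "+", tss=10, end3=60)
        mat = tss_aligned_matrix(
            {"g": genomic_track(5, np.ones(60))}, [ann], window=20
        )
        assert np.isnan(mat.loc["g", -20])  # genomic -10, before the track
        assert mat.loc["g", 0] == 1.0

    def test_rows_sorted_by_length(self):
        anns = [
            GeneAnnotation("long", "chrI", "+", tss=0, end3=300),
            GeneAnnotation("short", "chrI", "+", tss=0, end3=50),
        ]
        tracks = {g.gene_id: genomic_track(0, np.ones(400)) for g in anns}
        mat = tss_aligned_matrix(tracks, anns, window=10)
        assert list(mat.index) == ["short", "long"]


class TestTssSiteDistribution:
    ANN = [
        GeneAnnotation("a", "chrI", "+", tss=100, end3=400),
        GeneAnnotation("b", "chrI", "-", tss=900, end3=500),
        GeneAnnotation("c", "chrI", "+", tss=2000, end3=2400),
    ]

    def test_all_sites_at_tss(self):
        sites = {"a": [100, 100], "b": [900]}
        vec = tss_site_distribution(sites, self.ANN, window=10)
        assert vec[10] == pytest.approx(2.0)  # two genes, all mass at 0
        assert vec.sum() == pytest.approx(2.0)

    def test_within_gene_normalization(self):
        vec = tss_site_distribution({"a": [90, 110]}, self.ANN, window=20)
        assert vec[20 - 10] == pytest.approx(0.5)
        assert vec[20 + 10] == pytest.approx(0.5)

    def test_three_gene_fixture_matches_hand_tally(self):
        sites = {"a": [100, 105], "b": [895, 905, 910], "c": [2000]}
        vec = tss_site_distribution(sites, self.ANN, window=10)
        # gene a: rel 0, +5 -> 0.5 each; gene b (minus): rel +5, -5, -10
        # -> 1/3 each; gene c: rel 0 -> 1
        expected = np.zeros(21)
        expected[10] += 0.5 + 1.0
        expected[15] += 0.5 + 1 / 3
        expected[5] += 1 / 3
        expected[0] += 1 / 3
        assert np.allclose(vec, expected)


class TestCompareSiteDistributions:
    def test_identical_samples_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0])
        d, p = compare_site_distributions(a, a.copy())
        assert d == 0.0

    def test_disjoint_supports_statistic_one(self):
        d, _ = compare_site_distributions([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_matches_brute_force_ecdf_sweep(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 5)
        d, _ = compare_site_distributions(a, b)
        grid = np.concatenate([a, b])
        brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            compare_site_distributions([], [1.0])


def oriented_track(coverage):
    return PileupTrack(scope="g", strand="+", coverage=coverage, oriented=True)


class TestMetaprofile:
    def test_uniform_coverage_divisible_length(self):
        mp = metaprofile_bins({"g": oriented_track(np.ones(2000))}, n_bins=1000)
        assert np.allclose(mp.fractions.loc["g"], 1 / 1000)

    def test_five_prime_mass_stays_in_first_bins(self):
        cov = np.zeros(1000)
        cov[:100] = 4.0  # first 10% of the transcript
        mp = metaprofile_bins({"g": oriented_track(cov)}, n_bins=1000)
        frac = mp.fractions.loc["g"].to_numpy()
        assert frac[:100].sum() == pytest.approx(1.0)
        assert frac[100:].sum() == pytest.approx(0.0)

    def test_non_divisible_length_matches_brute_force(self, rng):
        cov = rng.poisson(3.0, 1500).astype(float)
        cov[cov.argmin()] += 1  # ensure non-zero mass
        mp = metaprofile_bins({"g": oriented_track(cov)}, n_bins=1000)
        # brute force: each nucleotide's unit interval split across bins
        expected = np.zeros(1000)
        width = 1500 / 1000
        for j in range(1500):
            lo, hi = j, j + 1
            b0 = int(lo // width)
            for b in range(b0, min(int(np.ceil(hi / width)) + 1, 1000)):
                overlap = max(0.0, min(hi, (b + 1) * width) - max(lo, b * width))
                expected[b] += cov[j] * overlap
        expected /= expected.sum()
        assert np.allclose(mp.fractions.loc["g"], expected, atol=1e-9)

    def test_fractions_sum_to_one_and_total_counts_transcripts(self, rng):
        tracks = {
            f"g{i}": oriented_track(rng.poisson(2.0, int(rng.integers(30, 400))) + 1.0)
            for i in range(6)
        }
        mp = metaprofile_bins(tracks, n_bins=1000)
        assert np.allclose(mp.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert mp.summed.sum() == pytest.approx(len(tracks), abs=1e-9)

    def test_zero_coverage_transcript_excluded_and_reported(self):
        mp = metaprofile_bins(
            {"z": oriented_track(np.zeros(50)), "g": oriented_track(np.ones(50))},
            n_bins=10,
        )
        assert mp.excluded == ["z"]
        assert list(mp.fractions.index) == ["g"]
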