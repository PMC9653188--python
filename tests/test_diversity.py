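"""Covariance PCA, pairwise LD, distance-class binning, Tukey comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import corepanel as cp
from corepanel.diversity import LD_CLASS_EDGES_MB, _compact_letter_display
from tests.test_genotype import gm_from_dosages


class TestCovariancePCA:
    def test_matches_direct_eigendecomposition(self, rng):
        """Scores and explained variance agree with an explicit covariance
        eigendecomposition (independent route)."""
        X = rng.integers(0, 3, size=(30, 12)).astype(float)
        pca = cp.CovariancePCA().fit(X)
        scores = pca.transform(X)
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (len(X) - 1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        pct = 100 * evals / evals.sum()
        np.testing.assert_allclose(pca.explained_pct_, pct[: len(pca.explained_pct_)], atol=1e-8)
        # score covariance reproduces the eigenvalues
        sc_var = scores.var(axis=0, ddof=1)
        np.testing.assert_allclose(sc_var[:5], evals[:5], rtol=1e-8)

    def test_duplicated_accessions_coincide(self, rng):
        base = rng.integers(0, 3, size=(10, 20)).astype(float)
        X = np.vstack([base, base])
        scores = cp.CovariancePCA(n_components=2).fit_transform(X)
        np.testing.assert_allclose(scores[:10], scores[10:], atol=1e-8)

    def test_rank_one_structure_explains_everything(self):
        u = np.arange(8, dtype=float)
        v = np.array([1.0, 2.0, 0.5, 1.5])
        X = np.outer(u, v)
        pca = cp.CovariancePCA().fit(X)
        assert pca.explained_pct_[0] == pytest.approx(100.0, abs=1e-8)

    def test_full_decomposition_sums_to_100(self, small_population):
        _, gm, _, _ = small_population
        pca = cp.CovariancePCA().fit(gm.dosages)
        assert pca.explained_pct_.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(pca.explained_pct_) <= 1e-9).all()

    def test_translation_invariance(self, rng):
        """Adding a constant to one site's dosages leaves scores unchanged."""
        X = rng.integers(0, 3, size=(20, 10)).astype(float)
        shifted = X.copy()
        shifted[:, 3] += 7.0
        a = cp.CovariancePCA(n_components=3).fit_transform(X)
        b = cp.CovariancePCA(n_components=3).fit_transform(shifted)
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_k_beyond_rank_truncated(self, rng):
        X = rng.normal(size=(5, 40))
        with pytest.warns(UserWarning, match="truncat"):
            pca = cp.CovariancePCA(n_components=30).fit(X)
        assert len(pca.explained_pct_) <= 5

    def test_planted_subpopulations_recovered(self):
        """Three station founder pools separate in PC space; k-means on the
        top two PCs recovers the labels almost perfectly."""
        from scipy.optimize import linear_sum_assignment
        from sklearn.cluster import KMeans

        cfg = cp.barley_like(n_accessions=240, n_stations=3, fst=0.1, seed=3)
        gm, truth = cp.simulate_population(cfg)
        res = cp.pca_covariance(gm, k=2)
        labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit(res.scores).labels_
        codes = {s: i for i, s in enumerate(np.unique(truth.station))}
        true = np.array([codes[s] for s in truth.station])
        C = np.zeros((3, 3))
        for t, l in zip(true, labels):
            C[t, l] += 1
        r, c = linear_sum_assignment(-C)
        assert C[r, c].sum() / len(true) >= 0.9


class TestLdPairwise:
    def test_duplicated_site_r2_one(self):
        col = np.array([0, 0, 2, 2, 0, 2, 0, 2, 2, 0] * 2, dtype=float)
        gm = gm_from_dosages(np.column_stack([col, col]))
        rec = cp.ld_pairwise(gm, min_obs=5)
        assert rec["r2"].iloc[0] == pytest.approx(1.0)

    def test_sign_free(self):
        a = np.array([0, 0, 2, 2] * 5, dtype=float)
        gm = gm_from_dosages(np.column_stack([a, 2 - a]))
        rec = cp.ld_pairwise(gm, min_obs=5)
        assert rec["r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        """Eight accessions; r2 equals the brute-force Pearson formula."""
        a = np.array([0, 0, 0, 2, 2, 2, 0, 2], dtype=float)
        b = np.array([0, 2, 0, 2, 2, 0, 0, 2], dtype=float)
        gm = gm_from_dosages(np.column_stack([a, b]))
        rec = cp.ld_pairwise(gm, min_obs=5)
        num = np.mean(a * b) - a.mean() * b.mean()
        expected = num**2 / (a.var() * b.var())
        assert rec["r2"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_allele_swap_invariance(self, small_population):
        _, gm, _, _ = small_population
        sub = gm.subset_sites(np.arange(30))
        swapped = cp.GenotypeMatrix(2 - sub.dosages, sub.site_meta, sub.accession_meta)
        a = cp.ld_pairwise(sub, min_obs=5).set_index(["site_a", "site_b"])["r2"]
        b = cp.ld_pairwise(swapped, min_obs=5).set_index(["site_a", "site_b"])["r2"]
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[common], b.loc[common], rtol=1e-9, atol=1e-12)

    def test_subsampling_is_seeded(self, small_population):
        _, gm, _, _ = small_population
        a = cp.ld_pairwise(gm, max_pairs_per_chrom=50, seed=11)
        b = cp.ld_pairwise(gm, max_pairs_per_chrom=50, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_path_matches_complete_path(self, rng):
        """Per-pair masked computation agrees with the correlation-matrix fast
        path when nothing is actually missing."""
        X = rng.integers(0, 3, (40, 8)).astype(float)
        gm = gm_from_dosages(X)
        fast = cp.ld_pairwise(gm, min_obs=5)
        Xn = X.copy()
        Xn[0, 0] = np.nan  # forces the masked path everywhere
        slow = cp.ld_pairwise(gm_from_dosages(Xn), min_obs=5)
        merged = fast.merge(slow, on=["site_a", "site_b"], suffixes=("_f", "_s"))
        later = merged[(merged["site_a"] != "s0") & (merged["site_b"] != "s0")]
        np.testing.assert_allclose(later["r2_f"], later["r2_s"], rtol=1e-9)


class TestDistanceClasses:
    @pytest.mark.parametrize(
        "mb,expected",
        [(0.5, 1), (0.9999, 1), (1.0, 2), (4.9, 2), (5.0, 3), (9.9, 3), (10.0, 4),
         (49.9, 4), (50.0, 5), (99.9, 5), (100.0, 6), (199.9, 6), (200.0, 7),
         (399.9, 7), (400.0, 8), (700.0, 8)],
    )
    def test_half_open_boundaries(self, mb, expected):
        rec = pd.DataFrame({"distance_bp": [int(mb * 1e6)], "r2": [0.1]})
        assert cp.bin_distance_classes(rec)["distance_class"].iloc[0] == expected

    def test_every_record_classified_once(self, small_population):
        _, gm, _, _ = small_population
        rec = cp.ld_pairwise(gm, max_pairs_per_chrom=300, seed=1)
        binned = cp.bin_distance_classes(rec)
        assert binned["distance_class"].between(1, 8).all()
        assert cp.class_summary(binned)["n"].sum() == len(rec)

    def test_exponential_decay_is_monotone(self, rng):
        """Generated r2 = exp(-d / tau) + noise: per-class medians decrease."""
        d_mb = rng.uniform(0.01, 700, size=40_000)
        r2 = np.clip(np.exp(-d_mb / 30.0) + rng.normal(0, 0.02, d_mb.size), 0, 1)
        rec = cp.bin_distance_classes(
            pd.DataFrame({"distance_bp": (d_mb * 1e6).astype(int), "r2": r2})
        )
        med = cp.class_summary(rec).set_index("distance_class")["median_r2"]
        assert (np.diff(med.loc[sorted(med.index)]) < 0).all()

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            cp.bin_distance_classes(pd.DataFrame({"distance_bp": [0], "r2": [0.1]}))


class TestThresholdPercentile:
    def test_hand_counted(self):
        rec = pd.DataFrame({"r2": [0.05] * 9 + [0.5]})
        with pytest.warns(UserWarning):
            assert cp.ld_threshold_percentile(rec, 0.1) == pytest.approx(90.0)

    def test_all_below_threshold(self):
        rec = pd.DataFrame({"r2": np.full(200, 0.01)})
        assert cp.ld_threshold_percentile(rec, 0.1) == 100.0

    def test_matches_analytic_mixture_cdf(self, rng):
        """Monte-Carlo percentile agrees with the closed-form mixture CDF."""
        w, a1, b1, a2, b2 = 0.7, 0.5, 8.0, 4.0, 2.0
        n = 40_000
        comp = rng.random(n) < w
        r2 = np.where(comp, rng.beta(a1, b1, n), rng.beta(a2, b2, n))
        rec = pd.DataFrame({"r2": r2})
        analytic = 100 * (w * sps.beta.cdf(0.1, a1, b1) + (1 - w) * sps.beta.cdf(0.1, a2, b2))
        mc_se = 100 * np.sqrt(analytic / 100 * (1 - analytic / 100) / n)
        assert abs(cp.ld_threshold_percentile(rec, 0.1) - analytic) < 4 * mc_se + 0.1


class TestCompareDistanceClasses:
    def test_same_distribution_shares_letter(self):
        """Type-I control: equal-distribution classes share a letter in at
        least 95% of seeded replicates."""
        share = 0
        reps = 40
        for seed in range(reps):
            r = np.random.default_rng(seed)
            rec = pd.DataFrame(
                {"distance_class": [1] * 200 + [2] * 200, "r2": r.normal(0.2, 0.05, 400)}
            )
            out = cp.compare_distance_classes(rec)
            lets = dict(zip(out["distance_class"], out["letters"]))
            if set(lets[1]) & set(lets[2]):
                share += 1
        assert share / reps >= 0.95

    def test_separated_classes_get_distinct_letters(self, rng):
        rec = pd.DataFrame(
            {
                "distance_class": [1] * 100 + [2] * 100,
                "r2": np.r_[rng.normal(0.1, 0.02, 100), rng.normal(0.2, 0.02, 100)],
            }
        )
        out = cp.compare_distance_classes(rec)
        lets = dict(zip(out["distance_class"], out["letters"]))
        assert not (set(lets[1]) & set(lets[2]))

    def test_tukey_matches_studentized_range_critical_value(self, rng):
        """The reject decision reproduces the textbook studentized-range rule
        q(0.05, k, df): manual computation on a tiny balanced example."""
        k, n = 3, 5
        data = {
            1: rng.normal(0.0, 1.0, n),
            2: rng.normal(0.5, 1.0, n),
            3: rng.normal(3.0, 1.0, n),
        }
        rec = pd.DataFrame(
            {
                "distance_class": np.repeat(list(data), n),
                "r2": np.concatenate([data[g] for g in data]),
            }
        )
        out = cp.compare_distance_classes(rec)
        df = k * (n - 1)
        q_crit = sps.studentized_range.ppf(0.95, k, df)
        assert q_crit == pytest.approx(3.77, abs=0.01)  # classic q-table value
        mse = np.mean([np.var(v, ddof=1) for v in data.values()])
        hsd = q_crit * np.sqrt(mse / n)
        lets = dict(zip(out["distance_class"], out["letters"]))
        for a, b in [(1, 2), (1, 3), (2, 3)]:
            manual_reject = abs(data[a].mean() - data[b].mean()) > hsd
            tukey_reject = not (set(lets[a]) & set(lets[b]))
            assert manual_reject == tukey_reject

    def test_cld_insert_absorb(self):
        letters = _compact_letter_display([1, 2, 3], [(1, 3)])
        assert set(letters[1]) & set(letters[2])
        assert set(letters[2]) & set(letters[3])
        assert not (set(letters[1]) & set(letters[3]))
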