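"""Supervised delimitation tests: EDDA likelihoods against plug-in oracles,
greedy merge behaviour, and the BIC -> Bayes-factor -> posterior arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import morphodelim as md
from morphodelim.edda import DelimitationScheme, _merged_name
from morphodelim.gmm import DegenerateFitError


def plug_in_loglik(X, labels, covs_by_group, means_by_group):
    """Independent sum of labelled Gaussian log-densities + log proportions."""
    n = X.shape[0]
    ll = 0.0
    for g in set(labels):
        mask = labels == g
        pi = mask.sum() / n
        dev = X[mask] - means_by_group[g]
        cov = covs_by_group[g]
        sign, logdet = np.linalg.slogdet(cov)
        iv = np.linalg.inv(cov)
        ll += mask.sum() * np.log(pi)
        ll += -0.5 * (mask.sum() * (X.shape[1] * np.log(2 * np.pi) + logdet)
                      + np.einsum("ij,jk,ik->", dev, iv, dev))
    return float(ll)


@pytest.fixture(scope="module")
def three_groups():
    """A far from B~C; B and C drawn from one distribution."""
    rng = np.random.default_rng(5)
    cov = np.diag([1.0, 0.8, 1.2])
    a = rng.multivariate_normal([8, 8, 8], cov, 40)
    b = rng.multivariate_normal([0, 0, 0], cov, 25)
    c = rng.multivariate_normal([0, 0, 0], cov, 30)
    X = np.vstack([a, b, c])
    labels = np.array(["A"] * 40 + ["B"] * 25 + ["C"] * 30, dtype=object)
    return X, labels


class TestFitEDDA:
    def test_k1_equals_g1_mixture(self, overlapping_data):
        X = overlapping_data
        labels = np.array(["one"] * X.shape[0], dtype=object)
        edda = md.fit_edda(X, labels, "VVV")
        gmm = md.fit_gmm(X, 1, "VVV")
        assert edda.loglik == pytest.approx(gmm.loglik, abs=1e-8)
        assert edda.n_params == gmm.n_params
        assert edda.bic == pytest.approx(gmm.bic, abs=1e-8)

    def test_vvv_matches_plug_in_oracle(self, three_groups):
        X, labels = three_groups
        fit = md.fit_edda(X, labels, "VVV")
        means = {g: X[labels == g].mean(axis=0) for g in "ABC"}
        covs = {g: np.cov(X[labels == g].T, bias=True) for g in "ABC"}
        for i, g in enumerate(fit.groups):
            np.testing.assert_allclose(fit.means[i], means[g], atol=1e-12)
            np.testing.assert_allclose(fit.covariances[i], covs[g], atol=1e-12)
        assert fit.loglik == pytest.approx(plug_in_loglik(X, labels, covs, means), abs=1e-8)

    def test_eee_uses_pooled_covariance(self, three_groups):
        X, labels = three_groups
        fit = md.fit_edda(X, labels, "EEE")
        pooled = np.zeros((3, 3))
        for g in "ABC":
            dev = X[labels == g] - X[labels == g].mean(axis=0)
            pooled += dev.T @ dev
        pooled /= X.shape[0]
        np.testing.assert_allclose(fit.covariances[0], pooled, atol=1e-12)
        assert np.array_equal(fit.covariances[0], fit.covariances[1])

    def test_small_group_rejected(self, three_groups):
        X, labels = three_groups
        bad = labels.copy()
        bad[0] = "LONER"
        with pytest.raises(ValueError, match="LONER"):
            md.fit_edda(X, bad, "EII")

    def test_true_labels_beat_permuted(self, three_groups):
        X, labels = three_groups
        rng = np.random.default_rng(1)
        perm = rng.permutation(labels)
        assert md.fit_edda(X, labels, "EEE").loglik > md.fit_edda(X, perm, "EEE").loglik


class TestMergePath:
    def test_two_otus_two_schemes(self, overlapping_data):
        X = overlapping_data
        labels = np.array(["A"] * 80 + ["B"] * 70, dtype=object)
        path = md.merge_path(X, labels)
        assert [s.K for s in path.schemes] == [2, 1]
        assert path.steps[1].merged_pair == ("A", "B")

    def test_identical_groups_merged_first(self, three_groups):
        X, labels = three_groups
        path = md.merge_path(X, labels)
        assert path.steps[1].merged_pair == ("B", "C")
        assert path.best_step.scheme.K == 2
        assert set(path.best_step.scheme.assignment) == {"A", "B-C"}

    def test_path_is_nested_coarsening(self, three_groups):
        X, labels = three_groups
        path = md.merge_path(X, labels)
        ks = [s.K for s in path.schemes]
        assert ks == [3, 2, 1]
        for earlier, later in itertools.pairwise(path.schemes):
            assert later.coarsens(earlier)

    def test_greedy_first_merge_equals_bruteforce_best_pair(self, three_groups):
        X, labels = three_groups
        path = md.merge_path(X, labels)
        best_pair, best_bic = None, -np.inf
        for a, b in itertools.combinations(sorted(set(labels)), 2):
            trial = labels.copy()
            trial[(trial == a) | (trial == b)] = _merged_name(a, b)
            bic = md.best_edda(X, trial).bic
            if bic > best_bic:
                best_pair, best_bic = (a, b), bic
        assert path.steps[1].merged_pair == best_pair
        assert path.steps[1].fit.bic == pytest.approx(best_bic)

    def test_greedy_best_scheme_usually_matches_exhaustive(self):
        """Greedy is not guaranteed optimal; it should match exhaustive
        merge-partition search in the large majority of replicates."""
        hits = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = np.vstack([
                rng.normal([0, 0], 1.0, (15, 2)),
                rng.normal([0.8, 0.5], 1.0, (15, 2)),
                rng.normal([4, 4], 1.0, (15, 2)),
            ])
            labels = np.array(["A"] * 15 + ["B"] * 15 + ["C"] * 15, dtype=object)
            path = md.merge_path(X, labels)
            greedy_best = path.best_step.fit.bic
            # exhaustive: all partitions reachable by merging {A,B,C}
            partitions = [["A", "B", "C"], ["AB", "AB", "C"], ["AC", "B", "AC"],
                          ["A", "BC", "BC"], ["X", "X", "X"]]
            best = -np.inf
            for part in partitions:
                assign = np.array([part["ABC".index(l)] for l in labels], dtype=object)
                best = max(best, md.best_edda(X, assign).bic)
            total += 1
            hits += bool(abs(greedy_best - best) < 1e-9)
        assert hits / total >= 0.9


class TestRankSchemes:
    def test_published_table_arithmetic(self):
        """Three BIC values (6681, 6670, 6394) -> dBIC 0/11/287, PP .996/.004."""
        delta, bf, pp = md.rank_schemes([6681.0, 6670.0, 6394.0])
        np.testing.assert_allclose(delta, [0.0, 11.0, 287.0])
        assert bf[0] == 1.0
        assert bf[1] == pytest.approx(np.exp(5.5), rel=1e-12)        # ~244.7
        # published values (244.945, 2.107E+62) come from unrounded BICs;
        # from the printed integers we must agree to rounding error
        assert bf[1] == pytest.approx(244.945, rel=0.01)
        assert bf[2] == pytest.approx(2.107e62, rel=0.01)
        assert round(pp[0], 3) == 0.996
        assert round(pp[1], 3) == 0.004
        assert pp[2] < 1e-60

    def test_single_scheme(self):
        delta, bf, pp = md.rank_schemes([100.0])
        assert (delta[0], bf[0], pp[0]) == (0.0, 1.0, 1.0)

    def test_tied_schemes_split_evenly(self):
        _, _, pp = md.rank_schemes([5.0, 5.0])
        np.testing.assert_allclose(pp, [0.5, 0.5])

    @given(st.lists(st.floats(min_value=-300, max_value=300), min_size=1, max_size=8))
    def test_pp_normalised_and_bf_monotone(self, bics):
        delta, bf, pp = md.rank_schemes(bics)
        assert pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert bf[np.argmax(np.asarray(bics))] == 1.0
        order = np.argsort(delta)
        assert np.all(np.diff(bf[order]) >= 0)

    def test_bf_formatting(self):
        assert md.format_bayes_factor(244.6919, 5.5) == "244.692"
        s = md.format_bayes_factor(np.exp(143.5), 143.5)
        assert s.startswith("2.0") and "E+62" in s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            md.rank_schemes([])


class TestCompareSchemes:
    def test_matches_merge_path_on_same_schemes(self, three_groups):
        X, labels = three_groups
        path = md.merge_path(X, labels)
        schemes = [DelimitationScheme(s.name, s.assignment) for s in path.schemes]
        table = md.compare_schemes(X, schemes)
        path_bics = {s.scheme.name: s.fit.bic for s in path.steps}
        for _, row in table.iterrows():
            assert row["BIC"] == pytest.approx(path_bics[row["scheme"]], abs=1e-9)

    def test_identical_schemes_share_posterior(self, three_groups):
        X, labels = three_groups
        s1 = DelimitationScheme("first", labels)
        s2 = DelimitationScheme("second", labels.copy())
        table = md.compare_schemes(X, [s1, s2])
        np.testing.assert_allclose(table["PP"], [0.5, 0.5])
        np.testing.assert_allclose(table["BIC"].iloc[0], table["BIC"].iloc[1])

    def test_duplicate_names_rejected(self, three_groups):
        X, labels = three_groups
        with pytest.raises(ValueError, match="duplicate"):
            md.compare_schemes(X, [DelimitationScheme("s", labels)] * 2)

    def test_random_split_of_homogeneous_otu_loses(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0.0, 1.0, (60, 3))
        whole = DelimitationScheme("whole", np.array(["A"] * 60, dtype=object))
        halves = np.array(["A1"] * 30 + ["A2"] * 30, dtype=object)
        split = DelimitationScheme("split", rng.permutation(halves))
        table = md.compare_schemes(X, [whole, split])
        assert table.iloc[0]["scheme"] == "whole"

    def test_non_estimable_family_skipped_not_fatal(self, three_groups):
        X, labels = three_groups
        fit = md.best_edda(X, labels, ("EII", "VVV"))
        assert fit.family in ("EII", "VVV")
        with pytest.raises(DegenerateFitError):
            # 3-dim VVV with a 2-specimen group cannot be estimated
            tiny = np.array(["A"] * 93 + ["B", "B"], dtype=object)
            md.fit_edda(X, tiny, "VVV")
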