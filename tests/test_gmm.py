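"""Unit and property tests for the constrained-covariance mixture engine.

The VVV fits are cross-checked against a deliberately naive, unconstrained
EM written here from scratch (same initial responsibilities), and the
closed-form G=1 Gaussian MLE anchors the likelihood scale.
"""

import numpy as np
import pytest
from scipy.special import logsumexp

import morphodelim as md
from morphodelim.gmm import FAMILIES, ward_init


def oracle_unconstrained_em(X, z, max_iter=5000, tol=1e-10):
    """Plain full-covariance EM, written independently of the package."""
    n, d = X.shape
    G = z.shape[1]
    ll_prev = -np.inf
    for _ in range(max_iter):
        nk = z.sum(axis=0)
        mu = (z.T @ X) / nk[:, None]
        covs = []
        for k in range(G):
            dev = X - mu[k]
            covs.append((z[:, k, None] * dev).T @ dev / nk[k])
        pi = nk / n
        ld = np.empty((n, G))
        for k in range(G):
            sign, logdet = np.linalg.slogdet(covs[k])
            iv = np.linalg.inv(covs[k])
            dev = X - mu[k]
            ld[:, k] = np.log(pi[k]) - 0.5 * (
                d * np.log(2 * np.pi) + logdet + np.einsum("ij,jk,ik->i", dev, iv, dev))
        norm = logsumexp(ld, axis=1)
        ll = float(norm.sum())
        z = np.exp(ld - norm[:, None])
        if ll - ll_prev < tol * (1 + abs(ll)):
            return ll
        ll_prev = ll
    return ll


def mvn_loglik(X, mean, cov):
    n, d = X.shape
    sign, logdet = np.linalg.slogdet(cov)
    iv = np.linalg.inv(cov)
    dev = X - mean
    return float(-0.5 * (n * d * np.log(2 * np.pi) + n * logdet
                         + np.einsum("ij,jk,ik->", dev, iv, dev)))


class TestParameterCounts:
    @pytest.mark.parametrize(
        "family,G,d,expected",
        [
            ("EII", 2, 3, 8),        # (G-1)=1 + means 6 + lambda 1
            ("VVV", 2, 2, 11),       # 1 + 4 + 2*3
            ("EEE", 3, 2, 11),       # 2 + 6 + 3
            ("VVI", 3, 4, 26),       # 2 + 12 + 12
            ("VEV", 2, 3, 17),       # 1 + 6 + (2 + 2 + 2*3)
        ],
    )
    def test_enumeration(self, family, G, d, expected):
        assert md.count_params(family, G, d) == expected

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            md.count_params("ZZZ", 2, 2)

    def test_g1_families_never_exceed_vvv(self):
        for fam in FAMILIES:
            assert md.count_params(fam, 1, 5) <= md.count_params("VVV", 1, 5)


class TestBIC:
    def test_univariate_hand_example(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        fit = md.fit_gmm(X, 1, "EEE")
        # closed form: mu=0.5, sigma2=0.25 (ML), each (x-mu)^2/sigma2 = 1
        ll = -0.5 * (4 * np.log(2 * np.pi * 0.25) + 4)
        assert fit.loglik == pytest.approx(ll, abs=1e-10)
        assert fit.n_params == 2
        assert fit.bic == pytest.approx(2 * ll - 2 * np.log(4), abs=1e-10)
        assert md.bic_of(fit) == pytest.approx(fit.bic)

    def test_penalty_linearity(self, overlapping_data):
        f1 = md.fit_gmm(overlapping_data, 1, "EII")
        # same loglik, inflated parameter count: BIC drops by delta_k * ln n
        delta = 5
        fake = 2 * f1.loglik - (f1.n_params + delta) * np.log(f1.n)
        assert f1.bic - fake == pytest.approx(delta * np.log(f1.n))

    def test_specimen_order_invariance(self, overlapping_data):
        X = overlapping_data
        perm = np.random.default_rng(1).permutation(X.shape[0])
        f = md.fit_gmm(X, 1, "VVV")
        g = md.fit_gmm(X[perm], 1, "VVV")
        assert f.bic == pytest.approx(g.bic, rel=1e-12)


class TestEM:
    def test_g1_closed_form_mle(self, overlapping_data):
        X = overlapping_data
        for fam in ("EEE", "VVV"):
            fit = md.fit_gmm(X, 1, fam)
            mu = X.mean(axis=0)
            S = np.cov(X.T, bias=True)
            np.testing.assert_allclose(fit.means[0], mu, atol=1e-12)
            np.testing.assert_allclose(fit.covariances[0], S, atol=1e-12)
            assert fit.loglik == pytest.approx(mvn_loglik(X, mu, S), abs=1e-8)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_loglik_monotone_every_iteration(self, overlapping_data, family):
        fit = md.fit_gmm(overlapping_data, 2, family, seed=0)
        tr = np.asarray(fit.loglik_trace)
        drops = np.diff(tr) < -1e-9 * np.maximum(1.0, np.abs(tr[1:]))
        assert not drops.any()

    def test_vvv_matches_unconstrained_oracle(self, overlapping_data):
        X = overlapping_data
        z0 = np.zeros((X.shape[0], 2))
        z0[np.arange(X.shape[0]), ward_init(X, 2)] = 1.0
        mine = md.fit_gmm(X, 2, "VVV", init=z0.copy(), tol=1e-10, max_iter=5000)
        theirs = oracle_unconstrained_em(X, z0.copy())
        assert mine.loglik == pytest.approx(theirs, abs=1e-6)

    def test_eii_lambda_is_mean_within_cluster_variance(self, two_cluster_data):
        X, _ = two_cluster_data
        fit = md.fit_gmm(X, 2, "EII", seed=0)
        z = fit.responsibilities
        nk = z.sum(axis=0)
        tr = 0.0
        for k in range(2):
            dev = X - fit.means[k]
            tr += float(np.sum(z[:, k, None] * dev * dev))
        lam = tr / (X.shape[0] * X.shape[1])
        assert fit.covariances[0][0, 0] == pytest.approx(lam, rel=1e-10)

    def test_family_nesting_from_shared_init(self, overlapping_data):
        X = overlapping_data
        z0 = np.zeros((X.shape[0], 2))
        z0[np.arange(X.shape[0]), ward_init(X, 2)] = 1.0
        ll = {fam: md.fit_gmm(X, 2, fam, init=z0.copy()).loglik
              for fam in ("EEE", "VEE", "VVV", "EEI", "VVI")}
        eps = 1e-4
        assert ll["VVV"] >= ll["VEE"] - eps >= ll["EEE"] - 2 * eps
        assert ll["VVI"] >= ll["EEI"] - eps

    def test_shared_entities_bitwise_identical(self, two_cluster_data):
        X, _ = two_cluster_data
        for fam in ("EII", "EEI", "EEE"):
            fit = md.fit_gmm(X, 2, fam, seed=0)
            assert np.array_equal(fit.covariances[0], fit.covariances[1])
        # VEI: shapes proportional across components
        fit = md.fit_gmm(X, 2, "VEI", seed=0)
        a0, a1 = np.diag(fit.covariances[0]), np.diag(fit.covariances[1])
        np.testing.assert_allclose(a0 / np.prod(a0) ** (1 / 3),
                                   a1 / np.prod(a1) ** (1 / 3), rtol=1e-8)
        # VVE: shared orientation diagonalises both covariances
        fit = md.fit_gmm(X, 2, "VVE", seed=0)
        vals, vecs = np.linalg.eigh(fit.covariances[0])
        off = vecs.T @ fit.covariances[1] @ vecs
        assert np.max(np.abs(off - np.diag(np.diag(off)))) < 1e-8

    def test_parameter_recovery_vee(self):
        rng = np.random.default_rng(0)
        C = np.array([[1.0, 0.4, 0.0, 0.0], [0.4, 1.0, 0.2, 0.0],
                      [0.0, 0.2, 1.0, 0.1], [0.0, 0.0, 0.1, 1.0]])
        mu1 = np.zeros(4)
        mu2 = np.full(4, 3.0)          # 6 sigma along each axis
        X = np.vstack([rng.multivariate_normal(mu1, 0.25 * C, 200),
                       rng.multivariate_normal(mu2, 0.5 * C, 200)])
        truth = np.array([0] * 200 + [1] * 200)
        fit = md.fit_gmm(X, 2, "VEE", seed=0)
        order = np.argsort(fit.means[:, 0])
        means = fit.means[order]
        assert np.linalg.norm(means[0] - mu1) < 0.15
        assert np.linalg.norm(means[1] - mu2) < 0.15
        pred = np.take(np.argsort(order), fit.classification)
        assert np.mean(pred == truth) >= 0.99

    def test_responsibilities_row_stochastic(self, two_cluster_data):
        X, _ = two_cluster_data
        fit = md.fit_gmm(X, 3, "VVI", seed=0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert fit.proportions.sum() == pytest.approx(1.0)

    def test_n_must_exceed_g(self):
        with pytest.raises(ValueError, match="n > G"):
            md.fit_gmm(np.zeros((3, 2)) + np.arange(3)[:, None], 3, "EII")
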