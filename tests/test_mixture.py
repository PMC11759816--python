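"""Constrained Gaussian mixtures: analytic oracles, recovery, mclust cross-check."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from otogeo.mixture import (bic_select, em_fit, n_free_parameters,
                            prepare_signatures, proportion_se)


class TestSingleComponentOracle:
    def test_matches_closed_form_mle(self, rng):
        X = rng.normal(size=(60, 3))
        fit = em_fit(X, 1, "VVV", n_restarts=1, seed=0)
        mu = X.mean(axis=0)
        S = (X - mu).T @ (X - mu) / len(X)
        assert np.allclose(fit.means[0], mu, atol=1e-10)
        assert np.allclose(fit.covariances[0], S, atol=1e-8)
        ll_ref = multivariate_normal(mu, S).logpdf(X).sum()
        assert fit.loglik == pytest.approx(ll_ref, rel=1e-10)
        assert fit.bic == pytest.approx(2 * ll_ref - n_free_parameters(1, 3, "VVV") * np.log(60))

    @pytest.mark.parametrize("model", ["VVV", "VEV", "VVE"])
    def test_all_models_agree_for_one_component(self, model, rng):
        X = rng.normal(size=(40, 2))
        fit = em_fit(X, 1, model, n_restarts=1, seed=0)
        ref = em_fit(X, 1, "VVV", n_restarts=1, seed=0)
        assert fit.loglik == pytest.approx(ref.loglik, rel=1e-8)


class TestParameterCounts:
    # hand enumeration: means G*d; weights G-1; covariance by family
    @pytest.mark.parametrize("G,d,model,expected", [
        (2, 2, "VVV", 11),   # 4 means + 1 weight + 2*3 covariances
        (2, 3, "VEV", 17),   # 6 + 1 + (2 vol + 2 shape + 2*3 orientation)
        (2, 3, "VVE", 16),   # 6 + 1 + (2 vol + 4 shape + 3 orientation)
        (3, 2, "VVE", 15),   # 6 + 2 + (3 vol + 3 shape + 1 orientation)
        (1, 4, "VVV", 14),   # 4 + 0 + 10
    ])
    def test_free_parameters_match_hand_count(self, G, d, model, expected):
        assert n_free_parameters(G, d, model) == expected


class TestRecovery:
    def test_well_separated_two_sources(self, rng):
        X = np.vstack([rng.normal([0, 0], 1.0, size=(140, 2)),
                       rng.normal([8, 8], 1.0, size=(60, 2))])
        truth = np.array([0] * 140 + [1] * 60)
        fit = em_fit(X, 2, "VVV", n_restarts=5, seed=1)
        assert np.allclose(sorted(fit.proportions), [0.3, 0.7], atol=0.02)
        labels = fit.labels
        agree = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agree >= 0.99

    @pytest.mark.parametrize("model", ["VEV", "VVE"])
    def test_constrained_models_recover_structure(self, model, rng):
        cov1 = np.array([[2.0, 0.0], [0.0, 0.3]])
        cov2 = 4.0 * cov1  # same shape/orientation, larger volume
        X = np.vstack([rng.multivariate_normal([0, 0], cov1, 150),
                       rng.multivariate_normal([10, 0], cov2, 150)])
        fit = em_fit(X, 2, model, n_restarts=5, seed=0)
        vols = np.sort([np.linalg.det(c) ** 0.5 for c in fit.covariances])
        assert vols[1] / vols[0] == pytest.approx(4.0, rel=0.35)

    def test_same_seed_identical_fit(self, rng):
        X = rng.normal(size=(80, 2))
        a = em_fit(X, 2, "VEV", n_restarts=4, seed=3)
        b = em_fit(X, 2, "VEV", n_restarts=4, seed=3)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.proportions, b.proportions)
        assert a.loglik == b.loglik

    def test_components_sorted_by_descending_weight(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(150, 2)), rng.normal(6, 1, size=(50, 2))])
        fit = em_fit(X, 2, "VVV", n_restarts=3, seed=0)
        assert fit.proportions[0] >= fit.proportions[1]
        assert np.all(np.diff(fit.proportions) <= 0)


class TestBicSelection:
    def test_bic_ranks_and_deltas(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(120, 2)), rng.normal(7, 1, size=(80, 2))])
        fits = bic_select(X, range(1, 4), n_restarts=3, seed=0)
        bics = [f.bic for f in fits]
        assert bics == sorted(bics, reverse=True)
        assert fits[0]._delta_bic == 0.0
        assert all(f._delta_bic >= 0 for f in fits)
        assert fits[0].G == 2

    def test_single_gaussian_prefers_one_source(self, rng):
        X = rng.normal(size=(200, 2))
        fits = bic_select(X, range(1, 3), n_restarts=3, seed=1)
        assert fits[0].G == 1


class TestAgainstMclust:
    """Cross-check loglik and BIC against the R reference implementation."""

    def test_loglik_and_bic_match_reference(self, tmp_path, rng):
        X = np.vstack([rng.normal([0, 0], 1.0, size=(120, 2)),
                       rng.normal([6, 3], 1.5, size=(80, 2))])
        csv = tmp_path / "X.csv"
        np.savetxt(csv, X, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(mclust))
            X <- as.matrix(read.csv("{csv}", header=FALSE))
            for (m in c("VVV","VEV","VVE")) {{
              fit <- Mclust(X, G=2, modelNames=m, verbose=FALSE)
              cat(m, fit$loglik, fit$bic, "\\n")
            }}
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             timeout=240)
        assert out.returncode == 0, out.stderr
        ref = {}
        for line in out.stdout.strip().splitlines():
            name, ll, bic = line.split()
            ref[name] = (float(ll), float(bic))
        for model in ("VVV", "VEV", "VVE"):
            fit = em_fit(X, 2, model, n_restarts=6, seed=0)
            ll_ref, bic_ref = ref[model]
            # same optimum (or ours mildly better from extra restarts)
            assert fit.loglik >= ll_ref - 0.05
            assert fit.loglik == pytest.approx(ll_ref, abs=max(0.05, 5e-4 * abs(ll_ref)))
            assert fit.bic == pytest.approx(bic_ref, abs=max(0.1, 1e-3 * abs(bic_ref)))


class TestProportionSE:
    def test_single_source_has_zero_se(self, rng):
        X = rng.normal(size=(50, 2))
        fit = em_fit(X, 1, "VVV", n_restarts=1, seed=0)
        assert proportion_se(fit, X, B=60, seed=0).tolist() == [0.0]

    def test_bootstrap_se_near_binomial_for_clean_mixture(self, rng):
        p, n = 0.3, 150
        labels = rng.random(n) < p
        X = np.where(labels, rng.normal(10, 1, n), rng.normal(0, 1, n))[:, None]
        fit = em_fit(X, 2, "VVV", n_restarts=3, seed=0)
        se = proportion_se(fit, X, B=80, seed=1, n_restarts=2)
        ref = np.sqrt(p * (1 - p) / n)
        assert se[0] == pytest.approx(ref, rel=0.25)

    def test_low_b_warns(self, rng):
        X = rng.normal(size=(40, 1))
        fit = em_fit(X, 1, "VVV", n_restarts=1, seed=0)
        with pytest.warns(UserWarning, match="B=10"):
            proportion_se(fit, X, B=10, seed=0)

    def test_fixed_seed_reproducible(self, rng):
        X = np.concatenate([rng.normal(0, 1, 60), rng.normal(8, 1, 40)])[:, None]
        fit = em_fit(X, 2, "VVV", n_restarts=2, seed=0)
        a = proportion_se(fit, X, B=50, seed=4, n_restarts=1)
        b = proportion_se(fit, X, B=50, seed=4, n_restarts=1)
        assert np.array_equal(a, b)


class TestPrepareSignatures:
    def test_log_and_zscore(self):
        import pandas as pd

        df = pd.DataFrame({"Sr": [100.0, 1000.0, 10000.0], "d18O": [3.0, 4.0, 5.0]})
        Z, names = prepare_signatures(df)
        assert names == ["Sr", "d18O"]
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)
        # element column is log-spaced, so standardized values are equispaced
        assert np.allclose(np.diff(Z[:, 0]), np.diff(Z[:, 0])[0])

    def test_nonpositive_element_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="non-positive"):
            prepare_signatures(pd.DataFrame({"Sr": [1.0, -2.0]}))
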