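"""Finite Gaussian mixtures with uneven-volume covariance parameterizations.

Nursery sources are modelled as components of a multivariate Gaussian mixture
fitted to nuclear-region signatures by EM.  Component covariances follow the
eigen-decomposition parameterization Sigma_g = lambda_g D_g A_g D_g', with the
volume lambda_g always free ("uneven-volume" family) and equality constraints
defining the model:

* VVV - volume, shape and orientation all vary (unconstrained);
* VEV - shared shape A, per-component volume and orientation;
* VVE - shared orientation D, per-component volume and shape (fitted by an
  iterative majorize-minimize update of the common orthogonal basis).

Model selection maximizes BIC = 2 loglik - m ln n (the mclust sign convention,
so reported values are typically negative and higher is better) across a grid
of component counts and covariance models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

log = logging.getLogger("otogeo")

__all__ = [
    "MixtureFit",
    "ConstrainedGaussianMixture",
    "em_fit",
    "bic_select",
    "proportion_se",
    "n_free_parameters",
    "prepare_signatures",
]

_MODELS = ("VVV", "VEV", "VVE")


@dataclass
class MixtureFit:
    """Canonicalized mixture estimate (components sorted by descending weight)."""

    G: int
    covariance_model: str
    proportions: np.ndarray
    means: np.ndarray  # (G, d)
    covariances: np.ndarray  # (G, d, d)
    loglik: float
    bic: float
    n: int
    converged: bool
    n_restarts: int
    seed: int | None
    proportion_se: np.ndarray | None = None
    responsibilities: np.ndarray | None = field(default=None, repr=False)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    @property
    def delta_bic(self) -> float | None:
        return getattr(self, "_delta_bic", None)


def n_free_parameters(G: int, d: int, model: str) -> int:
    """Free-parameter count m for BIC: means + weights + covariance family."""
    base = G * d + (G - 1)
    if model == "VVV":
        cov = G * d * (d + 1) // 2
    elif model == "VEV":
        cov = G + (d - 1) + G * d * (d - 1) // 2
    elif model == "VVE":
        cov = G + G * (d - 1) + d * (d - 1) // 2
    else:
        raise ValueError(f"unknown covariance model {model!r}")
    return base + cov


# ---------------------------------------------------------------------------
# M-step covariance updates
# ---------------------------------------------------------------------------

def _mstep_vvv(W: np.ndarray, nk: np.ndarray) -> np.ndarray:
    return W / nk[:, None, None]


def _mstep_vev(W: np.ndarray, nk: np.ndarray, n_inner: int = 10) -> np.ndarray:
    """Shared shape A (det 1), free volume and orientation per component."""
    G, d, _ = W.shape
    omegas = np.empty((G, d))
    Ds = np.empty((G, d, d))
    for g in range(G):
        vals, vecs = np.linalg.eigh(W[g])
        order = np.argsort(vals)[::-1]
        omegas[g] = np.maximum(vals[order], 1e-300)
        Ds[g] = vecs[:, order]
    lam = np.ones(G)
    A = np.ones(d)
    for _ in range(n_inner):
        A_new = np.sum(omegas / lam[:, None], axis=0)
        A_new = np.maximum(A_new, 1e-300)
        A_new = A_new / np.exp(np.mean(np.log(A_new)))  # det 1
        lam_new = np.sum(omegas / A_new[None, :], axis=1) / (nk * d)
        if np.allclose(A_new, A, rtol=1e-10) and np.allclose(lam_new, lam, rtol=1e-10):
            A, lam = A_new, lam_new
            break
        A, lam = A_new, lam_new
    cov = np.empty_like(W)
    for g in range(G):
        cov[g] = Ds[g] @ np.diag(lam[g] * A) @ Ds[g].T
    return cov


def _mstep_vve(W: np.ndarray, nk: np.ndarray, D: np.ndarray | None,
               n_inner: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Shared orientation D, free volume and shape per component.

    The common orthogonal basis minimizes sum_g tr(A_g^-1 D' (W_g/lambda_g) D)
    over the orthogonal group; each MM step majorizes the objective by its
    tangent and solves the resulting Procrustes problem in closed form.
    """
    G, d, _ = W.shape
    if D is None:
        vals, vecs = np.linalg.eigh(W.sum(axis=0))
        D = vecs[:, np.argsort(vals)[::-1]]
    lam = np.ones(G)
    A = np.ones((G, d))
    for _ in range(n_inner):
        # shape/volume given D
        F = np.einsum("li,glm,mj->gij", D, W, D)
        f = np.maximum(np.einsum("gii->gi", F), 1e-300)
        geo = np.exp(np.mean(np.log(f), axis=1))
        A = f / geo[:, None]
        lam = geo / nk
        # D given shapes: MM with PSD surrogate P_g = kappa_g I - C_g
        M = np.zeros((d, d))
        for g in range(G):
            C = W[g] / lam[g]
            kappa = float(np.linalg.eigvalsh(C)[-1]) + 1e-12
            P = kappa * np.eye(d) - C
            M += P @ D / A[g][None, :]
        U, _, Vt = np.linalg.svd(M)
        D_new = U @ Vt
        if np.allclose(np.abs(D_new.T @ D), np.eye(d), atol=1e-12):
            D = D_new
            break
        D = D_new
    cov = np.einsum("il,gl,jl->gij", D, lam[:, None] * A, D)
    return cov, D


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = np.linalg.solve(L, (X - mean).T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(diff**2, axis=0))


class ConvergenceError(RuntimeError):
    pass


class ConstrainedGaussianMixture(BaseEstimator):
    """EM-fitted Gaussian mixture with a V?? covariance constraint.

    Parameters
    ----------
    n_components : int
        Number of sources G.
    covariance_model : {"VVV", "VEV", "VVE"}
    n_restarts : int
        Initializations tried: the first is a Ward hierarchical-agglomeration
        partition, the rest are random responsibility draws; the fit with the
        best log-likelihood wins.
    tol : float
        Relative log-likelihood convergence tolerance.
    random_state : int or None

    Attributes (after fit)
    ----------------------
    weights_, means_, covariances_, loglik_, bic_, converged_,
    responsibilities_ -- components sorted by descending weight.
    """

    def __init__(self, n_components: int = 2, covariance_model: str = "VVV",
                 n_restarts: int = 20, tol: float = 1e-8, max_iter: int = 1000,
                 random_state: int | None = None, reg_covar: float = 1e-9,
                 min_eig_ratio: float = 1e-3):
        self.n_components = n_components
        self.covariance_model = covariance_model
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.reg_covar = reg_covar
        self.min_eig_ratio = min_eig_ratio

    # -- internals ---------------------------------------------------------

    def _estep(self, X, weights, means, covs):
        G = len(weights)
        logp = np.empty((X.shape[0], G))
        for g in range(G):
            logp[:, g] = np.log(weights[g]) + _log_gaussian(X, means[g], covs[g])
        norm = logsumexp(logp, axis=1)
        return np.exp(logp - norm[:, None]), float(np.sum(norm))

    def _mstep(self, X, resp, D_shared):
        n, d = X.shape
        G = resp.shape[1]
        nk = resp.sum(axis=0)
        # ill-posed M-step: a free covariance needs more weight than dimensions
        min_nk = d + 1.0 if self.covariance_model == "VVV" else 3.0
        if np.any(nk < min_nk):
            raise ConvergenceError("component too small for covariance estimation")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        W = np.empty((G, d, d))
        for g in range(G):
            diff = X - means[g]
            W[g] = (resp[:, g][:, None] * diff).T @ diff
        reg = self.reg_covar * np.eye(d)
        if self.covariance_model == "VVV":
            covs = _mstep_vvv(W, nk)
        elif self.covariance_model == "VEV":
            covs = _mstep_vev(W + reg[None], nk)
        elif self.covariance_model == "VVE":
            covs, D_shared = _mstep_vve(W + reg[None], nk, D_shared)
        else:
            raise ValueError(f"unknown covariance model {self.covariance_model!r}")
        covs = covs + reg[None]
        # Hathaway-style relative bound: reject quasi-singular components that
        # drive the unbounded-likelihood pathology of ML mixtures
        eigs = np.array([np.linalg.eigvalsh(c) for c in covs])
        if eigs[:, 0].min() < self.min_eig_ratio * eigs[:, -1].max():
            raise ConvergenceError("quasi-singular component covariance")
        return weights, means, covs, D_shared

    def _run_em(self, X, resp0):
        ll_prev = -np.inf
        resp = resp0
        D_shared = None
        weights = means = covs = None
        converged = False
        for _ in range(self.max_iter):
            weights, means, covs, D_shared = self._mstep(X, resp, D_shared)
            resp, ll = self._estep(X, weights, means, covs)
            # EM monotonicity guard; inner MM updates keep this exact up to
            # numerical noise
            if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
                raise ConvergenceError(f"log-likelihood decreased: {ll_prev} -> {ll}")
            if abs(ll - ll_prev) <= self.tol * max(1.0, abs(ll)):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return weights, means, covs, resp, float(ll_prev), converged

    def _initial_resps(self, X, rng):
        n = X.shape[0]
        G = self.n_components
        inits = []
        if G == 1:
            return [np.ones((n, 1))]
        # model-based start: Ward agglomeration on standardized coordinates
        Z = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        labels = fcluster(ward(pdist(Z)), t=G, criterion="maxclust")
        resp = np.full((n, G), 1e-10)
        resp[np.arange(n), labels - 1] = 1.0
        inits.append(resp / resp.sum(1, keepdims=True))
        for _ in range(max(self.n_restarts - 1, 0)):
            r = rng.dirichlet(np.ones(G), size=n)
            inits.append(r)
        return inits

    # -- public API ---------------------------------------------------------

    def fit(self, X, y=None) -> "ConstrainedGaussianMixture":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_samples, n_features)")
        n, d = X.shape
        if n <= self.n_components:
            raise ValueError(f"need n > G (n={n}, G={self.n_components})")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        rng = np.random.default_rng(self.random_state)

        best = None
        failures = 0
        for resp0 in self._initial_resps(X, rng):
            try:
                out = self._run_em(X, resp0)
            except (ConvergenceError, np.linalg.LinAlgError):
                failures += 1
                continue
            if best is None or out[4] > best[4]:
                best = out
        if best is None:
            raise ConvergenceError(
                f"all {failures} EM starts failed (degenerate components); "
                "consider fewer components or more data"
            )
        weights, means, covs, resp, ll, converged = best
        order = np.argsort(weights)[::-1]
        self.weights_ = weights[order]
        self.means_ = means[order]
        self.covariances_ = covs[order]
        self.responsibilities_ = resp[:, order]
        self.loglik_ = ll
        m = n_free_parameters(self.n_components, d, self.covariance_model)
        self.n_parameters_ = m
        self.bic_ = 2.0 * ll - m * np.log(n)
        self.converged_ = converged
        self.n_samples_ = n
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        resp, _ = self._estep(X, self.weights_, self.means_, self.covariances_)
        return resp

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        X = np.asarray(X, dtype=float)
        _, ll = self._estep(X, self.weights_, self.means_, self.covariances_)
        return ll / X.shape[0]

    def to_fit(self) -> MixtureFit:
        return MixtureFit(
            G=self.n_components,
            covariance_model=self.covariance_model,
            proportions=self.weights_.copy(),
            means=self.means_.copy(),
            covariances=self.covariances_.copy(),
            loglik=self.loglik_,
            bic=float(self.bic_),
            n=self.n_samples_,
            converged=self.converged_,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            responsibilities=self.responsibilities_.copy(),
        )


def em_fit(X, G: int, covariance_model: str = "VVV", n_restarts: int = 20,
           tol: float = 1e-8, max_iter: int = 1000, seed: int | None = None) -> MixtureFit:
    """Fit one (G, model) mixture and return the canonicalized estimate."""
    est = ConstrainedGaussianMixture(
        n_components=G, covariance_model=covariance_model, n_restarts=n_restarts,
        tol=tol, max_iter=max_iter, random_state=seed,
    )
    return est.fit(np.asarray(X, dtype=float)).to_fit()


def bic_select(X, G_range=range(1, 6), models: tuple[str, ...] = _MODELS,
               n_restarts: int = 20, seed: int | None = None, **em_kwargs) -> list[MixtureFit]:
    """Fit every (G, model) pair and rank by BIC (higher = better).

    Each fit's ``_delta_bic`` is BIC_best - BIC_fit >= 0.
    """
    X = np.asarray(X, dtype=float)
    fits = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(list(G_range)) * len(models))
    k = 0
    for G in G_range:
        for model in models:
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            try:
                fits.append(em_fit(X, G, model, n_restarts=n_restarts,
                                   seed=sub_seed, **em_kwargs))
            except (ConvergenceError, ValueError) as err:
                log.warning("mixture fit G=%d model=%s failed: %s", G, model, err)
    if not fits:
        raise ConvergenceError("no mixture configuration could be fitted")
    fits.sort(key=lambda f: f.bic, reverse=True)
    best = fits[0].bic
    for f in fits:
        f._delta_bic = best - f.bic
    return fits


def proportion_se(fit: MixtureFit, X, B: int = 999, seed: int | None = None,
                  n_restarts: int = 2) -> np.ndarray:
    """Nonparametric bootstrap SEs of the mixing proportions.

    Resamples rows with replacement, refits the selected (G, model), matches
    components to the original by proximity of means, and reports the SD of
    each component's proportion over the B replicates.
    """
    if B < 50:
        warnings.warn(f"bootstrap with B={B} < 50 replicates is unreliable", stacklevel=2)
    X = np.asarray(X, dtype=float)
    if fit.G == 1:
        fit.proportion_se = np.zeros(1)
        return fit.proportion_se
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    props = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            bf = em_fit(X[idx], fit.G, fit.covariance_model, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)))
        except (ConvergenceError, ValueError):
            continue
        # match bootstrap components to the original ones by mean proximity
        cost = np.linalg.norm(fit.means[:, None, :] - bf.means[None, :, :], axis=-1)
        from scipy.optimize import linear_sum_assignment

        _, cols = linear_sum_assignment(cost)
        props.append(bf.proportions[cols])
    if len(props) < 2:
        raise ConvergenceError("bootstrap failed on nearly all replicates")
    fit.proportion_se = np.std(np.asarray(props), axis=0, ddof=1)
    return fit.proportion_se


def prepare_signatures(df, log_elements: bool = True, isotope_cols=("d18O", "d13C")):
    """Column-wise transform of a signature matrix before mixture fitting.

    Elemental ratios are positive and span orders of magnitude, so they are
    log-transformed and z-scored; isotope columns (already in permil) are
    z-scored untransformed.  Returns (array, column names).
    """
    import pandas as pd

    df = pd.DataFrame(df).copy()
    cols = list(df.columns)
    for c in cols:
        x = df[c].astype(float)
        if log_elements and c not in isotope_cols:
            if (x <= 0).any():
                raise ValueError(f"column {c!r} has non-positive values; cannot log")
            x = np.log(x)
        sd = x.std(ddof=0)
        df[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return df.to_numpy(dtype=float), cols
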