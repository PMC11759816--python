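"""Juvenile-vs-adult signature comparisons.

Two complementary analyses of nuclear (juvenile) versus marginal (adult)
otolith chemistry:

* univariate paired contrasts: an intercept-only model of within-fish
  (adult - juvenile) differences, optionally with a fishing-event random
  intercept fitted by REML through a one-dimensional profile optimization of
  the variance ratio; the intercept's t statistic tests H0: no stage change;
* PERMANOVA on a Mahalanobis distance matrix, with the fishing event entered
  as a fixed first term and permutations of region labels restricted to
  within-fish swaps.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "PairedContrast",
    "PermanovaResult",
    "paired_contrast",
    "stage_ratio",
    "percent_change",
    "mahalanobis_gram",
    "permanova",
]


@dataclass
class PairedContrast:
    variable: str
    mean_juvenile: float
    mean_adult: float
    sd_juvenile: float
    sd_adult: float
    t_statistic: float
    df: int
    p_value: float
    n_pairs: int
    event_sd: float = 0.0
    residual_sd: float = 0.0


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    n_samples: int


# ---------------------------------------------------------------------------
# paired contrasts
# ---------------------------------------------------------------------------

def _reml_intercept(d: np.ndarray, events: np.ndarray):
    """Intercept, SE and variance components of d ~ 1 + (1|event), by REML.

    Profiles the restricted likelihood over the variance ratio
    theta = sigma_event^2 / sigma_resid^2 (one-dimensional search), then
    solves the generalized least squares intercept in closed form.
    """
    n = len(d)
    uniq, inv = np.unique(events, return_inverse=True)
    n_groups = len(uniq)
    group_n = np.bincount(inv)
    group_sum = np.bincount(inv, weights=d)

    def gls(theta):
        # V = I + theta Z Z' has blockwise inverse; weights per group
        # 1' V^-1 1 = sum_j n_j / (1 + theta n_j)
        denom = 1.0 + theta * group_n
        one_v_one = np.sum(group_n / denom)
        one_v_d = np.sum(group_sum / denom) + 0.0
        # within-group parts: d' V^-1 d = sum d_i^2 - theta sum_j S_j^2/(1+theta n_j)
        d_v_d = np.sum(d * d) - theta * np.sum(group_sum**2 / denom)
        mu = one_v_d / one_v_one
        rss = d_v_d - 2 * mu * one_v_d + mu * mu * one_v_one
        logdet_v = np.sum(np.log(denom))
        return mu, one_v_one, rss, logdet_v

    def neg_restricted_ll(log_theta):
        theta = np.exp(log_theta)
        mu, ovo, rss, logdet = gls(theta)
        sigma2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(sigma2) + logdet + np.log(ovo) + (n - 1))

    if n_groups < 2:
        theta_hat = 0.0
    else:
        res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-10})
        theta_hat = float(np.exp(res.x))
        if neg_restricted_ll(-30.0) <= res.fun:  # boundary: no event variance
            theta_hat = 0.0
    mu, ovo, rss, _ = gls(theta_hat)
    sigma2 = rss / (n - 1)
    se = np.sqrt(sigma2 / ovo)
    return float(mu), float(se), float(sigma2), float(theta_hat * sigma2)


def paired_contrast(
    juvenile: np.ndarray,
    adult: np.ndarray,
    variable: str = "",
    events: np.ndarray | None = None,
    group_by_event: bool = False,
) -> PairedContrast:
    """Test the mean within-fish (adult - juvenile) difference against zero.

    Pairs with a missing value on either side are dropped.  With
    ``group_by_event`` a fishing-event random intercept is included (REML);
    the residual df stays n_pairs - 1, matching a paired t-test layout.
    """
    juvenile = np.asarray(juvenile, dtype=float)
    adult = np.asarray(adult, dtype=float)
    ok = np.isfinite(juvenile) & np.isfinite(adult)
    juvenile, adult = juvenile[ok], adult[ok]
    n = len(juvenile)
    if n < 3:
        raise ValueError(f"paired_contrast needs >= 3 complete pairs, got {n}")
    d = adult - juvenile

    if group_by_event:
        if events is None:
            raise ValueError("group_by_event requires event labels")
        ev = np.asarray(events)[ok]
        mu, se, sigma2, sigma2_event = _reml_intercept(d, ev)
    else:
        mu = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(n))
        sigma2, sigma2_event = float(np.var(d, ddof=1)), 0.0

    df = n - 1
    if se == 0.0:
        t = 0.0 if mu == 0.0 else np.inf * np.sign(mu)
    else:
        t = mu / se
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return PairedContrast(
        variable=variable,
        mean_juvenile=float(np.mean(juvenile)),
        mean_adult=float(np.mean(adult)),
        sd_juvenile=float(np.std(juvenile, ddof=1)),
        sd_adult=float(np.std(adult, ddof=1)),
        t_statistic=float(t),
        df=df,
        p_value=min(p, 1.0),
        n_pairs=n,
        event_sd=float(np.sqrt(sigma2_event)),
        residual_sd=float(np.sqrt(sigma2)),
    )


def stage_ratio(mean_adult: float, mean_juvenile: float) -> float:
    """Adult/juvenile mean ratio (how many times higher in the adult stage)."""
    return mean_adult / mean_juvenile


def percent_change(mean_juvenile: float, mean_adult: float) -> float:
    """Percent increase from the juvenile to the adult stage mean.

    Computed relative to the juvenile magnitude so that negative-valued
    variables (e.g. d13C in permil) report an increase as positive.
    """
    return 100.0 * (mean_adult - mean_juvenile) / abs(mean_juvenile)


# ---------------------------------------------------------------------------
# multivariate: Mahalanobis distances and PERMANOVA
# ---------------------------------------------------------------------------

def mahalanobis_gram(X: np.ndarray) -> np.ndarray:
    """Pairwise Mahalanobis distances under the total-sample covariance.

    d(i,j)^2 = (x_i - x_j)' S^-1 (x_i - x_j) with S the covariance of all
    rows pooled.  Requires n > p and non-singular S.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for a stable covariance (n={n}, p={p})")
    S = np.cov(X, rowvar=False)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "total-sample covariance is singular; reduce dimensions before "
            "computing Mahalanobis distances"
        ) from None
    W = np.linalg.solve(L, X.T).T  # whitened coordinates
    diff = W[:, None, :] - W[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(Xd: np.ndarray) -> np.ndarray:
    return Xd @ np.linalg.pinv(Xd)


def _dummies(labels: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(uniq)))
    Z[np.arange(len(labels)), inv] = 1.0
    return Z


def permanova(
    D: np.ndarray,
    groups,
    covariate=None,
    within=None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix (pseudo-F on squared distances).

    ``groups`` is the factor under test.  ``covariate`` enters first as a
    fixed term (sequential partition), absorbing e.g. fishing-event structure.
    ``within`` restricts permutations: group labels are shuffled only inside
    each ``within`` block (e.g. swapping nuclear/marginal within a fish).
    p = (1 + #{perm F >= observed F}) / (1 + n_perm).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be a square symmetric zero-diagonal distance matrix")
    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")

    G = _gower_center(D)
    total_ss = float(np.trace(G))
    ones = np.ones((n, 1))
    base = [ones] if covariate is None else [ones, _dummies(np.asarray(covariate))]
    X0 = np.hstack(base)
    H0 = _hat(X0)
    rank0 = np.linalg.matrix_rank(X0)

    def pseudo_f(g_labels):
        X1 = np.hstack(base + [_dummies(g_labels)])
        H1 = _hat(X1)
        rank1 = np.linalg.matrix_rank(X1)
        ss_g = float(np.sum((H1 - H0) * G.T))  # trace((H1-H0) G)
        ss_res = total_ss - float(np.sum(H1 * G.T))
        df_g = rank1 - rank0
        df_res = n - rank1
        if df_g == 0 or df_res == 0 or abs(ss_g) < 1e-12:
            return 0.0
        if ss_res < 1e-12:
            return np.inf
        return (ss_g / df_g) / (ss_res / df_res)

    f_obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    if within is not None:
        within = np.asarray(within)
        blocks = [np.nonzero(within == b)[0] for b in np.unique(within)]
    for _ in range(n_perm):
        if within is None:
            perm = rng.permutation(idx)
        else:
            perm = idx.copy()
            for blk in blocks:
                perm[blk] = rng.permutation(perm[blk])
        if pseudo_f(groups[perm]) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), p_value=float(p),
                           n_permutations=n_perm, n_samples=n)
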