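"""Seawater-d18O isoscape: covariate regression plus residual kriging.

The isoscape is fitted in two stages.  Stage one regresses observed seawater
d18O on salinity, temperature and depth through an additive penalized-spline
model (cubic B-splines per covariate, penalty weight chosen by generalized
cross-validation); its share of explained deviance is the headline diagnostic.
Stage two models the stage-one residuals as a spatial Gaussian process per
depth stratum with an exponential covariance (range, sill, nugget estimated by
maximum likelihood) and kriges them onto the grid.  Prediction mean is the
covariate fit plus the kriged residual; prediction variance adds the kriging
variance and the covariate-fit variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .isotopes import smow_to_vpdb
from .types import DepthStratum, EnvField, haversine_km

log = logging.getLogger("otogeo")

__all__ = ["ExponentialKriging", "Isoscape", "IsoscapeModel", "fit_isoscape",
           "interpolate_env"]


# ---------------------------------------------------------------------------
# Gaussian-process kriging with exponential covariance
# ---------------------------------------------------------------------------

class ExponentialKriging(BaseEstimator):
    """Kriging with covariance k(h) = sill * exp(-h/range) + nugget * 1{h=0}.

    Distances are great-circle kilometres between (lon, lat) sites.  With
    ``mean="constant"`` the constant is estimated by generalized least
    squares (ordinary kriging); with ``mean="zero"`` the prior mean is zero
    (simple kriging, the textbook GP posterior).  Unset covariance parameters
    are estimated by maximum likelihood.
    """

    def __init__(self, range_km: float | None = None, sill: float | None = None,
                 nugget: float | None = None, mean: str = "constant",
                 n_restarts: int = 3, random_state: int | None = None):
        self.range_km = range_km
        self.sill = sill
        self.nugget = nugget
        self.mean = mean
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _cov(self, H: np.ndarray, sill: float, rng_km: float) -> np.ndarray:
        return sill * np.exp(-H / rng_km)

    def _nll(self, params, H, y):
        rng_km, sill, nug = np.exp(params)
        K = self._cov(H, sill, rng_km) + nug * np.eye(len(y))
        try:
            c, low = cho_factor(K)
        except np.linalg.LinAlgError:
            return 1e10
        alpha = cho_solve((c, low), y)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return 0.5 * (y @ alpha + logdet + len(y) * np.log(2 * np.pi))

    def fit(self, X, y) -> "ExponentialKriging":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.X_ = X
        H = haversine_km(X[:, 0][:, None], X[:, 1][:, None], X[:, 0][None, :], X[:, 1][None, :])
        self.H_ = H

        mu = 0.0
        if self.mean == "constant":
            mu = float(np.mean(y))  # refined by GLS after covariance estimation
        resid = y - mu

        if self.range_km is None or self.sill is None or self.nugget is None:
            var0 = max(float(np.var(resid)), 1e-12)
            h_med = max(float(np.median(H[H > 0])) if np.any(H > 0) else 1.0, 1.0)
            rng = np.random.default_rng(self.random_state)
            best = None
            for k in range(self.n_restarts):
                jitter = rng.normal(0, 0.5, 3) if k else np.zeros(3)
                x0 = np.log([h_med, 0.7 * var0 + 1e-12, 0.3 * var0 + 1e-12]) + jitter
                res = minimize(self._nll, x0, args=(H, resid), method="Nelder-Mead",
                               options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
                if best is None or res.fun < best.fun:
                    best = res
            rng_km, sill, nug = np.exp(best.x)
            self.range_km_ = self.range_km if self.range_km is not None else float(rng_km)
            self.sill_ = self.sill if self.sill is not None else float(sill)
            self.nugget_ = self.nugget if self.nugget is not None else float(nug)
        else:
            self.range_km_ = float(self.range_km)
            self.sill_ = float(self.sill)
            self.nugget_ = float(self.nugget)

        K = self._cov(H, self.sill_, self.range_km_) + self.nugget_ * np.eye(len(y))
        for _ in range(6):
            try:
                self._chol_ = cho_factor(K)
                break
            except np.linalg.LinAlgError:
                infl = max(self.nugget_, 1e-10) * 10
                warnings.warn("covariance not positive definite; inflating nugget",
                              stacklevel=2)
                self.nugget_ += infl
                K += infl * np.eye(len(y))
        if self.mean == "constant":
            ones = np.ones(len(y))
            Ki1 = cho_solve(self._chol_, ones)
            mu = float(ones @ cho_solve(self._chol_, y) / (ones @ Ki1))
            self.mean_var_ = 1.0 / float(ones @ Ki1)
        else:
            mu = 0.0
            self.mean_var_ = 0.0
        self.mu_ = mu
        self.alpha_ = cho_solve(self._chol_, y - mu)
        self.y_ = y
        return self

    def predict(self, X, return_std: bool = False):
        X = np.asarray(X, dtype=float)
        Hs = haversine_km(X[:, 0][:, None], X[:, 1][:, None],
                          self.X_[:, 0][None, :], self.X_[:, 1][None, :])
        k_star = self._cov(Hs, self.sill_, self.range_km_)
        mean = self.mu_ + k_star @ self.alpha_
        if not return_std:
            return mean
        v = cho_solve(self._chol_, k_star.T)
        var = self.sill_ + self.nugget_ - np.sum(k_star * v.T, axis=1)
        if self.mean == "constant":
            # uncertainty of the GLS constant propagates into prediction
            ones = np.ones(len(self.y_))
            w = 1.0 - k_star @ cho_solve(self._chol_, ones)
            var = var + w**2 * self.mean_var_
        return mean, np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# smooth environmental interpolation (T / S fields from point observations)
# ---------------------------------------------------------------------------

def _local_linear(obs_xy: np.ndarray, obs_z: np.ndarray, pred_xy: np.ndarray,
                  bandwidth_km: float) -> np.ndarray:
    """Distance-weighted local plane fit; exact on planar truth."""
    out = np.empty(len(pred_xy))
    for i, (px, py) in enumerate(pred_xy):
        d = haversine_km(px, py, obs_xy[:, 0], obs_xy[:, 1])
        w = np.exp(-0.5 * (d / bandwidth_km) ** 2) + 1e-12
        A = np.column_stack([np.ones(len(obs_xy)), obs_xy[:, 0] - px, obs_xy[:, 1] - py])
        WA = A * w[:, None]
        beta, *_ = np.linalg.lstsq(WA.T @ A, WA.T @ obs_z, rcond=None)
        out[i] = beta[0]
    return out


def interpolate_env(obs: pd.DataFrame, variable: str, lon: np.ndarray, lat: np.ndarray,
                    strata: list[DepthStratum], bandwidth_km: float = 200.0,
                    min_obs: int = 10) -> EnvField:
    """Per-stratum smooth field from point observations (local regression).

    ``obs`` needs columns lon, lat, depth and ``variable``.  Strata with a
    single observation give a constant field with a warning; empty strata are
    flagged missing.  Leave-one-out RMSE per stratum is attached as
    ``field.loo_rmse``.
    """
    LON, LAT = np.meshgrid(lon, lat)
    pred_xy = np.column_stack([LON.ravel(), LAT.ravel()])
    values = np.full((len(strata), len(lat), len(lon)), np.nan)
    loo = {}
    for k, s in enumerate(strata):
        sel = obs[(obs["depth"] >= s.lower) & (obs["depth"] < s.upper)]
        if len(sel) == 0:
            warnings.warn(f"stratum {s.lower}-{s.upper} m: no observations", stacklevel=2)
            continue
        if len(sel) == 1:
            warnings.warn(f"stratum {s.lower}-{s.upper} m: single observation, "
                          "constant field", stacklevel=2)
            values[k] = float(sel[variable].iloc[0])
            continue
        if len(sel) < min_obs:
            warnings.warn(f"stratum {s.lower}-{s.upper} m: only {len(sel)} observations",
                          stacklevel=2)
        xy = sel[["lon", "lat"]].to_numpy()
        z = sel[variable].to_numpy(dtype=float)
        values[k] = _local_linear(xy, z, pred_xy, bandwidth_km).reshape(len(lat), len(lon))
        # leave-one-out at observation sites
        errs = []
        for i in range(len(sel)):
            mask = np.arange(len(sel)) != i
            zi = _local_linear(xy[mask], z[mask], xy[i:i + 1], bandwidth_km)[0]
            errs.append(z[i] - zi)
        loo[k] = float(np.sqrt(np.mean(np.square(errs))))
    out = EnvField(variable, np.asarray(lon), np.asarray(lat), strata, values)
    out.loo_rmse = loo  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# the isoscape itself
# ---------------------------------------------------------------------------

@dataclass
class Isoscape:
    """Gridded mean/sd of seawater d18O (permil VPDB) per cell and stratum."""

    lon: np.ndarray
    lat: np.ndarray
    strata: list[DepthStratum]
    mean: np.ndarray  # (n_strata, n_lat, n_lon)
    sd: np.ndarray
    deviance_explained: float = np.nan
    covariance_params: dict = field(default_factory=dict)  # per stratum

    def to_fields(self) -> EnvField:
        return EnvField("d18o_water", self.lon, self.lat, self.strata,
                        self.mean, variance=self.sd**2)

    @classmethod
    def from_field(cls, f: EnvField) -> "Isoscape":
        sd = np.sqrt(f.variance) if f.variance is not None else np.zeros_like(f.values)
        return cls(f.lon, f.lat, f.strata, f.values, sd)


class IsoscapeModel(BaseEstimator):
    """Two-stage isoscape fit: additive covariate splines + residual kriging.

    Parameters
    ----------
    spline_df : int
        Basis dimension per covariate smooth (cubic B-splines with interior
        knots at covariate quantiles).
    alphas : sequence of float
        Candidate shared penalty weights; chosen by GCV.
    year_window : (int, int) or None
        Observation years pooled into the fit (inclusive window).
    """

    def __init__(self, spline_df: int = 8, alphas=(0.01, 0.1, 1.0, 10.0, 100.0),
                 year_window: tuple[int, int] | None = None,
                 kriging_kwargs: dict | None = None, min_obs: int = 30):
        self.spline_df = spline_df
        self.alphas = alphas
        self.year_window = year_window
        self.kriging_kwargs = kriging_kwargs
        self.min_obs = min_obs

    def _design(self, obs: pd.DataFrame):
        from statsmodels.gam.api import BSplines

        X = obs[["salinity", "temperature", "depth"]].to_numpy(dtype=float)
        return BSplines(X, df=[self.spline_df] * 3, degree=[3] * 3,
                        include_intercept=False)

    def fit(self, obs: pd.DataFrame, y=None) -> "IsoscapeModel":
        """Fit to a water-observation table.

        Columns: lon, lat, depth, d18o_water, temperature, salinity, year,
        and ``scale`` ("SMOW" or "VPDB"); SMOW rows are converted on entry.
        """
        import statsmodels.api as sm
        from statsmodels.gam.api import GLMGam

        obs = obs.copy()
        if "scale" in obs:
            smow = obs["scale"].astype(str).str.upper() == "SMOW"
            obs.loc[smow, "d18o_water"] = smow_to_vpdb(obs.loc[smow, "d18o_water"])
            obs["scale"] = "VPDB"
        if self.year_window is not None and "year" in obs:
            lo, hi = self.year_window
            obs = obs[(obs["year"] >= lo) & (obs["year"] <= hi)]
        if len(obs) < self.min_obs:
            raise ValueError(f"isoscape fit needs >= {self.min_obs} observations, "
                             f"got {len(obs)}")
        self.obs_ = obs.reset_index(drop=True)
        y = self.obs_["d18o_water"].to_numpy(dtype=float)

        smoother = self._design(self.obs_)
        best = None
        for alpha in self.alphas:
            gam = GLMGam(y, np.ones((len(y), 1)), smoother=smoother,
                         alpha=[alpha] * 3, family=sm.families.Gaussian())
            res = gam.fit()
            resid = y - res.fittedvalues
            edof = float(res.df_model) + 1.0
            denom = max(len(y) - edof, 1.0)
            gcv = len(y) * float(np.sum(resid**2)) / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, alpha, res)
        self.gcv_, self.alpha_, self.gam_ = best
        self.smoother_ = smoother
        fitted = self.gam_.fittedvalues
        tss = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum((y - fitted) ** 2))
        self.deviance_explained_ = 1.0 - rss / tss if tss > 0 else np.nan

        # stage two: residual kriging per stratum (pooled fall-back)
        resid = y - fitted
        self.kriger_ = {}
        kw = dict(self.kriging_kwargs or {})
        xy = self.obs_[["lon", "lat"]].to_numpy(dtype=float)
        self._resid_ = resid
        self._xy_ = xy
        self._pooled_kriger_ = ExponentialKriging(mean="zero", **kw).fit(xy, resid)
        return self

    def _covariate_prediction(self, sal, temp, depth):
        """Stage-one mean and variance on arbitrary covariate vectors."""
        import statsmodels.api as sm

        Xn = np.column_stack([np.asarray(sal, float).ravel(),
                              np.asarray(temp, float).ravel(),
                              np.asarray(depth, float).ravel()])
        # clip to the observed covariate support: B-spline bases do not
        # extrapolate
        lo = self.obs_[["salinity", "temperature", "depth"]].min().to_numpy()
        hi = self.obs_[["salinity", "temperature", "depth"]].max().to_numpy()
        Xc = np.clip(Xn, lo, hi)
        basis = self.smoother_.transform(Xc)
        exog = np.column_stack([np.ones(len(Xc)), basis])
        mean = exog @ self.gam_.params
        cov = self.gam_.cov_params()
        var = np.einsum("ij,jk,ik->i", exog, cov, exog)
        return mean, np.maximum(var, 0.0)

    def predict_grid(self, temperature: EnvField, salinity: EnvField) -> Isoscape:
        """Krige onto the grid of the supplied environmental fields."""
        lon, lat, strata = temperature.lon, temperature.lat, temperature.strata
        LON, LAT = np.meshgrid(lon, lat)
        n_s = len(strata)
        mean = np.full((n_s, len(lat), len(lon)), np.nan)
        sd = np.full_like(mean, np.nan)
        xy_grid = np.column_stack([LON.ravel(), LAT.ravel()])
        cov_params = {}
        for k, s in enumerate(strata):
            t_k = temperature.values[k].ravel()
            s_k = salinity.values[k].ravel()
            cov_mean, cov_var = self._covariate_prediction(s_k, t_k, np.full(t_k.shape, s.mid))
            sel = (self.obs_["depth"] >= s.lower) & (self.obs_["depth"] < s.upper)
            if sel.sum() >= 10:
                krig = ExponentialKriging(mean="zero", **dict(self.kriging_kwargs or {}))
                krig.fit(self._xy_[sel.to_numpy()], self._resid_[sel.to_numpy()])
            else:
                krig = self._pooled_kriger_
            r_mean, r_sd = krig.predict(xy_grid, return_std=True)
            mean[k] = (cov_mean + r_mean).reshape(len(lat), len(lon))
            sd[k] = np.sqrt(cov_var + r_sd**2).reshape(len(lat), len(lon))
            cov_params[k] = {"range_km": krig.range_km_, "sill": krig.sill_,
                             "nugget": krig.nugget_}
        iso = Isoscape(lon, lat, strata, mean, sd,
                       deviance_explained=self.deviance_explained_,
                       covariance_params=cov_params)
        log.info("isoscape fitted: deviance explained by covariates = %.3f",
                 self.deviance_explained_)
        return iso


def fit_isoscape(obs: pd.DataFrame, temperature: EnvField, salinity: EnvField,
                 year_window: tuple[int, int] | None = None, **kwargs) -> Isoscape:
    """One-call isoscape: fit the two-stage model and predict the grid."""
    model = IsoscapeModel(year_window=year_window, **kwargs)
    return model.fit(obs).predict_grid(temperature, salinity)
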