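"""Bayesian Kriging of strip soil metals and the two-stage health model.

A dense sampling strip supports Gaussian-process interpolation of
log-concentrations to residences: an exponential-covariance GP

    cov(s, s') = sill * exp(-d(s, s') / range) + nugget * 1{s = s'}

with a constant mean, whose hyperparameters get weakly-informative priors and
are sampled by Metropolis-within-Gibbs. Predictions marginalise over the
hyperparameter draws, giving each address a predictive mean and standard
deviation per chemical.

Eligibility for the validation analysis is residence inside, or within a
buffer (default 1 km) of, the convex hull of the strip sites.

The two-stage health model consumes the interpolated exposures: stage 1 is
the Kriging above; stage 2 is the NMIG spike-and-slab logistic mixed model
where each interpolated exposure enters as mean_ij plus a latent additive
measurement error omega_ij ~ N(0, sd_ij^2) with sd_ij the Kriging predictive
standard deviation (plug-in uncertainty propagation; no feedback from
outcomes to the GP, and no cross-chemical error correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point
from sklearn.base import BaseEstimator, RegressorMixin

from .exposure import EARTH_RADIUS_KM, great_circle_distance
from .selection import (
    InclusionSummary,
    MCMCSettings,
    NMIGHyperparams,
    PosteriorSamples,
    SpikeSlabLogisticRegression,
    inclusion_summary,
)

__all__ = [
    "KrigingPriors",
    "BayesianKriging",
    "TwoStageFit",
    "fit_kriging",
    "krige_predict",
    "buffer_filter",
    "two_stage_fit",
]


@dataclass
class KrigingPriors:
    """Priors for the GP hyperparameters.

    The location defaults are empirically centred (data mean/variance, median
    pairwise distance) with wide log-scale spreads — weakly informative in
    the usual applied-GP sense. Explicit values override the centring.
    """

    mean_loc: float | None = None
    mean_scale: float = 10.0
    log_sill_loc: float | None = None
    log_sill_scale: float = 1.5
    log_range_loc: float | None = None
    log_range_scale: float = 1.5
    log_nugget_loc: float | None = None
    log_nugget_scale: float = 1.5


class BayesianKriging(BaseEstimator, RegressorMixin):
    """Gaussian-process interpolation with posterior hyperparameter sampling.

    Parameters
    ----------
    log_transform : model log-concentrations (recommended for skewed
        nonnegative measurements); predictions stay on the log scale, which
        is also what the health model consumes.
    priors : :class:`KrigingPriors`; None uses empirically centred defaults.
    fixed_params : optional dict with keys ``sill, range_km, nugget, mean``;
        when given, no MCMC runs and predictions condition on these values.
    n_iter, burn_in, thin : Metropolis-within-Gibbs chain geometry.
    n_predict_draws : hyperparameter draws the predictive marginalises over.

    Attributes
    ----------
    draws_ : DataFrame of posterior draws (sill, range_km, nugget, mean).
    accept_rate_ : MH acceptance fraction after burn-in.
    """

    def __init__(
        self,
        log_transform: bool = True,
        priors: KrigingPriors | None = None,
        fixed_params: dict | None = None,
        n_iter: int = 4000,
        burn_in: int = 2000,
        thin: int = 10,
        n_predict_draws: int = 100,
        random_state: int | None = 0,
    ):
        self.log_transform = log_transform
        self.priors = priors
        self.fixed_params = fixed_params
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_predict_draws = n_predict_draws
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _dist_matrix(lon1, lat1, lon2, lat2):
        return great_circle_distance(
            (lon1[:, None], lat1[:, None]), (lon2[None, :], lat2[None, :])
        )

    @staticmethod
    def _chol(dmat, sill, rng_km, nugget):
        cov = sill * np.exp(-dmat / rng_km)
        cov[np.diag_indices_from(cov)] += nugget + 1e-12 * sill
        return np.linalg.cholesky(cov)

    def _loglik(self, chol, resid):
        alpha = np.linalg.solve(chol, resid)
        return -0.5 * (alpha @ alpha) - np.log(np.diag(chol)).sum()

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Fit the GP to site coordinates X (lon, lat) and concentrations y."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_sites, 2) lon/lat")
        if self.fixed_params is None and len(y) < 5:
            raise ValueError("need at least 5 sites to infer GP hyperparameters")
        if self.fixed_params is None and np.ptp(y) == 0.0:
            raise ValueError(
                "constant field: no spatial structure to krige; "
                "consider a nugget-only (pure noise) model"
            )
        if self.log_transform:
            if np.any(y <= 0):
                raise ValueError("log transform requires positive concentrations")
            y = np.log(y)
        self.train_lon_, self.train_lat_ = X[:, 0].copy(), X[:, 1].copy()
        self.train_y_ = y
        dmat = self._dist_matrix(self.train_lon_, self.train_lat_,
                                 self.train_lon_, self.train_lat_)
        n = len(y)

        if self.fixed_params is not None:
            fp = dict(self.fixed_params)
            if float(fp.get("nugget", 0.0)) == 0.0:
                iu = np.triu_indices(n, 1)
                clash = (dmat[iu] == 0.0) & (y[iu[0]] != y[iu[1]])
                if np.any(clash):
                    raise ValueError(
                        "duplicated site coordinates with conflicting values "
                        "cannot be interpolated with nugget = 0"
                    )
            draws = pd.DataFrame(
                {
                    "sill": [float(fp["sill"])],
                    "range_km": [float(fp["range_km"])],
                    "nugget": [float(fp.get("nugget", 0.0))],
                    "mean": [float(fp.get("mean", y.mean()))],
                }
            )
            try:
                self._chol(dmat, draws["sill"][0], draws["range_km"][0],
                           draws["nugget"][0])
            except np.linalg.LinAlgError:
                raise ValueError(
                    "singular GP covariance: duplicated sites with nugget = 0 "
                    "(conflicting values cannot be interpolated exactly)"
                )
            self.draws_ = draws
            self.accept_rate_ = float("nan")
            return self

        pr = self.priors or KrigingPriors()
        m0 = y.mean() if pr.mean_loc is None else pr.mean_loc
        s0 = pr.mean_scale
        var_y = max(y.var(ddof=1), 1e-12)
        ls0 = np.log(var_y) if pr.log_sill_loc is None else pr.log_sill_loc
        off = dmat[np.triu_indices(n, 1)]
        lr0 = (np.log(max(np.median(off), 1e-6))
               if pr.log_range_loc is None else pr.log_range_loc)
        ln0 = (np.log(0.1 * var_y)
               if pr.log_nugget_loc is None else pr.log_nugget_loc)
        p_loc = np.array([ls0, lr0, ln0])
        p_scale = np.array([pr.log_sill_scale, pr.log_range_scale,
                            pr.log_nugget_scale])

        rng = np.random.default_rng(self.random_state)
        theta = p_loc.copy()  # (log sill, log range, log nugget)
        mu = m0
        chol = self._chol(dmat, *np.exp(theta))
        ll = self._loglik(chol, y - mu)
        lp = -0.5 * float(((theta - p_loc) / p_scale) @ ((theta - p_loc) / p_scale))
        step = 0.3
        kept, acc, tot = [], 0, 0
        ones = np.ones(n)
        for it in range(self.n_iter):
            prop = theta + step * rng.standard_normal(3)
            try:
                chol_p = self._chol(dmat, *np.exp(prop))
                ll_p = self._loglik(chol_p, y - mu)
            except np.linalg.LinAlgError:
                ll_p = -np.inf
            lp_p = -0.5 * float(((prop - p_loc) / p_scale) @ ((prop - p_loc) / p_scale))
            if np.log(rng.random() + 1e-300) < (ll_p + lp_p) - (ll + lp):
                theta, chol, ll, lp = prop, chol_p, ll_p, lp_p
                accepted = True
            else:
                accepted = False
            if it < self.burn_in:
                # Robbins-Monro scale adaptation toward ~30% acceptance
                step = float(np.clip(
                    step * np.exp((1.0 if accepted else 0.0) - 0.3) ** (2.0 / (it + 20)),
                    1e-3, 2.0,
                ))
            else:
                acc += accepted
                tot += 1
            # conjugate Gibbs update of the constant mean
            ci_one = np.linalg.solve(chol.T, np.linalg.solve(chol, ones))
            prec = ones @ ci_one + 1.0 / s0 ** 2
            mean = (y @ ci_one + m0 / s0 ** 2) / prec
            mu = mean + rng.standard_normal() / np.sqrt(prec)
            ll = self._loglik(chol, y - mu)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                s, r, nu = np.exp(theta)
                kept.append((s, r, nu, mu))
        self.draws_ = pd.DataFrame(kept, columns=["sill", "range_km", "nugget", "mean"])
        self.accept_rate_ = acc / max(tot, 1)
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, X, return_std: bool = False):
        """Posterior-predictive mean (and sd) at lon/lat rows of X,
        marginalised over the stored hyperparameter draws."""
        if not hasattr(self, "draws_"):
            raise RuntimeError("BayesianKriging is not fitted")
        X = np.asarray(X, dtype=float)
        lon, lat = X[:, 0], X[:, 1]
        dtr = self._dist_matrix(self.train_lon_, self.train_lat_,
                                self.train_lon_, self.train_lat_)
        dcross = self._dist_matrix(lon, lat, self.train_lon_, self.train_lat_)
        draws = self.draws_
        if len(draws) > self.n_predict_draws:
            ix = np.linspace(0, len(draws) - 1, self.n_predict_draws).astype(int)
            draws = draws.iloc[ix]
        means, m2 = np.zeros(len(X)), np.zeros(len(X))
        for sill, rng_km, nugget, mu in draws.itertuples(index=False):
            chol = self._chol(dtr, sill, rng_km, nugget)
            alpha = np.linalg.solve(chol.T, np.linalg.solve(chol, self.train_y_ - mu))
            k = sill * np.exp(-dcross / rng_km)
            m = mu + k @ alpha
            v = np.linalg.solve(chol, k.T)
            var = np.maximum(sill + nugget - np.sum(v * v, axis=0), 0.0)
            means += m
            m2 += var + m ** 2
        means /= len(draws)
        var_mix = np.maximum(m2 / len(draws) - means ** 2, 0.0)
        if return_std:
            return means, np.sqrt(var_mix)
        return means

    def interval(self, param: str, level: float = 0.90) -> tuple[float, float]:
        """Equal-tailed posterior credible interval for a hyperparameter."""
        a = (1.0 - level) / 2.0
        q = np.quantile(self.draws_[param].to_numpy(), [a, 1.0 - a])
        return float(q[0]), float(q[1])


def fit_kriging(
    sites: pd.DataFrame,
    priors: KrigingPriors | None = None,
    mcmc: dict | None = None,
    seed: int = 0,
    log_transform: bool = True,
    fixed_params: dict | None = None,
) -> BayesianKriging:
    """Fit the GP to a site-measurement table holding a single chemical."""
    chems = sites["chemical"].unique()
    if len(chems) != 1:
        raise ValueError(f"expected one chemical, got {list(chems)}")
    mcmc = mcmc or {}
    model = BayesianKriging(
        log_transform=log_transform, priors=priors, fixed_params=fixed_params,
        random_state=seed, **mcmc,
    )
    model.fit(sites[["lon", "lat"]].to_numpy(), sites["concentration"].to_numpy())
    model.chemical_ = str(chems[0])
    return model


def krige_predict(model: BayesianKriging, targets: pd.DataFrame) -> pd.DataFrame:
    """Predictive mean and sd at each target address.

    Returns a DataFrame (participant_id, chemical, mean, sd) on the fitted
    model's (log) scale.
    """
    mean, sd = model.predict(targets[["lon", "lat"]].to_numpy(), return_std=True)
    return pd.DataFrame(
        {
            "participant_id": targets["participant_id"].to_numpy(),
            "chemical": getattr(model, "chemical_", ""),
            "mean": mean,
            "sd": sd,
        }
    )


def _local_km(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection to km around a reference point; adequate at
    the few-tens-of-km scale of a sampling strip."""
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_KM
    return x, y


def buffer_filter(
    addresses: pd.DataFrame, strip_sites: pd.DataFrame, radius_km: float = 1.0
) -> pd.DataFrame:
    """Addresses inside the strip's convex hull or within `radius_km` of it."""
    if strip_sites.empty:
        raise ValueError("need at least one strip site")
    lon0 = float(strip_sites["lon"].mean())
    lat0 = float(strip_sites["lat"].mean())
    sx, sy = _local_km(strip_sites["lon"], strip_sites["lat"], lon0, lat0)
    hull = MultiPoint(list(zip(sx, sy))).convex_hull
    ax, ay = _local_km(addresses["lon"], addresses["lat"], lon0, lat0)
    keep = [hull.distance(Point(x, y)) <= radius_km for x, y in zip(ax, ay)]
    return addresses.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)


@dataclass
class TwoStageFit:
    """Stage-2 posterior: coefficients, inclusion summary, and the latent
    measurement-error draws carrying stage-1 interpolation uncertainty."""

    samples: PosteriorSamples
    summary: InclusionSummary
    chemicals: list[str]
    omega: np.ndarray | None  # draws x participants x chemicals

    def to_text(self) -> str:
        return self.summary.to_text()


def two_stage_fit(
    y,
    kriged: dict[str, pd.DataFrame],
    personal: pd.DataFrame | None = None,
    hyper: NMIGHyperparams | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int | None = None,
) -> TwoStageFit:
    """Stage-2 spike-and-slab logistic fit on interpolated exposures.

    Parameters
    ----------
    y : binary outcomes of the buffer-eligible participants.
    kriged : chemical -> prediction table (participant_id, mean, sd), one row
        per eligible participant, all chemicals aligned.
    personal : optional personal-covariate DataFrame (row-aligned with y).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    cols, sds = {}, {}
    for chem, pred in kriged.items():
        if len(pred) != n or pred[["mean", "sd"]].isna().any().any():
            bad = (pred["participant_id"].iloc[0] if len(pred) else "?")
            raise ValueError(
                f"missing or misaligned prediction for chemical {chem!r} "
                f"(first participant {bad!r}): expected {n} complete rows"
            )
        cols[chem] = pred["mean"].to_numpy()
        sds[chem] = pred["sd"].to_numpy()
    X = pd.DataFrame(cols)
    msd = pd.DataFrame(sds)
    if personal is not None:
        personal = personal.reset_index(drop=True)
        X = pd.concat([personal, X], axis=1)
    hyper = hyper or NMIGHyperparams()
    mcmc = mcmc or MCMCSettings()
    if seed is not None:
        mcmc = MCMCSettings(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                            thin=mcmc.thin, n_chains=mcmc.n_chains, seed=seed)
    est = SpikeSlabLogisticRegression(
        v0=hyper.v0, a_tau=hyper.a_tau, b_tau=hyper.b_tau,
        a_w=hyper.a_w, b_w=hyper.b_w,
        prec_shape=hyper.fe_prec_shape, prec_rate=hyper.fe_prec_rate,
        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        n_chains=mcmc.n_chains, random_state=mcmc.seed,
    )
    est.fit(X, y, measurement_sd=msd)
    return TwoStageFit(
        samples=est.samples_,
        summary=inclusion_summary(est.samples_),
        chemicals=list(kriged),
        omega=est.samples_.measurement_error,
    )
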