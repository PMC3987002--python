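"""Bayesian logistic mixed model with NMIG spike-and-slab variable selection.

Model
-----
For binary outcomes ``y_i ~ Bernoulli(p_i)`` with

    logit(p_i) = x_i' beta + gamma_i,

selectable coefficients carry the Normal-mixture-of-inverse-Gammas (NMIG)
prior

    beta_j | eta_j, tau2_j ~ N(0, tau2_j * eta_j),
    tau2_j ~ InvGamma(a_tau, b_tau),
    eta_j  = 1 with probability w, = v0 with probability 1 - w,
    w ~ Beta(a_w, b_w),

so the marginal prior on beta_j is a bimodal spike (eta = v0, a small
constant) / slab (eta = 1) mixture; the posterior frequency of eta_j = 1 is
the term's inclusion probability. Non-selectable coefficients get a zero-mean
Gaussian prior whose precision has a Ga(1, 5e-05) hyperprior, as does the
precision of the individual random intercepts gamma_i. Optional smooth terms
use a first-order random-walk (step-function increment) basis whose
increment block shares a single eta.

Computation is a Gibbs sampler: the logistic likelihood is linearised
exactly by Polya-Gamma augmentation (omega_i ~ PG(1, psi_i)), making every
full conditional standard (Gaussian, inverse-Gamma, Bernoulli, Beta).

Default NMIG hyperparameters v0 = 0.00025, a_tau = 5, b_tau = 25,
a_w = b_w = 1 follow common spike-and-slab GAMM practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from ._polyagamma import sample_pg

__all__ = [
    "ModelTerm",
    "NMIGHyperparams",
    "MCMCSettings",
    "PosteriorSamples",
    "InclusionSummary",
    "SpikeSlabLogisticRegression",
    "fit_ssvs_logistic",
    "conditional_eta_probability",
    "sample_tau2_conditional",
    "inclusion_summary",
    "modal_model",
]

RANDOM_INTERCEPT = "random_intercept"


@dataclass
class ModelTerm:
    """One block of the linear predictor.

    kind "linear" uses the named columns as-is (standardized); "smooth" expands
    one column into a first-order random-walk increment basis selected as a
    block; "random_intercept" is the per-individual intercept.
    ``prior_variance`` fixes the Gaussian prior variance of a non-selectable
    block (no hyperprior update), e.g. for an effectively flat reference fit.
    """

    name: str
    columns: Sequence[str] | None = None
    kind: str = "linear"  # linear | smooth | random_intercept
    selectable: bool = True
    design: pd.DataFrame | None = None
    prior_variance: float | None = None
    n_knots: int = 8

    def __post_init__(self):
        if self.kind not in ("linear", "smooth", "random_intercept"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "smooth" and self.columns is not None and len(self.columns) != 1:
            raise ValueError("smooth terms take exactly one column")


@dataclass
class NMIGHyperparams:
    """Spike-and-slab and precision hyperparameters (all configurable)."""

    v0: float = 0.00025
    a_tau: float = 5.0
    b_tau: float = 25.0
    a_w: float = 1.0
    b_w: float = 1.0
    fe_prec_shape: float = 1.0  # Ga prior on non-selectable coefficient precisions
    fe_prec_rate: float = 5e-05
    ri_prec_shape: float = 1.0  # Ga prior on the random-intercept precision
    ri_prec_rate: float = 5e-05

    def __post_init__(self):
        if not 0.0 < self.v0 < 1.0:
            raise ValueError("v0 must lie in (0, 1)")
        for nm in ("a_tau", "b_tau", "a_w", "b_w",
                   "fe_prec_shape", "fe_prec_rate", "ri_prec_shape", "ri_prec_rate"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass
class MCMCSettings:
    """Chain geometry; recorded iterations = (n_iter - burn_in) / thin per chain."""

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= 0 or self.thin <= 0 or self.n_chains <= 0:
            raise ValueError("MCMC settings must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")


@dataclass
class PosteriorSamples:
    """Recorded MCMC draws for all model unknowns."""

    beta: pd.DataFrame  # draws x coefficients (named columns)
    eta: pd.DataFrame  # draws x selectable terms; values in {v0, 1}
    tau2: pd.DataFrame  # draws x selectable terms
    w: np.ndarray
    gamma: np.ndarray  # draws x individuals (empty if no random intercept)
    tau_gamma: np.ndarray
    chain: np.ndarray  # chain index per draw
    term_slices: dict[str, np.ndarray]
    settings: MCMCSettings
    hyper: NMIGHyperparams
    measurement_error: np.ndarray | None = None  # draws x n x n_error_columns

    @property
    def n_draws(self) -> int:
        return len(self.w)

    def inclusion_indicators(self) -> pd.DataFrame:
        """Binary slab-membership draws {eta == 1} per selectable term."""
        return (self.eta == 1.0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        """Flat (iteration, chain, parameter, value) table for persistence."""
        recs = []
        per_chain = np.concatenate([np.arange((self.chain == c).sum())
                                    for c in np.unique(self.chain)])
        for blockname, block in (("beta", self.beta), ("eta", self.eta),
                                 ("tau2", self.tau2)):
            for col in block.columns:
                recs.append(pd.DataFrame({
                    "iteration": per_chain, "chain": self.chain,
                    "parameter": f"{blockname}[{col}]",
                    "value": block[col].to_numpy(),
                }))
        recs.append(pd.DataFrame({"iteration": per_chain, "chain": self.chain,
                                  "parameter": "w", "value": self.w}))
        if self.gamma.size:
            recs.append(pd.DataFrame({"iteration": per_chain, "chain": self.chain,
                                      "parameter": "tau_gamma",
                                      "value": self.tau_gamma}))
        return pd.concat(recs, ignore_index=True)


@dataclass
class InclusionSummary:
    """Per-term inclusion probabilities with threshold classification.

    A term is "included" when its mean inclusion probability reaches 0.5
    (ties included) and "reported" from 0.25; included single-coefficient
    terms carry a posterior mean and equal-tailed 95% credible interval and
    are starred "well estimated" when that interval excludes zero.
    """

    table: pd.DataFrame
    c_include: float
    c_report: float

    def included(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "included"])

    def reported(self) -> list[str]:
        return list(self.table.index[self.table["classification"] != "excluded"])

    def to_text(self) -> str:
        lines = [f"{'term':<22}{'incl. mean (sd)':<22}{'estimate (95% CI)':<30}"]
        for name, row in self.table.iterrows():
            if row["classification"] == "excluded":
                continue
            est = "---"
            if np.isfinite(row["coef_mean"]):
                star = " *" if row["well_estimated"] else ""
                est = (f"{row['coef_mean']:.3f} ({row['ci_lo']:.3f}, "
                       f"{row['ci_hi']:.3f}){star}")
            lines.append(f"{name:<22}"
                         f"{row['prob_mean']:.4f} ({row['prob_sd']:.4f})    "
                         f"{est}")
        return "\n".join(lines)


def conditional_eta_probability(beta, tau2: float, w: float, v0: float):
    """Full-conditional probability that an NMIG indicator sits in the slab.

    P(eta = 1 | beta, tau2, w) =
        w N(beta; 0, tau2) / [ w N(beta; 0, tau2) + (1-w) N(beta; 0, v0 tau2) ]

    For a block (beta a vector sharing one indicator) the densities multiply.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if w == 0.0:
        return 0.0
    if w == 1.0:
        return 1.0
    q = beta.size
    ss = float(np.sum(beta ** 2))
    # log [ N(beta;0,tau2) / N(beta;0,v0 tau2) ] summed over the block
    log_ratio = 0.5 * q * math.log(v0) + ss / (2.0 * tau2) * (1.0 / v0 - 1.0)
    return float(expit(math.log(w) - math.log1p(-w) + log_ratio))


def sample_tau2_conditional(
    rng: np.random.Generator, beta, eta: float, a_tau: float, b_tau: float
) -> float:
    """Draw tau2 from its inverse-Gamma full conditional
    IG(a_tau + q/2, b_tau + sum(beta^2) / (2 eta))."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    shape = a_tau + beta.size / 2.0
    scale = b_tau + float(np.sum(beta ** 2)) / (2.0 * eta)
    return scale / rng.gamma(shape)


def _rw1_basis(x: np.ndarray, n_knots: int) -> np.ndarray:
    """First-order random-walk step basis: level shifts at interior quantile
    knots, centered. Coefficients are the RW1 increments, iid under the prior."""
    qs = np.linspace(0, 1, n_knots + 1)[1:-1]
    knots = np.unique(np.quantile(x, qs))
    cols = [(x >= k).astype(float) for k in knots]
    if not cols:
        raise ValueError("too few distinct values for a smooth term")
    b = np.column_stack(cols)
    return b - b.mean(axis=0)


class SpikeSlabLogisticRegression(BaseEstimator, ClassifierMixin):
    """Logistic mixed model with NMIG spike-and-slab selection, fit by Gibbs.

    Parameters
    ----------
    terms : optional list of :class:`ModelTerm`. Default: one selectable
        linear term per column of X, plus a random intercept when
        ``random_intercept=True``.
    v0, a_tau, b_tau, a_w, b_w : NMIG hyperparameters.
    prec_shape, prec_rate : Ga hyperprior on non-selectable coefficient and
        random-intercept precisions (default Ga(1, 5e-05)).
    random_intercept : include per-observation intercepts gamma_i.
    intercept_selectable : give the random-intercept block its own NMIG
        indicator (it then appears in the inclusion summary).
    standardize : z-score linear design columns before fitting; coefficients
        are reported on the standardized scale.
    n_iter, burn_in, thin, n_chains : chain geometry per chain.
    random_state : master seed; chains use independent spawned streams.

    Attributes
    ----------
    samples_ : :class:`PosteriorSamples`.
    summary_ : :class:`InclusionSummary`.
    inclusion_probabilities_ : Series of posterior slab frequencies per term.
    coef_ : posterior mean coefficients (standardized scale).
    max_rhat_ : largest split-Rhat over coefficients (needs >= 2 chains).
    """

    def __init__(
        self,
        terms: list[ModelTerm] | None = None,
        v0: float = 0.00025,
        a_tau: float = 5.0,
        b_tau: float = 25.0,
        a_w: float = 1.0,
        b_w: float = 1.0,
        prec_shape: float = 1.0,
        prec_rate: float = 5e-05,
        random_intercept: bool = True,
        intercept_selectable: bool = True,
        standardize: bool = True,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 5,
        n_chains: int = 3,
        prior_only: bool = False,
        random_state: int | None = 0,
    ):
        self.terms = terms
        self.v0 = v0
        self.a_tau = a_tau
        self.b_tau = b_tau
        self.a_w = a_w
        self.b_w = b_w
        self.prec_shape = prec_shape
        self.prec_rate = prec_rate
        self.random_intercept = random_intercept
        self.intercept_selectable = intercept_selectable
        self.standardize = standardize
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.prior_only = prior_only
        self.random_state = random_state

    # -- design assembly ---------------------------------------------------

    def _resolve_terms(self, X: pd.DataFrame) -> list[ModelTerm]:
        if self.terms is not None:
            terms = [t for t in self.terms]
        else:
            terms = [ModelTerm(name=str(c), columns=[str(c)]) for c in X.columns]
        n_ri = sum(t.kind == RANDOM_INTERCEPT for t in terms)
        if n_ri > 1:
            raise ValueError("at most one random_intercept term is allowed")
        if n_ri == 0 and self.random_intercept:
            terms.append(ModelTerm(name=RANDOM_INTERCEPT, kind=RANDOM_INTERCEPT,
                                   selectable=self.intercept_selectable))
        return terms

    def _build_design(self, X: pd.DataFrame, terms, measurement_sd):
        cols, names, slices = [], [], {}
        sd_cols = {}
        pos = 1  # 0 is the fixed intercept
        for t in terms:
            if t.kind == RANDOM_INTERCEPT:
                continue
            if t.columns is None:
                raise ValueError(f"term {t.name!r} names no columns")
            missing = [c for c in t.columns if c not in X.columns]
            if missing:
                raise ValueError(f"term {t.name!r}: columns {missing} not in X")
            if t.kind == "linear":
                block = X[list(t.columns)].to_numpy(dtype=float)
                mu = block.mean(axis=0) if self.standardize else np.zeros(block.shape[1])
                sd = block.std(axis=0, ddof=0) if self.standardize else np.ones(block.shape[1])
                if np.any(sd == 0):
                    bad = [c for c, s in zip(t.columns, sd) if s == 0]
                    raise ValueError(f"constant column(s) in term {t.name!r}: {bad}")
                block = (block - mu) / sd
                for j, c in enumerate(t.columns):
                    if measurement_sd is not None and c in measurement_sd.columns:
                        sd_cols[pos + j] = measurement_sd[c].to_numpy(dtype=float) / sd[j]
                local_names = list(t.columns)
            else:  # smooth
                x = X[t.columns[0]].to_numpy(dtype=float)
                block = _rw1_basis(x, t.n_knots)
                local_names = [f"{t.name}.rw{j + 1}" for j in range(block.shape[1])]
            cols.append(block)
            names.extend(local_names)
            slices[t.name] = np.arange(pos, pos + block.shape[1])
            pos += block.shape[1]
        n = len(X)
        design = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
        return design, ["(Intercept)"] + names, slices, sd_cols

    # -- Gibbs sampler -----------------------------------------------------

    def fit(self, X, y=None, measurement_sd: pd.DataFrame | None = None):
        """Run the Gibbs sampler.

        measurement_sd : optional DataFrame aligned with X giving a known
            per-observation standard deviation for a subset of linear design
            columns; those columns get an additive latent error updated in
            the sampler (two-stage exposure-uncertainty propagation).
        """
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel() if y is not None else np.zeros(len(X))
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        n = len(X)
        if n < 2:
            raise ValueError("need at least 2 observations")
        terms = self._resolve_terms(X)
        if not terms:
            raise ValueError("empty term list")
        hyper = NMIGHyperparams(
            v0=self.v0, a_tau=self.a_tau, b_tau=self.b_tau,
            a_w=self.a_w, b_w=self.b_w,
            fe_prec_shape=self.prec_shape, fe_prec_rate=self.prec_rate,
            ri_prec_shape=self.prec_shape, ri_prec_rate=self.prec_rate,
        )
        settings = MCMCSettings(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            n_chains=self.n_chains,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        design, coef_names, slices, sd_cols = self._build_design(X, terms, measurement_sd)
        ri_term = next((t for t in terms if t.kind == RANDOM_INTERCEPT), None)
        sel_terms = [t.name for t in terms
                     if t.selectable and t.kind != RANDOM_INTERCEPT]
        ri_selectable = ri_term is not None and ri_term.selectable
        if ri_selectable:
            sel_terms = sel_terms + [ri_term.name]
        fixed_var = {}
        for t in terms:
            if t.kind == RANDOM_INTERCEPT:
                continue
            if t.prior_variance is not None:
                if t.selectable:
                    raise ValueError(f"term {t.name!r}: fixed prior variance is "
                                     "incompatible with selection")
                fixed_var[t.name] = float(t.prior_variance)

        ss = np.random.SeedSequence(settings.seed)
        chain_seeds = ss.spawn(settings.n_chains)
        chains = [
            self._run_chain(design, y, terms, slices, sd_cols, sel_terms,
                            ri_term, ri_selectable, fixed_var, hyper, settings,
                            np.random.default_rng(cs))
            for cs in chain_seeds
        ]
        samples = self._collect(chains, coef_names, sel_terms, slices, settings, hyper)
        self.terms_ = terms
        self.coef_names_ = coef_names
        self.samples_ = samples
        self.summary_ = inclusion_summary(samples)
        self.inclusion_probabilities_ = self.summary_.table["prob_mean"]
        self.coef_ = samples.beta.mean(axis=0).to_numpy()
        self._design_info_ = (slices, X.columns)
        self.classes_ = np.array([0.0, 1.0])
        if settings.n_chains >= 2:
            self.max_rhat_ = _max_split_rhat(samples)
        return self

    def _run_chain(self, design, y, terms, slices, sd_cols, sel_terms,
                   ri_term, ri_selectable, fixed_var, hyper, settings, rng):
        n, p = design.shape
        kappa = (y - 0.5) if not self.prior_only else np.zeros(n)
        d0 = design
        deff = design.copy() if sd_cols else design
        err = {j: np.zeros(n) for j in sd_cols}

        # prior precision bookkeeping per coefficient
        sel_slice = {t.name: slices[t.name] for t in terms
                     if t.selectable and t.kind != RANDOM_INTERCEPT}
        nonsel_idx = [0]  # intercept
        fixed_prec = {}
        for t in terms:
            if t.kind == RANDOM_INTERCEPT or t.selectable:
                continue
            if t.name in fixed_var:
                for j in slices[t.name]:
                    fixed_prec[j] = 1.0 / fixed_var[t.name]
            else:
                nonsel_idx.extend(slices[t.name])
        nonsel_idx = np.asarray(nonsel_idx, dtype=int)

        beta = np.zeros(p)
        gamma = np.zeros(n)
        has_ri = ri_term is not None
        eta = {nm: 1.0 for nm in sel_terms}
        tau2 = {nm: hyper.b_tau / (hyper.a_tau + 1.0) for nm in sel_terms
                if nm != (ri_term.name if has_ri else None)}
        w = hyper.a_w / (hyper.a_w + hyper.b_w)
        tau_gamma = 1.0
        tau_beta = np.full(p, 0.1)

        n_rec = len(range(settings.burn_in, settings.n_iter, settings.thin))
        rec = {
            "beta": np.empty((n_rec, p)),
            "eta": np.empty((n_rec, len(sel_terms))),
            "tau2": np.empty((n_rec, len(sel_terms))),
            "w": np.empty(n_rec),
            "gamma": np.empty((n_rec, n if has_ri else 0)),
            "tau_gamma": np.empty(n_rec),
            "err": np.empty((n_rec, n, len(sd_cols))) if sd_cols else None,
        }
        ri_name = ri_term.name if has_ri else None
        k = 0
        for it in range(settings.n_iter):
            psi = deff @ beta + gamma
            omega = np.zeros(n) if self.prior_only else sample_pg(rng, psi)

            # beta | rest: Gaussian from the PG-linearised likelihood
            prior_prec = np.empty(p)
            prior_prec[nonsel_idx] = tau_beta[nonsel_idx]
            for j, pr in fixed_prec.items():
                prior_prec[j] = pr
            for nm, sl in sel_slice.items():
                prior_prec[sl] = 1.0 / (tau2[nm] * eta[nm])
            prec = (deff * omega[:, None]).T @ deff
            prec[np.diag_indices_from(prec)] += prior_prec
            b = deff.T @ (kappa - omega * gamma)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)

            f = deff @ beta
            if has_ri:
                ri_eta = eta[ri_name] if ri_selectable else 1.0
                g_prec = omega + tau_gamma / ri_eta
                g_mean = (kappa - omega * f) / g_prec
                gamma = g_mean + rng.standard_normal(n) / np.sqrt(g_prec)

            # latent measurement error on uncertain exposure columns
            for j, s in sd_cols.items():
                bj = beta[j]
                psi_wo = f + gamma - bj * err[j]
                with np.errstate(divide="ignore"):
                    prior_p = np.where(s > 0, 1.0 / np.maximum(s, 1e-300) ** 2, np.inf)
                e_prec = omega * bj * bj + prior_p
                e_mean = bj * (kappa - omega * psi_wo) / e_prec
                new = np.where(
                    s > 0, e_mean + rng.standard_normal(n) / np.sqrt(e_prec), 0.0
                )
                err[j] = new
                deff[:, j] = d0[:, j] + new
                f = deff @ beta

            # NMIG indicators and variances
            for nm, sl in sel_slice.items():
                pr1 = conditional_eta_probability(beta[sl], tau2[nm], w, hyper.v0)
                eta[nm] = 1.0 if rng.random() < pr1 else hyper.v0
                tau2[nm] = sample_tau2_conditional(
                    rng, beta[sl], eta[nm], hyper.a_tau, hyper.b_tau
                )
            if has_ri:
                if ri_selectable:
                    pr1 = conditional_eta_probability(
                        gamma, 1.0 / tau_gamma, w, hyper.v0
                    )
                    eta[ri_name] = 1.0 if rng.random() < pr1 else hyper.v0
                ri_eta = eta[ri_name] if ri_selectable else 1.0
                tau_gamma = rng.gamma(
                    hyper.ri_prec_shape + n / 2.0,
                    1.0 / (hyper.ri_prec_rate + float(gamma @ gamma) / (2.0 * ri_eta)),
                )

            n_slab = sum(eta[nm] == 1.0 for nm in sel_terms)
            if sel_terms:
                w = rng.beta(hyper.a_w + n_slab, hyper.b_w + len(sel_terms) - n_slab)

            # hierarchical precisions of non-selectable coefficients
            tau_beta[nonsel_idx] = rng.gamma(
                hyper.fe_prec_shape + 0.5,
                1.0 / (hyper.fe_prec_rate + beta[nonsel_idx] ** 2 / 2.0),
            )

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                rec["beta"][k] = beta
                rec["eta"][k] = [eta[nm] for nm in sel_terms]
                rec["tau2"][k] = [
                    tau2[nm] if nm in tau2 else 1.0 / tau_gamma for nm in sel_terms
                ]
                rec["w"][k] = w
                if has_ri:
                    rec["gamma"][k] = gamma
                rec["tau_gamma"][k] = tau_gamma
                if sd_cols:
                    rec["err"][k] = np.column_stack([err[j] for j in sd_cols])
                k += 1
        return rec

    @staticmethod
    def _collect(chains, coef_names, sel_terms, slices, settings, hyper):
        cat = lambda key: np.concatenate([c[key] for c in chains], axis=0)
        chain_ix = np.concatenate(
            [np.full(len(c["w"]), i) for i, c in enumerate(chains)]
        )
        me = None
        if chains[0]["err"] is not None:
            me = cat("err")
        return PosteriorSamples(
            beta=pd.DataFrame(cat("beta"), columns=coef_names),
            eta=pd.DataFrame(cat("eta"), columns=sel_terms),
            tau2=pd.DataFrame(cat("tau2"), columns=sel_terms),
            w=cat("w"),
            gamma=cat("gamma"),
            tau_gamma=cat("tau_gamma"),
            chain=chain_ix,
            term_slices=slices,
            settings=settings,
            hyper=hyper,
            measurement_error=me,
        )

    def predict_proba(self, X):
        """Posterior-mean outcome probability at new covariate rows
        (population level: random intercepts set to zero)."""
        X = pd.DataFrame(X)
        design, _, _, _ = self._build_design(X, self.terms_, None)
        draws = self.samples_.beta.to_numpy()
        p1 = expit(design @ draws.T).mean(axis=1)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


def _max_split_rhat(samples: PosteriorSamples) -> float:
    """Largest split-Rhat over regression coefficients."""
    import arviz as az

    chains = np.unique(samples.chain)
    per = min((samples.chain == c).sum() for c in chains)
    arr = np.stack(
        [samples.beta.to_numpy()[samples.chain == c][:per] for c in chains]
    )
    rhat = az.rhat(az.convert_to_dataset(arr))
    return float(rhat["x"].max())


def fit_ssvs_logistic(
    y,
    terms: list[ModelTerm],
    hyper: NMIGHyperparams | None = None,
    mcmc: MCMCSettings | None = None,
) -> PosteriorSamples:
    """Functional front end: terms carry their design columns directly."""
    hyper = hyper or NMIGHyperparams()
    mcmc = mcmc or MCMCSettings()
    frames, resolved = [], []
    for t in terms:
        if t.kind == RANDOM_INTERCEPT:
            resolved.append(t)
            continue
        if t.design is None:
            raise ValueError(f"term {t.name!r} must carry a design DataFrame")
        frames.append(t.design)
        resolved.append(
            ModelTerm(name=t.name, columns=list(t.design.columns), kind=t.kind,
                      selectable=t.selectable, prior_variance=t.prior_variance,
                      n_knots=t.n_knots)
        )
    X = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=range(len(y)))
    est = SpikeSlabLogisticRegression(
        terms=resolved,
        v0=hyper.v0, a_tau=hyper.a_tau, b_tau=hyper.b_tau,
        a_w=hyper.a_w, b_w=hyper.b_w,
        prec_shape=hyper.fe_prec_shape, prec_rate=hyper.fe_prec_rate,
        random_intercept=any(t.kind == RANDOM_INTERCEPT for t in resolved),
        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        n_chains=mcmc.n_chains, random_state=mcmc.seed,
    )
    est.fit(X, y)
    return est.samples_


def inclusion_summary(
    samples: PosteriorSamples, c_include: float = 0.5, c_report: float = 0.25
) -> InclusionSummary:
    """Posterior inclusion probabilities, classification, and coefficient
    summaries for included terms."""
    if samples.n_draws < 1:
        raise ValueError("no recorded draws")
    ind = samples.inclusion_indicators()
    rows = {}
    for nm in ind.columns:
        z = ind[nm].to_numpy()
        prob, sd = float(z.mean()), float(z.std(ddof=1)) if len(z) > 1 else 0.0
        if prob >= c_include:
            cls = "included"
        elif prob >= c_report:
            cls = "reported"
        else:
            cls = "excluded"
        coef_mean = ci_lo = ci_hi = float("nan")
        well = False
        sl = samples.term_slices.get(nm)
        if cls == "included" and sl is not None and len(sl) == 1:
            draws = samples.beta.iloc[:, sl[0]].to_numpy()
            coef_mean = float(draws.mean())
            ci_lo, ci_hi = (float(q) for q in np.quantile(draws, [0.025, 0.975]))
            well = ci_lo > 0.0 or ci_hi < 0.0
        rows[nm] = {
            "prob_mean": prob, "prob_sd": sd, "classification": cls,
            "coef_mean": coef_mean, "ci_lo": ci_lo, "ci_hi": ci_hi,
            "well_estimated": well,
        }
    columns = ["prob_mean", "prob_sd", "classification", "coef_mean",
               "ci_lo", "ci_hi", "well_estimated"]
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        table = pd.DataFrame(columns=columns)
    return InclusionSummary(table=table[columns], c_include=c_include,
                            c_report=c_report)


def modal_model(samples: PosteriorSamples) -> frozenset[str]:
    """Most frequent configuration of slab-resident terms across draws
    (the 'selected model'; empty set = null / non-selectable-only model)."""
    ind = samples.inclusion_indicators().to_numpy().astype(bool)
    names = list(samples.eta.columns)
    counts: dict[frozenset, int] = {}
    for row in ind:
        key = frozenset(nm for nm, b in zip(names, row) if b)
        counts[key] = counts.get(key, 0) + 1
    return max(counts, key=counts.get)
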