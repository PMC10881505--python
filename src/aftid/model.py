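"""Bayesian AFT illness-death model with log-normal errors and shared frailty.

The three-state illness-death structure gives each transition its own
accelerated-failure-time equation on the log-time scale:

    transition 1 (healthy -> recurrence):       log T1 = x'b1 + g_i + e1
    transition 2 (healthy -> death, no recur.): log T2 = x'b2 + g_i + e2
    transition 3 (recurrence -> death):    log(T2-T1) = x'b3 + g_i + e3

with e_g ~ Normal(mu_g, sigma_g^2) and a subject-specific frailty
g_i ~ Normal(0, theta) shared across transitions, inducing positive
dependence between recurrence and death.  exp(b) is a time ratio (TR):
TR > 1 means multiplicatively longer time to the event.

Priors: improper flat priors on each (mu_g, beta_g); conjugate inverse
gamma IG(a, b) on each sigma_g^2 and on theta.  Posterior sampling is a
data-augmentation Gibbs sampler: censored log-times are imputed from
truncated normals, after which every full conditional is standard
(normal regression updates, inverse-gamma scale updates, normal frailty
updates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Dataset, SemiCompetingRecord, encode_design

__all__ = [
    "ModelParameters",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "TransitionData",
    "TRANSITION_NAMES",
    "SOJOURN_EPSILON",
    "transition_location",
    "record_loglik",
    "loglik_subjects",
    "sample_truncated_normal",
    "augment_latent_logtimes",
    "gibbs_sweep",
    "fit_model",
    "time_ratio_table",
]

logger = logging.getLogger(__name__)

TRANSITION_NAMES = ("recurrence", "death_without_recurrence", "death_after_recurrence")

#: sojourn substituted when death is recorded at the recurrence time (months)
SOJOURN_EPSILON = 0.01

ALL_BLOCKS = frozenset({"latent", "coef", "sigma", "frailty", "theta"})


@dataclass
class ModelParameters:
    """All parameters of the three-transition AFT model.

    ``beta`` is a list of three coefficient vectors (one per transition,
    dimension = number of design columns), ``mu`` and ``sigma2`` the error
    locations and variances, ``theta`` the frailty variance and ``gamma``
    the length-n frailty vector (may be ``None`` when only the population
    parameters are needed, e.g. as simulation truth).
    """

    beta: list[np.ndarray]
    mu: np.ndarray
    sigma2: np.ndarray
    theta: float
    gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = [np.atleast_1d(np.asarray(b, dtype=float)) for b in self.beta]
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if len(self.beta) != 3 or self.mu.shape != (3,) or self.sigma2.shape != (3,):
            raise ValueError("need three transitions: beta list of 3, mu and sigma2 of shape (3,)")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if not np.all(np.isfinite(self.gamma)):
                raise ValueError("gamma must be finite")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            beta=[b.copy() for b in self.beta],
            mu=self.mu.copy(),
            sigma2=self.sigma2.copy(),
            theta=float(self.theta),
            gamma=None if self.gamma is None else self.gamma.copy(),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-gamma hyperparameters; flat priors on coefficients.

    Defaults a = b = 0.7 everywhere are weakly informative.  ``mu_g`` and
    ``beta_g`` carry improper uniform priors; posterior propriety requires
    at least one event per transition and a full-rank design, which the
    fitter checks.
    """

    a_theta: float = 0.7
    b_theta: float = 0.7
    a_sigma: tuple[float, float, float] = (0.7, 0.7, 0.7)
    b_sigma: tuple[float, float, float] = (0.7, 0.7, 0.7)

    def __post_init__(self) -> None:
        vals = (self.a_theta, self.b_theta, *self.a_sigma, *self.b_sigma)
        if any(v <= 0 for v in vals):
            raise ValueError("all inverse-gamma hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths and seeding. The seed must be given explicitly."""

    seed: int
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 5
    n_chains: int = 2

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def transition_location(
    x: np.ndarray, g: int, params: ModelParameters, gamma_i: float = 0.0
) -> float:
    """Location on the log-time scale: mu_g + x'beta_g + gamma_i (g in 1..3)."""
    if g not in (1, 2, 3):
        raise ValueError("transition g must be 1, 2 or 3")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    b = params.beta[g - 1]
    if x.shape != b.shape:
        raise ValueError(f"covariate dimension {x.shape} does not match beta_{g} {b.shape}")
    return float(params.mu[g - 1] + x @ b + gamma_i)


def _ln_logpdf(t: float, loc: float, sd: float) -> float:
    """log of the log-normal density at t with log-scale location/sd."""
    return float(norm.logpdf(np.log(t), loc, sd) - np.log(t))


def _ln_logsf(t: float, loc: float, sd: float) -> float:
    """log of the log-normal survival function at t."""
    if t <= 0:
        return 0.0
    return float(norm.logsf(np.log(t), loc, sd))


def record_loglik(
    rec: SemiCompetingRecord | tuple,
    x: np.ndarray,
    params: ModelParameters,
    gamma_i: float = 0.0,
) -> float:
    """Log-likelihood contribution of one record, conditional on its frailty.

    With f_g / S_g the log-normal density / survival at location
    mu_g + x'beta_g + gamma_i:

    * recurrence then death:      log f1(y1) + log S2(y1) + log f3(y2-y1)
    * recurrence, then censored:  log f1(y1) + log S2(y1) + log S3(y2-y1)
    * death without recurrence:   log S1(y2) + log f2(y2)
    * doubly censored:            log S1(y1) + log S2(y1)

    A death recorded at the recurrence time has its zero sojourn replaced
    by :data:`SOJOURN_EPSILON` months (warned once per process).
    """
    if isinstance(rec, SemiCompetingRecord):
        y1, d1, y2, d2 = rec.y1, rec.d1, rec.y2, rec.d2
    else:
        y1, d1, y2, d2 = rec
    l1 = transition_location(x, 1, params, gamma_i)
    l2 = transition_location(x, 2, params, gamma_i)
    l3 = transition_location(x, 3, params, gamma_i)
    s1, s2, s3 = params.sigma
    if d1 == 1:
        sojourn = y2 - y1
        out = _ln_logpdf(y1, l1, s1) + _ln_logsf(y1, l2, s2)
        if d2 == 1:
            if sojourn <= 0:
                _warn_tied_sojourn()
                sojourn = SOJOURN_EPSILON
            out += _ln_logpdf(sojourn, l3, s3)
        else:
            out += _ln_logsf(sojourn, l3, s3)
        return out
    if d2 == 1:
        return _ln_logsf(y2, l1, s1) + _ln_logpdf(y2, l2, s2)
    return _ln_logsf(y1, l1, s1) + _ln_logsf(y1, l2, s2)


_tied_sojourn_warned = False


def _warn_tied_sojourn() -> None:
    global _tied_sojourn_warned
    if not _tied_sojourn_warned:
        warnings.warn(
            f"death recorded at the recurrence time; sojourn replaced by {SOJOURN_EPSILON} months",
            UserWarning,
            stacklevel=3,
        )
        _tied_sojourn_warned = True


# ---------------------------------------------------------------------------
# Complete-data layout for the sampler
# ---------------------------------------------------------------------------


@dataclass
class TransitionData:
    """Precomputed observed/censored structure of the cohort.

    Transitions 1 and 2 involve every subject; transition 3 only subjects
    with an observed recurrence (the clock resets at recurrence, so the
    response is the log sojourn).  For each transition we keep the indices
    of subjects with an observed log-time, the observed values, and for
    censored pieces the truncation bound on the log scale.
    """

    X: np.ndarray                # (n, p) shared design
    columns: list[str]
    y1: np.ndarray
    d1: np.ndarray
    y2: np.ndarray
    d2: np.ndarray
    # per transition g (0-based): subject indices entering the transition
    idx: list[np.ndarray] = field(init=False)
    obs_mask: list[np.ndarray] = field(init=False)   # within idx: observed?
    z_obs: list[np.ndarray] = field(init=False)      # observed log-times (within idx order)
    cens_bound: list[np.ndarray] = field(init=False)  # truncation bounds for censored (within idx)

    def __post_init__(self) -> None:
        n = len(self.y1)
        all_idx = np.arange(n)
        logy1 = np.log(self.y1)
        rec = self.d1 == 1
        sojourn = np.where(rec, self.y2 - self.y1, np.nan)
        tied = rec & (self.d2 == 1) & (sojourn <= 0)
        if tied.any():
            _warn_tied_sojourn()
            sojourn = np.where(tied, SOJOURN_EPSILON, sojourn)

        # transition 1: observed iff d1=1, else censored at log y1
        obs1 = rec.copy()
        z1 = np.where(obs1, logy1, np.nan)
        b1 = np.where(obs1, np.nan, logy1)

        # transition 2: observed iff death without recurrence; subjects with a
        # recurrence (or doubly censored) contribute S2 beyond log y1
        obs2 = (~rec) & (self.d2 == 1)
        z2 = np.where(obs2, np.log(self.y2), np.nan)
        b2 = np.where(obs2, np.nan, logy1)

        # transition 3: only recurrence subjects; observed iff d2=1, else
        # censored at the log sojourn (bound -inf when the censored sojourn is 0)
        idx3 = all_idx[rec]
        obs3 = self.d2[rec] == 1
        s3 = sojourn[rec]
        with np.errstate(divide="ignore"):
            logs3 = np.log(np.maximum(s3, 0.0))
        z3 = np.where(obs3, logs3, np.nan)
        b3 = np.where(obs3, np.nan, np.where(s3 > 0, logs3, -np.inf))

        self.idx = [all_idx, all_idx, idx3]
        self.obs_mask = [obs1, obs2, obs3]
        self.z_obs = [z1, z2, z3]
        self.cens_bound = [b1, b2, b3]

    @property
    def n(self) -> int:
        return len(self.y1)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def events_per_transition(self) -> list[int]:
        return [int(m.sum()) for m in self.obs_mask]

    @classmethod
    def from_dataset(cls, ds: Dataset, X: pd.DataFrame) -> "TransitionData":
        y1, d1, y2, d2 = ds.arrays()
        return cls(
            X=X.to_numpy(float), columns=list(X.columns), y1=y1, d1=d1, y2=y2, d2=d2
        )


def loglik_subjects(data: TransitionData, params: ModelParameters) -> np.ndarray:
    """Vector of per-subject log-likelihood contributions at the given state.

    Conditional on the frailty vector ``params.gamma`` (zeros if absent).
    """
    gamma = params.gamma if params.gamma is not None else np.zeros(data.n)
    out = np.zeros(data.n)
    for g in range(3):
        idx = data.idx[g]
        loc = data.X[idx] @ params.beta[g] + params.mu[g] + gamma[idx]
        sd = params.sigma[g]
        obs = data.obs_mask[g]
        contrib = np.zeros(len(idx))
        if obs.any():
            z = data.z_obs[g][obs]
            contrib[obs] = norm.logpdf(z, loc[obs], sd) - z
        cens = ~obs
        if cens.any():
            b = data.cens_bound[g][cens]
            finite = np.isfinite(b)
            vals = np.zeros(cens.sum())
            vals[finite] = norm.logsf(b[finite], loc[cens][finite], sd)
            contrib[cens] = vals
        np.add.at(out, idx, contrib)
    return out


# ---------------------------------------------------------------------------
# Data augmentation
# ---------------------------------------------------------------------------


def _standard_truncnorm(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard normal draws conditioned on exceeding ``a`` (vectorized).

    Inverse-CDF through the survival function: with s = Phi_bar(a) and
    u ~ U(0,1), isf(u*s) has the exact truncated law and stays accurate far
    into the upper tail (s underflows only beyond a ~ 37; those extreme
    bounds fall back on the asymptotic a + Exp(1)/a tail sampler).
    """
    a = np.asarray(a, dtype=float)
    out = np.empty(a.shape)
    u = rng.uniform(size=a.shape)
    far = a > 30.0
    if far.any():
        # upper-tail asymptotics: (X - a) | X > a  ->  Exp(a)/a
        out[far] = a[far] + rng.exponential(size=int(far.sum())) / a[far]
    rest = ~far
    if rest.any():
        s = norm.sf(a[rest])
        out[rest] = norm.isf(u[rest] * s)
    return out


def sample_truncated_normal(mean, sd, lower, rng: np.random.Generator):
    """Draw from Normal(mean, sd^2) conditioned on exceeding ``lower``.

    Vectorized over the inputs; ``lower = -inf`` entries are untruncated.
    Numerically stable for bounds many standard deviations above the mean.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    mean_b, sd_b, lower_b = np.broadcast_arrays(mean, sd, lower)
    a = (lower_b - mean_b) / sd_b
    out = np.empty(mean_b.shape)
    free = ~np.isfinite(a)
    if free.any():
        out[free] = rng.normal(mean_b[free], sd_b[free])
    trunc = ~free
    if trunc.any():
        out[trunc] = mean_b[trunc] + sd_b[trunc] * _standard_truncnorm(a[trunc], rng)
    if mean.ndim == 0 and sd.ndim == 0 and lower.ndim == 0:
        return float(out.reshape(())[()])
    return out


def augment_latent_logtimes(
    data: TransitionData, params: ModelParameters, rng: np.random.Generator
) -> list[np.ndarray]:
    """Impute complete-data log-times z_g for every transition.

    Observed events keep their exact log times (no randomness); censored
    pieces are drawn from the normal conditional truncated above the
    censoring bound.  Returns a list of three arrays aligned with
    ``data.idx[g]``.
    """
    gamma = params.gamma if params.gamma is not None else np.zeros(data.n)
    zs = []
    for g in range(3):
        idx = data.idx[g]
        loc = data.X[idx] @ params.beta[g] + params.mu[g] + gamma[idx]
        sd = params.sigma[g]
        z = data.z_obs[g].copy()
        cens = ~data.obs_mask[g]
        if cens.any():
            z[cens] = sample_truncated_normal(
                loc[cens], np.full(cens.sum(), sd), data.cens_bound[g][cens], rng
            )
        zs.append(z)
    return zs


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_sweep(
    data: TransitionData,
    state: ModelParameters,
    priors: PriorSpec,
    rng: np.random.Generator,
    update: frozenset[str] = ALL_BLOCKS,
) -> ModelParameters:
    """One full Gibbs scan; returns the updated state (input not modified).

    Blocks, in order: latent-time augmentation; joint (mu_g, beta_g) draw
    from the flat-prior normal conditional (least squares on z_g - gamma);
    sigma_g^2 from its inverse-gamma conditional; each gamma_i from its
    normal conditional pooling the subject's transition residuals with
    precision sum_g 1/sigma_g^2 + 1/theta; theta from
    IG(a + n/2, b + sum gamma_i^2 / 2).  ``update`` restricts the sweep to
    a subset of blocks (used by calibration tests with parameters pinned).
    """
    state = state.copy()
    if state.gamma is None:
        state.gamma = np.zeros(data.n)
    n = data.n

    zs = augment_latent_logtimes(data, state, rng) if "latent" in update else None
    if zs is None:
        raise ValueError("the latent block is required: the sweep operates on complete data")

    for g in range(3):
        idx = data.idx[g]
        m_g = len(idx)
        if m_g == 0:
            continue
        A = np.column_stack([np.ones(m_g), data.X[idx]])
        r = zs[g] - state.gamma[idx]
        if "coef" in update:
            AtA = A.T @ A
            coef_hat = np.linalg.solve(AtA, A.T @ r)
            # coef | z, sigma2 ~ N(coef_hat, sigma2 (A'A)^-1) under the flat prior
            L = np.linalg.cholesky(np.linalg.inv(AtA))
            coef = coef_hat + np.sqrt(state.sigma2[g]) * (
                L @ rng.standard_normal(len(coef_hat))
            )
            state.mu[g] = coef[0]
            state.beta[g] = coef[1:]
        if "sigma" in update:
            resid = r - A @ np.concatenate([[state.mu[g]], state.beta[g]])
            rss = float(resid @ resid)
            # IG(a + m/2, b + RSS/2) drawn as reciprocal of a gamma variate
            state.sigma2[g] = (priors.b_sigma[g] + rss / 2.0) / rng.gamma(
                priors.a_sigma[g] + m_g / 2.0
            )

    if "frailty" in update:
        if state.theta <= 0:
            state.gamma = np.zeros(n)
        else:
            prec = np.full(n, 1.0 / state.theta)
            mean_num = np.zeros(n)
            for g in range(2):  # transitions 1 and 2 involve every subject
                e = zs[g] - (data.X @ state.beta[g] + state.mu[g])
                mean_num += e / state.sigma2[g]
                prec += 1.0 / state.sigma2[g]
            idx3 = data.idx[2]
            if len(idx3):
                e3 = zs[2] - (data.X[idx3] @ state.beta[2] + state.mu[2])
                mean_num[idx3] += e3 / state.sigma2[2]
                prec[idx3] += 1.0 / state.sigma2[2]
            state.gamma = mean_num / prec + rng.standard_normal(n) / np.sqrt(prec)

    if "theta" in update:
        state.theta = float(
            (priors.b_theta + float(state.gamma @ state.gamma) / 2.0)
            / rng.gamma(priors.a_theta + n / 2.0)
        )

    bad = (
        not np.all(np.isfinite(state.mu))
        or not np.all(np.isfinite(state.sigma2))
        or not np.isfinite(state.theta)
        or not np.all(np.isfinite(state.gamma))
        or any(not np.all(np.isfinite(b)) for b in state.beta)
    )
    if bad:
        raise FloatingPointError(f"non-finite sampler state encountered: {state!r}")
    return state


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from all chains, plus diagnostics.

    Arrays are stacked over chains: ``beta`` has shape (draws, 3, p),
    ``mu``/``sigma2`` (draws, 3), ``theta`` (draws,), ``gamma`` (draws, n),
    ``loglik`` (draws,) and ``loglik_subject`` (draws, n) — the per-subject
    contributions conditional on the sampled frailty, used for LPML.
    """

    columns: list[str]
    beta: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    loglik: np.ndarray
    loglik_subject: np.ndarray
    chain: np.ndarray
    n_chains: int
    diagnostics: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return len(self.theta)

    def posterior_mean_params(self) -> ModelParameters:
        """Posterior means of (beta, mu, sigma2, theta, gamma) as a state."""
        return ModelParameters(
            beta=[self.beta[:, g, :].mean(axis=0) for g in range(3)],
            mu=self.mu.mean(axis=0),
            sigma2=self.sigma2.mean(axis=0),
            theta=float(self.theta.mean()),
            gamma=self.gamma.mean(axis=0),
        )

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Scalar parameters reshaped to (chain, draw) for diagnostics."""
        per = self.n_draws // self.n_chains
        out = {}

        def reshape(v):
            return v.reshape(self.n_chains, per)

        for g in range(3):
            for j, name in enumerate(self.columns):
                out[f"beta{g + 1}[{name}]"] = reshape(self.beta[:, g, j])
            out[f"mu{g + 1}"] = reshape(self.mu[:, g])
            out[f"sigma2_{g + 1}"] = reshape(self.sigma2[:, g])
        out["theta"] = reshape(self.theta)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: iteration, chain, parameter, value."""
        rows = []
        per = self.n_draws // self.n_chains
        for name, arr in self.scalar_draws().items():
            for c in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "iteration": np.arange(per),
                            "chain": c,
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _initial_state(data: TransitionData) -> ModelParameters:
    """beta=0, mu_g = mean observed log time of the transition, sigma2=1, theta=1."""
    mu = np.zeros(3)
    for g in range(3):
        obs = data.obs_mask[g]
        if obs.any():
            mu[g] = float(np.mean(data.z_obs[g][obs]))
    return ModelParameters(
        beta=[np.zeros(data.p) for _ in range(3)],
        mu=mu,
        sigma2=np.ones(3),
        theta=1.0,
        gamma=np.zeros(data.n),
    )


def _compute_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per scalar parameter (via arviz)."""
    import arviz as az

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in samples.scalar_draws().items():
            # arr has shape (chain, draw); arviz applies the split-R-hat rule
            rhat = float(np.asarray(az.rhat(arr))) if arr.shape[0] > 1 else np.nan
            ess = float(np.asarray(az.ess(arr)))
            rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
    return pd.DataFrame(rows)


def fit_model(
    ds: Dataset,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    model_variant: str = "stage_site_composite",
    X: pd.DataFrame | None = None,
    compute_diagnostics: bool = True,
) -> PosteriorSamples:
    """Fit the AFT illness-death model by data-augmentation Gibbs sampling.

    Runs ``mcmc.n_chains`` independent chains, discards burn-in, thins, and
    records the total and per-subject log-likelihood of every retained draw
    (conditional on the sampled frailties).  Raises if a transition has no
    observed event (the flat-prior posterior would be improper) or if the
    design is rank deficient.  Warns when split-R-hat exceeds 1.05.
    """
    if priors is None:
        priors = PriorSpec()
    if mcmc is None:
        raise ValueError("an MCMCConfig with an explicit seed is required")
    if X is None:
        X = encode_design(ds, model_variant)
    data = TransitionData.from_dataset(ds, X)
    events = data.events_per_transition()
    for g, m in enumerate(events):
        if m == 0:
            raise ValueError(
                f"no observed events for transition {g + 1} ({TRANSITION_NAMES[g]}): "
                "the model is not identifiable"
            )

    per_chain = mcmc.n_draws_per_chain
    n, p = data.n, data.p
    total = per_chain * mcmc.n_chains
    beta = np.empty((total, 3, p))
    mu = np.empty((total, 3))
    sigma2 = np.empty((total, 3))
    theta = np.empty(total)
    gamma = np.empty((total, n))
    loglik = np.empty(total)
    loglik_subject = np.empty((total, n))
    chain_id = np.empty(total, dtype=int)

    seed_seq = np.random.SeedSequence(mcmc.seed)
    for c, child in enumerate(seed_seq.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        state = _initial_state(data)
        k = 0
        for it in range(mcmc.n_iter):
            state = gibbs_sweep(data, state, priors, rng)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                if k >= per_chain:
                    break
                row = c * per_chain + k
                for g in range(3):
                    beta[row, g] = state.beta[g]
                mu[row] = state.mu
                sigma2[row] = state.sigma2
                theta[row] = state.theta
                gamma[row] = state.gamma
                ll = loglik_subjects(data, state)
                loglik_subject[row] = ll
                loglik[row] = float(ll.sum())
                chain_id[row] = c
                k += 1

    samples = PosteriorSamples(
        columns=data.columns,
        beta=beta,
        mu=mu,
        sigma2=sigma2,
        theta=theta,
        gamma=gamma,
        loglik=loglik,
        loglik_subject=loglik_subject,
        chain=chain_id,
        n_chains=mcmc.n_chains,
    )
    if compute_diagnostics and mcmc.n_chains > 1:
        diag = _compute_diagnostics(samples)
        samples.diagnostics = diag
        worst = diag["rhat"].max()
        if np.isfinite(worst) and worst > 1.05:
            bad = diag.loc[diag["rhat"].idxmax(), "parameter"]
            logger.warning("split-R-hat %.3f > 1.05 for %s: chains may not have mixed", worst, bad)
    return samples


def time_ratio_table(
    samples: PosteriorSamples,
    referents: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Time ratios with 95% credible intervals, per covariate per transition.

    TR = exp(posterior median of beta); the interval is the exp of the
    equal-tailed 2.5%/97.5% quantiles.  ``significant`` is True when the
    interval excludes 1.  ``referents`` maps a covariate group prefix to a
    referent label, adding the conventional referent rows of a dummy-coded
    covariate (TR and CI left blank).
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior")
    rows = []
    added_ref: set[str] = set()
    for j, name in enumerate(samples.columns):
        if referents:
            for prefix, ref_label in referents.items():
                if name.startswith(prefix + "_") and prefix not in added_ref:
                    for g in range(3):
                        rows.append(
                            {
                                "covariate": f"{prefix}_{ref_label}",
                                "transition": TRANSITION_NAMES[g],
                                "TR": np.nan,
                                "ci_low": np.nan,
                                "ci_high": np.nan,
                                "significant": False,
                                "referent": True,
                            }
                        )
                    added_ref.add(prefix)
        for g in range(3):
            draws = samples.beta[:, g, j]
            med = float(np.median(draws))
            lo, hi = np.quantile(draws, [0.025, 0.975])
            tr, cl, ch = float(np.exp(med)), float(np.exp(lo)), float(np.exp(hi))
            rows.append(
                {
                    "covariate": name,
                    "transition": TRANSITION_NAMES[g],
                    "TR": tr,
                    "ci_low": cl,
                    "ci_high": ch,
                    "significant": bool(cl > 1.0 or ch < 1.0),
                    "referent": False,
                }
            )
    return pd.DataFrame(rows)
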