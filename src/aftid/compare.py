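"""Model comparison: deviance information criterion and pseudo-marginal likelihood.

Both criteria are computed from the retained MCMC draws.  The deviance is
conditional on the frailties: the plug-in deviance evaluates the
likelihood at the posterior means of (beta, mu, sigma^2, gamma), so p_D
counts the frailty vector among the effective parameters.  The
conditional predictive ordinate of subject i is the harmonic mean of the
subject's per-draw likelihood, computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Dataset, encode_design
from .model import (
    MCMCConfig,
    PosteriorSamples,
    PriorSpec,
    TransitionData,
    fit_model,
    loglik_subjects,
)

__all__ = ["FitMetrics", "compute_dic", "compute_lpml", "compare_variants"]

#: per-subject log-likelihood draws below this are clipped before the
#: harmonic mean (they would otherwise overflow the reciprocal)
LOGLIK_CLIP = -700.0


@dataclass
class FitMetrics:
    """DIC (lower is better) and LPML (higher is better) for one fit."""

    dic: float
    p_d: float
    mean_deviance: float
    lpml: float
    cpo: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "dic": self.dic,
            "p_d": self.p_d,
            "mean_deviance": self.mean_deviance,
            "lpml": self.lpml,
        }


def compute_dic(samples: PosteriorSamples, data: TransitionData) -> tuple[float, float, float]:
    """(DIC, p_D, mean deviance) from the per-draw log-likelihoods.

    DIC = Dbar + p_D with Dbar the posterior mean of -2 log L and
    p_D = Dbar - D(posterior means), plugging in posterior means of all
    continuous parameters including the frailties.
    """
    if samples.n_draws < 2:
        raise ValueError("DIC needs at least two posterior draws")
    dbar = float(np.mean(-2.0 * samples.loglik))
    at_mean = samples.posterior_mean_params()
    d_hat = float(-2.0 * loglik_subjects(data, at_mean).sum())
    p_d = dbar - d_hat
    return dbar + p_d, p_d, dbar


def compute_lpml(samples: PosteriorSamples) -> tuple[float, np.ndarray]:
    """(LPML, CPO vector) via per-subject harmonic means over draws.

    log CPO_i = log M - logsumexp_m(-log L_i^(m)); LPML = sum_i log CPO_i.
    Draws with log L_i below the clip threshold are truncated with a
    warning rather than silently underflowing.
    """
    ll = samples.loglik_subject
    if ll.size == 0:
        raise ValueError("no per-subject likelihood contributions recorded")
    if np.any(~np.isfinite(ll)):
        bad = np.unique(np.nonzero(~np.isfinite(ll))[1])
        raise ValueError(f"non-finite likelihood contribution for subject index {bad[:5]}")
    if np.any(ll < LOGLIK_CLIP):
        warnings.warn(
            "per-subject log-likelihood draws below clip threshold; truncating",
            UserWarning,
        )
        ll = np.maximum(ll, LOGLIK_CLIP)
    m = ll.shape[0]
    log_cpo = np.log(m) - logsumexp(-ll, axis=0)
    return float(log_cpo.sum()), np.exp(log_cpo)


def fit_metrics(samples: PosteriorSamples, data: TransitionData) -> FitMetrics:
    dic, p_d, dbar = compute_dic(samples, data)
    lpml, cpo = compute_lpml(samples)
    return FitMetrics(dic=dic, p_d=p_d, mean_deviance=dbar, lpml=lpml, cpo=cpo)


def compare_variants(
    ds: Dataset,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    variants: tuple[str, str] = ("interaction", "stage_site_composite"),
) -> tuple[pd.DataFrame, dict[str, PosteriorSamples]]:
    """Fit the requested model variants and tabulate DIC and LPML.

    Preference is declared per criterion (lower DIC, higher LPML) without
    forcing the two to agree.  Returns the comparison table and the fitted
    samples keyed by variant.
    """
    rows = []
    fits: dict[str, PosteriorSamples] = {}
    for variant in variants:
        X = encode_design(ds, variant)
        samples = fit_model(ds, priors, mcmc, X=X)
        data = TransitionData.from_dataset(ds, X)
        metrics = fit_metrics(samples, data)
        fits[variant] = samples
        rows.append({"variant": variant, **metrics.summary()})
    table = pd.DataFrame(rows)
    table["preferred_by_dic"] = table["dic"] == table["dic"].min()
    table["preferred_by_lpml"] = table["lpml"] == table["lpml"].max()
    return table, fits
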