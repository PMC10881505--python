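"""Synthetic semi-competing-risks cohorts from the generative AFT model.

The generator emulates a surgical colorectal-cancer cohort: n = 284
patients, covariate category frequencies matching the published profile,
event times drawn from the three-transition log-normal AFT model with a
shared normal frailty, and administrative right-censoring drawn uniformly
over an accrual-style window.

Generative scheme per subject i, given covariates x_i:

1. gamma_i ~ Normal(0, theta);
2. latent T1* ~ LogNormal(mu_1 + x'b1 + gamma_i, sigma_1) and
   T2* ~ LogNormal(mu_2 + x'b2 + gamma_i, sigma_2), independent given
   gamma_i;
3. if T2* < T1* the subject dies without recurrence at T2*; otherwise the
   recurrence occurs at T1* and death follows at T1* + V with the sojourn
   V ~ LogNormal(mu_3 + x'b3 + gamma_i, sigma_3);
4. an administrative censoring time C_i ~ Uniform(c_min, c_max) truncates
   whatever it precedes, yielding (y1, d1, y2, d2) in the canonical
   cohort conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (
    DEFAULT_CODINGS,
    Dataset,
    SemiCompetingRecord,
    TIME_DECIMALS,
    build_design,
)
from .model import ModelParameters

__all__ = [
    "SimulationConfig",
    "TABLE1_FREQUENCIES",
    "default_true_params",
    "simulate_cohort",
    "event_type_probability",
]


# Marginal category frequencies of the study profile (counts / 284).
# stage and site are derived from the joint stage_site draw so the three
# stay mutually consistent; likewise chemotherapy (yes/no) follows from the
# chemotherapy-session group.  pt_stage, pn_stage and metastasis are not
# profiled in the published table; plausible surgical-cohort frequencies
# are used (see the methods note).
TABLE1_FREQUENCIES: dict[str, dict[int, float]] = {
    "age_group": {1: 91 / 284, 2: 158 / 284, 3: 35 / 284},
    "gender": {0: 134 / 284, 1: 150 / 284},
    "bmi_group": {1: 46 / 284, 2: 180 / 284, 3: 58 / 284},
    "grade": {1: 117 / 284, 2: 145 / 284, 3: 22 / 284},
    "tumor_size_group": {1: 72 / 284, 2: 160 / 284, 3: 52 / 284},
    "chemo_group": {0: 41 / 284, 1: 95 / 284, 2: 148 / 284},
    "stage_site": {1: 76 / 284, 2: 141 / 284, 3: 23 / 284, 4: 44 / 284},
    "radiotherapy": {0: 195 / 284, 1: 89 / 284},
    "morphology": {0: 3 / 284, 1: 281 / 284},
    "metastasis": {0: 0.85, 1: 0.15},
    "pt_stage": {1: 0.20, 2: 0.45, 3: 0.25, 4: 0.10},
    "pn_stage": {1: 0.45, 2: 0.30, 3: 0.15, 4: 0.10},
}

#: stage_site level -> (stage, site) codes; RC=rectum(1), CC=colon(2)
_STAGE_SITE_TO_PARTS = {1: (1, 1), 2: (1, 2), 3: (2, 1), 4: (2, 2)}

# Published time ratios for the stage-by-site dummies (Early_CC, Adv_RC,
# Adv_CC against the Early_RC referent), used as fixture effect sizes for
# the composite design; their logs are the default true coefficients.
_FIXTURE_TR = {
    "stage_site_Early_CC": (1.712, 1.933, 1.847),
    "stage_site_Adv_RC": (0.665, 1.399, 1.203),
    "stage_site_Adv_CC": (0.847, 2.743, 1.065),
}


def default_true_params(columns: list[str]) -> ModelParameters:
    """Fixture truth for a given composite-design column list.

    Stage-site dummy coefficients are the logs of the published time
    ratios; all other coefficients are zero.  These are fixture effect
    sizes for testing the pipeline, not ground truth of the real cohort.
    The error locations and scales are chosen so baseline median event
    times are tens of months (see the methods note for the calibration).
    """
    p = len(columns)
    beta = [np.zeros(p) for _ in range(3)]
    for name, trs in _FIXTURE_TR.items():
        if name in columns:
            j = columns.index(name)
            for g in range(3):
                beta[g][j] = np.log(trs[g])
    return ModelParameters(
        beta=beta,
        mu=np.array([4.15, 5.05, 3.3]),
        sigma2=np.array([1.0, 1.0, 0.64]),
        theta=0.75,
    )


@dataclass
class SimulationConfig:
    """Cohort size, covariate mix, generative truth and censoring window."""

    n: int = 284
    covariate_frequencies: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_FREQUENCIES.items()}
    )
    true_params: ModelParameters | None = None  # default: default_true_params
    censoring_window: tuple[float, float] = (12.0, 192.0)
    model_variant: str = "stage_site_composite"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        c_min, c_max = self.censoring_window
        if not (0 < c_min < c_max):
            raise ValueError("censoring window needs 0 < c_min < c_max")
        for name, freqs in self.covariate_frequencies.items():
            total = sum(freqs.values())
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"probabilities for {name!r} sum to {total}, not 1")
            if any(p < 0 for p in freqs.values()):
                raise ValueError(f"negative probability for {name!r}")
        if self.true_params is not None:
            if np.any(self.true_params.sigma2 <= 0):
                raise ValueError("sigma2 must be positive")
            if self.true_params.theta < 0:
                raise ValueError("theta must be nonnegative")


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Independent categorical draws; stage/site/chemotherapy derived."""
    n = cfg.n
    cols: dict[str, np.ndarray] = {}
    for name, freqs in cfg.covariate_frequencies.items():
        levels = np.array(sorted(freqs))
        probs = np.array([freqs[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        cols[name] = levels[rng.choice(len(levels), size=n, p=probs)]
    ss = cols["stage_site"]
    cols["stage"] = np.array([_STAGE_SITE_TO_PARTS[v][0] for v in ss])
    cols["site"] = np.array([_STAGE_SITE_TO_PARTS[v][1] for v in ss])
    cols["chemotherapy"] = (cols["chemo_group"] > 0).astype(int)
    return pd.DataFrame(cols)


def simulate_cohort(
    cfg: SimulationConfig, seed: int | np.random.Generator
) -> tuple[Dataset, pd.DataFrame]:
    """Generate a cohort and the latent truth behind it.

    Returns the validated :class:`Dataset` plus a truth table with one row
    per subject: the frailty, the latent recurrence and death times, the
    sojourn draw (NaN when death came first) and the censoring time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = _draw_covariates(cfg, rng)
    X = build_design(frame, DEFAULT_CODINGS, cfg.model_variant, check_rank=False)
    params = cfg.true_params or default_true_params(list(X.columns))
    Xa = X.to_numpy(float)
    n = cfg.n

    gamma = (
        rng.normal(0.0, np.sqrt(params.theta), size=n)
        if params.theta > 0
        else np.zeros(n)
    )
    s1, s2, s3 = params.sigma
    t1 = np.exp(params.mu[0] + Xa @ params.beta[0] + gamma + s1 * rng.standard_normal(n))
    t2 = np.exp(params.mu[1] + Xa @ params.beta[1] + gamma + s2 * rng.standard_normal(n))
    v = np.exp(params.mu[2] + Xa @ params.beta[2] + gamma + s3 * rng.standard_normal(n))
    c = rng.uniform(*cfg.censoring_window, size=n)

    death_first = t2 < t1
    sojourn = np.where(death_first, np.nan, v)

    y1 = np.empty(n)
    d1 = np.zeros(n, dtype=int)
    y2 = np.empty(n)
    d2 = np.zeros(n, dtype=int)

    # death without recurrence
    m = death_first & (t2 <= c)
    y1[m] = y2[m] = t2[m]
    d2[m] = 1
    # censored before anything
    m = (death_first & (t2 > c)) | (~death_first & (t1 > c))
    y1[m] = y2[m] = c[m]
    # recurrence observed
    rec = ~death_first & (t1 <= c)
    death_time = t1 + v
    m = rec & (death_time <= c)
    y1[m], d1[m], y2[m], d2[m] = t1[m], 1, death_time[m], 1
    m = rec & (death_time > c)
    y1[m], d1[m], y2[m] = t1[m], 1, c[m]

    y1 = np.round(y1, TIME_DECIMALS)
    y2 = np.round(y2, TIME_DECIMALS)
    y2 = np.maximum(y1, y2)  # guard against rounding inversions
    # canonical dialect: censored recurrence clock stops with the death clock
    y1 = np.where(d1 == 0, y2, y1)

    cov_names = [c_.name for c_ in DEFAULT_CODINGS]
    records = [
        SemiCompetingRecord(
            id=f"S{i + 1:04d}",
            y1=float(y1[i]),
            d1=int(d1[i]),
            y2=float(y2[i]),
            d2=int(d2[i]),
            covariates={name: int(frame[name].iloc[i]) for name in cov_names},
        )
        for i in range(n)
    ]
    ds = Dataset(records, list(DEFAULT_CODINGS))
    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "gamma": gamma,
            "t1_latent": t1,
            "t2_latent": t2,
            "sojourn": sojourn,
            "censor_time": c,
        }
    )
    return ds, truth


def event_type_probability(params: ModelParameters, x: np.ndarray) -> float:
    """P(death precedes recurrence), marginal over the shared frailty.

    The latent log-times differ by a Normal(l1 - l2, sigma_1^2 + sigma_2^2)
    variate once the shared frailty cancels, so the probability is
    Phi((l1 - l2) / sqrt(sigma_1^2 + sigma_2^2)) with l_g = mu_g + x'b_g.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    l1 = params.mu[0] + x @ params.beta[0]
    l2 = params.mu[1] + x @ params.beta[1]
    denom = np.sqrt(params.sigma2[0] + params.sigma2[1])
    return float(norm.cdf((l1 - l2) / denom))
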