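"""Fitting drivers: priors, initialization, and posterior sampling wrappers.

Default priors are weakly informative in the usual N-mixture style:
Normal(0, 10) on regression coefficients, with uniform constraints on the
interpretable intercept scales — mean total site abundance in (0, 100),
mean detection probability and mean proportion melanic in (0, 1).

Chains start from moment-based estimates (naive abundance regression,
empirical melanic share, typical detection rates) jittered per chain, which
keeps starts overdispersed without wasting burn-in in absurd regions of a
flat prior; prior-draw initialization remains available via ``init="prior"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit

from .data import SiteDataset, Standardizer
from .likelihood import (
    DOR_PARAM_NAMES,
    LIVING_PARAM_NAMES,
    DORModelParams,
    LivingLikelihood,
    dor_model_loglik,
)
from .mcmc import MCMCConfig, PosteriorSamples, Prior, PriorSpec, sample_posterior

__all__ = [
    "living_prior_spec",
    "dor_prior_spec",
    "laplace_approximation",
    "fit_living_model",
    "fit_dor_model",
]


def _prior_bounds(priors: PriorSpec) -> list[tuple[float | None, float | None]]:
    bounds = []
    for p in priors.priors.values():
        if p.family == "uniform" and p.scale == "identity":
            bounds.append((p.a, p.b))
        elif p.family == "uniform" and p.scale == "exp":
            lo = np.log(p.a) if p.a > 0 else None
            bounds.append((lo, np.log(p.b)))
        else:  # normal, or uniform on the expit scale over (0,1): unbounded
            bounds.append((None, None))
    return bounds


def laplace_approximation(loglik, priors: PriorSpec, x0: np.ndarray,
                          h: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and inverse-Hessian covariance (Gaussian approximation).

    Used to seed the random-walk sampler with a well-shaped proposal: the
    N-mixture posterior has a strong abundance-detection ridge that an
    identity proposal mixes through very slowly.
    """
    from scipy.optimize import minimize

    def neg(x):
        lp = priors.logpdf(x)
        if not np.isfinite(lp):
            return 1e10
        ll = loglik(x)
        return -(lp + ll) if np.isfinite(ll) else 1e10

    res = minimize(neg, x0, method="L-BFGS-B", bounds=_prior_bounds(priors),
                   options={"maxiter": 100, "maxfun": 1200, "eps": 1e-6})
    mode = res.x
    d = mode.size
    hess = np.empty((d, d))
    f0 = neg(mode)
    steps = h * (1.0 + np.abs(mode))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = steps[i]
        hess[i, i] = (neg(mode + ei) + neg(mode - ei) - 2 * f0) / steps[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = steps[j]
            hess[i, j] = hess[j, i] = (
                neg(mode + ei + ej) - neg(mode + ei - ej)
                - neg(mode - ei + ej) + neg(mode - ei - ej)
            ) / (4 * steps[i] * steps[j])
    # make the curvature safely positive definite before inverting
    eigval, eigvec = np.linalg.eigh(hess)
    eigval = np.clip(eigval, 1e-4, None)
    cov = (eigvec / eigval) @ eigvec.T
    return mode, cov


def living_prior_spec() -> PriorSpec:
    coef = Prior("normal", 0.0, 10.0)
    return PriorSpec({
        "beta0_N": Prior("uniform", 0.0, 100.0, scale="exp"),
        "beta1_N": coef,
        "beta0_M": Prior("uniform", 0.0, 1.0, scale="expit"),
        "beta1_M": coef,
        "a0_melanic": Prior("uniform", 0.0, 1.0, scale="expit"),
        "a1_melanic": coef,
        "a2_melanic": coef,
        "a0_gray": Prior("uniform", 0.0, 1.0, scale="expit"),
        "a1_gray": coef,
        "a2_gray": coef,
    })


def dor_prior_spec() -> PriorSpec:
    return PriorSpec({
        "alpha_D": Prior("normal", 0.0, 10.0),
        "beta_D": Prior("normal", 0.0, 10.0),
    })


def _living_moment_init(data: SiteDataset) -> np.ndarray:
    """Crude data-driven center for chain initialization."""
    z = data.distance_z()
    per_site = data.counts.groupby("site")
    tot_max = per_site[["count_melanic", "count_gray"]].max()
    tot = (tot_max["count_melanic"] + tot_max["count_gray"]).reindex(
        data.sites["site"]).to_numpy(dtype=float)
    # inflate naive maxima by a typical detection ~0.3 per survey
    lam_hat = np.log(np.clip(tot / 0.5 + 0.5, 0.2, 95.0))
    b1n, b0n = np.polyfit(z, lam_hat, 1)
    mel = per_site["count_melanic"].sum().reindex(data.sites["site"]).to_numpy(dtype=float)
    both = per_site[["count_melanic", "count_gray"]].sum().sum(axis=1).reindex(
        data.sites["site"]).to_numpy(dtype=float)
    share = np.clip((mel + 0.5) / (both + 1.0), 0.02, 0.98)
    b1m, b0m = np.polyfit(z, logit(share), 1)
    a0 = float(logit(0.15))
    return np.array([b0n, b1n, b0m, b1m, a0, 0.0, 0.0, a0, 0.0, 0.0])


def _overdispersed_inits(center, cov, priors, config, scale: float = 1.0):
    """Chain starts drawn around a center, rejecting prior-incompatible points."""
    chol = np.linalg.cholesky(cov)
    inits = []
    for seed in config.chain_seeds:
        rng = np.random.default_rng(seed ^ 0x5EED)
        for _ in range(100):
            cand = center + scale * (chol @ rng.standard_normal(center.size))
            if np.isfinite(priors.logpdf(cand)):
                inits.append(cand)
                break
        else:
            inits.append(np.asarray(center, dtype=float))
    return inits


def fit_living_model(
    data: SiteDataset,
    config: MCMCConfig,
    priors: PriorSpec | None = None,
    init: str = "laplace",
) -> PosteriorSamples:
    """Sample the posterior of the integrated living-squirrel model.

    With the default ``init="laplace"`` a mode/inverse-Hessian Gaussian
    approximation (itself started from moment estimates) supplies the
    proposal covariance and overdispersed chain starts; ``"moment"`` and
    ``"prior"`` fall back to jittered moment starts or raw prior draws with
    a fully adapted covariance.  Returns :class:`PosteriorSamples` whose
    meta carries the distance and temperature standardizers of the fitting
    dataset.
    """
    priors = priors or living_prior_spec()
    if tuple(priors.names) != LIVING_PARAM_NAMES:
        raise ValueError("living-model priors must cover the canonical parameters")
    loglik = LivingLikelihood(data, cam_dtype=np.float32)
    inits = None
    proposal_cov = None
    if init == "laplace":
        # mode finding needs smooth double precision for finite differences
        mode, cov = laplace_approximation(
            LivingLikelihood(data), priors, _living_moment_init(data))
        proposal_cov = cov
        inits = _overdispersed_inits(mode, cov, priors, config)
    elif init == "moment":
        center = _living_moment_init(data)
        inits = _overdispersed_inits(center, 0.25**2 * np.eye(center.size), priors, config,
                                     scale=1.0)
    elif init != "prior":
        raise ValueError("init must be 'laplace', 'moment' or 'prior'")
    meta = {
        "distance_mean": data.distance_std.mean,
        "distance_sd": data.distance_std.sd,
        "temperature_mean": data.temperature_std.mean,
        "temperature_sd": data.temperature_std.sd,
        "model": "living",
    }
    return sample_posterior(loglik, priors, config, init=inits,
                            proposal_cov=proposal_cov, meta=meta)


def fit_dor_model(
    records: pd.DataFrame,
    config: MCMCConfig,
    priors: PriorSpec | None = None,
    init: str = "moment",
) -> PosteriorSamples:
    """Sample the posterior of the DOR melanism cline.

    ``records`` needs columns ``distance_km`` and ``morph``; distances are
    standardized with the sample's own constants (stored in meta).
    """
    if len(records) == 0:
        raise ValueError("no DOR records")
    priors = priors or dor_prior_spec()
    if tuple(priors.names) != DOR_PARAM_NAMES:
        raise ValueError("DOR priors must cover (alpha_D, beta_D)")
    std = Standardizer.fit(records["distance_km"].to_numpy())
    z = std.transform(records["distance_km"].to_numpy())
    m = records["morph"].to_numpy(dtype=float)

    def loglik(theta):
        return dor_model_loglik(DORModelParams(theta[0], theta[1]), z, m)

    inits = None
    if init == "moment":
        center = np.array([float(logit(np.clip(m.mean(), 0.02, 0.98))), 0.0])
        inits = []
        for seed in config.chain_seeds:
            rng = np.random.default_rng(seed ^ 0x5EED)
            inits.append(center + 0.3 * rng.standard_normal(2))
    elif init != "prior":
        raise ValueError("init must be 'moment' or 'prior'")
    meta = {"distance_mean": std.mean, "distance_sd": std.sd, "model": "dor"}
    return sample_posterior(loglik, priors, config, init=inits, meta=meta)
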