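"""Self-contained posterior sampling and diagnostics.

A bundled adaptive random-walk Metropolis sampler stands in for an external
probabilistic-programming runtime: proposals are multivariate normal with a
global scale and an empirical covariance that are tuned only during a
dedicated adaptation phase (targeting 20-45% acceptance) and frozen before
sampling, which preserves detailed balance for the retained draws.

Diagnostics follow the usual protocol: split-chain Gelman-Rubin potential
scale reduction (each chain halved, so within-chain drift also registers)
with the conventional 1.1 convergence threshold, and posterior summaries as
pooled means with 2.5/97.5 percentile credible intervals (linear
interpolation between order statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import Standardizer

__all__ = [
    "Prior",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "standardize",
    "sample_posterior",
    "gelman_rubin",
    "posterior_summary",
]


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, SD 1 (n-1 denominator); returns constants."""
    std = Standardizer.fit(values)
    return std.transform(values), std.mean, std.sd


@dataclass(frozen=True)
class Prior:
    """One parameter's prior: ``normal(mean, sd)`` on the sampling scale, or
    ``uniform(lo, hi)`` on a named scale (``identity``, ``exp`` or ``expit``
    of the sampled parameter)."""

    family: str  # "normal" | "uniform"
    a: float  # mean | lo
    b: float  # sd | hi
    scale: str = "identity"  # for uniform: identity | exp | expit

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "normal" and self.b <= 0:
            raise ValueError("normal prior needs a positive SD")
        if self.family == "uniform" and not self.a < self.b:
            raise ValueError("uniform prior needs ordered bounds")
        if self.scale not in ("identity", "exp", "expit"):
            raise ValueError(f"unknown prior scale {self.scale!r}")

    def logpdf(self, x: float) -> float:
        if self.family == "normal":
            return -0.5 * ((x - self.a) / self.b) ** 2 - math.log(self.b * math.sqrt(2 * math.pi))
        width = self.b - self.a
        if self.scale == "identity":
            return -math.log(width) if self.a < x < self.b else -np.inf
        if self.scale == "exp":
            y = math.exp(x)
            return x - math.log(width) if self.a < y < self.b else -np.inf
        y = expit(x)
        if not self.a < y < self.b:
            return -np.inf
        return math.log(y) + math.log1p(-y) - math.log(width)

    def sample_init(self, rng: np.random.Generator) -> float:
        """Overdispersed but numerically safe starting draw (normal SDs are
        capped at 2.5 so flat priors do not start chains in absurd regions)."""
        if self.family == "normal":
            return self.a + min(self.b, 2.5) * rng.standard_normal()
        y = rng.uniform(self.a, self.b)
        if self.scale == "exp":
            return math.log(y)
        if self.scale == "expit":
            return float(logit(y))
        return y


@dataclass(frozen=True)
class PriorSpec:
    """Ordered parameter-name -> Prior mapping defining the sampling space."""

    priors: dict

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.priors)

    def logpdf(self, theta: np.ndarray) -> float:
        return sum(p.logpdf(x) for p, x in zip(self.priors.values(), theta))

    def sample_init(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample_init(rng) for p in self.priors.values()])


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: adaptation, iterations, burn-in, thinning, seeds."""

    n_chains: int = 3
    n_adapt: int = 1000
    n_iter: int = 3000
    n_burnin: int = 500
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("burn-in must be shorter than the sampling run")
        if self.thin < 1 or self.n_chains < 1 or self.n_adapt < 0:
            raise ValueError("invalid MCMC configuration")

    @classmethod
    def reference_protocol(cls, seed: int = 0) -> "MCMCConfig":
        """Three chains, 20,000 adaptation + 12,000 iterations, 1,000 burn-in,
        thin 10 -> 1,100 retained draws per chain (3,300 total)."""
        return cls(n_chains=3, n_adapt=20_000, n_iter=12_000, n_burnin=1_000,
                   thin=10, seed=seed)

    @property
    def chain_seeds(self) -> tuple[int, ...]:
        ss = np.random.SeedSequence(self.seed)
        return tuple(int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(self.n_chains))

    @property
    def n_retained(self) -> int:
        return math.ceil((self.n_iter - self.n_burnin) / self.thin)


@dataclass
class PosteriorSamples:
    """Labeled MCMC draws: array (chain, draw, parameter) plus run metadata.

    ``meta`` carries the standardizer constants of the fitting dataset and
    sampler bookkeeping (acceptance rates, seeds) needed to reproduce or
    back-transform the fit.
    """

    names: tuple[str, ...]
    draws: np.ndarray  # (n_chains, n_draws, n_params)
    config: MCMCConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, draws, parameters)")
        if not np.isfinite(self.draws).all():
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self, name: str | None = None) -> np.ndarray:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        if name is None:
            return flat
        return flat[:, self.names.index(name)]

    def standardizer(self, covariate: str = "distance") -> Standardizer:
        try:
            mean, sd = self.meta[f"{covariate}_mean"], self.meta[f"{covariate}_sd"]
        except KeyError as err:
            raise KeyError(f"no standardizer stored for {covariate!r}") from err
        return Standardizer(mean=mean, sd=sd)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iter, parameter, value."""
        c, d, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d * p),
            "iter": np.tile(np.repeat(np.arange(d), p), c),
            "parameter": np.tile(list(self.names), c * d),
            "value": self.draws.reshape(-1),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "PosteriorSamples":
        names = tuple(frame["parameter"].drop_duplicates())
        chains = sorted(frame["chain"].unique())
        mats = []
        for c in chains:
            sub = frame[frame["chain"] == c].pivot(index="iter", columns="parameter", values="value")
            mats.append(sub[list(names)].to_numpy())
        return cls(names=names, draws=np.stack(mats), meta=meta or {})


def _run_chain(loglik, priors: PriorSpec, config: MCMCConfig, seed: int,
               init: np.ndarray | None, proposal_cov: np.ndarray | None = None):
    rng = np.random.default_rng(seed)
    dim = len(priors.names)

    x = None
    for _ in range(100):
        cand = priors.sample_init(rng) if init is None else np.asarray(init, dtype=float)
        lp = priors.logpdf(cand)
        ll = loglik(cand) if np.isfinite(lp) else -np.inf
        if np.isfinite(lp + ll):
            x, logpost = cand, lp + ll
            break
        if init is not None:
            raise ValueError("log-likelihood is not finite at the supplied initial values")
    if x is None:
        raise RuntimeError("could not find finite initial values after 100 prior draws")

    log_s = math.log(2.38 / math.sqrt(dim))
    # a supplied covariance (e.g. a Laplace approximation) seeds the proposal
    # shape; the empirical covariance still refines it during adaptation
    chol = np.eye(dim) if proposal_cov is None else np.linalg.cholesky(proposal_cov)
    target = 0.30  # inside the 20-45% band
    history = np.empty((config.n_adapt, dim))

    def step(x, logpost, adapting, t):
        nonlocal log_s, chol
        prop = x + math.exp(log_s) * (chol @ rng.standard_normal(dim))
        lp = priors.logpdf(prop)
        ll = loglik(prop) if np.isfinite(lp) else -np.inf
        new = lp + ll
        log_alpha = new - logpost
        alpha = 1.0 if log_alpha >= 0 else math.exp(log_alpha)
        accept = rng.random() < alpha
        if accept:
            x, logpost = prop, new
        if adapting:
            log_s += (alpha - target) / (t + 1) ** 0.6
        return x, logpost, accept

    for t in range(config.n_adapt):
        x, logpost, _ = step(x, logpost, True, t)
        history[t] = x
        if t >= 200 and (t + 1) % 100 == 0:
            cov = np.cov(history[: t + 1].T).reshape(dim, dim)
            cov += 1e-6 * np.eye(dim)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:  # pragma: no cover
                pass

    kept = np.empty((config.n_retained, dim))
    n_acc = 0
    k = 0
    for t in range(config.n_iter):
        x, logpost, accepted = step(x, logpost, False, t)
        n_acc += accepted
        if t >= config.n_burnin and (t - config.n_burnin) % config.thin == 0:
            kept[k] = x
            k += 1
    return kept, n_acc / config.n_iter


def sample_posterior(
    loglik,
    priors: PriorSpec,
    config: MCMCConfig,
    init: np.ndarray | list | None = None,
    proposal_cov: np.ndarray | None = None,
    meta: dict | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of ``loglik`` + ``priors`` with adaptive RWM.

    ``init`` may be a per-chain sequence of starting vectors; by default each
    chain starts from an (overdispersed) prior draw.  When ``proposal_cov``
    is supplied (e.g., a Laplace approximation of the posterior), the
    proposal shape is fixed and only the global scale is tuned during
    adaptation.  Fully reproducible: chain seeds derive deterministically
    from ``config.seed``.
    """
    chains, rates = [], []
    for c, seed in enumerate(config.chain_seeds):
        chain_init = None if init is None else np.asarray(init[c], dtype=float)
        kept, rate = _run_chain(loglik, priors, config, seed, chain_init, proposal_cov)
        chains.append(kept)
        rates.append(rate)
    meta = dict(meta or {})
    meta["acceptance_rates"] = rates
    meta["chain_seeds"] = list(config.chain_seeds)
    return PosteriorSamples(names=priors.names, draws=np.stack(chains),
                            config=config, meta=meta)


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter."""
    draws = samples.draws
    if draws.shape[0] < 2:
        raise ValueError("R-hat needs at least two chains")
    if draws.shape[1] < 4:
        raise ValueError("R-hat needs at least 4 draws per chain to split")
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half, :], draws[:, -half:, :]], axis=0)
    m, n, _ = split.shape
    means = split.mean(axis=1)  # (m, p)
    w = split.var(axis=1, ddof=1).mean(axis=0)  # within
    b_over_n = means.var(axis=0, ddof=1)  # between / n
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w == 0, 1.0, rhat)
    return dict(zip(samples.names, rhat.astype(float)))


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Pooled mean and central 95% credible interval per parameter.

    Quantiles use linear interpolation between order statistics.
    """
    flat = samples.pooled()
    lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "mean": flat.mean(axis=0),
        "lower95": lo,
        "upper95": hi,
    }, index=list(samples.names))
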