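"""Posterior sampling by adaptive Metropolis-within-Gibbs.

The sampler works on a fixed unit hypercube.  Each unknown is mapped to a
coordinate u in (0,1):

* a plain-uniform parameter v ~ U(a, b) is v = a + u (b - a);
* a two-step pair (v, b) with b ~ U(b1, b2), v ~ U(a, b) becomes
  b = b1 + w (b2 - b1), v = a + u (b - a) for (u, w) in the unit square;
* a covariance with the accuracy-dependent feasible range [0, B(se, sp)]
  becomes cov = u * B, u in (0, 1).

In these coordinates the joint prior density is exactly constant (the
range-dependent normalizations cancel against the change-of-variables
Jacobians), so the target is the likelihood alone, the support is a fixed
cube, and no proposal can step outside the prior.  Each coordinate is then
logit-transformed to the real line and updated one at a time by a Gaussian
random walk whose scale adapts toward 0.44 acceptance during burn-in only
(Robbins-Monro), preserving the correct stationary distribution afterwards.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .priors import PARAM_NAMES, PriorSpec, TwoStepHierarchicalPrior, UniformPrior
from .screening_model import (
    ModelParams,
    ScreeningCounts,
    derived_quantities,
    log_likelihood,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "summarize",
    "convergence_diagnostics",
    "HEADLINE_PARAMS",
    "DERIVED_QUANTITIES",
]

HEADLINE_PARAMS = ("pi", "se1", "se2", "sp1", "sp2", "cov_dp", "cov_dn")
DERIVED_QUANTITIES = ("se_je", "sp_je", "ppv_je", "rho_dp", "rho_dn")

RHAT_WARN = 1.05


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``n_iterations`` is the total per-chain length *including* burn-in, so
    the retained draw count is ``n_chains * (n_iterations - n_burnin) /
    thinning``.  The defaults mirror the length used for the worked
    example's reported posteriors; tests and simulation replicates use
    shorter chains.
    """

    n_chains: int = 2
    n_iterations: int = 105_000
    n_burnin: int = 5_000
    thinning: int = 1
    seed: int = 0
    target_accept: float = 0.44
    init_scale: float = 1.0
    adapt_decay: float = 0.6
    factorized_likelihood: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thinning

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_iterations": self.n_iterations,
            "n_burnin": self.n_burnin,
            "thinning": self.thinning,
            "seed": self.seed,
            "target_accept": self.target_accept,
            "init_scale": self.init_scale,
            "adapt_decay": self.adapt_decay,
            "factorized_likelihood": self.factorized_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MCMCConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


# --------------------------------------------------------------------------
# coordinate system


def _coordinate_names(spec: PriorSpec) -> list[str]:
    names = []
    for p in PARAM_NAMES:
        if isinstance(spec.prior_for(p), TwoStepHierarchicalPrior):
            names.append(f"b_{p}")
        names.append(p)
    if spec.dependence:
        names += ["u_cov_dp", "u_cov_dn"]
    return names


def _make_transform(spec: PriorSpec):
    """Map a unit-cube vector to (pi, se1, se2, sp1, sp2, cdp, cdn, bounds).

    Returns ``(transform, names)`` where ``transform(u) -> (values7, bounds)``
    with values on the natural scale.  Flat prior on the cube by design.
    """
    names = _coordinate_names(spec)
    steps = []  # (param, lower, upper_or_None, has_hyper, b1, b2)
    for p in PARAM_NAMES:
        prior = spec.prior_for(p)
        if isinstance(prior, TwoStepHierarchicalPrior):
            steps.append((p, prior.lower, None,
                          prior.upper_hyper_lower, prior.upper_hyper_upper))
        else:
            steps.append((p, prior.lower, prior.upper, None, None))
    dependence = spec.dependence

    def transform(u: list[float]) -> tuple[tuple, dict]:
        k = 0
        vals = {}
        bounds = {}
        for p, lo, hi, b1, b2 in steps:
            if hi is None:
                b = b1 + u[k] * (b2 - b1)
                bounds[f"b_{p}"] = b
                k += 1
                vals[p] = lo + u[k] * (b - lo)
            else:
                vals[p] = lo + u[k] * (hi - lo)
            k += 1
        se1, se2, sp1, sp2 = vals["se1"], vals["se2"], vals["sp1"], vals["sp2"]
        if dependence:
            cdp = u[k] * (min(se1, se2) - se1 * se2)
            cdn = u[k + 1] * (min(sp1, sp2) - sp1 * sp2)
        else:
            cdp = cdn = 0.0
        return (vals["pi"], se1, se2, sp1, sp2, cdp, cdn), bounds

    return transform, names


def _make_loglik(counts: ScreeningCounts, factorized: bool):
    """Fast scalar log-likelihood closure (constants included)."""
    x11, x10, x01, x00 = (float(counts.x11), float(counts.x10),
                          float(counts.x01), float(counts.x00))
    a11, a10, a0 = float(counts.a11), float(counts.a10), float(counts.a0)
    n = x11 + x10 + x01 + x00
    m = a11 + a10
    lgamma = math.lgamma
    const_x = lgamma(n + 1) - (lgamma(x11 + 1) + lgamma(x10 + 1)
                               + lgamma(x01 + 1) + lgamma(x00 + 1))
    if factorized:
        const_a = lgamma(m + 1) - (lgamma(a11 + 1) + lgamma(a10 + 1))
    else:
        const_a = lgamma(n + 1) - (lgamma(a11 + 1) + lgamma(a10 + 1)
                                   + lgamma(a0 + 1))
    const = const_x + const_a
    log = math.log
    neg_inf = -math.inf

    def loglik(pi, se1, se2, sp1, sp2, cdp, cdn):
        q = 1.0 - pi
        p11 = pi * (se1 * se2 + cdp) + q * ((1 - sp1) * (1 - sp2) + cdn)
        p10 = pi * (se1 * (1 - se2) - cdp) + q * ((1 - sp1) * sp2 - cdn)
        p01 = pi * ((1 - se1) * se2 - cdp) + q * (sp1 * (1 - sp2) - cdn)
        p00 = pi * ((1 - se1) * (1 - se2) + cdp) + q * (sp1 * sp2 + cdn)
        se_je = se1 + se2 - se1 * se2 - cdp
        sp_je = sp1 * sp2 + cdn
        pa11 = pi * se_je
        pa10 = q * (1.0 - sp_je)
        ll = const
        for c, p in ((x11, p11), (x10, p10), (x01, p01), (x00, p00)):
            if c > 0.0:
                if p <= 0.0:
                    return neg_inf
                ll += c * log(p)
        if factorized:
            psum = pa11 + pa10
            if m > 0.0:
                if psum <= 0.0:
                    return neg_inf
                if a11 > 0.0:
                    if pa11 <= 0.0:
                        return neg_inf
                    ll += a11 * log(pa11 / psum)
                if a10 > 0.0:
                    if pa10 <= 0.0:
                        return neg_inf
                    ll += a10 * log(pa10 / psum)
        else:
            for c, p in ((a11, pa11), (a10, pa10), (a0, p00)):
                if c > 0.0:
                    if p <= 0.0:
                        return neg_inf
                    ll += c * log(p)
        return ll

    return loglik


# --------------------------------------------------------------------------
# draws container


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, one array of shape (n_chains, n_draws) per key.

    Keys: the seven base parameters, any latent two-step upper bounds
    (``b_se1`` etc.), and ``log_lik`` (the per-draw observed-data
    log-likelihood, multinomial constants included).
    """

    arrays: dict[str, np.ndarray]
    config: MCMCConfig
    prior_spec: PriorSpec
    counts: ScreeningCounts
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def stacked(self, key: str) -> np.ndarray:
        """All chains concatenated, shape (n_chains * n_draws,)."""
        if key in self.arrays:
            return self.arrays[key].reshape(-1)
        return self.derived(key).reshape(-1)

    def derived(self, key: str) -> np.ndarray:
        """Per-draw derived quantity, shape (n_chains, n_draws)."""
        a = self.arrays
        pi, se1, se2 = a["pi"], a["se1"], a["se2"]
        sp1, sp2 = a["sp1"], a["sp2"]
        cdp, cdn = a["cov_dp"], a["cov_dn"]
        if key == "se_je":
            return se1 + se2 - se1 * se2 - cdp
        if key == "sp_je":
            return sp1 * sp2 + cdn
        if key == "ppv_je":
            se_je = se1 + se2 - se1 * se2 - cdp
            sp_je = sp1 * sp2 + cdn
            return pi * se_je / (pi * se_je + (1 - pi) * (1 - sp_je))
        if key == "rho_dp":
            with np.errstate(divide="ignore", invalid="ignore"):
                return cdp / np.sqrt(se1 * (1 - se1) * se2 * (1 - se2))
        if key == "rho_dn":
            with np.errstate(divide="ignore", invalid="ignore"):
                return cdn / np.sqrt(sp1 * (1 - sp1) * sp2 * (1 - sp2))
        raise KeyError(key)

    def params_at(self, chain: int, draw: int) -> ModelParams:
        a = self.arrays
        return ModelParams(
            pi=a["pi"][chain, draw], se1=a["se1"][chain, draw],
            se2=a["se2"][chain, draw], sp1=a["sp1"][chain, draw],
            sp2=a["sp2"][chain, draw], cov_dp=a["cov_dp"][chain, draw],
            cov_dn=a["cov_dn"][chain, draw],
        )

    def posterior_mean_params(self) -> ModelParams:
        """Posterior mean of the seven base parameters on the natural scale."""
        m = {k: float(self.stacked(k).mean()) for k in HEADLINE_PARAMS}
        # the mean covariance can exceed the bound at the mean accuracies;
        # clip into the feasible range for a valid plug-in
        bdp = min(m["se1"], m["se2"]) - m["se1"] * m["se2"]
        bdn = min(m["sp1"], m["sp2"]) - m["sp1"] * m["sp2"]
        m["cov_dp"] = min(max(m["cov_dp"], 0.0), max(bdp, 0.0))
        m["cov_dn"] = min(max(m["cov_dn"], 0.0), max(bdn, 0.0))
        return ModelParams(**m)

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_d = self.n_chains, self.n_draws
        data = {"chain": np.repeat(np.arange(n_c), n_d),
                "draw": np.tile(np.arange(n_d), n_c)}
        for k, v in self.arrays.items():
            data[k] = v.reshape(-1)
        for k in DERIVED_QUANTITIES:
            data[k] = self.derived(k).reshape(-1)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def data_digest(self) -> str:
        payload = json.dumps(
            {"counts": self.counts.to_dict(), "priors": self.prior_spec.to_dict(),
             "config": self.config.to_dict()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# sampler


def _logit(u: float) -> float:
    return math.log(u / (1.0 - u))


def fit(
    counts: ScreeningCounts,
    spec: PriorSpec,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the two-stage model.

    Chains start from independent prior draws (uniform on the unit cube in
    sampler coordinates) and are updated coordinate-wise by an adaptive
    Gaussian random walk on the logit scale.  Reproducible for a fixed
    ``config.seed``.  If any headline parameter's split-chain potential
    scale reduction exceeds 1.05 a warning is attached to the result (and
    emitted), never an exception.
    """
    if config is None:
        config = MCMCConfig()
    transform, names = _make_transform(spec)
    loglik = _make_loglik(counts, config.factorized_likelihood)
    dim = len(names)
    n_ret = config.n_retained
    bound_names = [nm for nm in names if nm.startswith("b_")]
    store_keys = list(HEADLINE_PARAMS) + bound_names + ["log_lik"]
    out = {k: np.empty((config.n_chains, n_ret)) for k in store_keys}
    acc_rates: dict[str, float] = {}

    for chain in range(config.n_chains):
        # python's Random is noticeably faster than numpy Generator for
        # the scalar draws this single-site sampler needs
        chain_seed = int(np.random.SeedSequence([config.seed, chain])
                         .generate_state(1)[0])
        rng = random.Random(chain_seed)
        z = [_logit(min(max(rng.random(), 1e-12), 1 - 1e-12))
             for _ in range(dim)]
        u = [1.0 / (1.0 + math.exp(-zi)) for zi in z]
        vals, bounds = transform(u)
        # log target in z-space: loglik + sum log u(1-u) (flat cube prior)
        ll = loglik(*vals)
        jac = sum(math.log(ui * (1.0 - ui)) for ui in u)
        log_scales = [math.log(config.init_scale)] * dim
        accepted = [0] * dim
        proposed = [0] * dim
        k_ret = 0
        for t in range(config.n_iterations):
            adapting = t < config.n_burnin
            if adapting:
                gamma = (t + 1.0) ** (-config.adapt_decay)
            for j in range(dim):
                zj_old = z[j]
                uj_old = u[j]
                z[j] = zj_old + math.exp(log_scales[j]) * rng.gauss(0.0, 1.0)
                u[j] = 1.0 / (1.0 + math.exp(-z[j]))
                vals_new, bounds_new = transform(u)
                ll_new = loglik(*vals_new)
                jac_new = jac - math.log(uj_old * (1.0 - uj_old)) \
                    + math.log(u[j] * (1.0 - u[j]))
                log_alpha = (ll_new + jac_new) - (ll + jac)
                if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
                    vals, bounds, ll, jac = vals_new, bounds_new, ll_new, jac_new
                    accepted[j] += 1
                    acc = 1.0
                else:
                    z[j] = zj_old
                    u[j] = uj_old
                    acc = 0.0
                proposed[j] += 1
                if adapting:
                    log_scales[j] += gamma * (acc - config.target_accept)
            if t >= config.n_burnin and (t - config.n_burnin) % config.thinning == 0:
                for key, v in zip(HEADLINE_PARAMS, vals):
                    out[key][chain, k_ret] = v
                for bn in bound_names:
                    out[bn][chain, k_ret] = bounds[bn]
                out["log_lik"][chain, k_ret] = ll
                k_ret += 1
        for j, nm in enumerate(names):
            acc_rates[f"chain{chain}:{nm}"] = accepted[j] / max(proposed[j], 1)

    draws = PosteriorDraws(
        arrays=out, config=config, prior_spec=spec, counts=counts,
        acceptance_rates=acc_rates,
    )
    if config.n_chains >= 2:
        diag = convergence_diagnostics(draws)
        bad = diag[diag["rhat"] > RHAT_WARN]
        if len(bad):
            msg = ("potential scale reduction > "
                   f"{RHAT_WARN} for: {', '.join(bad.index)}")
            draws.warnings_.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return draws


# --------------------------------------------------------------------------
# summaries and diagnostics


@dataclass
class PosteriorSummary:
    """Posterior medians and central 95% credible intervals.

    ``table`` is indexed by quantity with columns ``median``, ``lower``,
    ``upper`` (2.5th / 97.5th percentiles) and, for base parameters when at
    least two chains were run, ``rhat`` and ``ess``.  Derived quantities
    are summarized from their per-draw values, never from summarized base
    parameters.
    """

    table: pd.DataFrame

    def median(self, key: str) -> float:
        return float(self.table.loc[key, "median"])

    def interval(self, key: str) -> tuple[float, float]:
        return (float(self.table.loc[key, "lower"]),
                float(self.table.loc[key, "upper"]))

    def to_dict(self) -> dict:
        out = {}
        for key, row in self.table.iterrows():
            out[key] = {c: (None if pd.isna(row[c]) else float(row[c]))
                        for c in self.table.columns}
        return out


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    if draws.n_draws == 0:
        raise ValueError("cannot summarize empty draws")
    diag = convergence_diagnostics(draws) if draws.n_chains >= 2 else None
    bound_names = [k for k in draws.arrays if k.startswith("b_")]
    rows = {}
    for key in list(HEADLINE_PARAMS) + list(DERIVED_QUANTITIES) + bound_names:
        v = draws.stacked(key)
        lo, med, hi = np.nanpercentile(v, [2.5, 50.0, 97.5])
        row = {"median": med, "lower": lo, "upper": hi,
               "rhat": np.nan, "ess": np.nan}
        if diag is not None and key in diag.index:
            row["rhat"] = diag.loc[key, "rhat"]
            row["ess"] = diag.loc[key, "ess"]
        rows[key] = row
    return PosteriorSummary(pd.DataFrame.from_dict(rows, orient="index"))


def convergence_diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-chain potential scale reduction and effective sample size.

    With a single chain the between-chain statistic is unavailable and the
    rhat column is NaN.
    """
    rows = {}
    for key in HEADLINE_PARAMS:
        arr = draws.arrays[key]
        if np.allclose(arr, arr.reshape(-1)[0]):
            # constant (e.g. covariances of the independence model)
            rows[key] = {"rhat": 1.0, "ess": float(arr.size)}
            continue
        idata = az.convert_to_dataset(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(idata)["x"])
            if draws.n_chains >= 2:
                rhat = float(az.rhat(idata)["x"])
            else:
                rhat = np.nan
        rows[key] = {"rhat": rhat, "ess": ess}
    return pd.DataFrame.from_dict(rows, orient="index")
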