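"""Prior structure: flat uniforms, two-step hierarchical uniforms, and
range-constrained uniforms on the dependence covariances.

The sensitivities receive a *two-step hierarchical uniform*: the analyst
fixes a defensible lower bound ``a`` and, instead of committing to an upper
bound, draws it from a second uniform, ``b ~ U(b1, b2)`` and then
``se ~ U(a, b)``.  This diffuses a risky upper-bound choice while keeping
the elicitation a matter of plain ranges.  Specificities and prevalence get
flat U(0,1) priors (or any plain uniform), and the covariances are uniform
on their accuracy-dependent feasible ranges [0, min(Se1,Se2) - Se1*Se2] and
[0, min(Sp1,Sp2) - Sp1*Sp2].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import yaml

from .screening_model import ModelParams, cov_dp_bound, cov_dn_bound

__all__ = [
    "UniformPrior",
    "TwoStepHierarchicalPrior",
    "PriorSpec",
    "sample_prior",
    "log_prior_density",
]

PARAM_NAMES = ("pi", "se1", "se2", "sp1", "sp2")


@dataclass(frozen=True)
class UniformPrior:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"uniform prior needs lower < upper, got "
                             f"({self.lower}, {self.upper})")
        if not (0.0 <= self.lower and self.upper <= 1.0):
            raise ValueError("probability-parameter prior must sit in [0, 1]")

    def to_dict(self) -> dict:
        return {"type": "uniform", "lower": self.lower, "upper": self.upper}


@dataclass(frozen=True)
class TwoStepHierarchicalPrior:
    """Uniform prior U(lower, b) whose upper bound b ~ U(b1, b2)."""

    lower: float
    upper_hyper_lower: float
    upper_hyper_upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper_hyper_lower
                < self.upper_hyper_upper <= 1.0):
            raise ValueError(
                "two-step prior needs lower < b1 < b2 <= 1, got "
                f"({self.lower}, {self.upper_hyper_lower}, "
                f"{self.upper_hyper_upper})"
            )

    def to_dict(self) -> dict:
        return {
            "type": "two_step_uniform",
            "lower": self.lower,
            "upper_hyper": [self.upper_hyper_lower, self.upper_hyper_upper],
        }


def _prior_from_dict(d: dict):
    kind = d.get("type", "uniform")
    if kind == "uniform":
        return UniformPrior(float(d["lower"]), float(d["upper"]))
    if kind == "two_step_uniform":
        b1, b2 = d["upper_hyper"]
        return TwoStepHierarchicalPrior(float(d["lower"]), float(b1), float(b2))
    raise ValueError(f"unknown prior type {kind!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Complete prior specification for the model's unknowns.

    ``dependence=False`` selects the conditional-independence variant with
    both covariances fixed at zero (no covariance priors at all); otherwise
    the covariances are uniform on their feasible ranges, with the
    range-dependent normalization included in the joint density.
    """

    pi: UniformPrior | TwoStepHierarchicalPrior
    se1: UniformPrior | TwoStepHierarchicalPrior
    se2: UniformPrior | TwoStepHierarchicalPrior
    sp1: UniformPrior | TwoStepHierarchicalPrior
    sp2: UniformPrior | TwoStepHierarchicalPrior
    dependence: bool = True

    def prior_for(self, name: str):
        return getattr(self, name)

    def two_step_names(self) -> list[str]:
        return [n for n in PARAM_NAMES
                if isinstance(self.prior_for(n), TwoStepHierarchicalPrior)]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {n: self.prior_for(n).to_dict() for n in PARAM_NAMES}
        d["dependence"] = self.dependence
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {n: _prior_from_dict(d[n]) for n in PARAM_NAMES}
        return cls(dependence=bool(d.get("dependence", True)), **kwargs)

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_yaml(cls, source) -> "PriorSpec":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                d = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_json(cls, source) -> "PriorSpec":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def flat(cls, dependence: bool = True) -> "PriorSpec":
        """U(0,1) on every probability parameter."""
        u = UniformPrior(0.0, 1.0)
        return cls(pi=u, se1=u, se2=u, sp1=u, sp2=u, dependence=dependence)


def _sample_one(prior, rng: np.random.Generator) -> tuple[float, float | None]:
    """Draw (value, latent upper bound or None)."""
    if isinstance(prior, TwoStepHierarchicalPrior):
        b = rng.uniform(prior.upper_hyper_lower, prior.upper_hyper_upper)
        return rng.uniform(prior.lower, b), b
    return rng.uniform(prior.lower, prior.upper), None


def sample_prior(
    spec: PriorSpec, seed=None
) -> tuple[ModelParams, dict[str, float]]:
    """Draw one parameter set (plus latent two-step upper bounds).

    For two-step priors the latent bound is drawn first, then the parameter
    uniformly on (lower, bound).  Covariances are drawn uniformly on the
    feasible range implied by the just-drawn accuracies, so the feasibility
    constraint holds by construction.  Returns ``(params, latent_bounds)``
    where ``latent_bounds`` maps e.g. ``"b_se1"`` to the drawn bound.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[str, float] = {}
    bounds: dict[str, float] = {}
    for name in PARAM_NAMES:
        v, b = _sample_one(spec.prior_for(name), rng)
        values[name] = v
        if b is not None:
            bounds[f"b_{name}"] = b
    if spec.dependence:
        cdp = rng.uniform(0.0, cov_dp_bound(values["se1"], values["se2"]))
        cdn = rng.uniform(0.0, cov_dn_bound(values["sp1"], values["sp2"]))
    else:
        cdp = cdn = 0.0
    return ModelParams(cov_dp=cdp, cov_dn=cdn, **values), bounds


def log_prior_density(
    params: ModelParams,
    latent_bounds: dict[str, float],
    spec: PriorSpec,
) -> float:
    """Joint log prior density of (params, latent bounds).

    For a two-step prior the joint density of (value, bound) is
    ``1/(b2-b1) * 1/(b-a)`` on its support; for a plain uniform it is
    ``1/(upper-lower)``.  The covariance terms contribute the reciprocal of
    their feasible range at the *current* accuracies (conditionally uniform
    given the accuracies).  Out of support returns ``-inf``, never raises.
    """
    total = 0.0
    for name in PARAM_NAMES:
        prior = spec.prior_for(name)
        v = getattr(params, name)
        if isinstance(prior, TwoStepHierarchicalPrior):
            key = f"b_{name}"
            if key not in latent_bounds:
                raise ValueError(f"missing latent bound {key!r} for two-step prior")
            b = latent_bounds[key]
            if not (prior.upper_hyper_lower <= b <= prior.upper_hyper_upper):
                return -math.inf
            if not (prior.lower <= v <= b):
                return -math.inf
            total -= math.log(prior.upper_hyper_upper - prior.upper_hyper_lower)
            total -= math.log(b - prior.lower)
        else:
            if not (prior.lower <= v <= prior.upper):
                return -math.inf
            total -= math.log(prior.upper - prior.lower)
    if spec.dependence:
        bdp = cov_dp_bound(params.se1, params.se2)
        bdn = cov_dn_bound(params.sp1, params.sp2)
        if not (0.0 <= params.cov_dp <= bdp) or bdp <= 0.0:
            return -math.inf
        if not (0.0 <= params.cov_dn <= bdn) or bdn <= 0.0:
            return -math.inf
        total -= math.log(bdp) + math.log(bdn)
    else:
        if params.cov_dp != 0.0 or params.cov_dn != 0.0:
            return -math.inf
    return total
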