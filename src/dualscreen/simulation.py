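"""Synthetic-data generation for the two-stage screening design and a
scenario runner for the simulation study.

Data are generated from the latent 8-cell disease x T1 x T2 multinomial
(so the stage-one table and the stage-two verification counts are
internally consistent by construction) and collapsed to the observable
seven-number summary: joint-positives are verified by a perfect gold
standard, double-negatives are not.

The bundled scenario presets cover the two study regimes: low prevalence
with a large sample (community cancer screening, pi = 0.01, n = 20,000)
and high prevalence with a small sample (clinic-based screening of
suspicious patients, pi = 0.40, n = 200), each with a high-accuracy and a
low-accuracy test pair, and conditional correlations rho_D+ = 0.5,
rho_D- = 0.4 as typically seen when two tests share a biological basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .inference import HEADLINE_PARAMS, MCMCConfig, fit, summarize
from .model_checking import deviance_summaries
from .priors import PriorSpec, TwoStepHierarchicalPrior, UniformPrior
from .screening_model import ModelParams, ScreeningCounts

__all__ = [
    "Scenario",
    "correlations_to_covariances",
    "simulate_counts",
    "run_scenario",
    "preset_scenario",
    "prior_spec_for_truth",
    "PRIOR_MODES",
    "SCENARIO_PRESETS",
]

PRIOR_MODES = (
    "informative_model",
    "informative_se",
    "two_step_se",
    "informative_sp",
)

# informative one-step uniforms, keyed by the true value
_INFORMATIVE_ACCURACY = {
    0.6: (0.5, 0.7),
    0.7: (0.6, 0.8),
    0.8: (0.7, 0.9),
    0.9: (0.85, 0.95),
    0.95: (0.90, 0.99),
}
# two-step hierarchical uniforms for sensitivities, keyed by the true value
_TWO_STEP_SE = {
    0.6: (0.5, 0.55, 0.99),
    0.7: (0.6, 0.65, 0.99),
    0.8: (0.7, 0.75, 0.99),
    0.9: (0.85, 0.9, 0.99),
    0.95: (0.9, 0.95, 0.99),
}
_INFORMATIVE_PI = {
    0.4: (0.3, 0.5),
    0.1: (0.05, 0.15),
    0.01: (0.005, 0.015),
}

# (pi, n, (se1, sp1), (se2, sp2)) for the four study regimes
SCENARIO_PRESETS = {
    "1.1": (0.01, 20_000, (0.90, 0.95), (0.95, 0.90)),
    "1.2": (0.01, 20_000, (0.60, 0.70), (0.70, 0.60)),
    "2.1": (0.40, 200, (0.90, 0.95), (0.95, 0.90)),
    "2.2": (0.40, 200, (0.60, 0.70), (0.70, 0.60)),
}

DEFAULT_RHO_DP = 0.5
DEFAULT_RHO_DN = 0.4


def correlations_to_covariances(
    rho_dp: float,
    rho_dn: float,
    se1: float,
    se2: float,
    sp1: float,
    sp2: float,
) -> tuple[float, float]:
    """Invert the correlation definitions to covariances.

    cov_dp = rho_dp * sqrt(Se1(1-Se1) Se2(1-Se2)), and analogously for the
    non-diseased class.  Raises if the requested correlation exceeds the
    maximum compatible with the feasibility bound, naming that maximum.
    """
    for name, v in (("se1", se1), ("se2", se2), ("sp1", sp1), ("sp2", sp2)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name}={v} must be strictly inside (0, 1)")
    sd_p = math.sqrt(se1 * (1 - se1) * se2 * (1 - se2))
    sd_n = math.sqrt(sp1 * (1 - sp1) * sp2 * (1 - sp2))
    cov_dp = rho_dp * sd_p
    cov_dn = rho_dn * sd_n
    max_dp = (min(se1, se2) - se1 * se2) / sd_p
    max_dn = (min(sp1, sp2) - sp1 * sp2) / sd_n
    if not 0.0 <= rho_dp <= max_dp + 1e-12:
        raise ValueError(
            f"rho_dp={rho_dp} infeasible for (se1, se2)=({se1}, {se2}); "
            f"maximum feasible correlation is {max_dp:.6f}"
        )
    if not 0.0 <= rho_dn <= max_dn + 1e-12:
        raise ValueError(
            f"rho_dn={rho_dn} infeasible for (sp1, sp2)=({sp1}, {sp2}); "
            f"maximum feasible correlation is {max_dn:.6f}"
        )
    return cov_dp, cov_dn


def latent_cell_probs(params: ModelParams) -> np.ndarray:
    """The 8-cell disease x T1 x T2 probabilities, ordered as
    (D+,11), (D+,10), (D+,01), (D+,00), (D-,11), (D-,10), (D-,01), (D-,00).
    """
    p, q = params.pi, 1.0 - params.pi
    se1, se2, sp1, sp2 = params.se1, params.se2, params.sp1, params.sp2
    cdp, cdn = params.cov_dp, params.cov_dn
    return np.array([
        p * (se1 * se2 + cdp),
        p * (se1 * (1 - se2) - cdp),
        p * ((1 - se1) * se2 - cdp),
        p * ((1 - se1) * (1 - se2) + cdp),
        q * ((1 - sp1) * (1 - sp2) + cdn),
        q * ((1 - sp1) * sp2 - cdn),
        q * (sp1 * (1 - sp2) - cdn),
        q * (sp1 * sp2 + cdn),
    ])


def simulate_counts(params: ModelParams, n: int, seed=None) -> ScreeningCounts:
    """Simulate one two-stage screening dataset of size n.

    Draws the latent 8-cell multinomial and collapses: the stage-one cells
    sum over disease status; the verified counts split the joint-positive
    patterns by disease status (perfect gold standard); a0 = x00.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = rng.multinomial(n, latent_cell_probs(params))
    dpos, dneg = cells[:4], cells[4:]
    x11 = int(dpos[0] + dneg[0])
    x10 = int(dpos[1] + dneg[1])
    x01 = int(dpos[2] + dneg[2])
    x00 = int(dpos[3] + dneg[3])
    a11 = int(dpos[0] + dpos[1] + dpos[2])   # diseased among joint-positives
    a10 = int(dneg[0] + dneg[1] + dneg[2])
    return ScreeningCounts(x11=x11, x10=x10, x01=x01, x00=x00,
                           a11=a11, a10=a10, a0=x00)


def _closest_key(table: dict, value: float, what: str) -> tuple:
    for k, v in table.items():
        if abs(k - value) < 1e-9:
            return v
    raise KeyError(
        f"no {what} prior is tabulated for true value {value}; "
        f"tabulated values: {sorted(table)}"
    )


def prior_spec_for_truth(
    truth: ModelParams, mode: str, dependence: bool = True
) -> PriorSpec:
    """Build the prior specification a given study mode pairs with a truth.

    Modes: ``informative_model`` centres one-step uniforms on every
    parameter's true value; ``informative_se`` does so for sensitivities
    only; ``two_step_se`` gives the sensitivities two-step hierarchical
    uniforms (lower bound below the truth, diffuse upper bound) and leaves
    everything else flat; ``informative_sp`` centres the specificities
    only.
    """
    if mode not in PRIOR_MODES:
        raise ValueError(f"unknown prior mode {mode!r}; one of {PRIOR_MODES}")
    flat = UniformPrior(0.0, 1.0)

    def se_prior(v):
        if mode == "two_step_se":
            return TwoStepHierarchicalPrior(*_closest_key(_TWO_STEP_SE, v, "two-step Se"))
        if mode in ("informative_model", "informative_se"):
            return UniformPrior(*_closest_key(_INFORMATIVE_ACCURACY, v, "Se"))
        return flat

    def sp_prior(v):
        if mode in ("informative_model", "informative_sp"):
            return UniformPrior(*_closest_key(_INFORMATIVE_ACCURACY, v, "Sp"))
        return flat

    if mode == "informative_model":
        pi_prior = UniformPrior(*_closest_key(_INFORMATIVE_PI, truth.pi, "pi"))
    else:
        pi_prior = flat
    return PriorSpec(
        pi=pi_prior,
        se1=se_prior(truth.se1), se2=se_prior(truth.se2),
        sp1=sp_prior(truth.sp1), sp2=sp_prior(truth.sp2),
        dependence=dependence,
    )


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a truth, a sample size, a prior mode and a
    model variant, replicated ``replicates`` times."""

    pi: float
    se1: float
    sp1: float
    se2: float
    sp2: float
    n: int
    rho_dp: float = DEFAULT_RHO_DP
    rho_dn: float = DEFAULT_RHO_DN
    prior_mode: str = "two_step_se"
    dependent_model: bool = True
    replicates: int = 1
    seed: int = 0
    name: str = ""

    def true_params(self) -> ModelParams:
        cdp, cdn = correlations_to_covariances(
            self.rho_dp, self.rho_dn, self.se1, self.se2, self.sp1, self.sp2
        )
        return ModelParams(pi=self.pi, se1=self.se1, se2=self.se2,
                           sp1=self.sp1, sp2=self.sp2,
                           cov_dp=cdp, cov_dn=cdn)

    def prior_spec(self) -> PriorSpec:
        return prior_spec_for_truth(
            self.true_params(), self.prior_mode, dependence=self.dependent_model
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name, "pi": self.pi,
            "se1": self.se1, "sp1": self.sp1,
            "se2": self.se2, "sp2": self.sp2,
            "n": self.n, "rho_dp": self.rho_dp, "rho_dn": self.rho_dn,
            "prior_mode": self.prior_mode,
            "dependent_model": self.dependent_model,
            "replicates": self.replicates, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**{k: d[k] for k in cls(pi=0.1, se1=0.5, sp1=0.5, se2=0.5,
                                           sp2=0.5, n=1).to_dict() if k in d})

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)


def preset_scenario(name: str, **overrides) -> Scenario:
    """One of the study presets '1.1', '1.2', '2.1', '2.2'."""
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown preset {name!r}; one of {sorted(SCENARIO_PRESETS)}")
    pi, n, (se1, sp1), (se2, sp2) = SCENARIO_PRESETS[name]
    base = Scenario(pi=pi, se1=se1, sp1=sp1, se2=se2, sp2=sp2, n=n, name=name)
    return replace(base, **overrides) if overrides else base


@dataclass
class ScenarioResult:
    """Per-replicate posterior summaries plus aggregates."""

    scenario: Scenario
    table: pd.DataFrame          # one row per replicate
    coverage: dict[str, float]   # fraction of replicates whose BCI covers truth
    mean_p_d: float
    mean_dic: float

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "coverage": self.coverage,
            "mean_pD": self.mean_p_d,
            "mean_DIC": self.mean_dic,
            "median_of_medians": {
                p: float(self.table[f"{p}_median"].median())
                for p in HEADLINE_PARAMS[:5]
            },
        }


def run_scenario(
    scenario: Scenario, mcmc: MCMCConfig | None = None
) -> ScenarioResult:
    """Simulate ``replicates`` datasets from the scenario's truth and fit
    the requested model variant to each.

    Reported per replicate: posterior medians and 95% BCIs of the five
    headline accuracy/prevalence parameters, pD and DIC; aggregated: BCI
    coverage of the truth, mean pD/DIC, and the median of medians.
    Sampler warnings (non-convergence) are collected, not fatal.
    """
    if mcmc is None:
        mcmc = MCMCConfig(n_chains=1, n_iterations=20_000, n_burnin=2_000)
    truth = scenario.true_params()
    spec = scenario.prior_spec()
    rng = np.random.default_rng(scenario.seed)
    rows = []
    import warnings as _warnings

    for rep in range(scenario.replicates):
        counts = simulate_counts(truth, scenario.n, rng)
        cfg = replace(mcmc, seed=int(np.random.SeedSequence(
            [scenario.seed, rep]).generate_state(1)[0]) % (2**31))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            draws = fit(counts, spec, cfg)
        summ = summarize(draws)
        _, _, p_d, dic = deviance_summaries(draws)
        row = {"replicate": rep, "pD": p_d, "DIC": dic}
        for p in HEADLINE_PARAMS[:5]:
            lo, hi = summ.interval(p)
            row[f"{p}_median"] = summ.median(p)
            row[f"{p}_lower"] = lo
            row[f"{p}_upper"] = hi
            row[f"{p}_covered"] = bool(lo <= getattr(truth, p) <= hi)
        rows.append(row)
    table = pd.DataFrame(rows)
    coverage = {p: float(table[f"{p}_covered"].mean())
                for p in HEADLINE_PARAMS[:5]}
    return ScenarioResult(
        scenario=scenario, table=table, coverage=coverage,
        mean_p_d=float(table["pD"].mean()), mean_dic=float(table["DIC"].mean()),
    )
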