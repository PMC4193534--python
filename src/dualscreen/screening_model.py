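"""Core probability model for a two-stage screening design with two
conditionally dependent dichotomous tests.

Stage one applies two imperfect tests T1, T2 simultaneously to all *n*
subjects, giving the 2x2 cross-classification ``(x11, x10, x01, x00)``.
Stage two verifies disease status with a gold standard, but only for
subjects positive on at least one test ("simultaneous testing" positive);
joint negatives are never verified, which is the source of the
partial-verification / non-identifiability problem this model addresses.

Conditional dependence between the tests within the diseased and
non-diseased subpopulations is parameterized by the covariances
``cov_dp = Cov(T1, T2 | D+)`` and ``cov_dn = Cov(T1, T2 | D-)``, both
restricted to their nonnegative feasible ranges.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "ScreeningCounts",
    "ModelParams",
    "CellProbs",
    "DerivedQuantities",
    "stage_one_cell_probs",
    "stage_two_cell_probs",
    "cell_probs",
    "joint_accuracy",
    "sequential_accuracy",
    "ppv_and_correlations",
    "derived_quantities",
    "log_likelihood",
    "cov_dp_bound",
    "cov_dn_bound",
]

COUNT_FIELDS = ("x11", "x10", "x01", "x00", "a11", "a10", "a0")


@dataclass(frozen=True)
class ScreeningCounts:
    """Observed count summary of a two-stage screening study.

    ``x11, x10, x01, x00`` are the stage-one cell counts for the test
    patterns (T1,T2) = (+,+), (+,-), (-,+), (-,-).  Among the
    joint-positives (anyone with at least one positive test), ``a11`` were
    verified diseased and ``a10`` verified non-diseased; ``a0`` is the
    unverified joint-negative total, which by design equals ``x00``.
    """

    x11: int
    x10: int
    x01: int
    x00: int
    a11: int
    a10: int
    a0: int

    def __post_init__(self) -> None:
        for name in COUNT_FIELDS:
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a nonnegative integer")
        pos = self.x11 + self.x10 + self.x01
        if self.a11 + self.a10 != pos:
            raise ValueError(
                "a11 + a10 must equal the joint-positive total x11 + x10 + x01 "
                f"({self.a11} + {self.a10} != {pos})"
            )
        if self.a0 != self.x00:
            raise ValueError(
                f"a0 must equal x00 (joint-negatives are exactly the "
                f"double-negatives): a0={self.a0}, x00={self.x00}"
            )

    @property
    def n(self) -> int:
        return self.x11 + self.x10 + self.x01 + self.x00

    @property
    def n_positive(self) -> int:
        """Number of subjects verified in stage two."""
        return self.x11 + self.x10 + self.x01

    def stage_one(self) -> np.ndarray:
        return np.array([self.x11, self.x10, self.x01, self.x00], dtype=float)

    def stage_two(self) -> np.ndarray:
        return np.array([self.a11, self.a10, self.a0], dtype=float)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: int(getattr(self, k)) for k in COUNT_FIELDS}
        d["n"] = self.n
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningCounts":
        counts = cls(**{k: int(d[k]) for k in COUNT_FIELDS})
        if "n" in d and int(d["n"]) != counts.n:
            raise ValueError(
                f"declared n={d['n']} does not equal x11+x10+x01+x00={counts.n}"
            )
        return counts

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "ScreeningCounts":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(COUNT_FIELDS + ("n",))
        w.writerow([getattr(self, k) for k in COUNT_FIELDS] + [self.n])
        s = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_csv(cls, source) -> "ScreeningCounts":
        if hasattr(source, "read"):
            rows = list(csv.DictReader(source))
        else:
            text = str(source)
            if "\n" in text or "," in text:
                rows = list(csv.DictReader(io.StringIO(text)))
            else:
                with open(text) as fh:
                    rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise ValueError(f"expected exactly one data row, got {len(rows)}")
        return cls.from_dict({k: int(v) for k, v in rows[0].items()})


def cov_dp_bound(se1: float, se2: float) -> float:
    """Upper feasibility bound for Cov(T1,T2|D+): min(Se1,Se2) - Se1*Se2."""
    return min(se1, se2) - se1 * se2


def cov_dn_bound(sp1: float, sp2: float) -> float:
    """Upper feasibility bound for Cov(T1,T2|D-): min(Sp1,Sp2) - Sp1*Sp2."""
    return min(sp1, sp2) - sp1 * sp2


@dataclass(frozen=True)
class ModelParams:
    """The seven base parameters plus the gold-standard accuracy constants.

    The gold standard is assumed perfect (``se_gs = sp_gs = 1``) by default;
    the constants are carried only for the sequential-testing formulas and
    are never treated as unknowns.
    """

    pi: float
    se1: float
    se2: float
    sp1: float
    sp2: float
    cov_dp: float = 0.0
    cov_dn: float = 0.0
    se_gs: float = 1.0
    sp_gs: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pi", "se1", "se2", "sp1", "sp2", "se_gs", "sp_gs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        bdp = cov_dp_bound(self.se1, self.se2)
        if not -1e-12 <= self.cov_dp <= bdp + 1e-12:
            raise ValueError(
                f"cov_dp={self.cov_dp} violates 0 <= cov_dp <= "
                f"min(se1,se2) - se1*se2 = {bdp}"
            )
        bdn = cov_dn_bound(self.sp1, self.sp2)
        if not -1e-12 <= self.cov_dn <= bdn + 1e-12:
            raise ValueError(
                f"cov_dn={self.cov_dn} violates 0 <= cov_dn <= "
                f"min(sp1,sp2) - sp1*sp2 = {bdn}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CellProbs:
    """Multinomial cell probabilities of both stages."""

    px11: float
    px10: float
    px01: float
    px00: float
    pa11: float
    pa10: float
    pa0: float

    def stage_one(self) -> np.ndarray:
        return np.array([self.px11, self.px10, self.px01, self.px00])

    def stage_two(self) -> np.ndarray:
        return np.array([self.pa11, self.pa10, self.pa0])


@dataclass(frozen=True)
class DerivedQuantities:
    """Joint-testing accuracy summaries derived from the base parameters.

    ``se_je``/``sp_je`` are the sensitivity and specificity of simultaneous
    testing ("Joint Either": positive if either test is positive);
    ``se_jb``/``sp_jb`` are those of the sequential strategy ("Joint Both":
    positive only if both the joint screen and the gold standard are
    positive).  ``rho_dp``/``rho_dn`` are the conditional correlations
    implied by the covariances; they are NaN when an accuracy sits exactly
    on the 0/1 boundary, where the correlation is undefined.
    """

    se11: float
    sp22: float
    se_je: float
    sp_je: float
    se_jb: float
    sp_jb: float
    ppv_je: float
    rho_dp: float
    rho_dn: float


def stage_one_cell_probs(params: ModelParams) -> np.ndarray:
    """Stage-one cell probabilities (px11, px10, px01, px00).

    Each cell mixes the diseased and non-diseased joint test-pattern
    probabilities, with the within-class dependence entering through the
    covariances:

        px11 = pi (Se1 Se2 + covDp) + (1-pi) ((1-Sp1)(1-Sp2) + covDn)
        px10 = pi (Se1(1-Se2) - covDp) + (1-pi) ((1-Sp1)Sp2 - covDn)
        px01 = pi ((1-Se1)Se2 - covDp) + (1-pi) (Sp1(1-Sp2) - covDn)
        px00 = pi ((1-Se1)(1-Se2) + covDp) + (1-pi) (Sp1 Sp2 + covDn)
    """
    p, q = params.pi, 1.0 - params.pi
    se1, se2, sp1, sp2 = params.se1, params.se2, params.sp1, params.sp2
    cdp, cdn = params.cov_dp, params.cov_dn
    px11 = p * (se1 * se2 + cdp) + q * ((1 - sp1) * (1 - sp2) + cdn)
    px10 = p * (se1 * (1 - se2) - cdp) + q * ((1 - sp1) * sp2 - cdn)
    px01 = p * ((1 - se1) * se2 - cdp) + q * (sp1 * (1 - sp2) - cdn)
    px00 = p * ((1 - se1) * (1 - se2) + cdp) + q * (sp1 * sp2 + cdn)
    return np.array([px11, px10, px01, px00])


def joint_accuracy(params: ModelParams) -> tuple[float, float]:
    """Sensitivity and specificity of simultaneous testing (JE).

    The joint screen is positive if either test is positive, so
    ``se_je = Se1 + Se2 - Se11`` with ``Se11 = Se1*Se2 + covDp``, and the
    joint screen is negative only when both tests are negative, so
    ``sp_je = Sp22 = Sp1*Sp2 + covDn``.
    """
    se_je = params.se1 + params.se2 - (params.se1 * params.se2 + params.cov_dp)
    sp_je = params.sp1 * params.sp2 + params.cov_dn
    return se_je, sp_je


def sequential_accuracy(
    se_je: float, sp_je: float, se_gs: float = 1.0, sp_gs: float = 1.0
) -> tuple[float, float]:
    """Sensitivity and specificity of sequential testing (JB).

    Sequential testing calls a subject positive only when the joint screen
    AND the gold standard are positive: ``se_jb = se_je * se_gs`` and
    ``sp_jb = 1 - (1 - sp_je)(1 - sp_gs)``.  With a perfect gold standard
    this is (se_je, 1).
    """
    for name, v in (("se_je", se_je), ("sp_je", sp_je),
                    ("se_gs", se_gs), ("sp_gs", sp_gs)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} must lie in [0, 1]")
    return se_je * se_gs, 1.0 - (1.0 - sp_je) * (1.0 - sp_gs)


def stage_two_cell_probs(params: ModelParams) -> np.ndarray:
    """Stage-two cell probabilities (pa11, pa10, pa0).

    With a perfect gold standard, a verified subject is diseased with the
    joint screen's true-positive mass:

        pa11 = pi * se_je         (diseased, screen positive)
        pa10 = (1-pi) * (1-sp_je) (non-diseased, screen positive)
        pa0  = pi (1-se_je) + (1-pi) sp_je  (screen negative, unverified)

    An imperfect gold standard misclassifies the verified subjects; the
    screen-negative mass ``pa0`` is unchanged because those subjects never
    reach the gold standard.
    """
    se_je, sp_je = joint_accuracy(params)
    p, q = params.pi, 1.0 - params.pi
    tp = p * se_je          # diseased and screen-positive
    fp = q * (1.0 - sp_je)  # non-diseased and screen-positive
    pa11 = tp * params.se_gs + fp * (1.0 - params.sp_gs)
    pa10 = tp * (1.0 - params.se_gs) + fp * params.sp_gs
    pa0 = p * (1.0 - se_je) + q * sp_je
    return np.array([pa11, pa10, pa0])


def cell_probs(params: ModelParams) -> CellProbs:
    """All seven multinomial cell probabilities of the two stages."""
    px = stage_one_cell_probs(params)
    pa = stage_two_cell_probs(params)
    return CellProbs(*px, *pa)


def ppv_and_correlations(params: ModelParams) -> tuple[float, float, float]:
    """PPV of simultaneous testing and the conditional correlations.

    ``ppv_je = pi se_je / (pi se_je + (1-pi)(1-sp_je))`` is the probability
    of disease given a positive joint screen.  The correlations rescale the
    covariances by the binary-variance product; at a boundary accuracy
    (0 or 1) the denominator vanishes and NaN is returned rather than an
    exception.
    """
    se_je, sp_je = joint_accuracy(params)
    denom = params.pi * se_je + (1.0 - params.pi) * (1.0 - sp_je)
    ppv = params.pi * se_je / denom if denom > 0 else math.nan
    vp = params.se1 * (1 - params.se1) * params.se2 * (1 - params.se2)
    vn = params.sp1 * (1 - params.sp1) * params.sp2 * (1 - params.sp2)
    rho_dp = params.cov_dp / math.sqrt(vp) if vp > 0 else math.nan
    rho_dn = params.cov_dn / math.sqrt(vn) if vn > 0 else math.nan
    return ppv, rho_dp, rho_dn


def derived_quantities(params: ModelParams) -> DerivedQuantities:
    se_je, sp_je = joint_accuracy(params)
    se_jb, sp_jb = sequential_accuracy(se_je, sp_je, params.se_gs, params.sp_gs)
    ppv, rho_dp, rho_dn = ppv_and_correlations(params)
    return DerivedQuantities(
        se11=params.se1 * params.se2 + params.cov_dp,
        sp22=params.sp1 * params.sp2 + params.cov_dn,
        se_je=se_je,
        sp_je=sp_je,
        se_jb=se_jb,
        sp_jb=sp_jb,
        ppv_je=ppv,
        rho_dp=rho_dp,
        rho_dn=rho_dn,
    )


def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> float:
    n = counts.sum()
    out = math.lgamma(n + 1.0)
    for c, p in zip(counts, probs):
        out -= math.lgamma(c + 1.0)
        if c > 0:
            if p <= 0.0:
                return -math.inf
            out += c * math.log(p)
    return out


def log_likelihood(
    counts: ScreeningCounts,
    params: ModelParams,
    factorized: bool = False,
    include_constant: bool = True,
) -> float:
    """Observed-data log-likelihood of the two-stage model.

    The default is the two-multinomial product formulation: the stage-one
    vector (x11, x10, x01, x00) is multinomial over its cell probabilities
    and the stage-two vector (a11, a10, a0) is a second multinomial over
    (pa11, pa10, pa0).  Because a0 = x00 and a11 + a10 equals the
    joint-positive total, the two factors share margin information; this is
    the model as fitted, kept for comparability of deviance summaries.

    With ``factorized=True`` the non-redundant factorization is used
    instead: the stage-one multinomial times a binomial split of the
    verified subjects into diseased/non-diseased with success probability
    pa11 / (pa11 + pa10).  Useful as a sensitivity analysis.

    Multinomial normalizing constants (log factorials) are included by
    default so deviance values are comparable across models on the same
    data; set ``include_constant=False`` to drop them.

    A zero cell probability paired with a positive count yields ``-inf``.
    """
    px = stage_one_cell_probs(params)
    pa = stage_two_cell_probs(params)
    x = counts.stage_one()
    ll = _multinomial_logpmf(x, px)
    if factorized:
        m = counts.n_positive
        psum = pa[0] + pa[1]
        if m > 0:
            if psum <= 0.0:
                return -math.inf
            p1 = pa[0] / psum
            ll += _multinomial_logpmf(
                np.array([counts.a11, counts.a10], dtype=float),
                np.array([p1, 1.0 - p1]),
            )
    else:
        ll += _multinomial_logpmf(counts.stage_two(), pa)
    if not include_constant and math.isfinite(ll):
        x_const = math.lgamma(counts.n + 1.0) - sum(
            math.lgamma(v + 1.0) for v in x
        )
        if factorized:
            a_const = math.lgamma(counts.n_positive + 1.0) - (
                math.lgamma(counts.a11 + 1.0) + math.lgamma(counts.a10 + 1.0)
            )
        else:
            a_const = math.lgamma(counts.n + 1.0) - sum(
                math.lgamma(v + 1.0) for v in counts.stage_two()
            )
        ll -= x_const + a_const
    return ll
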