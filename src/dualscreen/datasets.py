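"""Bundled example data: the colorectal-cancer screening study.

5,727 subjects aged 40-59 were screened with rehydrated guaiac faecal
occult blood testing (Hemoccult, T1) and immunochemical reversed passive
haemagglutination (RPHA-Hemeselect, T2); anyone positive on either test
was offered colonoscopic verification, double-negatives were not verified
(Castiglione et al.'s study, as analysed by Berry et al.).
"""

from __future__ import annotations

from .priors import PriorSpec, TwoStepHierarchicalPrior, UniformPrior
from .screening_model import ScreeningCounts

__all__ = ["colorectal_counts", "colorectal_priors"]


def colorectal_counts() -> ScreeningCounts:
    """The observed seven-number summary of the colorectal screening study.

    367 joint-positives were verified: 29 diseased (colorectal cancer or
    adenoma >= 10 mm), 338 not; the 5,360 double-negatives were not.
    """
    return ScreeningCounts(x11=39, x10=91, x01=237, x00=5360,
                           a11=29, a10=338, a0=5360)


def colorectal_priors(dependence: bool = True) -> PriorSpec:
    """The worked example's prior specification.

    Expert opinion put the sensitivity of Hemoccult above 0.5 and that of
    RPHA-Hemeselect above 0.6; the risky upper bounds are diffused by the
    two-step hierarchy, Se1 ~ U(0.5, U(0.55, 0.99)) and
    Se2 ~ U(0.6, U(0.65, 0.99)).  Specificities and prevalence are flat
    U(0, 1); the covariances are uniform on their feasible ranges.
    """
    return PriorSpec(
        pi=UniformPrior(0.0, 1.0),
        se1=TwoStepHierarchicalPrior(0.5, 0.55, 0.99),
        se2=TwoStepHierarchicalPrior(0.6, 0.65, 0.99),
        sp1=UniformPrior(0.0, 1.0),
        sp2=UniformPrior(0.0, 1.0),
        dependence=dependence,
    )
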