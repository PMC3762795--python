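"""Funnel-plot data and Harbord's modified small-study bias test.

For binary-outcome meta-analyses, regression-based asymmetry tests on the
log OR (Egger) have inflated type-I error when the odds ratio is large or
arms are unbalanced. Harbord's modification replaces the log OR with the
efficient score of the conditional likelihood and its information: for a
2×2 table with cells a,b (cases) and c,d (controls), margins fixed,

.. math::

    Z = a - \\frac{(a+b)(a+c)}{n}, \\qquad
    V = \\frac{(a+b)(c+d)(a+c)(b+d)}{n^2 (n-1)}.

``Z/\\sqrt{V}`` is regressed on ``\\sqrt{V}`` by ordinary least squares;
the intercept estimates small-study bias and is tested against zero with a
two-sided t-test on k−2 degrees of freedom. Scores are computed on the
uncorrected integer tables — Z and V are well defined with zero cells, and
a continuity correction would distort the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .contrasts import Contrast, ContrastTable, included_tables, study_effect
from .corpus import StudyCorpus

__all__ = ["FunnelPoint", "HarbordResult", "funnel_data", "harbord_test", "harbord"]


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    log_or: float
    se: float


@dataclass(frozen=True)
class HarbordResult:
    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float
    k: int
    dropped: tuple[str, ...] = ()


def funnel_data(corpus: StudyCorpus, contrast: Contrast | str) -> list[FunnelPoint]:
    """(log OR, SE) per included study, corpus order."""
    points = []
    for table in included_tables(corpus, contrast):
        eff = study_effect(table)
        points.append(FunnelPoint(study_id=eff.study_id, log_or=eff.log_or, se=eff.se))
    return points


def harbord_test(tables: Sequence[ContrastTable]) -> HarbordResult:
    """Harbord's modified test on a set of (non-excluded) 2×2 tables.

    Tables with zero score information (a degenerate margin) are dropped
    with their ids recorded; at least 3 informative studies are required.
    """
    usable = []
    dropped = []
    for t in tables:
        if t.excluded:
            dropped.append(t.study_id)
            continue
        a, b, c, d = t.uncorrected()
        n = a + b + c + d
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
        if v <= 0:
            dropped.append(t.study_id)
            continue
        z = a - (a + b) * (a + c) / n
        usable.append((z, v))
    k = len(usable)
    if k < 3:
        raise ValueError(f"Harbord test needs >=3 informative studies, found {k}")
    z = np.array([u[0] for u in usable])
    v = np.array([u[1] for u in usable])
    y = z / np.sqrt(v)
    x = np.sqrt(v)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    se = float(fit.bse[0])
    df = k - 2
    if se == 0.0 or not math.isfinite(se):
        # perfectly collinear residual-free fit: no evidence of bias
        t_stat, p = 0.0, 1.0
    else:
        t_stat = intercept / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return HarbordResult(
        intercept=intercept,
        intercept_se=se,
        t=t_stat,
        df=df,
        p=p,
        k=k,
        dropped=tuple(dropped),
    )


def harbord(corpus: StudyCorpus, contrast: Contrast | str) -> HarbordResult:
    """Harbord test for one contrast of a corpus."""
    contrast = Contrast.coerce(contrast)
    return harbord_test(included_tables(corpus, contrast))
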