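"""Fixed- and random-effects pooling of per-study odds ratios.

The fixed-effect pool is Mantel–Haenszel by default,

.. math::

    \\mathrm{OR}_{MH} = \\frac{\\sum_i a_i d_i / n_i}{\\sum_i b_i c_i / n_i},

with the Robins–Breslow–Greenland variance for its log, or optionally the
inverse-variance (Woolf) weighted mean of log ORs. Heterogeneity is
Cochran's Q — the inverse-variance weighted sum of squared deviations of
study log ORs about the fixed pooled log OR — with

.. math::

    I^2 = \\max\\left(0, 100\\,\\frac{Q - df}{Q}\\right), \\qquad
    \\tau^2_{DL} = \\max\\left(0, \\frac{Q - df}{\\sum w_i - \\sum w_i^2 / \\sum w_i}\\right).

The random-effects pool is DerSimonian–Laird: inverse-variance pooling with
weights :math:`w_i^* = 1/(se_i^2 + \\tau^2)`.

Model selection follows the heterogeneity rule used throughout the
analysis: fixed effect when the Q-test p-value exceeds 0.10, random effects
otherwise. Confidence intervals use the normal 1.96 multiplier and the
significance test of the pooled effect is a two-sided normal Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .contrasts import (
    Contrast,
    ContrastTable,
    EffectEstimate,
    included_tables,
    study_effect,
)
from .corpus import StudyCorpus

__all__ = [
    "FIXED_MH",
    "FIXED_IV",
    "RANDOM_DL",
    "Heterogeneity",
    "PooledResult",
    "pool_fixed",
    "pool_random",
    "heterogeneity",
    "select_model",
    "meta_analyse",
    "forest_frame",
]

FIXED_MH = "fixed_MH"
FIXED_IV = "fixed_IV"
RANDOM_DL = "random_DL"

_Z95 = 1.959963984540054  # normal 97.5% point; CIs are conventional 95%

# The analysis convention prints the 1.96 multiplier; keep exactly that so
# rendered intervals match hand computations of exp(logOR ± 1.96 SE).
_CI_MULTIPLIER = 1.96


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q with derived statistics."""

    q: float
    df: int
    p: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its inference and heterogeneity context."""

    contrast: Contrast
    model: str  # FIXED_MH, FIXED_IV or RANDOM_DL
    k: int
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p_z: float
    q: float
    p_q: float
    i2: float
    tau2: float
    n_cases: int | None = None
    n_controls: int | None = None

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def log_or(self) -> float:
        return math.log(self.or_)


def _iv_estimate(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    theta = np.array([e.log_or for e in effects])
    w = np.array([1 / e.se**2 for e in effects])
    return float(np.sum(w * theta) / np.sum(w)), float(1 / math.sqrt(np.sum(w)))


def _mh_estimate(tables: Sequence[ContrastTable]) -> tuple[float, float]:
    """Mantel–Haenszel log OR with Robins–Breslow–Greenland SE."""
    A = np.array([[t.a, t.b, t.c, t.d] for t in tables], dtype=float)
    a, b, c, d = A.T
    n = a + b + c + d
    R = np.sum(a * d / n)
    S = np.sum(b * c / n)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        np.sum(P * a * d / n) / (2 * R**2)
        + np.sum(P * b * c / n + Q * a * d / n) / (2 * R * S)
        + np.sum(Q * b * c / n) / (2 * S**2)
    )
    return float(np.log(R / S)), float(np.sqrt(var))


def _wrap(
    contrast: Contrast,
    model: str,
    k: int,
    log_or: float,
    se: float,
    het: Heterogeneity,
) -> PooledResult:
    z = log_or / se
    return PooledResult(
        contrast=contrast,
        model=model,
        k=k,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - _CI_MULTIPLIER * se),
        ci_high=math.exp(log_or + _CI_MULTIPLIER * se),
        z=z,
        p_z=float(2 * stats.norm.sf(abs(z))),
        q=het.q,
        p_q=het.p,
        i2=het.i2,
        tau2=0.0 if model in (FIXED_MH, FIXED_IV) else het.tau2,
    )


def heterogeneity(
    effects: Sequence[EffectEstimate], center: float | None = None
) -> Heterogeneity:
    """Cochran's Q about the fixed pooled log OR, with I² and DL τ².

    ``center`` defaults to the inverse-variance fixed estimate (classic
    Cochran form); pass the MH log OR to obtain the RevMan-style variant
    (dispersion about the MH estimate) instead. For a single study the
    statistics are defined as Q = 0, I² = 0, τ² = 0, p = 1.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effects to assess")
    if k == 1:
        return Heterogeneity(q=0.0, df=0, p=1.0, i2=0.0, tau2=0.0)
    theta = np.array([e.log_or for e in effects])
    w = np.array([1 / e.se**2 for e in effects])
    if center is None:
        center = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - center) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return Heterogeneity(q=q, df=df, p=p, i2=i2, tau2=tau2)


def pool_fixed(
    effects: Sequence[EffectEstimate],
    tables: Sequence[ContrastTable] | None = None,
    method: str = "MH",
    contrast: Contrast = Contrast.ALLELE,
    het: Heterogeneity | None = None,
) -> PooledResult:
    """Fixed-effect pooled OR (Mantel–Haenszel or inverse-variance)."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty effect list")
    method = method.upper()
    if method == "MH":
        if tables is None:
            raise ValueError("Mantel-Haenszel pooling requires the 2x2 tables")
        included = [t for t in tables if not t.excluded]
        if len(included) != len(effects):
            raise ValueError("tables and effects must describe the same studies")
        log_or, se = _mh_estimate(included)
        model = FIXED_MH
    elif method == "IV":
        log_or, se = _iv_estimate(effects)
        model = FIXED_IV
    else:
        raise ValueError(f"unknown fixed method {method!r}; expected 'MH' or 'IV'")
    if het is None:
        het = heterogeneity(effects)
    return _wrap(contrast, model, len(effects), log_or, se, het)


def pool_random(
    effects: Sequence[EffectEstimate],
    tau2: float,
    contrast: Contrast = Contrast.ALLELE,
    het: Heterogeneity | None = None,
) -> PooledResult:
    """DerSimonian–Laird random-effects pooled OR at a given τ²."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty effect list")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    theta = np.array([e.log_or for e in effects])
    w = np.array([1 / (e.se**2 + tau2) for e in effects])
    log_or = float(np.sum(w * theta) / np.sum(w))
    se = float(1 / math.sqrt(np.sum(w)))
    if het is None:
        het = heterogeneity(effects)
        het = replace(het, tau2=tau2)
    return _wrap(contrast, RANDOM_DL, len(effects), log_or, se, het)


def select_model(p_q: float, threshold: float = 0.10) -> str:
    """Heterogeneity rule: 'fixed' iff the Q-test p exceeds the threshold."""
    if not 0 <= p_q <= 1:
        raise ValueError(f"p_q must be a probability, got {p_q}")
    return "fixed" if p_q > threshold else "random"


def meta_analyse(
    corpus: StudyCorpus,
    contrast: Contrast | str,
    fixed_method: str = "MH",
    model_threshold: float = 0.10,
    q_about_mh: bool = False,
) -> PooledResult:
    """Full single-contrast meta-analysis of a corpus.

    Builds per-study tables (applying the zero-cell correction and the
    double-zero exclusion rule), assesses heterogeneity, selects fixed or
    random effects by the Q-test rule, pools, and attaches the included
    studies' summed sample sizes.

    ``q_about_mh`` switches Cochran's Q to disperse about the
    Mantel–Haenszel pooled estimate instead of the inverse-variance one.
    """
    contrast = Contrast.coerce(contrast)
    tables = included_tables(corpus, contrast)
    if not tables:
        raise ValueError(
            f"all studies are excluded from contrast {contrast.value!r}"
        )
    effects = [study_effect(t) for t in tables]
    center = None
    if q_about_mh:
        center = _mh_estimate(tables)[0]
    het = heterogeneity(effects, center=center)
    if select_model(het.p, model_threshold) == "fixed":
        result = pool_fixed(effects, tables, method=fixed_method,
                            contrast=contrast, het=het)
    else:
        result = pool_random(effects, het.tau2, contrast=contrast, het=het)
    included_ids = {t.study_id for t in tables}
    n_cases = sum(r.n_cases for r in corpus if r.study_id in included_ids)
    n_controls = sum(r.n_controls for r in corpus if r.study_id in included_ids)
    return replace(result, n_cases=n_cases, n_controls=n_controls)


def forest_frame(
    corpus: StudyCorpus, contrast: Contrast | str, **meta_kwargs
):
    """Forest-plot data: per-study rows plus the pooled row, corpus order."""
    import pandas as pd

    from .contrasts import effects_frame

    contrast = Contrast.coerce(contrast)
    per_study = effects_frame(corpus, contrast)
    pooled = meta_analyse(corpus, contrast, **meta_kwargs)
    pooled_row = pd.DataFrame(
        [{
            "study_id": f"Pooled ({pooled.model})",
            "contrast": contrast.value,
            "or": pooled.or_,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }]
    )
    return pd.concat([per_study, pooled_row], ignore_index=True)
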