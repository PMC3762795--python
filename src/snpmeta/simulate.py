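"""Synthetic case-control genotype corpora with controlled structure.

The generator emulates the shape of the real corpus: per study it draws a
control-arm minor (T) allele frequency, composes control genotypes under
Hardy–Weinberg proportions optionally distorted by an inbreeding
coefficient ``f``,

.. math::

    P(TT) = q^2 + f q (1-q), \\quad
    P(CT) = 2 q (1-q)(1-f), \\quad
    P(CC) = (1-q)^2 + f q (1-q),

and induces the disease association at the allele level: the study's true
log odds ratio :math:`\\theta_i \\sim N(\\theta, \\tau^2)` multiplies the
control-arm C-allele odds (C is the exposure of the allele contrast, so
the allele-contrast estimand is :math:`e^\\theta`), and case genotypes are
re-composed under HWE at the induced case allele frequency. Genotype
counts are multinomial draws.

Randomness is split per study from the master seed (``SeedSequence``
spawning), so corpora are reproducible and individual studies can be
regenerated independently of corpus size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .contrasts import Contrast, study_effects
from .corpus import (
    COMPLICATIONS_ABSENT,
    COMPLICATIONS_PRESENT,
    ETHNICITIES,
    StudyCorpus,
    StudyRecord,
)
from .pooling import heterogeneity, meta_analyse

__all__ = ["SimulationConfig", "simulate_corpus", "operating_characteristics",
           "OperatingCharacteristics"]

# Stratum label frequencies mirror the reference corpus composition
# (26/9/4 ethnicity split, 14/39 with complications present-or-unreported).
_ETHNICITY_P = (26 / 39, 9 / 39, 4 / 39)
_COMPLICATIONS_P = 14 / 39


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic study corpus.

    Defaults describe a corpus like the packaged one: 39 studies, arm
    sizes uniform on [40, 300] (the central range of the real corpus,
    which spans 7 to 1018), control T-allele frequency uniform on
    [0.10, 0.55], no true association, no between-study heterogeneity,
    controls in perfect HWE.
    """

    k: int = 39
    n_case_range: tuple[int, int] = (40, 300)
    n_ctrl_range: tuple[int, int] = (40, 300)
    maf_range: tuple[float, float] = (0.10, 0.55)
    true_log_or: float = 0.0
    tau: float = 0.0
    inbreeding_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("n_case_range", "n_ctrl_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-degenerate range of sizes >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie strictly inside (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding_f must lie in [0, 1)")


def _genotype_probs_control(q: float, f: float) -> np.ndarray:
    """(CC, CT, TT) control probabilities; q is the T frequency."""
    p = 1 - q
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError(
            f"degenerate genotype probabilities from q={q:.4f}, f={f:.4f}"
        )
    return probs


def _case_c_frequency(q_ctrl_t: float, theta: float) -> float:
    """Case C-allele frequency after multiplying control C odds by e^theta."""
    p_ctrl_c = 1 - q_ctrl_t
    odds = p_ctrl_c / (1 - p_ctrl_c) * math.exp(theta)
    return odds / (1 + odds)


def simulate_corpus(config: SimulationConfig) -> StudyCorpus:
    """Draw one corpus; deterministic under a fixed config (incl. seed)."""
    master = np.random.SeedSequence(config.seed)
    study_seeds = master.spawn(config.k)
    records = []
    for i, seq in enumerate(study_seeds):
        rng = np.random.default_rng(seq)
        n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
        n_ctrl = int(rng.integers(config.n_ctrl_range[0], config.n_ctrl_range[1] + 1))
        q = float(rng.uniform(*config.maf_range))
        theta = float(rng.normal(config.true_log_or, config.tau))
        ctrl_probs = _genotype_probs_control(q, config.inbreeding_f)
        p_case_c = _case_c_frequency(q, theta)
        case_probs = np.array([
            p_case_c**2,
            2 * p_case_c * (1 - p_case_c),
            (1 - p_case_c) ** 2,
        ])
        case = rng.multinomial(n_case, case_probs)
        ctrl = rng.multinomial(n_ctrl, ctrl_probs)
        ethnicity = ETHNICITIES[rng.choice(3, p=_ETHNICITY_P)]
        compl = (COMPLICATIONS_PRESENT if rng.random() < _COMPLICATIONS_P
                 else COMPLICATIONS_ABSENT)
        records.append(StudyRecord(
            study_id=f"sim{i + 1:03d}",
            ethnicity=ethnicity,
            complications=compl,
            case_cc=int(case[0]), case_ct=int(case[1]), case_tt=int(case[2]),
            ctrl_cc=int(ctrl[0]), ctrl_ct=int(ctrl[1]), ctrl_tt=int(ctrl[2]),
        ))
    return StudyCorpus(records=records,
                       provenance=f"simulated corpus (seed={config.seed})")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summary of the pooling pipeline on simulated corpora."""

    reps: int
    coverage: float         # share of 95% CIs containing the true OR
    rejection_rate: float   # share of reps with Z-test p < 0.05
    mean_or: float
    mean_tau2: float


def operating_characteristics(
    config: SimulationConfig,
    reps: int,
    seed: int | None = None,
    contrast: Contrast | str = Contrast.ALLELE,
    **meta_kwargs,
) -> OperatingCharacteristics:
    """Repeatedly simulate and meta-analyse; summarise calibration.

    Under ``true_log_or = 0`` the rejection rate is the Z-test's type-I
    error; under an effect it is power. Coverage is evaluated against
    ``exp(true_log_or)``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for stable operating characteristics")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    rep_seeds = master.spawn(reps)
    true_or = math.exp(config.true_log_or)
    covered = rejected = 0
    ors = []
    tau2s = []
    for seq in rep_seeds:
        rep_config = replace(config, seed=int(seq.generate_state(1)[0] % (2**31)))
        corpus = simulate_corpus(rep_config)
        result = meta_analyse(corpus, contrast, **meta_kwargs)
        covered += result.ci_low <= true_or <= result.ci_high
        rejected += result.p_z < 0.05
        ors.append(result.or_)
        # DL tau2 estimate itself, regardless of which model the rule picked
        tau2s.append(heterogeneity(study_effects(corpus, contrast)).tau2)
    return OperatingCharacteristics(
        reps=reps,
        coverage=covered / reps,
        rejection_rate=rejected / reps,
        mean_or=float(np.mean(ors)),
        mean_tau2=float(np.mean(tau2s)),
    )
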