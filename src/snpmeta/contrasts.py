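"""Genetic contrasts: 2×2 tables and per-study odds-ratio estimates.

A biallelic SNP with genotypes CC/CT/TT supports four standard 2×2 codings
of a case-control study ("genetic models"):

========================  ==========================  ==========================
contrast                  exposed                     unexposed
========================  ==========================  ==========================
``allele``                C alleles (2·CC + CT)       T alleles (2·TT + CT)
``dominant``              CC individuals              CT + TT individuals
``homozygote``            CC individuals              TT individuals (CT dropped)
``recessive``             TT individuals              CC + CT individuals
========================  ==========================  ==========================

The first-named group of the contrast label is always the exposure, i.e. the
numerator odds. Per-study effects are Woolf log odds ratios with
``se² = 1/a + 1/b + 1/c + 1/d``.

Zero-cell policy: if any single cell of the uncorrected table is zero, 0.5
is added to all four cells (the RevMan convention). If an entire exposure or
comparison column is empty in both arms (``a+c = 0`` or ``b+d = 0``), the
study carries no information about that contrast and is flagged excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .corpus import StudyCorpus, StudyRecord

__all__ = [
    "Contrast",
    "ContrastTable",
    "EffectEstimate",
    "ExcludedStudyError",
    "build_contrast",
    "study_effect",
    "contrast_tables",
    "included_tables",
    "study_effects",
    "effects_frame",
]


class Contrast(enum.Enum):
    """The four genetic contrasts of a biallelic (C/T) SNP."""

    ALLELE = "allele"
    DOMINANT = "dominant"
    HOMOZYGOTE = "homozygote"
    RECESSIVE = "recessive"

    @property
    def label(self) -> str:
        return {
            Contrast.ALLELE: "C-allele vs. T-allele",
            Contrast.DOMINANT: "CC vs. CT+TT",
            Contrast.HOMOZYGOTE: "CC vs. TT",
            Contrast.RECESSIVE: "TT vs. CC+CT",
        }[self]

    @classmethod
    def coerce(cls, value: "Contrast | str") -> "Contrast":
        if isinstance(value, cls):
            return value
        name = str(value).strip().lower()
        aliases = {
            "allele": cls.ALLELE,
            "allele_c_vs_t": cls.ALLELE,
            "dominant": cls.DOMINANT,
            "dominant_cc_vs_cttt": cls.DOMINANT,
            "homozygote": cls.HOMOZYGOTE,
            "homozygote_cc_vs_tt": cls.HOMOZYGOTE,
            "recessive": cls.RECESSIVE,
            "recessive_tt_vs_ccct": cls.RECESSIVE,
        }
        if name not in aliases:
            raise ValueError(
                f"unknown contrast {value!r}; expected one of "
                f"{sorted(set(a.value for a in cls))}"
            )
        return aliases[name]


class ExcludedStudyError(ValueError):
    """An operation was asked to use a table excluded from its contrast."""


@dataclass(frozen=True)
class ContrastTable:
    """A 2×2 case/control × exposed/unexposed table for one contrast.

    Cells are ``a`` = exposed cases, ``b`` = unexposed cases, ``c`` =
    exposed controls, ``d`` = unexposed controls. After the 0.5 zero-cell
    correction the cells are no longer integers and ``corrected`` is set.
    """

    study_id: str
    contrast: Contrast
    a: float
    b: float
    c: float
    d: float
    corrected: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def uncorrected(self) -> tuple[float, float, float, float]:
        """Cells with any 0.5 correction removed."""
        if not self.corrected:
            return (self.a, self.b, self.c, self.d)
        return (self.a - 0.5, self.b - 0.5, self.c - 0.5, self.d - 0.5)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study Woolf log odds ratio and its standard error."""

    study_id: str
    log_or: float
    se: float

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    def ci(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (
            math.exp(self.log_or - z * self.se),
            math.exp(self.log_or + z * self.se),
        )


def _raw_cells(record: StudyRecord, contrast: Contrast) -> tuple[int, int, int, int]:
    if contrast is Contrast.ALLELE:
        return (
            2 * record.case_cc + record.case_ct,
            2 * record.case_tt + record.case_ct,
            2 * record.ctrl_cc + record.ctrl_ct,
            2 * record.ctrl_tt + record.ctrl_ct,
        )
    if contrast is Contrast.DOMINANT:
        return (
            record.case_cc,
            record.case_ct + record.case_tt,
            record.ctrl_cc,
            record.ctrl_ct + record.ctrl_tt,
        )
    if contrast is Contrast.HOMOZYGOTE:
        return (record.case_cc, record.case_tt, record.ctrl_cc, record.ctrl_tt)
    return (
        record.case_tt,
        record.case_cc + record.case_ct,
        record.ctrl_tt,
        record.ctrl_cc + record.ctrl_ct,
    )


def build_contrast(record: StudyRecord, contrast: Contrast | str) -> ContrastTable:
    """Build the (possibly corrected, possibly excluded) 2×2 table.

    Exclusion (an empty exposed or unexposed column in both arms) is a
    flagged state rather than an error, so callers can count exclusions.
    """
    contrast = Contrast.coerce(contrast)
    a, b, c, d = _raw_cells(record, contrast)
    if a + c == 0 or b + d == 0:
        side = "exposed" if a + c == 0 else "unexposed"
        return ContrastTable(
            study_id=record.study_id,
            contrast=contrast,
            a=float(a), b=float(b), c=float(c), d=float(d),
            excluded=True,
            exclusion_reason=f"no {side} individuals in either arm",
        )
    if 0 in (a, b, c, d):
        return ContrastTable(
            study_id=record.study_id,
            contrast=contrast,
            a=a + 0.5, b=b + 0.5, c=c + 0.5, d=d + 0.5,
            corrected=True,
        )
    return ContrastTable(
        study_id=record.study_id, contrast=contrast,
        a=float(a), b=float(b), c=float(c), d=float(d),
    )


def study_effect(table: ContrastTable) -> EffectEstimate:
    """Woolf log OR and SE from a non-excluded table."""
    if table.excluded:
        raise ExcludedStudyError(
            f"study {table.study_id!r} is excluded from contrast "
            f"{table.contrast.value!r}: {table.exclusion_reason}"
        )
    log_or = math.log(table.a * table.d / (table.b * table.c))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return EffectEstimate(study_id=table.study_id, log_or=log_or, se=se)


def contrast_tables(
    corpus: StudyCorpus, contrast: Contrast | str, include_excluded: bool = True
) -> list[ContrastTable]:
    """Tables for every study in corpus order."""
    contrast = Contrast.coerce(contrast)
    tables = [build_contrast(rec, contrast) for rec in corpus]
    if not include_excluded:
        tables = [t for t in tables if not t.excluded]
    return tables


def included_tables(corpus: StudyCorpus, contrast: Contrast | str) -> list[ContrastTable]:
    return contrast_tables(corpus, contrast, include_excluded=False)


def study_effects(corpus: StudyCorpus, contrast: Contrast | str) -> list[EffectEstimate]:
    """Per-study effects for all non-excluded studies, corpus order."""
    return [study_effect(t) for t in included_tables(corpus, contrast)]


def effects_frame(corpus: StudyCorpus, contrast: Contrast | str) -> pd.DataFrame:
    """Exportable per-study table: cells, OR, 95% CI and IV weight."""
    contrast = Contrast.coerce(contrast)
    rows = []
    tables = contrast_tables(corpus, contrast)
    total_w = 0.0
    effs: dict[str, EffectEstimate] = {}
    for t in tables:
        if not t.excluded:
            e = study_effect(t)
            effs[t.study_id] = e
            total_w += 1 / e.se**2
    for t in tables:
        row = {
            "study_id": t.study_id,
            "contrast": contrast.value,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "corrected": t.corrected,
            "excluded": t.excluded,
        }
        if t.excluded:
            row.update({"or": float("nan"), "ci_low": float("nan"),
                        "ci_high": float("nan"), "weight_pct": 0.0})
        else:
            e = effs[t.study_id]
            lo, hi = e.ci()
            row.update({"or": e.or_, "ci_low": lo, "ci_high": hi,
                        "weight_pct": 100 * (1 / e.se**2) / total_w})
        rows.append(row)
    return pd.DataFrame(rows)
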