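"""Stratified meta-analysis and leave-one-out sensitivity analysis.

Strata come from record labels, never from run-time reclassification:
ethnicity (Asian / Caucasian / African), complication status of cases
(explicitly absent vs present-or-unreported), and control-arm HWE class.
The fixed-vs-random model rule is re-applied independently inside every
stratum and every leave-one-out iteration, because heterogeneity — and
therefore the selected model — is a property of the study set at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .contrasts import Contrast, included_tables
from .corpus import (
    COMPLICATIONS_ABSENT,
    COMPLICATIONS_PRESENT,
    ETHNICITIES,
    StudyCorpus,
)
from .hwe import partition_by_hwe
from .pooling import PooledResult, meta_analyse

__all__ = [
    "STRATIFICATIONS",
    "StratifiedReport",
    "LeaveOneOutReport",
    "stratified_meta",
    "leave_one_out",
    "report_frame",
    "leave_one_out_frame",
]

STRATIFICATIONS = ("overall", "ethnicity", "complications", "hwe")

HWE_IN = "controls_in_hwe"
HWE_OUT = "controls_not_in_hwe"


@dataclass
class StratifiedReport:
    """Pooled results per stratum × contrast for one stratification."""

    stratification: str
    cells: dict[str, dict[Contrast, PooledResult]] = field(default_factory=dict)
    stratum_sizes: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)


@dataclass
class LeaveOneOutReport:
    """Re-pooled results with each included study omitted in turn."""

    contrast: Contrast
    rows: list[tuple[str, PooledResult]] = field(default_factory=list)


def _strata(
    corpus: StudyCorpus, stratification: str, hwe_classifier: str, hwe_threshold: float
) -> list[tuple[str, StudyCorpus]]:
    if stratification == "overall":
        return [("all_studies", corpus)]
    if stratification == "ethnicity":
        return [
            (eth, corpus.subset(lambda r, e=eth: r.ethnicity == e))
            for eth in ETHNICITIES
        ]
    if stratification == "complications":
        return [
            (COMPLICATIONS_PRESENT,
             corpus.subset(lambda r: r.complications == COMPLICATIONS_PRESENT)),
            (COMPLICATIONS_ABSENT,
             corpus.subset(lambda r: r.complications == COMPLICATIONS_ABSENT)),
        ]
    if stratification == "hwe":
        in_hwe, out_hwe = partition_by_hwe(
            corpus, classifier=hwe_classifier, threshold=hwe_threshold
        )
        return [(HWE_IN, in_hwe), (HWE_OUT, out_hwe)]
    raise ValueError(
        f"unknown stratification {stratification!r}; expected one of {STRATIFICATIONS}"
    )


def stratified_meta(
    corpus: StudyCorpus,
    stratification: str,
    contrasts: tuple[Contrast, ...] = tuple(Contrast),
    hwe_classifier: str = "exact",
    hwe_threshold: float = 0.05,
    **meta_kwargs,
) -> StratifiedReport:
    """Meta-analyse every contrast within every stratum.

    Empty strata are omitted from the report with a notice rather than
    raising, so a corpus need not populate every label.
    """
    report = StratifiedReport(stratification=stratification)
    for label, sub in _strata(corpus, stratification, hwe_classifier, hwe_threshold):
        if len(sub) == 0:
            report.notices.append(f"stratum {label!r} has no studies; omitted")
            continue
        totals = sub.totals()
        report.stratum_sizes[label] = tuple(totals)
        report.cells[label] = {
            c: meta_analyse(sub, c, **meta_kwargs) for c in contrasts
        }
    return report


def leave_one_out(
    corpus: StudyCorpus, contrast: Contrast | str, **meta_kwargs
) -> LeaveOneOutReport:
    """Re-run the full meta-analysis once per included study, omitting it.

    Model selection is redone in every iteration. Only studies actually
    included for the contrast are omitted (an excluded study cannot change
    the pool), and each re-pooled analysis therefore has k−1 studies.
    """
    contrast = Contrast.coerce(contrast)
    included_ids = [t.study_id for t in included_tables(corpus, contrast)]
    if len(included_ids) < 2:
        raise ValueError(
            f"leave-one-out needs at least 2 included studies for "
            f"{contrast.value!r}, found {len(included_ids)}"
        )
    report = LeaveOneOutReport(contrast=contrast)
    for sid in included_ids:
        reduced = corpus.drop(sid)
        report.rows.append((sid, meta_analyse(reduced, contrast, **meta_kwargs)))
    return report


def _result_row(result: PooledResult) -> dict:
    return {
        "contrast": result.contrast.value,
        "model": result.model,
        "k": result.k,
        "df": result.df,
        "or": result.or_,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "z": result.z,
        "p_z": result.p_z,
        "q": result.q,
        "p_q": result.p_q,
        "i2": result.i2,
        "tau2": result.tau2,
        "n_cases": result.n_cases,
        "n_controls": result.n_controls,
    }


def report_frame(reports: list[StratifiedReport]) -> pd.DataFrame:
    """Flatten stratified reports into one results grid (one row per
    stratum × contrast), in report order."""
    rows = []
    for rep in reports:
        for label, by_contrast in rep.cells.items():
            for contrast, result in by_contrast.items():
                row = {"stratification": rep.stratification, "stratum": label}
                row.update(_result_row(result))
                rows.append(row)
    return pd.DataFrame(rows)


def leave_one_out_frame(report: LeaveOneOutReport) -> pd.DataFrame:
    rows = []
    for omitted, result in report.rows:
        row = {"omitted_study": omitted}
        row.update(_result_row(result))
        rows.append(row)
    return pd.DataFrame(rows)
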