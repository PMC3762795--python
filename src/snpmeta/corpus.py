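"""Study data model and corpus I/O.

A *study corpus* is an ordered collection of case-control studies of a
biallelic SNP, each contributing six genotype counts (CC/CT/TT among cases
and among controls) plus stratum labels used by the subgroup analyses:
a broad ethnicity group and whether serious disease-related complications
were explicitly absent among cases.

The corpus of 39 MTHFR 677C→T / type 2 diabetes case-control studies
(4855 cases, 5242 controls) ships with the package and is the reference
input for the whole pipeline; see :func:`load_mthfr_t2dm`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, NamedTuple

import pandas as pd

__all__ = [
    "ETHNICITIES",
    "COMPLICATIONS_ABSENT",
    "COMPLICATIONS_PRESENT",
    "CorpusError",
    "SchemaError",
    "ValidationError",
    "StudyRecord",
    "StudyCorpus",
    "CorpusTotals",
    "load_corpus",
    "write_corpus",
    "corpus_totals",
    "load_mthfr_t2dm",
]

ETHNICITIES = ("Asian", "Caucasian", "African")

#: Cases explicitly reported free of serious disease-related complications.
COMPLICATIONS_ABSENT = "explicitly_absent"
#: Complications reported present, or not reported on at all.
COMPLICATIONS_PRESENT = "present_or_unreported"

COMPLICATIONS = (COMPLICATIONS_ABSENT, COMPLICATIONS_PRESENT)

_COUNT_FIELDS = ("case_cc", "case_ct", "case_tt", "ctrl_cc", "ctrl_ct", "ctrl_tt")

REQUIRED_COLUMNS = ("study_id", "ethnicity", "complications") + _COUNT_FIELDS
OPTIONAL_COLUMNS = ("reported_hwe_p",)


class CorpusError(ValueError):
    """Base error for corpus construction problems."""


class SchemaError(CorpusError):
    """A required column is missing from an input file."""


class ValidationError(CorpusError):
    """A record violates a data invariant."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's genotype counts and stratum labels.

    ``reported_hwe_p`` keeps the control-arm HWE p-value as printed in the
    source table, which may be a bound such as ``"<0.001"``; use
    :meth:`reported_hwe_bound` for a parsed numeric form.
    """

    study_id: str
    ethnicity: str
    complications: str
    case_cc: int
    case_ct: int
    case_tt: int
    ctrl_cc: int
    ctrl_ct: int
    ctrl_tt: int
    reported_hwe_p: str | None = None

    def __post_init__(self) -> None:
        if not self.study_id or not str(self.study_id).strip():
            raise ValidationError("study_id must be a non-empty label")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {self.study_id!r}: ethnicity {self.ethnicity!r} "
                f"not one of {ETHNICITIES}"
            )
        if self.complications not in COMPLICATIONS:
            raise ValidationError(
                f"study {self.study_id!r}: complications {self.complications!r} "
                f"not one of {COMPLICATIONS}"
            )
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValidationError(
                    f"study {self.study_id!r}: field {name!r} must be an "
                    f"integer, got {value!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: field {name!r} is negative ({value})"
                )
        if self.n_cases < 1:
            raise ValidationError(f"study {self.study_id!r}: no cases")
        if self.n_controls < 1:
            raise ValidationError(f"study {self.study_id!r}: no controls")

    @property
    def n_cases(self) -> int:
        return self.case_cc + self.case_ct + self.case_tt

    @property
    def n_controls(self) -> int:
        return self.ctrl_cc + self.ctrl_ct + self.ctrl_tt

    @property
    def case_genotypes(self) -> tuple[int, int, int]:
        return (self.case_cc, self.case_ct, self.case_tt)

    @property
    def control_genotypes(self) -> tuple[int, int, int]:
        return (self.ctrl_cc, self.ctrl_ct, self.ctrl_tt)

    def reported_hwe_bound(self) -> tuple[float, bool] | None:
        """Parse ``reported_hwe_p`` into ``(value, is_upper_bound)``.

        ``"<0.001"`` parses to ``(0.001, True)``; a plain decimal parses to
        ``(value, False)``. Returns ``None`` when nothing was reported.
        """
        raw = self.reported_hwe_p
        if raw is None:
            return None
        raw = str(raw).strip()
        if not raw:
            return None
        if raw.startswith("<"):
            return (float(raw[1:]), True)
        return (float(raw), False)


class CorpusTotals(NamedTuple):
    n_studies: int
    n_cases: int
    n_controls: int


@dataclass
class StudyCorpus:
    """Ordered, identifier-unique collection of :class:`StudyRecord`.

    Order is meaningful: forest-plot and leave-one-out rows follow it.
    """

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise ValidationError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> StudyRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.study_id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def study_ids(self) -> list[str]:
        return [rec.study_id for rec in self.records]

    def subset(
        self, predicate: Callable[[StudyRecord], bool], provenance: str | None = None
    ) -> "StudyCorpus":
        """Order-preserving filtered copy."""
        return StudyCorpus(
            records=[r for r in self.records if predicate(r)],
            provenance=provenance if provenance is not None else self.provenance,
        )

    def drop(self, study_id: str) -> "StudyCorpus":
        if study_id not in self.study_ids:
            raise KeyError(study_id)
        return self.subset(lambda r: r.study_id != study_id)

    def totals(self) -> CorpusTotals:
        return corpus_totals(self)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {name: getattr(rec, name) for name in REQUIRED_COLUMNS}
            row["reported_hwe_p"] = rec.reported_hwe_p if rec.reported_hwe_p is not None else ""
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["reported_hwe_p"])


def _dialect_sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if dialect not in ("csv", "tsv"):
        raise CorpusError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    return "\t" if dialect == "tsv" else ","


def _record_from_row(row: pd.Series) -> StudyRecord:
    counts = {}
    for name in _COUNT_FIELDS:
        value = row[name]
        try:
            as_float = float(value)
        except (TypeError, ValueError):
            raise ValidationError(
                f"study {row['study_id']!r}: field {name!r} is not a number "
                f"({value!r})"
            ) from None
        if as_float != int(as_float):
            raise ValidationError(
                f"study {row['study_id']!r}: field {name!r} must be an "
                f"integer, got {value!r}"
            )
        counts[name] = int(as_float)
    hwe_raw = row.get("reported_hwe_p")
    if hwe_raw is None or (isinstance(hwe_raw, float) and pd.isna(hwe_raw)):
        hwe = None
    else:
        hwe = str(hwe_raw).strip() or None
    return StudyRecord(
        study_id=str(row["study_id"]).strip(),
        ethnicity=str(row["ethnicity"]).strip(),
        complications=str(row["complications"]).strip(),
        reported_hwe_p=hwe,
        **counts,
    )


def load_corpus(path: str | Path, dialect: str | None = None) -> StudyCorpus:
    """Read a corpus CSV/TSV and validate every row.

    The header must name ``study_id, ethnicity, complications, case_cc,
    case_ct, case_tt, ctrl_cc, ctrl_ct, ctrl_tt`` (``reported_hwe_p`` is
    optional). The dialect is inferred from the file extension unless given.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise CorpusError(f"corpus file {path} contains no data rows")
    records = [_record_from_row(row) for _, row in frame.iterrows()]
    return StudyCorpus(records=records, provenance=str(path))


def write_corpus(corpus: StudyCorpus, path: str | Path, dialect: str | None = None) -> None:
    """Write a corpus in the same CSV/TSV dialect ``load_corpus`` reads.

    Round-trips all counts and labels bit-exactly.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    corpus.to_frame().to_csv(path, sep=sep, index=False)


def corpus_totals(corpus: StudyCorpus) -> CorpusTotals:
    """Study count plus summed case and control sample sizes."""
    if len(corpus) == 0:
        raise CorpusError("corpus is empty")
    return CorpusTotals(
        n_studies=len(corpus),
        n_cases=sum(r.n_cases for r in corpus),
        n_controls=sum(r.n_controls for r in corpus),
    )


def load_mthfr_t2dm() -> StudyCorpus:
    """Load the packaged MTHFR 677C→T / type 2 diabetes corpus.

    39 case-control studies (4855 cases, 5242 controls) spanning Asian,
    Caucasian and African groups, with the control-arm HWE p-values as
    printed in the source table.
    """
    resource = importlib.resources.files("snpmeta").joinpath("data/mthfr_t2dm_corpus.csv")
    with importlib.resources.as_file(resource) as path:
        corpus = load_corpus(path)
    corpus.provenance = "packaged MTHFR 677C->T / T2DM corpus (39 studies)"
    return corpus
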