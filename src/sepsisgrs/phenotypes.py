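"""ICD/OPCS code-based phenotype ascertainment and cohort assembly.

Case status for sepsis and the three cardiovascular outcomes (myocardial
infarction, ischemic stroke, venous thromboembolism) is determined from a
long-format table of dated diagnosis/procedure events by prefix matching
against per-phenotype code lists.  Codes are compared after stripping dots
and upper-casing, so ``A41.5`` and ``A415`` are the same code and the include
prefix ``A41`` matches both.

VTE follows a stricter convention: a subject with any occurrence of an
exclusion code (superficial/other thrombosis codes and D68 coagulopathies) is
never a VTE case, regardless of qualifying events, and baseline self-report
marks prevalent rather than incident disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CodeEvent",
    "PhenotypeDefinition",
    "DEFAULT_DEFINITIONS",
    "ascertain",
    "build_cohort",
    "normalize_code",
]

CODING_SYSTEMS = ("ICD10", "ICD9", "OPCS4", "SELF_REPORT")

EVENT_COLUMNS = ["subject_id", "system", "code", "date"]


@dataclass(frozen=True)
class CodeEvent:
    subject_id: str
    system: str
    code: str
    date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.system not in CODING_SYSTEMS:
            raise ValueError(f"unknown coding system {self.system!r}")
        if not self.code:
            raise ValueError("empty code")


@dataclass(frozen=True)
class PhenotypeDefinition:
    """Include/exclude code-prefix lists for one phenotype."""

    name: str
    include: tuple[tuple[str, str], ...]  # (system, code-prefix)
    exclude: tuple[tuple[str, str], ...] = ()
    self_report_allowed: bool = False

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError(f"{self.name}: include list must be non-empty")
        inc = {(s, normalize_code(c)) for s, c in self.include}
        exc = {(s, normalize_code(c)) for s, c in self.exclude}
        if inc & exc:
            raise ValueError(f"{self.name}: include and exclude lists overlap")


def normalize_code(code: str) -> str:
    return code.replace(".", "").upper().strip()


def _defn(name, include, exclude=(), self_report=False) -> PhenotypeDefinition:
    return PhenotypeDefinition(
        name=name,
        include=tuple(include),
        exclude=tuple(exclude),
        self_report_allowed=self_report,
    )


#: Default hospital-coding case definitions.
#: sepsis: ICD-10 A40*, A41*, R65.2.
#: MI: ICD-10 I21, I22, I23, I24.1, I25.2; ICD-9 410, 411, 412, 429.79.
#: IS: ICD-10 I63, I64; ICD-9 434, 436.
#: VTE: ICD-10 I80.1, I80.2, I82.2, I26.0, I26.9; OPCS-4 L79.1, L90.2; baseline
#: self-report; excluding any I81, I82.0, I80.0, I80.3, I80.8, I80.9, D68.
DEFAULT_DEFINITIONS: dict[str, PhenotypeDefinition] = {
    "sepsis": _defn(
        "sepsis",
        [("ICD10", "A40"), ("ICD10", "A41"), ("ICD10", "R65.2")],
    ),
    "MI": _defn(
        "MI",
        [
            ("ICD10", "I21"),
            ("ICD10", "I22"),
            ("ICD10", "I23"),
            ("ICD10", "I24.1"),
            ("ICD10", "I25.2"),
            ("ICD9", "410"),
            ("ICD9", "411"),
            ("ICD9", "412"),
            ("ICD9", "429.79"),
        ],
    ),
    "IS": _defn(
        "IS",
        [("ICD10", "I63"), ("ICD10", "I64"), ("ICD9", "434"), ("ICD9", "436")],
    ),
    "VTE": _defn(
        "VTE",
        [
            ("ICD10", "I80.1"),
            ("ICD10", "I80.2"),
            ("ICD10", "I82.2"),
            ("ICD10", "I26.0"),
            ("ICD10", "I26.9"),
            ("OPCS4", "L79.1"),
            ("OPCS4", "L90.2"),
            ("SELF_REPORT", "VTE"),
        ],
        exclude=[
            ("ICD10", "I81"),
            ("ICD10", "I82.0"),
            ("ICD10", "I80.0"),
            ("ICD10", "I80.3"),
            ("ICD10", "I80.8"),
            ("ICD10", "I80.9"),
            ("ICD10", "D68"),
        ],
        self_report=True,
    ),
}


def _matches(events: pd.DataFrame, rules: Iterable[tuple[str, str]]) -> pd.Series:
    """Boolean mask of events matching any (system, prefix) rule."""
    mask = pd.Series(False, index=events.index)
    for system, prefix in rules:
        p = normalize_code(prefix)
        mask |= (events["system"] == system) & events["_code"].str.startswith(p)
    return mask


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    unknown = set(events["system"].unique()) - set(CODING_SYSTEMS)
    if unknown:
        raise ValueError(f"unknown coding system(s) {sorted(unknown)}")
    ev = events.copy()
    ev["_code"] = ev["code"].astype(str).map(normalize_code)
    ev["date"] = pd.to_datetime(ev["date"])
    return ev


def ascertain(events: pd.DataFrame, defn: PhenotypeDefinition) -> pd.DataFrame:
    """Per-subject case status and first qualifying date for one phenotype.

    Returns a DataFrame indexed by subject_id with columns ``case`` (bool)
    and ``first_date`` (NaT for non-cases).  A subject is a case iff they have
    at least one include-matching event and — where an exclude list exists —
    no exclude-matching event at any time.
    """
    ev = _validate_events(events)
    inc = ev[_matches(ev, defn.include)]
    first = inc.groupby("subject_id")["date"].min()
    if defn.exclude:
        excluded = set(ev.loc[_matches(ev, defn.exclude), "subject_id"])
        first = first[~first.index.isin(excluded)]
    out = pd.DataFrame({"first_date": first})
    out.insert(0, "case", True)
    return out


def build_cohort(
    registry: pd.DataFrame,
    events: pd.DataFrame,
    definitions: Mapping[str, PhenotypeDefinition] | None = None,
    outcomes: tuple[str, ...] = ("MI", "IS", "VTE"),
) -> pd.DataFrame:
    """Assemble the analysis cohort from a subject registry and event table.

    The registry needs ``subject_id`` and ``recruit_date`` columns (other
    covariates pass through).  Subjects whose first sepsis code is on or
    before recruitment are removed — the study population is sepsis-free at
    entry.  For each outcome the cohort gains ``<name>_event`` /
    ``<name>_date`` columns for incident (post-recruitment) first events and a
    ``<name>_prevalent`` flag for pre-recruitment disease; prevalent subjects
    stay in the cohort but are dropped from that outcome's risk set downstream.
    """
    definitions = dict(definitions or DEFAULT_DEFINITIONS)
    if "recruit_date" not in registry.columns:
        raise ValueError("registry must carry a recruit_date column")
    cohort = registry.copy()
    if cohort["recruit_date"].isna().any():
        bad = cohort.loc[cohort["recruit_date"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing recruitment date for subjects {bad[:5]}")
    cohort["recruit_date"] = pd.to_datetime(cohort["recruit_date"])
    cohort = cohort.set_index("subject_id", drop=False)

    def _first_dates(asc: pd.DataFrame) -> pd.Series:
        mapped = pd.to_datetime(cohort.index.map(asc["first_date"]))
        return pd.Series(mapped, index=cohort.index)

    sepsis = ascertain(events, definitions["sepsis"])
    prevalent_sepsis = (_first_dates(sepsis) <= cohort["recruit_date"]).fillna(False)
    cohort = cohort[~prevalent_sepsis]

    sep_date = _first_dates(sepsis)
    cohort["sepsis"] = pd.notna(sep_date)
    cohort["sepsis_date"] = sep_date

    for name in outcomes:
        asc = ascertain(events, definitions[name])
        first = _first_dates(asc)
        prevalent = (first <= cohort["recruit_date"]).fillna(False)
        incident = pd.notna(first) & ~prevalent
        cohort[f"{name}_prevalent"] = prevalent
        cohort[f"{name}_event"] = incident
        cohort[f"{name}_date"] = first.where(incident)
    return cohort.reset_index(drop=True)
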