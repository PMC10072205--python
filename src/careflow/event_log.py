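"""Treatment-line tables -> validated per-patient event log.

Real-world oncology treatment data arrives as one row per (patient, line,
modification): a *line* is a discrete therapy episode, and *modifications*
are within-line drug changes (maintenance after induction, a switch within
the same treatment class) that do not start a new line.  Before process
discovery the modifications of each line are merged into a single event
that keeps the line's first start date and latest stop date, labelled by
the treatment type of the *first* modification (the line keeps its
induction identity) together with the treatment setting (advanced vs
adjuvant).

Three CSV tables are consumed:

``treatments.csv``
    ``patient_id,line,modification,treatment,type,start,stop,setting``
    (blank setting means advanced; dates in ``DD.MM.YYYY`` or ISO).
``responses.csv``
    ``patient_id,line,date,label`` with labels from
    {CR, PR, SD, PD} for advanced lines and {RE, NR} for adjuvant lines.
``patients.csv``
    ``patient_id,sex,birth_date,death_date,last_followup_date`` plus free
    extra columns absorbed into an attribute map.

Rows or patients violating hard invariants are excluded and reported in a
validation report (one JSON object per issue), mirroring the eligibility
screening a curated registry performs before analysis.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

ADVANCED = "advanced"
ADJUVANT = "adjuvant"
SETTINGS = (ADVANCED, ADJUVANT)

#: Controlled treatment-type vocabulary.  User data may extend it via the
#: type-mapping table; unmapped tokens pass through with a warning.
DEFAULT_TYPES = frozenset(
    {"PD1", "CTLA4", "CTLA4+PD1", "BRAFi", "MEKi", "BRAFi+MEKi", "chemo", "other"}
)

RESPONSE_LABELS = frozenset({"CR", "PR", "SD", "PD", "RE", "NR"})
ADJUVANT_LABELS = frozenset({"RE", "NR"})

_DATE_FORMATS = ("%d.%m.%Y", "%Y-%m-%d")


def parse_date(text: str | None) -> dt.date | None:
    """Parse ``DD.MM.YYYY`` (as printed in curated treatment tables) or ISO-8601.

    Blank / missing -> ``None``.  Raises ``ValueError`` on anything else.
    """
    if text is None:
        return None
    text = str(text).strip()
    if not text or text.lower() in {"nan", "none", "nat"}:
        return None
    for fmt in _DATE_FORMATS:
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {text!r}")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class TreatmentRecord:
    """One raw treatment-table row: a single modification of a treatment line."""

    patient_id: str
    line: int
    modification: int
    treatment_name: str
    treatment_type: str
    start_date: dt.date
    stop_date: dt.date | None
    setting: str = ADVANCED


@dataclass
class ResponseRecord:
    """A dated response assessment for one treatment line of one patient."""

    patient_id: str
    line: int
    assessment_date: dt.date
    label: str


@dataclass
class PatientRecord:
    patient_id: str
    sex: str = "unknown"
    birth_date: dt.date | None = None
    death_date: dt.date | None = None
    last_followup_date: dt.date | None = None
    attributes: dict = field(default_factory=dict)


@dataclass
class TreatmentEvent:
    """A merged treatment line: one event per (patient, line).

    ``start_date`` is the earliest start among the line's modifications and
    ``stop_date`` the latest stop (``None`` while any modification is
    ongoing).  ``label`` couples the treatment type with the setting so that
    e.g. adjuvant PD1 and first-line advanced PD1 are distinct tree labels.
    """

    patient_id: str
    line: int
    treatment_type: str
    setting: str
    start_date: dt.date
    stop_date: dt.date | None

    @property
    def label(self) -> tuple[str, str]:
        return (self.treatment_type, self.setting)


@dataclass
class ValidationIssue:
    patient_id: str | None
    row: int | None
    rule: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "row": self.row,
                "rule": self.rule,
                "message": self.message,
            },
            sort_keys=True,
        )


def write_report(issues: Sequence[ValidationIssue], path) -> None:
    """Write the validation report as JSON lines (one object per issue)."""
    with open(path, "w") as fh:
        for issue in issues:
            fh.write(issue.to_json() + "\n")


# ---------------------------------------------------------------------------
# event log container
# ---------------------------------------------------------------------------


@dataclass
class EventLog:
    """Per-patient ordered treatment events plus the patient/response indexes."""

    events: dict[str, list[TreatmentEvent]]
    patients: dict[str, PatientRecord]
    responses: dict[str, list[ResponseRecord]]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.events)

    @property
    def n_patients(self) -> int:
        return len(self.events)

    def sequence(self, patient_id: str) -> list[tuple[str, str]]:
        """The patient's ordered (type, setting) label sequence."""
        return [e.label for e in self.events[patient_id]]

    def event_at(self, patient_id: str, line: int) -> TreatmentEvent | None:
        for e in self.events.get(patient_id, []):
            if e.line == line:
                return e
        return None

    def observed_types(self) -> set[str]:
        return {e.treatment_type for evs in self.events.values() for e in evs}

    def map_types(self, mapping: Mapping[str, str]) -> "EventLog":
        """Return a log with treatment types relabelled through ``mapping``.

        Used e.g. to group {BRAFi, BRAFi+MEKi} -> "TT" and PD1-based lines
        -> "ICI" when comparing treatment-class sequences.  Unmapped types
        pass through unchanged.
        """
        events = {
            pid: [
                replace(e, treatment_type=map_treatment_type(e.treatment_type, mapping))
                for e in evs
            ]
            for pid, evs in self.events.items()
        }
        return EventLog(events=events, patients=self.patients, responses=self.responses)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_tables(
    treatments_path,
    responses_path,
    patients_path,
    strict: bool = False,
) -> tuple[list[TreatmentRecord], list[ResponseRecord], list[PatientRecord], list[ValidationIssue]]:
    """Parse the three CSV tables.

    Rows that cannot be parsed (bad date, unknown enum token, non-positive
    line index, start after stop) are dropped and recorded in the returned
    validation report; with ``strict=True`` a :class:`ValidationError`
    listing the offending rows is raised instead.
    """
    issues: list[ValidationIssue] = []

    tdf = _read_csv(treatments_path)
    treatments: list[TreatmentRecord] = []
    for i, row in enumerate(tdf.itertuples(index=False), start=2):  # 1-based + header
        pid = str(row.patient_id).strip()
        try:
            line = int(row.line)
            modification = int(row.modification)
            if line < 1 or modification < 1:
                raise ValueError("line and modification must be >= 1")
            start = parse_date(row.start)
            if start is None:
                raise ValueError("missing start date")
            stop = parse_date(row.stop)
            setting = str(row.setting).strip() or ADVANCED
            if setting not in SETTINGS:
                raise ValueError(f"unknown setting {setting!r}")
            if stop is not None and start > stop:
                issues.append(
                    ValidationIssue(pid, i, "start_after_stop",
                                    f"start {start} after stop {stop}")
                )
                continue
            treatments.append(
                TreatmentRecord(
                    patient_id=pid,
                    line=line,
                    modification=modification,
                    treatment_name=str(row.treatment).strip(),
                    treatment_type=str(row.type).strip(),
                    start_date=start,
                    stop_date=stop,
                    setting=setting,
                )
            )
        except (ValueError, TypeError) as exc:
            issues.append(ValidationIssue(pid, i, "parse", str(exc)))

    rdf = _read_csv(responses_path)
    responses: list[ResponseRecord] = []
    for i, row in enumerate(rdf.itertuples(index=False), start=2):
        pid = str(row.patient_id).strip()
        try:
            line = int(row.line)
            if line < 1:
                raise ValueError("line must be >= 1")
            date = parse_date(row.date)
            if date is None:
                raise ValueError("missing assessment date")
            label = str(row.label).strip()
            if label not in RESPONSE_LABELS:
                raise ValueError(f"unknown response label {label!r}")
            responses.append(ResponseRecord(pid, line, date, label))
        except (ValueError, TypeError) as exc:
            issues.append(ValidationIssue(pid, i, "parse", str(exc)))

    pdf = _read_csv(patients_path)
    core = {"patient_id", "sex", "birth_date", "death_date", "last_followup_date"}
    extra_cols = [c for c in pdf.columns if c not in core]
    patients: list[PatientRecord] = []
    for i, row in enumerate(pdf.itertuples(index=False), start=2):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(pdf.columns, row))
        pid = str(d["patient_id"]).strip()
        try:
            rec = PatientRecord(
                patient_id=pid,
                sex=str(d.get("sex", "")).strip() or "unknown",
                birth_date=parse_date(d.get("birth_date")),
                death_date=parse_date(d.get("death_date")),
                last_followup_date=parse_date(d.get("last_followup_date")),
                attributes={c: d[c] for c in extra_cols if str(d.get(c, "")).strip()},
            )
            if rec.death_date is None and rec.last_followup_date is None:
                issues.append(
                    ValidationIssue(pid, i, "no_followup",
                                    "neither death date nor last follow-up present")
                )
                continue
            patients.append(rec)
        except (ValueError, TypeError) as exc:
            issues.append(ValidationIssue(pid, i, "parse", str(exc)))

    if strict and issues:
        raise ValidationError(
            f"{len(issues)} rows failed validation: rows "
            + ", ".join(str(x.row) for x in issues),
            issues,
        )
    return treatments, responses, patients, issues


# ---------------------------------------------------------------------------
# type mapping
# ---------------------------------------------------------------------------


def map_treatment_type(label: str, mapping: Mapping[str, str]) -> str:
    """Map a raw type token to its canonical token.

    Unmapped tokens pass through unchanged; ones outside the controlled
    vocabulary additionally log a warning (warn-and-pass contract, so messy
    registry exports never abort a run).
    """
    if label in mapping:
        return mapping[label]
    if label not in DEFAULT_TYPES:
        logger.warning("treatment type %r is not in the mapping or the "
                       "controlled vocabulary; passing through", label)
    return label


def load_type_map(path) -> dict[str, str]:
    """Read a two-column CSV ``raw,canonical`` mapping table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw_col, canon_col = df.columns[:2]
    return dict(zip(df[raw_col].str.strip(), df[canon_col].str.strip()))


def apply_type_map(
    records: Iterable[TreatmentRecord], mapping: Mapping[str, str]
) -> list[TreatmentRecord]:
    return [
        replace(r, treatment_type=map_treatment_type(r.treatment_type, mapping))
        for r in records
    ]


# ---------------------------------------------------------------------------
# merging and log construction
# ---------------------------------------------------------------------------


def merge_modifications(
    records: Sequence[TreatmentRecord],
) -> tuple[list[TreatmentEvent], list[ValidationIssue]]:
    """Merge within-line modifications into one event per (patient, line).

    Start = earliest modification start; stop = latest stop, or missing if
    any modification is ongoing.  The merged label is the treatment type of
    the first modification (lowest modification index): a maintenance or
    toxicity switch does not change the line's identity.  Duplicate
    (patient, line, modification) keys and conflicting setting flags within
    a line are hard errors that exclude the line.
    """
    issues: list[ValidationIssue] = []
    groups: dict[tuple[str, int], list[TreatmentRecord]] = {}
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        key3 = (rec.patient_id, rec.line, rec.modification)
        if key3 in seen:
            issues.append(
                ValidationIssue(rec.patient_id, None, "duplicate_modification",
                                f"duplicate (line {rec.line}, modification "
                                f"{rec.modification})")
            )
            continue
        seen.add(key3)
        groups.setdefault((rec.patient_id, rec.line), []).append(rec)

    events: list[TreatmentEvent] = []
    for (pid, line), group in groups.items():
        group = sorted(group, key=lambda r: r.modification)
        settings = {r.setting for r in group}
        if len(settings) > 1:
            issues.append(
                ValidationIssue(pid, None, "conflicting_setting",
                                f"line {line} mixes settings {sorted(settings)}")
            )
            continue
        stops = [r.stop_date for r in group]
        stop = None if any(s is None for s in stops) else max(stops)
        events.append(
            TreatmentEvent(
                patient_id=pid,
                line=line,
                treatment_type=group[0].treatment_type,
                setting=group[0].setting,
                start_date=min(r.start_date for r in group),
                stop_date=stop,
            )
        )
    return events, issues


def build_event_log(
    events: Sequence[TreatmentEvent],
    patients: Sequence[PatientRecord],
    responses: Sequence[ResponseRecord] = (),
) -> tuple[EventLog, list[ValidationIssue]]:
    """Assemble the per-patient event log, enforcing cross-reference invariants.

    Patients whose events reference no patient record, or whose line order
    disagrees with date order, are excluded with a per-patient reason.
    Responses for (patient, line) pairs absent from the treatment data are
    dropped with a warning; RE/NR labels on non-adjuvant lines likewise.
    Patients with a record but no treatments stay in the log with an empty
    sequence (they sit only in the tree root).
    """
    issues: list[ValidationIssue] = []
    pindex = {p.patient_id: p for p in patients}

    per_patient: dict[str, list[TreatmentEvent]] = {p.patient_id: [] for p in patients}
    orphans = []
    for e in events:
        if e.patient_id not in pindex:
            orphans.append(e.patient_id)
            continue
        per_patient[e.patient_id].append(e)
    for pid in sorted(set(orphans)):
        issues.append(
            ValidationIssue(pid, None, "unknown_patient",
                            "treatment events reference a patient absent from the "
                            "patient table; events dropped")
        )

    excluded: set[str] = set()
    for pid, evs in per_patient.items():
        evs.sort(key=lambda e: e.line)
        starts = [e.start_date for e in evs]
        if starts != sorted(starts):
            issues.append(
                ValidationIssue(pid, None, "line_date_order",
                                f"patient {pid}: line order disagrees with start-date "
                                "order; patient excluded")
            )
            excluded.add(pid)
    for pid in excluded:
        del per_patient[pid]
        del pindex[pid]

    known_lines = {(e.patient_id, e.line) for evs in per_patient.values() for e in evs}
    adjuvant_lines = {
        (e.patient_id, e.line)
        for evs in per_patient.values()
        for e in evs
        if e.setting == ADJUVANT
    }
    per_responses: dict[str, list[ResponseRecord]] = {pid: [] for pid in per_patient}
    for r in responses:
        key = (r.patient_id, r.line)
        if key not in known_lines:
            if r.patient_id not in excluded:
                issues.append(
                    ValidationIssue(r.patient_id, None, "orphan_response",
                                    f"response for unknown line {r.line}; ignored")
                )
            continue
        if (r.label in ADJUVANT_LABELS) != (key in adjuvant_lines):
            issues.append(
                ValidationIssue(r.patient_id, None, "label_setting_mismatch",
                                f"label {r.label} not permitted for line {r.line}; "
                                "ignored")
            )
            continue
        per_responses[r.patient_id].append(r)
    for rs in per_responses.values():
        rs.sort(key=lambda r: (r.line, r.assessment_date))

    log = EventLog(events=per_patient, patients=pindex, responses=per_responses)
    return log, issues


def load_event_log(
    treatments_path,
    responses_path,
    patients_path,
    type_map: Mapping[str, str] | None = None,
) -> tuple[EventLog, list[ValidationIssue]]:
    """Convenience pipeline: read -> map types -> merge -> build."""
    treatments, responses, patients, issues = read_tables(
        treatments_path, responses_path, patients_path
    )
    if type_map:
        treatments = apply_type_map(treatments, type_map)
    events, merge_issues = merge_modifications(treatments)
    log, build_issues = build_event_log(events, patients, responses)
    return log, issues + merge_issues + build_issues


def filter_event_types(log: EventLog, exclude: Iterable[str]) -> EventLog:
    """Drop events whose treatment type is in ``exclude``.

    Used to neglect low-impact regimens (e.g. chemo) in sequence analyses.
    Remaining events keep their original line indices and patients are never
    removed — a patient may end with an empty sequence.  Tokens must belong
    to the controlled vocabulary or be observed in the log.
    """
    exclude = set(exclude)
    allowed = DEFAULT_TYPES | log.observed_types()
    unknown = exclude - allowed
    if unknown:
        raise ValidationError(f"unknown treatment type token(s): {sorted(unknown)}")
    events = {
        pid: [e for e in evs if e.treatment_type not in exclude]
        for pid, evs in log.events.items()
    }
    return EventLog(events=events, patients=log.patients, responses=log.responses)
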