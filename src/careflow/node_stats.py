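"""Per-node outcome summaries: best overall response and anchored OS curves.

Each tree node summarises its sub-cohort with

* a best-overall-response (BOR) distribution over {CR, PR, SD, PD, NE} for
  advanced-setting nodes, ranked CR > PR > SD > PD (RECIST-style ordering;
  NE marks patients with no assessment on the line), or a two-category
  recurrence distribution {RE, NR, NE} for adjuvant nodes;
* a Kaplan-Meier overall-survival curve anchored at the start of the node's
  treatment line for each patient, censored at last follow-up, displayed up
  to a five-year horizon (the estimator itself uses all follow-up; the
  horizon only truncates the displayed steps).

The product-limit estimation is delegated to lifelines (Greenwood-type
confidence band); this module owns anchoring, label bookkeeping and the
distribution containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .event_log import ADJUVANT, EventLog
from .exceptions import ContractError

#: Response ranking used for best overall response (higher is better).
BOR_RANK = {"PD": 1, "SD": 2, "PR": 3, "CR": 4}
ADVANCED_BOR = ("CR", "PR", "SD", "PD", "NE")
ADJUVANT_BOR = ("RE", "NR", "NE")

FIVE_YEARS_DAYS = 1826


@dataclass
class BORDistribution:
    """Counts of best responses (or recurrence states) over a node's patients."""

    counts: dict[str, int]
    n_total: int

    @property
    def n_evaluable(self) -> int:
        return self.n_total - self.counts.get("NE", 0)

    def objective_response_rate(self) -> float | None:
        """(CR + PR) / evaluable — the usual objective response rate."""
        if self.n_evaluable == 0:
            return None
        return (self.counts.get("CR", 0) + self.counts.get("PR", 0)) / self.n_evaluable

    def fractions(self, include_ne: bool = True) -> dict[str, float]:
        """Normalised distribution, over all patients or evaluable only."""
        denom = self.n_total if include_ne else self.n_evaluable
        if denom == 0:
            return {k: 0.0 for k in self.counts}
        keys = self.counts if include_ne else {
            k: v for k, v in self.counts.items() if k != "NE"
        }
        return {k: v / denom for k, v in keys.items()}


@dataclass
class SurvivalCurve:
    """A right-censored product-limit curve on a day scale since the anchor."""

    times: np.ndarray            # step times, starting at 0
    survival: np.ndarray         # S(t) at each step, S(0) = 1
    at_risk: np.ndarray          # number at risk entering each step time
    censor_times: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n: int = 0
    n_events: int = 0

    def value_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def truncated(self, horizon_days: float) -> "SurvivalCurve":
        """Drop steps beyond the display horizon (estimates are unchanged)."""
        keep = self.times <= horizon_days
        return SurvivalCurve(
            times=self.times[keep],
            survival=self.survival[keep],
            at_risk=self.at_risk[keep],
            censor_times=self.censor_times[self.censor_times <= horizon_days],
            ci_lower=None if self.ci_lower is None else self.ci_lower[keep],
            ci_upper=None if self.ci_upper is None else self.ci_upper[keep],
            n=self.n,
            n_events=self.n_events,
        )


def km_estimate(durations, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with a Greenwood confidence band.

    ``durations`` are non-negative times since the anchor; ``event_flags``
    are 1 for death (event) and 0 for censoring.  Empty input is a contract
    error: a curve needs at least one subject.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if durations.size == 0:
        raise ContractError("cannot estimate a survival curve from zero subjects")
    if np.any(durations < 0):
        raise ContractError("durations must be >= 0")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = np.asarray(sf.index, dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table.reindex(sf.index)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(durations[events == 0]),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        n=int(durations.size),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# response summaries
# ---------------------------------------------------------------------------


def _line_setting(log: EventLog, patient_id: str, line: int) -> str:
    ev = log.event_at(patient_id, line)
    if ev is None:
        raise ContractError(f"patient {patient_id} has no line {line}")
    return ev.setting


def best_overall_response(log: EventLog, patient_id: str, line: int) -> str:
    """Best response on an advanced-setting line under CR > PR > SD > PD.

    Returns ``"NE"`` (not evaluable) when no assessment exists.  Calling
    this on an adjuvant line is a contract error — use
    :func:`recurrence_status`.
    """
    if _line_setting(log, patient_id, line) == ADJUVANT:
        raise ContractError(
            f"line {line} of patient {patient_id} is adjuvant; BOR is undefined "
            "(use recurrence_status)"
        )
    labels = [
        r.label
        for r in log.responses.get(patient_id, [])
        if r.line == line and r.label in BOR_RANK
    ]
    if not labels:
        return "NE"
    return max(labels, key=BOR_RANK.__getitem__)


def recurrence_status(log: EventLog, patient_id: str, line: int) -> str:
    """Recurrence state of an adjuvant line: RE if any recurrence label, else
    NR if a no-recurrence label exists, else NE."""
    if _line_setting(log, patient_id, line) != ADJUVANT:
        raise ContractError(
            f"line {line} of patient {patient_id} is not adjuvant; use "
            "best_overall_response"
        )
    labels = {r.label for r in log.responses.get(patient_id, []) if r.line == line}
    if "RE" in labels:
        return "RE"
    if "NR" in labels:
        return "NR"
    return "NE"


def node_bor(node, log: EventLog) -> BORDistribution:
    """BOR (or recurrence) distribution over a node's patients for the node's
    treatment line.  Adjuvant nodes use the two-category recurrence
    vocabulary — their pies show recurrence vs none rather than RECIST-style
    response."""
    if node.parent is None:
        raise ContractError("the root carries no treatment line; BOR is undefined")
    adjuvant = node.setting == ADJUVANT
    vocab = ADJUVANT_BOR if adjuvant else ADVANCED_BOR
    counts = {k: 0 for k in vocab}
    for pid in node.patient_ids:
        line = node.anchor_lines[pid]
        label = (
            recurrence_status(log, pid, line)
            if adjuvant
            else best_overall_response(log, pid, line)
        )
        counts[label] += 1
    return BORDistribution(counts=counts, n_total=node.n_patients)


# ---------------------------------------------------------------------------
# anchored overall survival
# ---------------------------------------------------------------------------


def os_time(log: EventLog, patient_id: str, anchor) -> tuple[float, int] | None:
    """(days from anchor to death-or-censoring, event flag), or ``None`` when
    the anchor postdates all follow-up for a patient still alive."""
    p = log.patients[patient_id]
    if p.death_date is not None:
        # a registry death date on/before the anchor clamps to day 0
        return (max(float((p.death_date - anchor).days), 0.0), 1)
    if p.last_followup_date is None or p.last_followup_date < anchor:
        return None
    return (float((p.last_followup_date - anchor).days), 0)


def node_os_curve(node, log: EventLog, horizon_days: float = FIVE_YEARS_DAYS) -> SurvivalCurve:
    """Kaplan-Meier OS for a node's sub-cohort, anchored at each patient's
    start of the node's treatment line.

    Patients whose last follow-up precedes the anchor (and who are not
    dead) cannot contribute and are excluded with a warning.  The curve is
    truncated at ``horizon_days`` for display; the estimate itself uses all
    follow-up.
    """
    if node.parent is None:
        raise ContractError("the root has no anchor; OS curves are per-treatment-node")
    durations, events = [], []
    for pid in sorted(node.patient_ids):
        res = os_time(log, pid, node.anchor_dates[pid])
        if res is None:
            warnings.warn(
                f"patient {pid}: anchor after last follow-up with no death date; "
                "excluded from the OS curve"
            )
            continue
        durations.append(res[0])
        events.append(res[1])
    curve = km_estimate(durations, events)
    return curve.truncated(horizon_days)
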