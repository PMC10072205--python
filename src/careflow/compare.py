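"""Custom cohorts from tree nodes and anchored survival comparison.

This is the scriptable counterpart of the interactive drag-and-drop: a
cohort is a union of tree-node patient sets minus a union of subtracted
node sets, each patient anchored at the start of the treatment line from
which they were selected.  Two cohorts are then compared on overall
survival (OS) or progression-free survival (PFS) with Kaplan-Meier curves,
the two-group log-rank test, a Cox proportional-hazards hazard ratio with
Wald 95% CI (Efron tie handling, via lifelines), landmark survival rates
with Greenwood log-log intervals, and per-group descriptive summaries
(n, median age at anchor, sex ratio, BOR distribution).

PFS is defined as time from the anchor to the first progression (PD)
assessment on the anchoring line or any later line, or death, whichever
comes first; patients without either are censored at last follow-up.
This is the standard oncology convention — the source data format records
progression labels rather than explicit PFS dates.

Cohort expressions give a shell-friendly mini-language for the same
algebra::

    "PD1>CTLA4+PD1 + PD1>PD1 - adj:PD1"

is the union of the two second-line paths minus the adjuvant PD1 node:
``>`` separates line labels within a path, whitespace-delimited ``+`` and
``-`` add or subtract node patient sets, and ``adj:`` marks adjuvant
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times  # noqa: F401  (re-export convenience)

from .event_log import EventLog, ADJUVANT
from .exceptions import ContractError, FitError
from .node_stats import (
    BORDistribution,
    SurvivalCurve,
    best_overall_response,
    km_estimate,
    os_time,
    recurrence_status,
)
from .tree import TreatmentTree, label_str, node_path, parse_label

__all__ = [
    "Cohort",
    "ComparisonResult",
    "cohort_from_nodes",
    "parse_cohort_expression",
    "cohort_from_expression",
    "pfs_time",
    "km_estimate",
    "logrank_test",
    "cox_hazard_ratio",
    "survival_rate_at",
    "compare_cohorts",
]


@dataclass
class Cohort:
    """A named patient set with per-patient anchor dates and provenance."""

    name: str
    members: set[str]
    anchors: dict  # patient_id -> anchor date
    anchor_lines: dict  # patient_id -> anchoring line index
    provenance: list = field(default_factory=list)  # (path labels, "add"/"subtract")

    @property
    def n(self) -> int:
        return len(self.members)


def cohort_from_nodes(
    tree: TreatmentTree,
    node_paths: Sequence[Sequence],
    subtract_paths: Sequence[Sequence] = (),
    name: str = "cohort",
    anchor_depth: int | None = None,
) -> Cohort:
    """Set algebra over tree nodes: union of added nodes minus subtracted ones.

    Anchors come from the node a patient was added through; when a patient
    enters via several nodes, the shallowest node's anchor wins (with a
    warning).  ``anchor_depth`` instead anchors every patient at their
    ancestor node at that depth — e.g. ``anchor_depth=1`` starts the
    analysis clock at the first treatment even when second-line nodes were
    selected.  Subtraction is a pure set difference: a subtracted node
    removes its patients no matter which added node contributed them.
    """
    provenance = []
    added: list = []
    for path in node_paths:
        node = tree.find(path)
        added.append(node)
        provenance.append(([label_str(l) for l in node_path(node)], "add"))
    removed: set[str] = set()
    for path in subtract_paths:
        node = tree.find(path)
        removed |= node.patient_ids
        provenance.append(([label_str(l) for l in node_path(node)], "subtract"))

    members: set[str] = set()
    anchors: dict = {}
    anchor_lines: dict = {}
    source_depth: dict = {}
    for node in sorted(added, key=lambda n: n.depth):
        anchor_node = node
        if anchor_depth is not None:
            if anchor_depth > node.depth:
                raise ContractError(
                    f"anchor_depth {anchor_depth} exceeds node depth {node.depth}"
                )
            while anchor_node.depth > anchor_depth:
                anchor_node = anchor_node.parent
        for pid in node.patient_ids:
            if pid in removed:
                continue
            if pid in members:
                warnings.warn(
                    f"patient {pid} enters cohort {name!r} through multiple nodes; "
                    f"keeping the shallowest anchor (depth {source_depth[pid]})"
                )
                continue
            members.add(pid)
            source_depth[pid] = node.depth
            anchors[pid] = anchor_node.anchor_dates[pid]
            anchor_lines[pid] = anchor_node.anchor_lines[pid]
    return Cohort(name=name, members=members, anchors=anchors,
                  anchor_lines=anchor_lines, provenance=provenance)


# -- expression mini-language ----------------------------------------------


def parse_cohort_expression(expr: str) -> tuple[list[list[tuple[str, str]]],
                                                list[list[tuple[str, str]]]]:
    """Parse ``"P1 + P2 - P3"`` into (added paths, subtracted paths).

    Paths are ``>``-separated label chains; ``adj:`` marks adjuvant labels.
    The operators must be whitespace-delimited (treatment types themselves
    contain ``+``, e.g. ``CTLA4+PD1``).
    """
    tokens = expr.split()
    if not tokens:
        raise ValueError("empty cohort expression")
    adds, subs = [], []
    sign = "+"
    expect_path = True
    for tok in tokens:
        if tok in {"+", "-"}:
            if expect_path:
                raise ValueError(f"misplaced operator in expression {expr!r}")
            sign = tok
            expect_path = True
            continue
        if not expect_path:
            raise ValueError(f"missing operator before {tok!r} in {expr!r}")
        path = [parse_label(part) for part in tok.split(">") if part.strip()]
        if not path:
            raise ValueError(f"empty path in expression {expr!r}")
        (adds if sign == "+" else subs).append(path)
        expect_path = False
    if expect_path:
        raise ValueError(f"dangling operator in expression {expr!r}")
    return adds, subs


def cohort_from_expression(
    tree: TreatmentTree, expr: str, name: str | None = None,
    anchor_depth: int | None = None,
) -> Cohort:
    adds, subs = parse_cohort_expression(expr)
    return cohort_from_nodes(tree, adds, subs, name=name or expr,
                             anchor_depth=anchor_depth)


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------


def pfs_time(log: EventLog, patient_id: str, line: int) -> tuple[float, int]:
    """Progression-free survival from the start of ``line``.

    Event time is the earliest of the first PD assessment on that line or a
    later line, or death; otherwise the patient is censored at last
    follow-up.
    """
    ev = log.event_at(patient_id, line)
    if ev is None:
        raise ContractError(f"patient {patient_id} has no line {line}")
    anchor = ev.start_date
    pd_dates = [
        r.assessment_date
        for r in log.responses.get(patient_id, [])
        if r.line >= line and r.label in {"PD", "RE"} and r.assessment_date >= anchor
    ]
    p = log.patients[patient_id]
    candidates = []
    if pd_dates:
        candidates.append(min(pd_dates))
    if p.death_date is not None:
        candidates.append(p.death_date)
    if candidates:
        t = min(candidates)
        return (max(float((t - anchor).days), 0.0), 1)
    fup = p.last_followup_date
    if fup is None or fup < anchor:
        return (0.0, 0)
    return (float((fup - anchor).days), 0)


def _cohort_durations(
    cohort: Cohort, log: EventLog, endpoint: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    endpoint = endpoint.upper()
    if endpoint not in {"OS", "PFS"}:
        raise ContractError(f"endpoint must be OS or PFS, got {endpoint!r}")
    durations, events, kept = [], [], []
    for pid in sorted(cohort.members):
        if endpoint == "OS":
            res = os_time(log, pid, cohort.anchors[pid])
            if res is None:
                warnings.warn(
                    f"patient {pid}: anchor after last follow-up; excluded from OS"
                )
                continue
        else:
            res = pfs_time(log, pid, cohort.anchor_lines[pid])
        durations.append(res[0])
        events.append(res[1])
        kept.append(pid)
    return np.asarray(durations, float), np.asarray(events, int), kept


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; each group is (durations, event_flags).

    Returns the chi-square statistic (1 df) and its p-value.
    """
    (ta, ea), (tb, eb) = group_a, group_b
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    if ta.size == 0 or tb.size == 0:
        raise ContractError("log-rank test requires two non-empty groups")
    if ea.sum() + eb.sum() == 0:
        return (0.0, 1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return (float(res.test_statistic), float(res.p_value))


def cox_hazard_ratio(group_a, group_b) -> tuple[float, float, float]:
    """Hazard ratio of group B vs group A with Wald 95% CI.

    Proportional-hazards fit with a single binary covariate (1 = group B),
    Efron handling of tied event times.  No events at all is a fit error;
    complete separation is reported with the infinite-bound convention.
    """
    (ta, ea), (tb, eb) = group_a, group_b
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    if ta.size == 0 or tb.size == 0:
        raise ContractError("Cox fit requires two non-empty groups")
    if ea.sum() + eb.sum() == 0:
        raise FitError("no events in either group; hazard ratio undefined")
    df = pd.DataFrame(
        {
            "T": np.concatenate([ta, tb]),
            "E": np.concatenate([ea, eb]),
            "group": np.concatenate([np.zeros(ta.size), np.ones(tb.size)]),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except Exception as exc:  # convergence failure / separation
        if ea.sum() == 0:
            return (np.inf, 0.0, np.inf)
        if eb.sum() == 0:
            return (0.0, 0.0, np.inf)
        raise FitError(f"Cox fit failed: {exc}") from exc
    coef = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])
    hr = float(np.exp(coef))
    lo = float(np.exp(coef - 1.959963984540054 * se))
    hi = float(np.exp(coef + 1.959963984540054 * se))
    return (hr, lo, hi)


def survival_rate_at(curve: SurvivalCurve, t: float) -> tuple[float, float, float]:
    """KM step-function value at ``t`` with its Greenwood log-log CI.

    Asking beyond the last observed time returns the last value with an
    extrapolation warning.
    """
    if t < 0:
        raise ContractError("landmark time must be >= 0")
    last = float(np.max(curve.times)) if curve.times.size else 0.0
    if t > last:
        warnings.warn(
            f"landmark {t} beyond last observed time {last}; returning the last value"
        )
        t = last
    idx = int(np.searchsorted(curve.times, t, side="right") - 1)
    idx = max(idx, 0)
    rate = float(curve.survival[idx])
    lo = float(curve.ci_lower[idx]) if curve.ci_lower is not None else np.nan
    hi = float(curve.ci_upper[idx]) if curve.ci_upper is not None else np.nan
    return (rate, lo, hi)


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Everything the interactive comparison view shows, as plain data."""

    endpoint: str
    names: tuple[str, str]
    curves: dict  # name -> SurvivalCurve
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float  # second-listed cohort vs first
    hr_ci_low: float
    hr_ci_high: float
    landmark_days: float
    landmark_estimates: dict  # name -> {time, rate, ci_low, ci_high}
    summaries: dict  # name -> {n, median_age_at_anchor, sex_ratio, bor}

    def to_frame(self) -> pd.DataFrame:
        """One-row-per-cohort summary table."""
        rows = []
        a, b = self.names
        for name in self.names:
            s = self.summaries[name]
            lm = self.landmark_estimates[name]
            rows.append(
                {
                    "cohort": name,
                    "endpoint": self.endpoint,
                    "n": s["n"],
                    "events": self.curves[name].n_events,
                    "median_age_at_anchor": s["median_age_at_anchor"],
                    "sex_ratio_M_F": s["sex_ratio"],
                    f"rate_at_{int(self.landmark_days)}d": lm["rate"],
                    "rate_ci_low": lm["ci_low"],
                    "rate_ci_high": lm["ci_high"],
                    "logrank_statistic": self.logrank_statistic,
                    "logrank_p": self.logrank_p,
                    f"hr_{b}_vs_{a}": self.hazard_ratio,
                    "hr_ci_low": self.hr_ci_low,
                    "hr_ci_high": self.hr_ci_high,
                }
            )
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        parts = []
        for name, curve in self.curves.items():
            parts.append(
                pd.DataFrame(
                    {
                        "cohort": name,
                        "time_days": curve.times,
                        "survival": curve.survival,
                        "at_risk": curve.at_risk,
                        "ci_lower": curve.ci_lower,
                        "ci_upper": curve.ci_upper,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def save(self, out_dir, basename: str = "comparison") -> list[str]:
        """Write summary + curve tables as CSV and a combined XLSX workbook."""
        import os

        paths = []
        summary = self.to_frame()
        curves = self.curves_frame()
        p_sum = os.path.join(out_dir, f"{basename}_summary.csv")
        p_cur = os.path.join(out_dir, f"{basename}_curves.csv")
        summary.to_csv(p_sum, index=False)
        curves.to_csv(p_cur, index=False)
        paths += [p_sum, p_cur]
        p_xlsx = os.path.join(out_dir, f"{basename}.xlsx")
        with pd.ExcelWriter(p_xlsx) as xl:
            summary.to_excel(xl, sheet_name="summary", index=False)
            curves.to_excel(xl, sheet_name="curves", index=False)
            bor = pd.DataFrame(
                {name: self.summaries[name]["bor"] for name in self.names}
            ).fillna(0)
            bor.to_excel(xl, sheet_name="bor")
        paths.append(p_xlsx)
        return paths

    def plot(self, path=None, title: str | None = None):
        """Step plot of both KM curves with confidence bands."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for name, curve in self.curves.items():
            months = curve.times / 30.44
            ax.step(months, curve.survival, where="post", label=f"{name} (n={curve.n})")
            if curve.ci_lower is not None:
                ax.fill_between(months, curve.ci_lower, curve.ci_upper,
                                step="post", alpha=0.15)
        ax.set_xlabel("months since anchor")
        ax.set_ylabel(f"{self.endpoint} probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        a, b = self.names
        ax.set_title(
            title
            or f"{self.endpoint}: HR({b} vs {a})={self.hazard_ratio:.2f}, "
               f"log-rank p={self.logrank_p:.3f}"
        )
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def _summary(cohort: Cohort, log: EventLog) -> dict:
    ages = []
    sexes = {"M": 0, "F": 0, "other": 0}
    bor: dict[str, int] = {}
    for pid in sorted(cohort.members):
        p = log.patients[pid]
        if p.birth_date is not None:
            ages.append((cohort.anchors[pid] - p.birth_date).days / 365.25)
        sexes[p.sex if p.sex in ("M", "F") else "other"] += 1
        line = cohort.anchor_lines[pid]
        ev = log.event_at(pid, line)
        label = (
            recurrence_status(log, pid, line)
            if ev is not None and ev.setting == ADJUVANT
            else best_overall_response(log, pid, line)
        )
        bor[label] = bor.get(label, 0) + 1
    return {
        "n": cohort.n,
        "median_age_at_anchor": float(np.median(ages)) if ages else None,
        "sex_ratio": f"{sexes['M']}:{sexes['F']}",
        "bor": dict(sorted(bor.items())),
    }


def compare_cohorts(
    cohort_a: Cohort,
    cohort_b: Cohort,
    endpoint: str,
    log: EventLog,
    landmark_days: float = 1826,
) -> ComparisonResult:
    """Full two-cohort comparison: KM curves, log-rank, Cox HR, landmark
    rates and descriptive summaries.

    The hazard ratio is reported for the second-listed cohort vs the first.
    Overlapping membership is legal but warned about — the drag-and-drop
    groups in practice are disjoint by construction.
    """
    if cohort_a.n == 0 or cohort_b.n == 0:
        raise ContractError("both cohorts must be non-empty")
    shared = cohort_a.members & cohort_b.members
    if shared:
        warnings.warn(
            f"cohorts {cohort_a.name!r} and {cohort_b.name!r} share "
            f"{len(shared)} patient(s): {sorted(shared)[:10]}"
        )
    da, ea, _ = _cohort_durations(cohort_a, log, endpoint)
    db, eb, _ = _cohort_durations(cohort_b, log, endpoint)
    curve_a = km_estimate(da, ea)
    curve_b = km_estimate(db, eb)
    stat, p = logrank_test((da, ea), (db, eb))
    try:
        hr, lo, hi = cox_hazard_ratio((da, ea), (db, eb))
    except FitError:
        hr, lo, hi = (np.nan, np.nan, np.nan)
    landmarks = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, curve in ((cohort_a.name, curve_a), (cohort_b.name, curve_b)):
            rate, rlo, rhi = survival_rate_at(curve, landmark_days)
            landmarks[name] = {
                "time": landmark_days, "rate": rate, "ci_low": rlo, "ci_high": rhi,
            }
    return ComparisonResult(
        endpoint=endpoint.upper(),
        names=(cohort_a.name, cohort_b.name),
        curves={cohort_a.name: curve_a, cohort_b.name: curve_b},
        logrank_statistic=stat,
        logrank_p=p,
        hazard_ratio=hr,
        hr_ci_low=lo,
        hr_ci_high=hi,
        landmark_days=landmark_days,
        landmark_estimates=landmarks,
        summaries={
            cohort_a.name: _summary(cohort_a, log),
            cohort_b.name: _summary(cohort_b, log),
        },
    )
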