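"""End-to-end scripted analyses over a treatment tree.

Three canonical cohort studies that an oncologist would otherwise set up by
drag-and-drop, expressed as reproducible functions:

``first_line_ici_comparison``
    CheckMate-067-style: first-line CTLA4+PD1 vs PD1 vs CTLA4 on overall
    survival, with objective response rates per arm.
``sequence_comparison``
    DREAMseq-style: the treatment-class sequence ICI->TT vs TT->ICI, with
    PD1-based lines grouped as ICI and BRAF-inhibitor-based lines as TT,
    chemo neglected in the sequences, and both OS and PFS anchored at the
    first-line start (PFS evaluates the first treatment).
``rechallenge_comparison``
    ICI rechallenge (a second ICI line after progressing on first-line ICI)
    vs switching to targeted treatment, anchored at second-line start.
    First lines that are not ICI are excluded by construction of the paths.

All three operate on any validated event log — typically the synthetic
cohort from :mod:`careflow.simulate`.
"""

from __future__ import annotations

from .compare import Cohort, ComparisonResult, cohort_from_nodes, compare_cohorts
from .event_log import ADVANCED, EventLog, filter_event_types
from .exceptions import ContractError
from .tree import discover_tree

#: Treatment-class grouping used by the sequence analyses: PD1-based lines
#: count as immune checkpoint inhibition, BRAFi-based lines as targeted
#: treatment.  CTLA4 monotherapy is intentionally left ungrouped (it is not
#: PD1-based) and chemo is excluded from sequences separately.
ICI_TT_MAP = {
    "PD1": "ICI",
    "CTLA4+PD1": "ICI",
    "BRAFi": "TT",
    "MEKi": "TT",
    "BRAFi+MEKi": "TT",
}

TWO_YEARS_DAYS = 730
FIVE_YEARS_DAYS = 1826


def advanced_only(log: EventLog) -> EventLog:
    """Drop adjuvant events so sequences start at the first advanced line."""
    events = {
        pid: [e for e in evs if e.setting == ADVANCED]
        for pid, evs in log.events.items()
    }
    return EventLog(events=events, patients=log.patients, responses=log.responses)


def _first_line_cohort(log: EventLog, treatment_type: str, name: str) -> Cohort:
    """Patients whose first advanced-setting line has the given type,
    anchored at that line."""
    members, anchors, anchor_lines = set(), {}, {}
    for pid, evs in log.events.items():
        adv = [e for e in evs if e.setting == ADVANCED]
        if adv and adv[0].treatment_type == treatment_type:
            members.add(pid)
            anchors[pid] = adv[0].start_date
            anchor_lines[pid] = adv[0].line
    return Cohort(name=name, members=members, anchors=anchors,
                  anchor_lines=anchor_lines,
                  provenance=[([f"first-line {treatment_type}"], "add")])


def first_line_ici_comparison(
    log: EventLog, landmark_days: float = FIVE_YEARS_DAYS
) -> dict:
    """First-line ICI arms compared on OS, with per-arm objective response.

    Returns ``{"cohorts": ..., "orr": ..., "combo_vs_pd1": ComparisonResult,
    "combo_vs_ctla4": ComparisonResult}``; hazard ratios are reported for
    the CTLA4+PD1 combination vs the comparator arm.
    """
    from .node_stats import best_overall_response

    arms = {
        t: _first_line_cohort(log, t, t) for t in ("CTLA4+PD1", "PD1", "CTLA4")
    }
    for t, cohort in arms.items():
        if cohort.n == 0:
            raise ContractError(f"no patients with first-line {t}")
    orr = {}
    for t, cohort in arms.items():
        labels = [
            best_overall_response(log, pid, cohort.anchor_lines[pid])
            for pid in cohort.members
        ]
        evaluable = [l for l in labels if l != "NE"]
        orr[t] = (
            sum(l in ("CR", "PR") for l in evaluable) / len(evaluable)
            if evaluable
            else None
        )
    return {
        "cohorts": arms,
        "orr": orr,
        "combo_vs_pd1": compare_cohorts(
            arms["PD1"], arms["CTLA4+PD1"], "OS", log, landmark_days
        ),
        "combo_vs_ctla4": compare_cohorts(
            arms["CTLA4"], arms["CTLA4+PD1"], "OS", log, landmark_days
        ),
    }


def _sequence_log(log: EventLog) -> EventLog:
    """Advanced lines only, chemo neglected, classes grouped to ICI/TT."""
    working = advanced_only(log)
    working = filter_event_types(working, {"chemo", "other"})
    return working.map_types(ICI_TT_MAP)


def sequence_comparison(log: EventLog, landmark_days: float = TWO_YEARS_DAYS) -> dict:
    """ICI->TT vs TT->ICI on OS and PFS, both anchored at first-line start.

    The analysis clock starts at the first treatment of the sequence even
    though the cohorts are selected from second-line nodes, and PFS
    evaluates the first line only.
    """
    slog = _sequence_log(log)
    tree = discover_tree(slog, min_patients=0)
    ici_tt = cohort_from_nodes(tree, [["ICI", "TT"]], name="ICI->TT",
                               anchor_depth=1)
    tt_ici = cohort_from_nodes(tree, [["TT", "ICI"]], name="TT->ICI",
                               anchor_depth=1)
    return {
        "cohorts": {"ICI->TT": ici_tt, "TT->ICI": tt_ici},
        "os": compare_cohorts(tt_ici, ici_tt, "OS", slog, landmark_days),
        "pfs": compare_cohorts(tt_ici, ici_tt, "PFS", slog, landmark_days),
    }


def rechallenge_comparison(
    log: EventLog, landmark_days: float = TWO_YEARS_DAYS
) -> dict:
    """ICI rechallenge vs switch to targeted treatment after first-line ICI.

    Both cohorts are second-line nodes under a first-line ICI node, so
    patients whose first line was CTLA4 monotherapy, targeted treatment or
    chemo are excluded by construction.  Analysis starts at second-line
    treatment initiation; the hazard ratio is reported for the rechallenge
    group vs the switch group.
    """
    slog = _sequence_log(log)
    tree = discover_tree(slog, min_patients=0)
    rechallenge = cohort_from_nodes(tree, [["ICI", "ICI"]], name="ICI rechallenge")
    switch = cohort_from_nodes(tree, [["ICI", "TT"]], name="switch to TT")
    return {
        "cohorts": {"rechallenge": rechallenge, "switch": switch},
        "os": compare_cohorts(switch, rechallenge, "OS", slog, landmark_days),
        "pfs": compare_cohorts(switch, rechallenge, "PFS", slog, landmark_days),
    }
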