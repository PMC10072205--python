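"""Shared fixtures and independent oracles.

The oracles here (hand product-limit, brute-force prefix counting,
permutation log-rank, partial-likelihood grid search) are deliberately
written from first principles, independent of the package's code paths.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from careflow.event_log import (
    EventLog,
    PatientRecord,
    ResponseRecord,
    TreatmentEvent,
)
from careflow.tree import parse_label

BASE = dt.date(2018, 1, 1)

TABLE1_TREATMENTS = """\
patient_id,line,modification,treatment,type,start,stop,setting
1234,1,1,Pembrolizumab,PD1,01.07.2016,15.12.2016,adjuvant
1234,2,1,Ipilimumab+Nivolumab,CTLA4+PD1,01.01.2017,01.03.2017,
1234,2,2,Nivolumab,PD1,15.03.2017,31.12.2017,
1234,3,1,Dabrafenib+Trametinib,BRAFi+TT_MEKi,15.01.2018,15.02.2018,
1234,3,2,Vemurafenib+Cobimetinib,BRAFi+TT_MEKi,01.03.2018,31.12.2018,
"""

TABLE1_RESPONSES = "patient_id,line,date,label\n"

TABLE1_PATIENTS = """\
patient_id,sex,birth_date,death_date,last_followup_date
1234,M,01.01.1960,,01.06.2021
"""

TABLE1_TYPE_MAP = "raw,canonical\nBRAFi+TT_MEKi,BRAFi+MEKi\n"


@pytest.fixture
def table1_paths(tmp_path):
    """The printed five-row worked example as on-disk CSV files."""
    t = tmp_path / "treatments.csv"
    r = tmp_path / "responses.csv"
    p = tmp_path / "patients.csv"
    m = tmp_path / "type_map.csv"
    t.write_text(TABLE1_TREATMENTS)
    r.write_text(TABLE1_RESPONSES)
    p.write_text(TABLE1_PATIENTS)
    m.write_text(TABLE1_TYPE_MAP)
    return {"treatments": t, "responses": r, "patients": p, "type_map": m}


def make_log(
    sequences: dict[str, list[str]],
    responses: dict[str, list[tuple[int, int, str]]] | None = None,
    death_days: dict[str, int] | None = None,
    followup_days: int = 2000,
) -> EventLog:
    """Build an EventLog from compact label sequences.

    ``sequences`` maps patient -> list of tree-label strings ("PD1",
    "adj:PD1", ...); line i starts ``120 * i`` days after a common base
    date and lasts 80 days.  ``responses`` maps patient -> list of
    (line, day_offset, label).  ``death_days`` is days after base.
    """
    responses = responses or {}
    death_days = death_days or {}
    events: dict[str, list[TreatmentEvent]] = {}
    patients: dict[str, PatientRecord] = {}
    resp: dict[str, list[ResponseRecord]] = {}
    for pid, labels in sequences.items():
        evs = []
        for i, lab in enumerate(labels):
            ttype, setting = parse_label(lab)
            start = BASE + dt.timedelta(days=120 * i)
            evs.append(
                TreatmentEvent(
                    patient_id=pid, line=i + 1, treatment_type=ttype,
                    setting=setting, start_date=start,
                    stop_date=start + dt.timedelta(days=80),
                )
            )
        events[pid] = evs
        death = death_days.get(pid)
        patients[pid] = PatientRecord(
            patient_id=pid,
            sex="M",
            birth_date=dt.date(1960, 1, 1),
            death_date=None if death is None else BASE + dt.timedelta(days=death),
            last_followup_date=BASE + dt.timedelta(
                days=death if death is not None else followup_days
            ),
        )
        resp[pid] = [
            ResponseRecord(pid, line, BASE + dt.timedelta(days=day), label)
            for line, day, label in responses.get(pid, [])
        ]
        resp[pid].sort(key=lambda r: (r.line, r.assessment_date))
    return EventLog(events=events, patients=patients, responses=resp)


@pytest.fixture
def two_patient_log():
    """A: [PD1]; B: [PD1, BRAFi+MEKi] — the minimal branching example."""
    return make_log({"A": ["PD1"], "B": ["PD1", "BRAFi+MEKi"]})


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def prefix_counts(sequences: dict[str, list]) -> dict[tuple, int]:
    """Brute-force enumeration of every sequence prefix and its patient count."""
    counts: dict[tuple, int] = {}
    for labels in sequences.values():
        for k in range(len(labels) + 1):
            counts[tuple(labels[:k])] = counts.get(tuple(labels[:k]), 0) + 1
    return counts


def km_oracle(durations, events):
    """Hand product-limit computation: (step_times, step_values), S(0)=1."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    times = [0.0]
    surv = [1.0]
    s = 1.0
    for t in np.unique(durations[events == 1]):
        n = int(np.sum(durations >= t))
        d = int(np.sum((durations == t) & (events == 1)))
        s *= 1.0 - d / n
        times.append(float(t))
        surv.append(s)
    return np.array(times), np.array(surv)


def logrank_chi2_oracle(t, e, g) -> float:
    """Two-group log-rank chi-square, straight from the O-E / variance sums."""
    t = np.asarray(t, float)
    e = np.asarray(e, int)
    g = np.asarray(g, int)
    O = E = V = 0.0
    for s in np.unique(t[e == 1]):
        risk = t >= s
        n = risk.sum()
        n1 = (risk & (g == 1)).sum()
        d = ((t == s) & (e == 1)).sum()
        d1 = ((t == s) & (e == 1) & (g == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V


def permutation_logrank_p(t, e, g, n_perm: int, seed: int) -> float:
    """Permutation-null p-value of the log-rank statistic (vectorised)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(t, float)
    e = np.asarray(e, int)
    g = np.asarray(g, int)
    n = t.size
    obs = logrank_chi2_oracle(t, e, g)
    perms = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perms[i] = rng.permutation(g).astype(bool)
    O = np.zeros(n_perm)
    E = np.zeros(n_perm)
    V = np.zeros(n_perm)
    for s in np.unique(t[e == 1]):
        risk = t >= s
        n_s = risk.sum()
        d_s = ((t == s) & (e == 1)).sum()
        n1 = perms[:, risk].sum(axis=1)
        d1 = perms[:, (t == s) & (e == 1)].sum(axis=1)
        O += d1
        E += d_s * n1 / n_s
        if n_s > 1:
            V += d_s * (n1 / n_s) * (1 - n1 / n_s) * (n_s - d_s) / (n_s - 1)
    stat = np.where(V > 0, (O - E) ** 2 / np.where(V > 0, V, 1.0), 0.0)
    return float(np.mean(stat >= obs - 1e-12))


def cox_loglik_grid_oracle(t, e, x, grid=None) -> float:
    """Maximise the Cox partial likelihood for one binary covariate on a grid.

    Valid for distinct event times (Breslow = Efron there).  Returns the
    maximising log hazard ratio.
    """
    t = np.asarray(t, float)
    e = np.asarray(e, int)
    x = np.asarray(x, int)
    if grid is None:
        grid = np.arange(-3.0, 3.0 + 1e-12, 1e-4)
    ll = np.zeros_like(grid)
    for ti, xi in zip(t[e == 1], x[e == 1]):
        risk = t >= ti
        n1 = int(x[risk].sum())
        n0 = int(risk.sum() - n1)
        ll += grid * xi - np.log(n0 + n1 * np.exp(grid))
    return float(grid[np.argmax(ll)])


def random_log(rng: np.random.Generator, max_patients: int = 30,
               vocab=("A", "B", "C", "adj:D", "E")) -> EventLog:
    """A random small event log over a ≤5-token label vocabulary."""
    n = int(rng.integers(1, max_patients + 1))
    seqs = {}
    for i in range(n):
        length = int(rng.integers(0, 5))
        seqs[f"p{i}"] = [vocab[int(rng.integers(0, len(vocab)))] for _ in range(length)]
    deaths = {
        pid: int(rng.integers(50, 1500))
        for pid in seqs
        if rng.uniform() < 0.4
    }
    return make_log(seqs, death_days=deaths)
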