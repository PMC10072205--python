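"""Synthetic real-world treatment-sequence cohorts with known ground truth.

The generator emulates the three curated registry tables the event-log
module consumes (treatments / responses / patients) for an advanced
melanoma-flavoured cohort: treatment paths are drawn from a Markov-style
transition structure over a (type, setting) vocabulary, best responses per
line from per-label response mixes, and overall survival from per-first-line
exponential hazards with optional multiplicative effects for later labels,
under administrative plus random censoring.  Every draw flows from a single
integer seed through one ``numpy`` generator, so a seed reproduces the
tables bit for bit, and the ground truth (each patient's path, event times
and response labels) is exported alongside the tables.

The default configuration is illustrative: sample size and vocabulary match
the scale of a single-centre advanced melanoma registry, with path
frequencies and response mixes loosely patterned on published first-line
usage and response rates.  It is not an estimate of any real cohort.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .tree import parse_label

BASE_DATE = dt.date(2015, 1, 1)
_DATE_FMT = "%d.%m.%Y"

TREATMENT_COLUMNS = [
    "patient_id", "line", "modification", "treatment", "type", "start", "stop",
    "setting",
]
RESPONSE_COLUMNS = ["patient_id", "line", "date", "label"]
PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_date", "death_date", "last_followup_date",
]

#: Representative drug names per treatment type (cosmetic only).
_DRUGS = {
    "PD1": "Pembrolizumab",
    "CTLA4": "Ipilimumab",
    "CTLA4+PD1": "Ipilimumab+Nivolumab",
    "BRAFi": "Vemurafenib",
    "MEKi": "Trametinib",
    "BRAFi+MEKi": "Dabrafenib+Trametinib",
    "chemo": "Dacarbazine",
    "other": "Other",
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; every probability vector sums to 1.

    Labels are strings in the tree-label syntax (``"PD1"``, ``"adj:PD1"``).
    ``transition`` maps a current label — or a ``>``-joined path prefix,
    which takes precedence — to a distribution over next labels plus a
    ``"stop"`` mass.  ``os_hazard`` is an exponential death rate per day
    keyed by the first-line label; ``hr_map`` multiplies the hazard for
    every patient whose path contains the given label.
    """

    n_patients: int = 300
    first_line: dict = field(default_factory=dict)
    transition: dict = field(default_factory=dict)
    response_mix: dict = field(default_factory=dict)
    line_duration: dict = field(default_factory=dict)  # label -> mean days
    os_hazard: dict = field(default_factory=dict)      # first-line label -> rate/day
    hr_map: dict = field(default_factory=dict)         # label -> hazard multiplier
    censor_rate: float = 0.15
    followup_horizon: int = 1826
    max_lines: int = 6
    split_prob: float = 0.0   # fraction of lines split into modifications
    seed: int = 0

    @property
    def vocabulary(self) -> list[str]:
        vocab = set(self.first_line)
        for dist in self.transition.values():
            vocab |= {k for k in dist if k != "stop"}
        return sorted(vocab)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValidationError("censor_rate must be in [0, 1]")
        if not 0.0 <= self.split_prob <= 1.0:
            raise ValidationError("split_prob must be in [0, 1]")
        for name, dist in [("first_line", self.first_line)] + [
            (f"transition[{k}]", v) for k, v in self.transition.items()
        ]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"{name} contains a negative probability")
        for label, mix in self.response_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"response_mix[{label}] sums to {total}, not 1"
                )
        for label, rate in self.os_hazard.items():
            if rate <= 0:
                raise ValidationError(f"os_hazard[{label}] must be > 0")
        for label in self.first_line:
            if label not in self.os_hazard:
                raise ValidationError(f"os_hazard missing first-line label {label!r}")
            if label not in self.line_duration:
                raise ValidationError(f"line_duration missing label {label!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


def default_config(n_patients: int = 300, seed: int = 0, **overrides) -> GeneratorConfig:
    """The shipped melanoma-flavoured study configuration.

    Vocabulary {adjuvant PD1, PD1, CTLA4, CTLA4+PD1, BRAFi+MEKi, chemo};
    first-line shares and onward transitions loosely patterned on the line
    counts of a single-centre advanced melanoma registry; response mixes
    give objective response rates of roughly 53 / 42 / 22% for
    CTLA4+PD1 / PD1 / CTLA4; exponential OS hazards correspond to first-line
    median OS of roughly 60 / 40 / 20 / 24 / 10 months (combination ICI /
    PD1 / CTLA4 / targeted / chemo) and ~90 months after adjuvant PD1.
    """
    ln2 = float(np.log(2.0))

    def rate(median_days: float) -> float:
        return ln2 / median_days

    cfg = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        first_line={
            "adj:PD1": 0.20,
            "PD1": 0.30,
            "CTLA4+PD1": 0.25,
            "BRAFi+MEKi": 0.15,
            "CTLA4": 0.06,
            "chemo": 0.04,
        },
        transition={
            "adj:PD1": {"stop": 0.72, "CTLA4+PD1": 0.12, "PD1": 0.08,
                        "BRAFi+MEKi": 0.08},
            "PD1": {"stop": 0.42, "CTLA4+PD1": 0.25, "BRAFi+MEKi": 0.18,
                    "CTLA4": 0.05, "chemo": 0.10},
            "CTLA4+PD1": {"stop": 0.50, "BRAFi+MEKi": 0.20, "PD1": 0.15,
                          "chemo": 0.10, "CTLA4": 0.05},
            "BRAFi+MEKi": {"stop": 0.50, "CTLA4+PD1": 0.25, "PD1": 0.15,
                           "chemo": 0.10},
            "CTLA4": {"stop": 0.40, "PD1": 0.30, "CTLA4+PD1": 0.20, "chemo": 0.10},
            "chemo": {"stop": 0.60, "PD1": 0.20, "BRAFi+MEKi": 0.20},
        },
        response_mix={
            "adj:PD1": {"RE": 0.10, "NR": 0.90},
            "PD1": {"CR": 0.15, "PR": 0.27, "SD": 0.25, "PD": 0.33},
            "CTLA4+PD1": {"CR": 0.17, "PR": 0.36, "SD": 0.20, "PD": 0.27},
            "CTLA4": {"CR": 0.05, "PR": 0.17, "SD": 0.25, "PD": 0.53},
            "BRAFi+MEKi": {"CR": 0.10, "PR": 0.45, "SD": 0.25, "PD": 0.20},
            "chemo": {"CR": 0.02, "PR": 0.10, "SD": 0.30, "PD": 0.58},
        },
        line_duration={
            "adj:PD1": 330, "PD1": 200, "CTLA4+PD1": 150, "CTLA4": 90,
            "BRAFi+MEKi": 260, "chemo": 90,
        },
        os_hazard={
            "adj:PD1": rate(2740),
            "PD1": rate(1216),
            "CTLA4+PD1": rate(1825),
            "CTLA4": rate(608),
            "BRAFi+MEKi": rate(730),
            "chemo": rate(304),
        },
        hr_map={},
        censor_rate=0.15,
        followup_horizon=1826,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@dataclass
class TruthExport:
    """Ground truth of a generated cohort: per-patient paths and event times."""

    config: dict
    patients: list  # dicts with path, line offsets, responses, death/censor days

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {"config": self.config, "patients": self.patients},
            indent=indent, sort_keys=True,
        )

    @property
    def paths(self) -> dict[str, tuple[str, ...]]:
        return {p["patient_id"]: tuple(p["path"]) for p in self.patients}


def _draw(rng: np.random.Generator, dist: dict) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _fmt(day_offset: float | None) -> str:
    if day_offset is None:
        return ""
    return (BASE_DATE + dt.timedelta(days=int(day_offset))).strftime(_DATE_FMT)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthExport]:
    """Draw a full synthetic cohort.

    Returns the three tables in exactly the event-log CSV dialects
    (dates printed ``DD.MM.YYYY``) plus the :class:`TruthExport`.  Paths
    are truncated at death or censoring, and the truth records the emitted
    (post-truncation) path for each patient, which is what the event log
    and treatment tree can recover.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    t_rows, r_rows, p_rows = [], [], []
    truth_patients = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        recruit = float(rng.integers(0, 1461))  # days after the registry base date

        # ---- sample the full treatment path ------------------------------
        path: list[str] = [_draw(rng, config.first_line)]
        while len(path) < config.max_lines:
            key = ">".join(path)
            dist = config.transition.get(key) or config.transition.get(path[-1])
            if dist is None:
                break
            nxt = _draw(rng, dist)
            if nxt == "stop":
                break
            path.append(nxt)

        # ---- schedule the lines ------------------------------------------
        starts, stops = [], []
        t = 0.0  # days since first treatment start
        for label in path:
            mean = float(config.line_duration.get(label, 180))
            duration = max(float(rng.gamma(2.0, mean / 2.0)), 7.0)
            starts.append(t)
            stops.append(t + duration)
            t = t + duration + float(rng.uniform(14, 90))

        # ---- survival and censoring --------------------------------------
        hazard = float(config.os_hazard[path[0]])
        for label in set(path):
            hazard *= float(config.hr_map.get(label, 1.0))
        death_day = float(rng.exponential(1.0 / hazard))
        censor_day = float(config.followup_horizon)
        if rng.uniform() < config.censor_rate:
            censor_day = min(censor_day, float(rng.uniform(0.25, 1.0))
                             * config.followup_horizon)
        died = death_day <= censor_day
        end_day = death_day if died else censor_day

        # ---- truncate the path at end of follow-up -----------------------
        keep = [j for j, s in enumerate(starts) if s < end_day or j == 0]
        path, starts, stops = (
            [path[j] for j in keep],
            [starts[j] for j in keep],
            [min(stops[j], end_day) if died else stops[j] for j in keep],
        )

        # ---- emit treatment rows -----------------------------------------
        for j, label in enumerate(path):
            ttype, setting = parse_label(label)
            ongoing = (not died) and stops[j] >= censor_day
            t_rows.append(
                {
                    "patient_id": pid,
                    "line": j + 1,
                    "modification": 1,
                    "treatment": _DRUGS.get(ttype, ttype),
                    "type": ttype,
                    "start": _fmt(recruit + starts[j]),
                    "stop": "" if ongoing else _fmt(recruit + stops[j]),
                    "setting": "adjuvant" if setting == "adjuvant" else "",
                    "_start_day": recruit + starts[j],
                    "_stop_day": None if ongoing else recruit + stops[j],
                }
            )

        # ---- responses ----------------------------------------------------
        bors = []
        for j, label in enumerate(path):
            ttype, setting = parse_label(label)
            has_next = j + 1 < len(path)
            if setting == "adjuvant":
                if has_next:
                    bor = "RE"
                else:
                    bor = _draw(rng, config.response_mix.get(label, {"NR": 1.0}))
                # recurrence assessed at line end or just before the next line
                when = stops[j] + float(rng.uniform(5, 30))
                if has_next:
                    when = min(when, max(starts[j + 1] - 1.0, stops[j] + 1.0))
                when = min(when, end_day)
                r_rows.append(
                    {"patient_id": pid, "line": j + 1,
                     "date": _fmt(recruit + when), "label": bor,
                     "_day": recruit + when}
                )
            else:
                mix = config.response_mix.get(
                    label, {"CR": 0.1, "PR": 0.3, "SD": 0.3, "PD": 0.3}
                )
                bor = _draw(rng, mix)
                span = max(stops[j] - starts[j], 2.0)
                when = starts[j] + float(rng.uniform(0.3, 0.9)) * span
                when = max(starts[j], min(when, end_day))
                r_rows.append(
                    {"patient_id": pid, "line": j + 1,
                     "date": _fmt(recruit + when), "label": bor,
                     "_day": recruit + when}
                )
                if has_next and bor != "PD":
                    # progression triggering the switch to the next line
                    pd_when = max(stops[j] + 1.0, when + 1.0)
                    pd_when = min(pd_when, max(starts[j + 1] - 1.0, when + 1.0))
                    r_rows.append(
                        {"patient_id": pid, "line": j + 1,
                         "date": _fmt(recruit + pd_when), "label": "PD",
                         "_day": recruit + pd_when}
                    )
            bors.append(bor)

        # ---- patient row ---------------------------------------------------
        sex = "M" if rng.uniform() < 0.6 else "F"
        birth = dt.date(1940 + int(rng.integers(0, 46)), 1 + int(rng.integers(0, 12)),
                        1 + int(rng.integers(0, 28)))
        p_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": birth.strftime(_DATE_FMT),
                "death_date": _fmt(recruit + death_day) if died else "",
                "last_followup_date": _fmt(recruit + end_day),
            }
        )

        truth_patients.append(
            {
                "patient_id": pid,
                "path": list(path),
                "line_start_days": [round(recruit + s, 1) for s in starts],
                "line_stop_days": [round(recruit + s, 1) for s in stops],
                "bor": bors,
                "first_treatment_day": round(recruit + starts[0], 1),
                "death_day": round(recruit + death_day, 1) if died else None,
                "censor_day": round(recruit + end_day, 1),
                "event": bool(died),
            }
        )

    treatments = pd.DataFrame(t_rows, columns=TREATMENT_COLUMNS + ["_start_day",
                                                                   "_stop_day"])
    if config.split_prob > 0 and len(treatments):
        treatments = inject_modifications(
            treatments, config.split_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    treatments = treatments[TREATMENT_COLUMNS].reset_index(drop=True)
    responses = (
        pd.DataFrame(r_rows, columns=RESPONSE_COLUMNS + ["_day"])[RESPONSE_COLUMNS]
        if r_rows
        else pd.DataFrame(columns=RESPONSE_COLUMNS)
    )
    patients = pd.DataFrame(p_rows, columns=PATIENT_COLUMNS)
    truth = TruthExport(config=config.to_dict(), patients=truth_patients)
    return treatments, responses, patients, truth


def inject_modifications(
    treatments: pd.DataFrame, split_prob: float, seed: int
) -> pd.DataFrame:
    """Split a fraction of single-modification lines into 2–3 consecutive
    modification rows spanning exactly the original interval.

    The earliest modification start equals the line's original start and the
    latest stop its original stop, so re-merging recovers each line's
    interval exactly.  Lines with a missing stop or a short duration are
    left alone.
    """
    if not 0.0 <= split_prob <= 1.0:
        raise ValidationError("split_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_rows = []
    date_fmt = _DATE_FMT

    def _parse(txt):
        txt = str(txt).strip()
        if not txt:
            return None
        for fmt in (date_fmt, "%Y-%m-%d"):
            try:
                return dt.datetime.strptime(txt, fmt).date()
            except ValueError:
                continue
        return None

    single = treatments.groupby(["patient_id", "line"])["modification"].transform(
        "max"
    ) == 1
    for idx, row in treatments.iterrows():
        start, stop = _parse(row["start"]), _parse(row["stop"])
        duration = None if stop is None else (stop - start).days
        splittable = bool(single.loc[idx]) and duration is not None and duration >= 9
        if not (splittable and rng.uniform() < split_prob):
            out_rows.append(dict(row))
            continue
        k = int(rng.integers(2, 4))  # 2 or 3 modifications
        cuts = np.sort(rng.choice(np.arange(2, duration - 1), size=k - 1,
                                  replace=False))
        bounds = [0] + [int(c) for c in cuts] + [duration]
        for m in range(k):
            seg_start = start + dt.timedelta(days=bounds[m] + (1 if m else 0))
            seg_stop = start + dt.timedelta(days=bounds[m + 1])
            r = dict(row)
            r["modification"] = m + 1
            r["start"] = seg_start.strftime(date_fmt)
            r["stop"] = seg_stop.strftime(date_fmt)
            out_rows.append(r)
    return pd.DataFrame(out_rows, columns=list(treatments.columns)).reset_index(
        drop=True
    )


def write_cohort(out_dir, config: GeneratorConfig):
    """Generate and write treatments/responses/patients CSVs + truth JSON."""
    import os

    treatments, responses, patients, truth = generate_cohort(config)
    paths = {}
    for name, df in [("treatments", treatments), ("responses", responses),
                     ("patients", patients)]:
        p = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    tp = os.path.join(out_dir, "truth.json")
    with open(tp, "w") as fh:
        fh.write(truth.to_json())
    paths["truth"] = tp
    return paths


def two_arm_survival(
    n_per_arm: int,
    hazard_ratio: float,
    base_rate: float = 1.0 / 365.0,
    censor_horizon: float = 1826.0,
    censor_rate: float = 0.1,
    seed: int = 0,
):
    """Plain two-arm exponential survival draws (arm B hazard = HR x arm A).

    A convenience for calibration and parameter-recovery studies: returns
    ``((t_a, e_a), (t_b, e_b))`` with administrative censoring at the
    horizon plus random uniform early censoring.
    """
    rng = np.random.default_rng(seed)

    def arm(rate):
        t_event = rng.exponential(1.0 / rate, size=n_per_arm)
        censor = np.full(n_per_arm, censor_horizon)
        early = rng.uniform(0, censor_horizon, size=n_per_arm)
        use_early = rng.uniform(size=n_per_arm) < censor_rate
        censor = np.where(use_early, np.minimum(early, censor), censor)
        t = np.minimum(t_event, censor)
        e = (t_event <= censor).astype(int)
        return t, e

    return arm(base_rate), arm(base_rate * hazard_ratio)
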