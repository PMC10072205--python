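"""ICI rechallenge vs switch to targeted treatment after first-line ICI.

Selects the second-line nodes under a first-line ICI node — rechallenging
with another ICI line vs switching to a BRAF-inhibitor-based line — and
compares OS and PFS anchored at second-line start.  Patients whose first
line was not PD1-based are excluded by construction of the paths.
"""

import os, tempfile, warnings

from careflow import default_config, generate_cohort, load_event_log
from careflow.workflows import rechallenge_comparison

with tempfile.TemporaryDirectory() as tmp:
    t, r, p, _ = generate_cohort(default_config(n_patients=500, seed=42))
    for name, df in (("t", t), ("r", r), ("p", p)):
        df.to_csv(os.path.join(tmp, f"{name}.csv"), index=False)
    log, _ = load_event_log(*(os.path.join(tmp, f"{n}.csv") for n in "trp"))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = rechallenge_comparison(log)

for endpoint in ("os", "pfs"):
    c = res[endpoint]
    a, b = c.names  # switch, rechallenge
    print(f"{c.endpoint}: HR({b} vs {a}) = {c.hazard_ratio:.2f} "
          f"[{c.hr_ci_low:.2f}, {c.hr_ci_high:.2f}], "
          f"log-rank p = {c.logrank_p:.3f}")
for name, cohort in res["cohorts"].items():
    print(f"  {name}: n = {cohort.n}")
print("\nUnder the default generator both second lines share the same "
      "hazard, so the HR should hover around 1; set hr_map to plant a "
      "true effect and watch the comparison recover it.")
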