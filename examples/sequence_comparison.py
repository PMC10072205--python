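"""Compare the treatment sequences ICI -> TT and TT -> ICI.

PD1-based lines are grouped as ICI (immune checkpoint inhibition) and
BRAF-inhibitor-based lines as TT (targeted treatment); chemo lines are
neglected in the sequences.  Both OS and PFS start at the first line of
the sequence, and PFS evaluates the first treatment only — the design of
the sequencing question in first-line BRAF-mutant melanoma.
"""

import os, tempfile, warnings

from careflow import default_config, generate_cohort, load_event_log
from careflow.workflows import sequence_comparison

with tempfile.TemporaryDirectory() as tmp:
    t, r, p, _ = generate_cohort(default_config(n_patients=500, seed=42))
    for name, df in (("t", t), ("r", r), ("p", p)):
        df.to_csv(os.path.join(tmp, f"{name}.csv"), index=False)
    log, _ = load_event_log(*(os.path.join(tmp, f"{n}.csv") for n in "trp"))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = sequence_comparison(log)  # 2-year landmark by default

for endpoint in ("os", "pfs"):
    c = res[endpoint]
    print(f"{c.endpoint}: log-rank p = {c.logrank_p:.3f}, "
          f"HR(ICI->TT vs TT->ICI) = {c.hazard_ratio:.2f} "
          f"[{c.hr_ci_low:.2f}, {c.hr_ci_high:.2f}]")
    for name in c.names:
        lm = c.landmark_estimates[name]
        print(f"  2y {c.endpoint} {name}: {lm['rate']:.0%} "
              f"[{lm['ci_low']:.0%}, {lm['ci_high']:.0%}] "
              f"(n={res['cohorts'][name].n})")
# A 2-year OS gap in favour of ICI->TT mirrors the sequencing-trial pattern
# whenever the generator's hazards make early TT switching less durable.
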