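# Methods

## Data model

The package consumes three tables that mirror how curated oncology registries
record systemic treatment:

* **treatments** — one row per (patient, line, modification). A *line* is a
  discrete therapy episode; a *modification* is a within-line change
  (maintenance after an induction doublet, a switch within the same class for
  toxicity) that does not open a new line. Types come from a controlled
  vocabulary (`PD1`, `CTLA4`, `CTLA4+PD1`, `BRAFi`, `MEKi`, `BRAFi+MEKi`,
  `chemo`, `other`); a user-editable mapping table canonicalises raw variants
  (e.g. `BRAFi+TT_MEKi` → `BRAFi+MEKi`) with a warn-and-pass contract for
  unknown tokens. The `setting` flag separates adjuvant from advanced lines.
* **responses** — dated labels per (patient, line): CR/PR/SD/PD for advanced
  lines, RE/NR (recurrence / no recurrence) for adjuvant lines.
* **patients** — sex, birth date, death date and/or last follow-up date, plus
  free extra columns absorbed into an attribute map.

Dates are accepted as `DD.MM.YYYY` (the registry print format) or ISO-8601.

### Merging rule and its rationale

Modifications of a line are merged into one event keeping the earliest start,
the latest stop (missing while any modification is ongoing) and the **first**
modification's treatment type. The first-modification rule encodes the
clinical reading that a line is named by its induction: PD1 maintenance after
a CTLA4+PD1 induction is still a CTLA4+PD1 line. Event labels are
*(type, setting)* pairs, so an adjuvant PD1 line and an advanced first-line
PD1 are different tree labels — they answer different clinical questions.

### Validation policy

Hard invariants (start ≤ stop, positive line/modification indices, unique
(patient, line, modification), one setting per line, line order consistent
with start-date order, at least one of death/last-follow-up) exclude the
offending row or patient with a machine-readable reason (JSON-lines report:
`{patient_id, row, rule, message}`). Soft problems (responses for unknown
lines, RE/NR on non-adjuvant lines) drop only the offending response.
Overlapping date ranges across *different* lines are not rejected — registry
data genuinely contains them — only order inversions are. Parsing collects
issues by default; a `strict` flag raises instead, for pipelines that prefer
to fail fast.

## Treatment-tree discovery

The tree is the prefix tree of per-patient label sequences: the root
("recruitment") holds all patients, and a node exists for every observed
prefix with at least `min_patients` patients. Discovery is a single recursive
partition of each node's patients by their next label — O(total events) — and
is deterministic: children are ordered by descending patient count, ties
broken lexicographically. Pruning removes whole subtrees (prefix-tree
semantics: a path through a removed node cannot survive) and is only allowed
to raise the threshold; the result equals rediscovery at the new threshold,
which the tests check. The default display threshold is 4 patients per node;
no maximum depth is imposed.

Exports: JSON (nodes with BOR counts and a compact OS summary, edges with
branch fractions; patient identifiers only on explicit request) and Graphviz
DOT text with edge `penwidth` equal to `1 + 6·fraction` and adjuvant nodes
filled distinctly.

## Outcome statistics

* **BOR** per line is the maximum label under CR > PR > SD > PD. The ordering
  is the RECIST convention; the source vocabulary names the labels but not the
  order. `NE` (not evaluable) marks lines with no assessment; distributions
  expose both the all-patients and the evaluable-only normalisation, and the
  objective response rate is (CR+PR)/evaluable.
* **Adjuvant nodes** report RE if any recurrence label exists, else NR if a
  no-recurrence label exists, else NE.
* **OS** per node is the Kaplan-Meier product-limit estimate of time from the
  node's per-patient anchor (start of that treatment line) to death, censored
  at last follow-up. A registry death date on/before the anchor clamps to day
  0; a patient whose last follow-up precedes the anchor (and who is not dead)
  cannot contribute and is excluded with a warning. The five-year horizon
  truncates the *displayed* steps only; the estimator uses all follow-up.
* **PFS** is time from anchor to the earliest of: first PD label on the
  anchoring line or any later line (RE plays the PD role when the anchor is
  adjuvant), or death; otherwise censoring at last follow-up. The data format
  records progression labels rather than PFS dates, and death without a
  recorded PD counts as an event — the standard oncology convention. When a
  sequence cohort is re-anchored at its first line, PFS therefore evaluates
  the first treatment; note that such cohorts condition on reaching the later
  line, which is a selection (immortal-time) effect inherent to path-defined
  cohorts, not an estimator artefact.

The product-limit estimator, Greenwood-type confidence bands, the two-group
log-rank test and the Cox proportional-hazards fit (single binary covariate,
Efron tie handling, Wald 95% CI) are delegated to `lifelines`; the package
owns anchoring, cohort construction and result assembly. The test suite
cross-checks these against independent oracles written from first principles:
a hand product-limit computation, a vectorised permutation null for the
log-rank p-value, and a partial-likelihood grid search for the Cox
coefficient (on distinct event times, where Efron and Breslow coincide).
Degenerate inputs have defined behaviour: empty groups and empty curves are
contract errors, a comparison with zero events returns statistic 0 / p 1, a
Cox fit with zero events is a fit error, and an event-free arm is reported
with the infinite-bound convention.

## Cohort algebra

A cohort is ∪(added nodes) ∖ ∪(subtracted nodes), as patient sets.
Subtraction is pure set difference — a subtracted node removes its patients
regardless of which added node contributed them. Anchors come from the node a
patient entered through; when several added nodes contain the same patient,
the shallowest node's anchor wins, with a warning (the interactive workflow
this replaces leaves the case undefined, so the package picks the earliest
clock and says so). `anchor_depth` re-anchors every member at their ancestor
at that depth, which is how sequence analyses start the clock at the first
line. Provenance (path, add/subtract) is recorded and replaying it reproduces
the membership exactly. Hazard ratios are always reported as second-listed
cohort vs first-listed, printed with the comparison order.

The expression mini-language (`"PD1>CTLA4+PD1 + PD1>PD1 - adj:PD1"`) is the
scriptable form of the drag-and-drop: `>` chains labels into a path,
whitespace-delimited `+`/`-` add or subtract nodes, `adj:` marks adjuvant
labels. Operators must be whitespace-delimited because treatment types
themselves contain `+`.

## Synthetic cohort generator

The generator emulates the registry tables with known ground truth:

* **Paths** are drawn from a first-line distribution and a Markov-style
  transition map (a `>`-joined path prefix key overrides the first-order
  fallback; a `stop` mass ends the path; paths cap at 6 lines).
* **Schedules**: line durations are gamma-distributed (shape 2) around a
  per-label mean with a 7-day floor and 14–90-day inter-line gaps;
  recruitment dates spread over four years.
* **Survival** is exponential from first-line start with a per-first-line
  rate times multiplicative `hr_map` effects for any label on the path;
  censoring is administrative at the follow-up horizon (5 years) plus random
  early censoring with probability `censor_rate`. Paths are truncated at
  death/censoring and the truth export records the *emitted* path — the one
  an event log can recover.
* **Responses**: one BOR label per line drawn from a per-label mix, dated
  inside the line; patients who move to a next line get a terminal PD (or
  RE, for adjuvant lines) before the next line starts, so tree transitions
  are response-consistent. A fraction of lines can be split into 2–3
  modification rows spanning exactly the original interval, to exercise the
  merging rule; re-merging recovers each interval bit for bit.

Default configuration (the shipped study conditions): 300 patients —
the scale of a single-centre advanced-melanoma registry — over the vocabulary
{adjuvant PD1, PD1, CTLA4, CTLA4+PD1, BRAFi+MEKi, chemo}; first-line shares
and transitions loosely patterned on published single-centre line counts
(30% PD1, 25% CTLA4+PD1, 20% adjuvant PD1, 15% BRAFi+MEKi, …; 72% of
adjuvant-PD1 patients never recur onto a next line); response mixes giving
objective response rates near 53/42/22% for CTLA4+PD1/PD1/CTLA4; exponential
OS medians near 60/40/20/24/10 months by first line and ~90 months after
adjuvant PD1; 15% random censoring. These are illustrative magnitudes chosen
once, not estimates of any real cohort. All randomness flows through one
`numpy` `default_rng(seed)`, so a seed reproduces the tables bit for bit
across platforms.

**What passing tests show — and don't.** The generator produces clean,
response-consistent, single-centre-sized data. It does not model
confounding by indication, immortal-time structure, informative censoring,
missing/contradictory annotations, or lesion-level response assessment, so
green tests certify the machinery (parsing, merging, discovery, estimation,
algebra) and its statistical calibration — not the clinical validity of any
comparison run on real data, where those biases dominate.

## Scripted analyses

Three canonical studies ship as functions (`careflow.workflows`) and as
narrative scripts under `examples/`:

* **First-line ICI arms**: first advanced-setting line in {CTLA4+PD1, PD1,
  CTLA4}, anchored there; ORR per arm; OS with five-year landmark.
* **Sequence comparison** ICI→TT vs TT→ICI: adjuvant lines dropped, chemo
  neglected in sequences, PD1-based lines grouped as ICI and BRAFi-based as
  TT; CTLA4 monotherapy is deliberately left ungrouped so it cannot enter an
  ICI sequence; both endpoints anchored at the first line of the sequence
  (PFS evaluates the first treatment); two-year landmark.
* **ICI rechallenge** vs switch to TT: second-line nodes under a first-line
  ICI node, anchored at second-line start; non-ICI first lines are excluded
  by construction of the paths.

## Numerical and design choices

* Ties in event times: Efron handling (the `lifelines` default);
  documented because the choice is otherwise invisible.
* Landmark rates read the KM step function with its Greenwood log-log CI;
  a landmark beyond the last observed time returns the last value with an
  extrapolation warning rather than guessing.
* Tree node ids are breadth-first, so serialisations are stable; no
  timestamps enter any artifact, making CLI reruns byte-identical.
* The CLI exits non-zero when validation excluded data (hard rules), zero
  when only warnings occurred.
* Problem sizes in tests and in `scripts/acceptance.py` (500-patient
  cohorts, 1000–2000 simulation replicates, 10,000 permutations) were chosen
  to make sampling error small relative to the asserted tolerances while
  keeping a full run in tens of seconds.

## Known limitations

* Single binary covariate only — no multivariable or covariate-adjusted
  models, no propensity scoring.
* No conformance checking, Petri-net/BPMN output or first-order Markov
  fitting; the tree is the only process model.
* PFS for sequences evaluates the anchoring line and does not censor at
  treatment switch; the alternative convention would need explicit switch
  dates.
* Whether node BOR pies should count NE patients is a display decision;
  both normalisations are exposed and the JSON export reports raw counts.
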