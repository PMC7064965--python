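# Methods

This note documents the models and procedures implemented in
`edjourney`, the parameters that matter, the numerical conventions, and
the design choices made where the design was genuinely open.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. Event-log model

An `Event` is one procedure occurrence for one patient with up to three
timestamps: `ordered_at` (the procedure is requested and the patient
enters the queue), `started_at` (service begins) and `completed_at`.
All timestamps are ISO-8601 at minute resolution in one implicit
timezone — the granularity of ED medical records — which also avoids
daylight-saving logic.  Patients carry only operational attributes
(triage 1–5, arrival mode, age, gender) and an opaque identifier; the
model has no fields for names or clinical results, and journey views
never render anything beyond procedure labels, times and locations.

**Activity aggregation.** Granular activities map to patient-facing
procedures through an explicit mapping; same-patient, same-procedure
events whose `[ordered_at, completed_at]` intervals overlap are merged
(earliest order, latest completion), with a missing completion treated
as an open interval.  Events that already carry a procedure label keep
it, which makes aggregation idempotent.  The merge criterion is interval
overlap rather than exact time equality because order timestamps of a
single blood draw's component tests can differ by a few minutes in
practice.

**Wait definition.** The realized wait for a procedure is
`started_at − ordered_at` by default.  Logs that record only completion
times can switch the endpoint to `completed_at` (then "wait" includes
service).  Rows with a missing endpoint are excluded from training and
counted — this is exactly what happens to lab records that are written
to the database only after completion.

## 2. The ED simulator

The simulator exists to give every downstream estimator a log whose true
dynamics are known.  It is an event-driven (priority-queue) simulation:

* **Arrivals** — non-homogeneous Poisson by thinning, with a 24×7
  hour-of-day × weekday rate table.  The default profile ramps from
  ~0.6/h at night to 7/h at midday (mean ≈ 3.6/h, ≈ 600 patients/week).
  Magnitudes are stated defaults, chosen as plausible for a mid-sized
  ED section; they are not calibrated to any particular hospital.
* **Routing** — per-triage stage lists; each stage is a categorical
  choice over branches, and a branch may order ≥2 procedures at once
  (e.g. lab tests + CT scan), creating genuinely simultaneous queue
  membership.  The default roster has nine procedures (nurse, physician,
  lab tests, CT scan and interpretation, ultrasound examination and
  interpretation, x-ray, specialist).
* **Queues** — FIFO multi-server per procedure.  Service-time families:
  exponential, deterministic, lognormal (parameterized by mean and
  log-scale sd), gamma.  Default staffing is sized for moderate peak
  utilization (~0.5–0.8) so queues form at busy hours.
* **Service exclusivity** — a patient can be *in service* in at most one
  procedure at a time (waiting in several queues is fine); a free server
  takes the first queued patient not busy elsewhere.  The physically
  sensible default; configurable off.
* **Succession pairs** — deterministic (antecedent → consequent) orders
  fired at the antecedent's completion; defaults are
  US examination → US interpretation and CT scan → CT interpretation.
* **Recording-delay noise** — with probability
  `recording_delay_fraction`, a lab-type event is logged as if it only
  appeared at completion: recorded `ordered_at == completed_at`,
  `started_at` absent.  Ground truth keeps the real times, so the
  information loss is measurable.
* **Truncation** — journeys unfinished at the horizon are emitted with
  missing start/completion fields and the patient flagged, exercising
  missing-data paths downstream.

One shared `numpy` generator, seeded from the config, drives everything;
identical seeds give byte-identical logs.  Emitted timestamps are
floored to whole minutes, and the ground-truth waits/queue lengths are
computed from the same floored times so that a brute-force recount on
the emitted log reproduces them exactly when recording noise is off.

`erlang_c_expected_wait` provides the closed-form M/M/c mean wait used
to validate the engine: a single-queue exponential configuration must
match it within three batch-means standard errors (warm-up discarded).

## 3. Process discovery

Journeys order each patient's events by `ordered_at`, breaking ties by
completion time then procedure name — deterministic even for
simultaneous orders, which ED data is full of.  The journey graph counts
*immediate* succession (that is what a process chart displays), while
rule confidence counts *eventual* follows (the consequent anywhere later
in the journey), because anticipation cares about eventual occurrence,
not adjacency.  Rule defaults: `min_support` 20 journeys,
`min_confidence` 0.9; both configurable.  Self-pairs (A → A) are not
mined.  DOT and JSON exports are plain text; the JSON export round-trips
losslessly.

## 4. Queueing features

Snapshot definitions, all conditioned on records with timestamps ≤ t:

| feature | definition | default |
|---|---|---|
| queue_length | orders with no recorded start/completion at t (incl. the focal order) | — |
| service_rate | completions in (t−W, t] / W | W = 2 h sliding |
| last_wait | wait of the most recent patient whose service started ≤ t | 0 if none |
| ed_census | patients arrived and not discharged at t | — |

Cold start: an empty window falls back to the long-run completions/hour
over the whole log so far and sets a flag in the vector.  The census
counts the whole log; a section filter can be applied upstream by
subsetting the log.  Categorical encodings for learning: arrival mode
(walk-in 0 / ambulance 1), gender (F 0 / M 1); the completed/anticipated
sets enter as counts.

The leakage guarantee is structural: every comparison in the snapshot
index is of the form `timestamp ≤ t`, so computing on the full log and
on the t-truncated log is provably identical; the test suite checks the
equality directly at random snapshots.

## 5. Waiting-time ranges

* **Quantile convention** — ceiling-index order statistic: the
  q-quantile of n values is the `ceil(q·n)`-th smallest (inverse
  empirical CDF).  For the per-procedure empirical estimator this bounds
  the in-sample exceedance by 1−q (15% at q = 0.85) by construction.
* **Quantile forest** — `RandomForestRegressor` (100 trees,
  `max_features` 0.6, seeded) with per-leaf retention of training waits;
  a prediction pools leaf co-inhabitants across trees with weights
  1/leaf-size and takes weighted quantiles.  `min_samples_leaf` is 10:
  tail order statistics from very small leaves are upward-biased, and
  ~10 waits per leaf keeps the 0.85-quantile recovery within 10%
  relative error on simulated strata while preserving conditioning.
  The forest errs on the conservative side out of sample (exceedance
  below the nominal 15%) — an intentional bias direction for a
  patient-facing bound.
* **Baseline** — procedures with fewer than `min_rows` = 50 training
  rows use empirical quantiles stratified by hour-of-day block
  (0–5, 6–11, 12–17, 18–23), flagged on the model.
* **Point estimate** — the conditional median; the display primarily
  uses the range.
* **Models are per procedure** (seeded per procedure for determinism); a
  joint model with procedure as a feature was considered and rejected to
  keep per-procedure guarantees auditable.
* **LoS** — a separate model of the same family trained on ED-level
  arrival snapshots with total stay as the target (the alternative —
  summing remaining per-stage predictions — ignores queue overlap).  At
  display time the lower bound is clamped to the elapsed stay, making
  the estimate monotone in elapsed time; a discharged patient's range
  collapses onto the realized stay.
* **Evaluation** — exceedance (actual strictly above the upper bound),
  undershoot, mean interval width and point MAE, by direct counting, per
  procedure and pooled.
* **Retraining** — refit on old+new rows (or new-only) with lineage in
  the metadata; the drift experiment in the test suite halves a service
  rate and verifies that retraining lowers the exceedance rate on
  post-shift data.
* **Persistence** — a model directory holds `params.json` plus the
  training table as CSV; loading refits deterministically from them
  (seeded forests), keeping artifacts plain text.

## 6. Journey views

`journey_state(log, rules, model, patient, t)` partitions the patient's
known journey at t into *Completed* (recorded completion ≤ t), *Now*
(ordered, not completed; each with a predicted range evaluated on the
snapshot at t) and *Later* (rule consequents of completed/ordered
antecedents, minus Completed ∪ Now).  The three sections are disjoint by
construction; a procedure that recurs later in a journey (e.g. a second
physician visit) is therefore not re-listed under Later while an earlier
occurrence sits in Completed — the conservative reading when the record
cannot distinguish a repeat visit from the same one.

Overdue fallback: when the elapsed wait strictly exceeds the predicted
upper bound, the range is replaced by a generic cap, default
"up to 15 min".  Two alternative behaviours ("time estimates are not
available" / "please check with the care team") are selectable.  Now
items are sorted by predicted lower bound ascending; Later by rule
confidence descending.  Estimates refresh on a 5-minute tick
(`refresh_schedule`), recomputing from the t-truncated log each time.

## 7. What the simulator does and does not emulate

Passing tests on simulated logs show that the estimators recover known
structure (planted succession rules, stratified wait distributions,
queue counts, Erlang-C means) and honour their guarantees under the
stated dynamics.  Real ED data differ in ways the simulator does not
model: patient physiology and acuity-dependent service times, staff
breaks and shift changes, priority (non-FIFO) disciplines, re-ordered or
cancelled procedures, guideline changes over time, and richer
recording noise than the single lab-delay mechanism.  Results on
simulated data therefore validate correctness of the machinery, not
field performance.

## 8. Problem sizes and numerical notes

The bundled experiments use one simulated week of the default ED
(~600 patients, ~2,300 completed waits) for pipeline-level checks, and
single-queue configurations of 1–4 weeks for calibration and
queueing-theory comparisons; these sizes give stable rates while keeping
any run in the minutes range on one core.  Probability vectors must sum
to 1 within 1e-9; degenerate inputs (empty logs, horizon 0, all-constant
waits, one-sample leaves) are exercised in the tests and produce empty
artifacts or collapsed ranges rather than errors.  Ties in journey
ordering are broken deterministically (completion time, then name);
range invariants (0 ≤ lower ≤ point ≤ upper) are enforced by sorting and
clamping at prediction time.

## 9. Known limitations

* Succession-rule confidence conflates interrupted journeys with true
  rule violations; mining on completed journeys only is recommended
  (and done in the bundled experiments).
* The quantile forest's conservative out-of-sample coverage means its
  intervals are wider than strictly necessary; the empirical baseline is
  the calibrated reference.
* Census and service rates are whole-log aggregates; multi-section EDs
  need pre-filtered logs per section.
* The LoS model conditions on arrival-time features only; mid-stay
  updates enter only through the elapsed-time clamp.
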