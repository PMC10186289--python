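# Methods

## Episode model and classification rules

One analysis case is a *therapy episode*: a client's journey from first to
last session. Psychological distress is measured on the CORE-10 scale
(0–40 points, dimensionless). Classification rules:

* **Severity bands.** Half-open intervals healthy [0, 6), low [6, 10),
  mild [10, 15), moderate [15, 20), moderately severe [20, 25) and severe
  [25, 40], the top band closed so the scale is tiled exactly. Scores are
  accepted as reals (instrument-transformed scores need not be integers).
* **Clinical cut-off.** 10 points; below it (healthy/low bands) distress
  is sub-clinical, and significant improvement is arithmetically
  constrained (healthy starters cannot drop 6 points).
* **Reliable change.** With d = post − pre: d ≤ −6 significant
  improvement, −6 < d ≤ 0 non-significant improvement, 0 < d < 6
  non-significant deterioration, d ≥ 6 significant deterioration. Zero
  change is folded into non-significant improvement ("decreased by fewer
  than 6 points" read as including a decrease of zero); the choice is
  visible in the classifier and its tests so users can audit it.
* **Session bins.** <2 / 2–7 / 8–15 / 16–20 / >20 total sessions, the
  four upper bins tracking typical stepped-care intervention durations.
  Episodes with 0–1 sessions keep a visible "<2" bin rather than being
  silently dropped — how such episodes were originally handled is not
  documented, and dropping them would hide a real service phenomenon.
* **Missed-appointment bins.** Singletons 0–3 plus "4+", for both
  cancelled (CNA) and unannounced (DNA) missed appointments.

**Wrangling.** Rows with any missing, unparseable or out-of-domain value
in a required column are dropped and tallied per column; a row failing on
several columns counts once in the drop total. `total_sessions` is always
recomputed as individual + group, dates are ISO-8601 calendar dates, and
per-client episode indices are assigned by ascending first date with ties
broken by last date then input order, so wrangling is deterministic.
Under-18 ages are flagged, not dropped (adult-service data occasionally
contain them). An episode whose last date precedes its first is treated
as unparseable history and dropped under `last_date`.

## Event logs

Each episode contributes one event per requested *aspect*. Stage ordering
is structural: pre-band events carry the first-session date, outcome
events (post band, change category, discharge) the last-session date, and
during-therapy aspects (session bins, session mix, CNA/DNA bins) a
synthetic date 5 days after the first session — attendance features are
not dated in episode tables, and a fixed small offset keeps them strictly
inside the episode for timestamp-based tooling. Episodes shorter than 5
days clamp the during date to the last date (warned) so within-case time
ordering always holds. When several during-aspects are combined, their
order is the user's aspect order, encoded in the activity-instance
identifier rather than implied by the shared timestamp. Activity label
text is configurable per aspect; defaults use the service vocabulary
("Pre - Severe", "8-15 total sessions", "4+ DNA", "Improvement
significant", "Goals achieved"). The session-mix aspect
(individual-only / group-only / mixed / no-sessions) is derived from the
two session counts.

Logs round-trip through a five-column CSV dialect and XES 2.0 (concept,
lifecycle and time extensions); the aspect sequence survives XES but not
CSV, so log equality is defined on events.

## Discovery

Trace variants are counted per distinct activity sequence and sorted by
descending count with a lexicographic tie-break (any cumulative-coverage
prefix is otherwise ambiguous at ties). Coverage filtering keeps the
minimal prefix whose cumulative case share reaches the threshold — whole
variants only, so achieved coverage can exceed the nominal figure and is
always reported alongside. The directly-follows graph is counted over the
included cases with start/end pseudo-nodes; flow conservation (node count
= inbound = outbound) is asserted on construction. Percentages are
rendered to one decimal place. A small epsilon (1e-12) absorbs float
rounding when cumulative shares are compared with thresholds.

## Conformance

Five declarative primitives per case — starts_with, ends_with, contains,
absent, and precedence (every occurrence of the consequent preceded
somewhere earlier by the antecedent) — plus comparison against an
expected transition set, which lists every observed off-map
directly-follows pair with its case count and the fraction of fully
on-map cases. The pipeline runs the expectation check of the full log
against each coverage-filtered map, quantifying what the displayed map
omits. Which rules to check is inherently service-specific; none are
built in as defaults.

## Statistics

Counts and scores in such services are bounded, skewed and overdispersed,
so group comparisons are rank-based: Kruskal–Wallis (tie-corrected H,
chi-squared approximation) across the six pre-therapy bands, pairwise
Wilcoxon rank-sum post hocs with Bonferroni correction (m = number of
pairs, capped at 1), Pearson chi-squared without continuity correction
for gender × band with Bonferroni-corrected pairwise column comparisons,
and Shapiro–Wilk normality screening. Wilcoxon p-values are computed by
exact enumeration when the combined sample is ≤ 20 without ties, and by
the normal approximation with continuity and tie corrections otherwise.
Descriptive summaries use the n−1 standard deviation and type-7
(linear-interpolation) quantiles; a single-episode band reports its SD as
undefined rather than erroring. Correlation is Pearson by default with
Spearman offered alongside (the published correlation's flavour is
unstated). All tests are two-sided at α = 0.05. Computations delegate to
scipy.stats.

## Synthetic generator

The generator emulates the joint structure the analysis relies on, not
any individual client:

* **Composition.** 2,766 clients with 1/2/3 episodes at probabilities
  0.942/0.056/0.002 (≈ 2,933 episodes); pre-band weights
  129/212/431/604/718/839 (healthy → severe); 60% female.
* **Counts.** Individual sessions, CNAs and DNAs are negative-binomial
  per band with method-of-moments parameters from the published per-band
  means/SDs (e.g. severe sessions 16.2 ± 13.8, CNA 2.0, DNA 2.2); SD ≤
  √mean falls back to Poisson. Count draws use a gamma–Poisson mixture.
* **Group sessions.** Zero-inflated: 3.1% of episodes are group-only and
  5.6% mixed; given any group attendance the count is 1 + NB with mean 9
  and SD 5, reproducing the published unconditional group-session means
  (~0.7–1.1) and attendance shares. Group-only episodes have their
  individual-session count set to zero and mixed episodes at least one,
  so the raw per-band session distribution is recovered exactly on the
  group-free (~91%) majority and within a small (< 0.7 session) bias on
  the severe-band mean overall.
* **Transitions.** Pre → post movement is specified on bands (the level
  at which transitions are reported), with ≥ 90% of mass within one band
  of the start, improvement dominating, and uniform within-band jitter
  for the post score.
* **Discharge.** Per-band outcome distributions with dropout rising from
  ~10% (healthy) to 27% (severe).
* **Correlation.** A Gaussian copula links the within-band pre-score
  position to the session-count quantile. The configured target (Pearson
  r = 0.2 between pre-score and total sessions) is mapped to the latent
  correlation by an affine rule r_latent = (target − 0.170)/0.221, whose
  constants were fitted once by simulation against the default
  configuration: the band-conditional session means alone induce r ≈
  0.17, and the copula supplies the remainder within bands.
* **Dates.** First dates uniform over 2007-09-01 – 2019-09-01; last date
  = first + (sessions − 1) × 7 days (weekly sessions assumed). Dates feed
  event ordering only, never statistics.
* **Ages.** Per-band normals truncated to [18, 89], rounded.

What it does **not** emulate: session-by-session score trajectories,
within-client dependence across repeat episodes, any discharge × change
joint structure beyond shared dependence on the pre-band, seasonal or
waiting-list date structure, and symptom-specific psychometrics. Passing
tests therefore demonstrate that the pipeline machinery is correct and
calibrated to the published margins — not that conclusions drawn from it
transfer to any real service.

**Fixtures.** `build_fixture` lays out exact compositions without
randomness: attribute patterns are resolved to concrete field values by
interval intersection (band × change-category constraints solved jointly,
midpoints taken so values sit away from classification boundaries), with
documented defaults for unspecified fields (moderate band, a 2-point
non-significant improvement, 10 individual sessions, zero missed
appointments, goals achieved, female, age 41, epoch date 2010-01-04).
Infeasible patterns (e.g. healthy → severe with significant improvement)
raise immediately.

## Pipeline

The report pipeline runs the default map set — pre→post band, pre→change
and pre→discharge at 90% coverage, pre→sessions→change at 95%,
pre→DNA→change at 90% and pre→CNA→change at 80% — and writes variant
tables, DOT/JSON maps, rare-pathway listings (share ≤ 1% by default),
off-map reports, band summaries, the test battery, repeat-use shares and
a manifest. Runs are fully deterministic for a fixed seed, including
byte-identical manifests. Stage failures re-raise tagged with the stage
name, leaving earlier outputs on disk.

## Problem sizes

Default generation produces ≈ 2,933 episodes and runs in well under a
second. The test suite uses one shared 20,000-client table for moment
recovery and locality checks, 2,000 simulations for type-I-error
calibration of the Kruskal–Wallis and chi-squared tests, and 20 default
replicates for the correlation calibration; the full suite completes in
about ten seconds on one CPU.

## Known limitations

* The generator's kernels (transitions, discharge) are calibrated to
  published margins; joint behaviour between features beyond the shared
  pre-band and the score–session copula is not modelled.
* Coverage filtering fixes the cumulative-case-share reading of
  "N% of episodes"; tools that select variants by rank percentile will
  keep a different set at the same nominal figure. The achieved coverage
  recorded with every map makes the two readings comparable.
* Conformance is rule-based only; alignment-based fitness/precision over
  Petri nets is out of scope, as are appointment-level logs (one event
  per attended session) and concurrency semantics.
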