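# Methods

## The screening problem

Longitudinal observational health data (claims, EHR) record, per person,
drug dispensings, condition occurrences and the span over which the person
is observed. Temporal pattern discovery (TPD) screens such data for adverse
drug reactions by asking, for every drug–condition pair, whether the event
rate shortly *after* first exposure to the drug exceeds what that pair's own
pre-exposure history predicts — a self-controlled design that absorbs
time-invariant confounding (sick people both take more drugs and have more
events), calibrated against the all-drugs background so that systematic
differences between calendar periods (enrolment ramp-up, seasonal coding)
do not masquerade as signals. The output is one summary statistic per pair
(ICΔ), a signal flag, and a diagnostic plot (the chronograph).

## Counting model

All time is measured in integer day offsets from the **index date**: a
person's first recorded exposure to a drug (`distinct` mode, the default).
In `all` mode every (person, drug, exposure-date) occurrence acts as its own
index unit; this trades the clean self-controlled anchor for a census of
exposure episodes and is retained for comparability. Windows are closed
integer intervals of offsets that never contain day 0: "1 to 30 days" means
offsets 1..30; the index day itself belongs to no window.

For each window *w* four counts are materialised:

| count | unit counted |
|---|---|
| `C(w)` | index units whose observation period overlaps *w* by ≥ 1 day |
| `CX(x,w)` | those of drug *x* |
| `CY(y,w)` | index units (any drug) with ≥ 1 occurrence of condition *y* in *w* |
| `CXY(x,y,w)` | drug-*x* units with ≥ 1 occurrence of *y* in *w* |

An index unit contributes at most once per window to `CY`/`CXY` — repeat
events of the same condition inside one window are not double counted. A
unit enters `C`/`CX` when its observation period *partially* overlaps the
window (census-style; a full-coverage requirement would be the stricter
alternative and can be emulated by shrinking windows). The `CY`/`C`
marginals pool over all drugs: the external comparator is the open
all-drugs cohort, which is cheap and appropriate for a first database scan,
at the cost of contamination when strong signals of other drugs share the
condition (see Limitations).

The production counter pre-aggregates the per-unit event offsets once and
slices them per window; `brute_force_counts` re-derives every cell by naive
per-person scanning and is kept as an independent oracle in the tests. The
drug-independent marginals `C`/`CY` can be cached and reused across
drug-specific queries (`skip_baseline`); the cache carries the counting
mode, the window set and a content fingerprint of the cohort, and any
mismatch raises an error rather than silently reusing stale counts.

## IC and ICΔ

The Information Component for an observed count `O` against an expected
count `E` is

    IC = log2((O + 0.5) / (E + 0.5)),

the log posterior mean of a Gamma(O + 0.5, rate E + 0.5) posterior for the
observed-to-expected ratio. The 0.5 shrinkage pulls small-count cells
towards IC = 0; the 95% credible interval (IC025, IC975) is the log2 of the
posterior's 2.5% / 97.5% quantiles. For O = E the point estimate is exactly
0; for O = E = 0 the posterior is a chi-square with 1 df, which the tests
use as an independent quantile oracle. Within a single window the expected
count is the marginal product `E = CX·CY/C`; a window with `C = 0` has an
*undefined* expectation (error), which is distinct from `E = 0`.

The temporal contrast compares a surveillance window *v* (after exposure)
with a control window *u* (before exposure). The expected surveillance
count rescales the observed control count by the cohort-size ratio and the
shift in the background event rate between the two periods:

    E* = CXY(u) · [CX(v)/CX(u)] · [(CY(v)/C(v)) / (CY(u)/C(u))]
    ICΔ = log2((CXY(v) + 0.5) / (E* + 0.5))

with credible bounds from the same Gamma posterior (shape `CXY(v)+0.5`,
rate `E*+0.5`). A pair is flagged when **ICΔ025 > 0**. If any of `CX(u)`,
`C(u)`, `C(v)`, `CY(u)` is zero the contrast is incalculable and the pair is
excluded, with its reason, from every downstream metric denominator —
treating such pairs as non-signals would silently inflate specificity.
`CX(v) = 0` is *not* incalculable: it makes `E* = 0` and, since
`CXY(v) ≤ CX(v)`, ICΔ = 0.

Four analytical settings ship as presets (control / surveillance, day
offsets): setting1 = −180..−1 / 1..30, setting2 = −180..−1 / 1..360,
setting3 = {−180..−1, −30..−1} / 1..30, setting4 = {−180..−1, −30..−1} /
1..360. With a simultaneous control period (settings 3 and 4) the ICΔ is
computed per candidate control window and the **lowest** retained — a
pair must beat its most adverse pre-exposure baseline, raising specificity
at some cost in sensitivity. The minimum is taken over the point estimate;
a `pick="lower"` switch minimises ICΔ025 instead for users who prefer the
decision statistic itself.

## Chronograph

The chronograph bins offsets into a uniform grid (default 30-day bins, 12
on each side of the index date, day 0 excluded; the monthly width follows
the framework's convention, and the span is a package default — pick any
`BinGrid`). The top tier plots per-bin IC with its credible ribbon, on a
y-axis symmetric around 0 so panels are comparable across pairs; the bottom
tier plots observed bars against the expected line on the absolute scale.
Bins with `C = 0` (offsets no one was observed at) are gaps, not zeros, in
both the plot and the CSV export, whose numeric fields round-trip at full
precision.

## Synthetic cohorts and what they do (and do not) emulate

The generator draws, per person: one observation period of fixed length;
per drug, an exposure with fixed probability at a date uniform over the
middle of the period, leaving `pre_margin_days` before and
`post_margin_days` after, so analytic windows inside the margins are fully
observed for every exposed person and closed-form expectations are exact
(infeasible margins are a configuration error, never silent truncation);
per condition, day-by-day independent Bernoulli events at a constant
background daily rate, at most one event per (person, condition, day). For
injected positive-control pairs the daily rate is multiplied by a rate
ratio on offsets inside the effect window after that person's exposure to
that drug — the affected day cells are *re-drawn* at the elevated rate, so
the elevation is exact. All other pairs are negative controls whose events
are independent of exposure timing by construction. An optional
`trend_break` scales every condition's rate by a common factor from a given
calendar day onward, exercising the ICΔ background calibration.

Defaults are desk-scale: 2000 persons, 10 drugs, 20 conditions, 720
observed days, exposure probability 0.3, baseline daily rate 0.001 (about
0.7 expected events per person-year per condition — an uncommon-but-codable
condition; rates, not realism of coding, are what the statistics consume).
The generator deliberately does not emulate claims-coding behaviour, visit
clustering, drug eras, censoring by death, or real pharmacology; passing
tests demonstrate that the statistical machinery is correct and
well-calibrated under its stated model, not that any particular real-world
pair would or would not signal.

The analytic oracle `expected_window_events` returns the expected number of
event-*days* in a relative window (n_persons × exposure_probability ×
Σ daily rate); note `CY`/`CXY` count units with *at least one* event, so
for long windows the unit-count expectation is smaller (1 − (1−p)^d per
unit, vs p·d event-days) — tests that compare the two use raw event
enumeration, not the count store.

## Evaluation harness

Labelled control pairs are scored with ICΔ under a setting; then

- **sensitivity** = flagged / calculable positives,
- **specificity** = unflagged / calculable negatives (false-positive rate =
  1 − specificity),
- **bias** = mean negative-control ICΔ (median and mean absolute value are
  reported alongside, as the location summary of a bias distribution is a
  convention choice),
- **AUC** = rank-based probability that a random positive's ICΔ exceeds a
  random negative's, ties counting ½ (Mann–Whitney; the point estimate, not
  ICΔ025, is the ranking score, since the threshold rule already consumes
  the interval — switchable).

Metrics with an empty denominator are undefined (NaN), never 0, and the
number of incalculable pairs is reported first-class.

## Numerical and design choices

- Dates are integer days since 1970-01-01 internally; parsing accepts
  ISO-8601 only. Observation intervals are closed; records on the boundary
  are kept. One observation period per person — if the source carries
  several, the longest is kept and the drop is logged — because every
  denominator assumes a single continuous observed span.
- The ICΔ expected count is the calibrated observed-to-expected rescaling
  given above, not a literal ratio of two IC values: a ratio of logs is
  scale-broken (division by an IC of 0) and would not adjust for
  between-period background shifts, which is the stated purpose of the
  external-cohort contrast.
- Credible intervals use the Gamma(O+0.5, E+0.5) posterior whose mean
  reproduces the point estimate exactly; under Poisson sampling its
  coverage of IC = 0 is conservative, increasingly so for small E (exact
  coverage ≈ 0.956 at E = 10, ≈ 0.983 at E = 2, ≈ 0.998 at E = 0.5). This
  is a property of the shrinkage, not a defect of the quantiles.
- No multiplicity correction: the scan is a screening tool and its
  operating characteristics are reported directly instead.
- Determinism: one `numpy` Generator seeded from the config drives the
  whole simulation; identical config + seed gives byte-identical tables.

Test and evaluation runs use smaller cohorts than the generator default
(200–1500 persons, 240–720 observed days) — sized so that every injected
pair carries well over 20 expected surveillance events and null checks have
~100 negative pairs, which is where the detector's behaviour stabilises.

## Known limitations

- The open all-drugs comparator is contaminated by strong signals of
  *other* drugs on the same condition: they raise `CY(v)/C(v)` and push
  negative-control ICΔ down (visible as negative bias in evaluation runs on
  heavily injected cohorts). Restricting the comparator to drugs of similar
  indication would address this at computational cost and is not
  implemented.
- The simultaneous-control minimum rule biases negative-control ICΔ
  downward (a minimum of noisy estimates), which is the intended
  specificity/sensitivity trade-off but makes "bias" summaries of settings
  3–4 systematically more negative.
- ICΔ flags temporal association only; it is not a risk estimate.
- `all` counting mode double-uses persons with repeat prescriptions in the
  marginals; it is provided for comparability, not recommended for
  inference.
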