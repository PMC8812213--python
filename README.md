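# tpdscan

Temporal pattern discovery (TPD) for drug-safety signal detection in
longitudinal observational health data.

Given OMOP-style tables of drug exposures, condition occurrences and
observation periods, `tpdscan` screens every drug–condition pair for a
temporal association between first exposure to the drug and subsequent
occurrence of the condition. It is aimed at pharmacovigilance and
pharmacoepidemiology analysts who need an open-ended first-pass database
scan with explicit operating characteristics, not a causal effect estimate.

## The statistic

All counting is anchored at each person's first exposure to a drug (day 0).
For a day-offset window *w* the engine stores the baseline count `C(w)`
(index units observed in *w*), the marginals `CX(x,w)` and `CY(y,w)`, and
the pair count `CXY(x,y,w)`. The Information Component of an observed count
O against an expected count E is the shrinkage-regularised log ratio

    IC = log2((O + 0.5) / (E + 0.5)),

with a 95% credible interval from the Gamma(O + 0.5, rate E + 0.5)
posterior whose mean is exactly the shrunk ratio. The temporal summary ICΔ
contrasts a post-exposure surveillance window *v* against a pre-exposure
control window *u*, with the expected count calibrated by the cohort-size
ratio and the all-drugs background rate shift between the periods:

    E*  = CXY(u) · [CX(v)/CX(u)] · [(CY(v)/C(v)) / (CY(u)/C(u))]
    ICΔ = log2((CXY(v) + 0.5) / (E* + 0.5))

A pair is flagged when the lower credible bound ICΔ025 exceeds 0. Four
analytical settings ship as presets (`setting1`..`setting4`), pairing the
−180..−1 day control period (alone or simultaneously with −30..−1, keeping
the lowest ICΔ) with 1..30 or 1..360 day surveillance. The chronograph —
per-bin IC with credible ribbon over observed-vs-expected bars — shows the
temporal pattern behind any flag. A built-in synthetic-cohort generator
with injected positive controls and an evaluation harness (sensitivity,
specificity, bias, AUC over labelled control pairs) quantify how the
detector behaves before it is pointed at real data. See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

```python
from tpdscan import (SimulationConfig, InjectedPair,
                     TemporalPatternDiscovery, simulate)

# synthetic cohort: 1000 persons, one true signal (drug 1 -> condition 101,
# rate ratio 10 in the 30 days after first exposure)
pairs = (InjectedPair(drug_id=1, condition_id=101, rate_ratio=10.0,
                      effect_start=1, effect_end=30),)
config = SimulationConfig(
    n_persons=1000, observation_days=720, n_drugs=4, n_conditions=6,
    exposure_probability=0.4, baseline_daily_rate=0.001,
    injected_pairs=pairs, seed=42,
    pre_margin_days=180, post_margin_days=360,
)
cohort, truth = simulate(config)

model = TemporalPatternDiscovery(cohort)          # distinct counting mode
res = model.fit(settings=["setting1", "setting2"])
print(res.summary())
```

```
Temporal Pattern Discovery Results
==================================================================
persons: 1000   counting mode: distinct
drug-condition pairs screened: 24   settings: setting1, setting2
signals (ICΔ025 > 0): 2   incalculable: 0
------------------------------------------------------------------
 setting  drug_id  condition_id  observed_v  expected_star  icdelta  icdelta025  icdelta975  signal
setting1        1           101          93         31.905    1.529       1.221       1.807    True
setting2        1           101         181        126.343    0.517       0.299       0.719    True
setting2        1           106         143        127.173    0.169      -0.078       0.395   False
...
```

The injected pair is the only signal: under setting1, 93 events were
observed in the 30 days after first exposure where the calibrated
pre-exposure contrast predicted ~31.9, an ICΔ of 1.53 (≈ 2.9-fold excess on
the log2 scale) with credible interval well above 0. Every non-injected
pair stays unflagged. Operating characteristics against the known labels:

```python
comp = res.evaluate(truth)
print(comp.table.to_string(index=False))
```

```
 setting  sensitivity  specificity  false_positive_rate      bias  auc  n_incalculable
setting1          1.0          1.0                  0.0 -0.161973  1.0               0
setting2          1.0          1.0                  0.0 -0.023111  1.0               0
```

`res.chronograph(1, 101, path="chronograph.png")` renders the two-tier
temporal profile for the flagged pair. The same pipeline is scriptable from
the shell (`tpdscan simulate | count | icdelta | chronograph | evaluate |
run-all`); `tpdscan run-all --config run.yaml --out runs/demo` writes the
cohort, counts, per-pair scores, metrics, bias plot, chronographs and a
provenance manifest in one deterministic pass.

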