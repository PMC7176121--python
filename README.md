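# prevalid

Deriving disease prevalence and diagnostic validity indices from each other
under outcome misclassification.

## The problem

Studies on electronic healthcare databases classify subjects as diseased or
non-diseased with a *case-finding algorithm* (CFA) — a rule over codes and
records, applied without seeing the patient. CFAs misclassify, so the
observed prevalence *P* (the fraction flagged positive) differs from the
true prevalence *π*. Validation studies quantify a CFA with four indices —
sensitivity (SE), specificity (SP), positive and negative predictive value
(PPV, NPV) — but most report only one or two of them, typically SE and PPV.

The six parameters are bound together by three identities:

```
P   = SE·π + (1 − SP)(1 − π)
PPV = SE·π / P
NPV = SP(1 − π) / (1 − P)
```

Hence knowing *P* (cheap: apply the CFA to the database) plus **any two** of
{π, SE, SP, PPV, NPV} determines the remaining three in closed form — ten
distinct solution sets in all. The {SE, SP} set contains the classical
Rogan–Gladen misclassification-corrected prevalence
π = (P + SP − 1)/(SE + SP − 1).

`prevalid` implements, for epidemiologists and pharmacoepidemiologists
validating CFAs:

- the six-parameter data model, forward equations and 2×2-count conversion
  (`prevalid.core`);
- all ten closed-form solution sets, interval sweeps, and the Rogan–Gladen
  estimator (`prevalid.solver`);
- the two validity-constraint regimes — derived parameters in [0, 1], and
  the stricter "better than chance" criterion SE + SP > 1 — plus label
  swapping to repair worse-than-chance classifiers (`prevalid.constraints`);
- Monte-Carlo uncertainty propagation: beta distributions fitted to
  reported means and 95% CIs by the method of moments, independent
  sampling with constraint-based rejection, 95% percentile uncertainty
  intervals under both regimes (`prevalid.uncertainty`);
- one-at-a-time sensitivity analysis of every solution set to ±1 standard
  error input perturbations (`prevalid.sensitivity`);
- synthetic 2×2 generators and two published validation case studies as
  golden fixtures (`prevalid.fixtures`).

## Worked example

A claims-based pneumonia CFA flagged 219 of 10,828 emergency-department
encounters (P = 2.02%); its validation reported PPV = 80.8% and NPV = 99.1%.

```python
from prevalid import solve
profile = solve(0.0202, {"ppv": 0.808, "npv": 0.991})
for name, value in profile.to_dict().items():
    print(f"{name:>4} = {100 * value:7.3f}%")
```

prints

```
  pi =   2.514%
   p =   2.020%
  se =  64.923%
  sp =  99.602%
 ppv =  80.800%
 npv =  99.100%
```

The misclassification-corrected prevalence is 2.51% — above the observed
2.02%, because at 65% sensitivity the CFA misses more true cases than it
falsely flags — and the derived SP (99.6%) matches the value the original
validation study reported. The same call with CIs attached
(`prevalid.propagate`) yields 95% uncertainty intervals by Monte-Carlo
sampling; see `examples/` for one short script per capability (derivation
and interval sweeps, 2×2 counts, uncertainty propagation, OAT sensitivity
analysis).

A thin CLI mirrors the library:

```bash
prevalid derive --p 0.0202 --ppv 0.808 --npv 0.991
prevalid uncertainty --p 0.0202 --ppv 0.808,0.751,0.855 --npv 0.991,0.989,0.993 --seed 1
prevalid sensitivity --pi 0.01,0.05,0.2 --se 0.75 --sp 0.99
```

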