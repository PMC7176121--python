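# Methods

## Model

A dichotomous disease status is assessed two ways on the same N subjects:
by an error-free reference ("gold standard") and by a case-finding
algorithm (CFA). The joint distribution is a 2×2 table (TP, FP, FN, TN),
and six linked parameters summarise it: true prevalence π = (TP+FN)/N,
observed prevalence P = (TP+FP)/N, SE = TP/(TP+FN), SP = TN/(FP+TN),
PPV = TP/(TP+FP), NPV = TN/(FN+TN). Writing the table in terms of the
parameters gives the forward system

    P   = SE·π + (1−SP)(1−π)
    PPV = SE·π / P
    NPV = SP·(1−π) / (1−P)

Two assumptions carry over from the 2×2 representation: disease status is
truly dichotomous, and the gold standard is error-free. The algebra
applies to prevalences and incidence *proportions*, not incidence rates,
and to non-differential misclassification only.

### Solution sets

Given P and any two of {π, SE, SP, PPV, NPV} — ten unordered pairs — the
other three parameters have closed-form rational expressions, implemented
row by row in `solver.py` with an explicit denominator guard each, rather
than re-derived symbolically at run time. This keeps degenerate inputs
(SE + SP = 1 for the {SE, SP} pair, π = 0 for {π, PPV}, …) as precise,
named errors. The {SE, SP} row's π is the Rogan–Gladen estimator. Every
expression is held as a (numerator, denominator) pair so the constraint
module can reason about signs without dividing.

One derivation note: for the {π, NPV} pair the SE and PPV expressions share
the numerator π − (1−P)(1−NPV); the implementation uses this form, which is
the one consistent with the forward system (verified by the ten-combo
round-trip test at 1e−9 over 10⁴ random triples — worst observed deviation
≈ 1e−11).

### Undefined conditionals

PPV is a probability conditional on P > 0 and NPV on P < 1; at the
boundary they are 0/0. The profile container keeps them as an explicit
`None` rather than coercing to 0 or 1, and consistency checking uses the
cross-multiplied identities PPV·P = SE·π and NPV·(1−P) = SP·(1−π), which
hold by convention in the undefined cases.

## Constraints

Derived parameters must be probabilities. For each solution set the [0,1]
requirement on a derived quotient N/D is evaluated as N·D ≥ 0 and
(D−N)·D ≥ 0 — sign-safe products that avoid both division and case
analysis on the sign of D. The correctness contract is semantic, not
symbolic: *valid ⇔ every non-strictly solved parameter lies in [0, 1]*,
and the test suite enforces that equivalence against the direct evaluation
on a 40×40×40 input grid per solution set (64,000 points × 10 sets).

The better-than-chance regime adds SE + SP > 1 (the CFA selects diseased
subjects with higher probability than non-diseased ones) on the implied
profile, evaluated strictly: equality is an uninformative classifier and is
rejected. Range bounds, by contrast, are closed ([0,1] admitted, with a
1e−12 boundary tolerance for round-off). Better-than-chance validity is a
strict subset of range validity. A worse-than-chance CFA is repaired by
relabelling its outputs (P′=1−P, SE′=1−SE, SP′=1−SP, PPV′=1−NPV,
NPV′=1−PPV, π unchanged), an involution implemented in `swap_labels`.

## Uncertainty propagation

Inputs given with a 95% CI get a beta distribution by method of moments:
the mean is used as-is and sd = (CI upper − CI lower)/(2·1.96), i.e. the
CI is read as a symmetric normal-approximation interval — the standard
reading when only a mean and CI are published. Then α = m·k,
β = (1−m)·k with k = m(1−m)/v − 1; the fit is infeasible when
v ≥ m(1−m). Inputs without a CI (or a zero-width one) are fixed constants.
Optionally P can instead be drawn from the Jeffreys posterior
Beta(positives+½, total−positives+½) when raw counts are available;
fixed-P is the default.

Draws are independent across parameters (their correlations are unknown in
practice); each draw is solved non-strictly and rejected if it violates
the active constraint regime. Both regimes are evaluated on one draw
stream, so the two 95% percentile UIs (numpy linear-interpolation
percentiles, 2.5/97.5) and both rejection percentages come from a single
pass and a single seed. Results are bit-reproducible by seed; defaults are
100,000 draws, with a warning flag below 100 accepted draws and an error
at zero.

Published check: for the intussusception study the package yields a 95% UI
for π of about (0.032–0.040)% at 10⁵ draws versus the printed
(0.034–0.038)%. The original MC configuration (sample count, whether P was
sampled, exact moment formulas) is not fully specified, so the tests treat
the printed UI as a soft band (point estimate inside the UI, comparable
width), not a hard target.

## One-at-a-time sensitivity analysis

For each solution set, each of the three inputs is moved to value ± 1 s.e.
(the others at baseline) and the set is re-solved under the less
restrictive range constraints. Standard errors are binomial,
√(v(1−v)/n), at a nominal validation sample size n = 1000 by default.
Biases of the derived parameters are reported in units of their own
binomial s.e. at the derived baseline value with the same n — the
symmetric convention, adopted because no other scale for the derived
parameters is available — and truncated at ±3 s.e. in the report while the
untruncated value is retained. Baseline derived values are computed
through the same solution-set expressions as the perturbed runs, so a
zero-width perturbation yields exactly zero bias; where a set's
denominator vanishes at the baseline itself (perfect-test corners) the
forward-model values stand in. Perturbed inputs leaving [0,1] are clipped
and flagged; perturbed triples violating the range constraints are kept as
flagged invalid rows rather than dropped.

The scenario suite runs baselines π ∈ {0.01, 0.05, 0.2} with SE = 0.75,
SP = 0.99 by default and ranks the ten sets by worst-case |bias| (ties by
mean |bias|) over all scenarios, inputs, directions and derived
parameters. Under these conditions the {SE, PPV} set is the most robust on
both summaries — practically convenient, since SE and PPV are the two most
commonly reported indices. Note the baseline matters: the companion
perturbation-figure baseline SE = 0.95, SP = 0.75 produces the ~2 s.e. PPV
excursion exercised in the tests, while the SE = 0.75, SP = 0.99 baselines
produce the printed P/PPV/NPV triples; both are covered, as they probe
different corners of the maps.

Two numerical caveats surfaced by the tests and kept in them: the
{SP, PPV} set's SE expression has denominator (1−SP) − P(1−PPV), which is
≈ 5e−4 at the SP = 0.99 baselines, so that map is locally ill-conditioned —
its first-order properties (antisymmetry of ±1 s.e. biases, linear scaling
in the step) hold only once the step is small (n ≳ 10⁶), while all other
sets show them already at n = 1000–10⁶.

## Synthetic data and golden cases

`expected_counts` inverts the 2×2 parameterisation into exact (real-valued)
expected cells n·π·SE etc.; when integral they convert to a count table and
round-trip the generating triple exactly. `sample_counts` draws the four
cells jointly from one multinomial (equivalent in distribution to nested
binomials, single-seed simpler). These generators emulate only the
summary-level 2×2 world of CFA validation — no record-level covariates, no
differential misclassification, no gold-standard error — so passing tests
demonstrate the algebra and its uncertainty machinery, not robustness to
violations of the 2×2 assumptions.

The two packaged golden cases carry the published numbers of an
intussusception CFA validation (N = 417,997; 185 CFA-positives; 150 gold
cases; SE 89.3% (83.3–93.8); PPV 72.4% (65.4–78.7)) and a pneumonia CFA
validation (N = 10,828; 219 CFA-positives; 272 gold cases; SE 65.1%
(59.2–70.5); SP 99.6% (99.5–99.7); PPV 80.8% (75.1–85.5); NPV 99.1%
(98.9–99.3)). Expected values are stored as printed strings at their
original precision and compared with a rounding-aware comparator
(`rounds_to`): the sources themselves chain rounded numbers (e.g. the
derived SE of 88.5% only arises from the rounded prevalences 0.044% and
0.036%), so string-precision comparison is the faithful contract. One
looseness is inherent: from the rounded pneumonia inputs the derived SE is
64.9% against a reported 65.1%; the tests assert agreement within the
reported CI, the strongest claim the rounded inputs support.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| `solve(strict=)` | `True` | out-of-range derived values are an input error unless explicitly tolerated |
| boundary tolerance | 1e−12 | pure double round-off; far below any epidemiological signal |
| consistency tol | 1e−9 | round-trip accuracy achievable by the rational expressions away from degeneracies |
| MC draws | 100,000 | percentile noise ≪ reporting precision; seconds on one core |
| MC seed | required when sampling | no silent default; bit-reproducibility is part of the contract |
| OAT `n_se` | 1000 | nominal validation-study size behind the ±1 s.e. perturbations |
| OAT truncation | ±3 s.e. | report cap only; raw biases retained |
| interval sweep `n_grid` | 101 | endpoints always included; expressions are monotone per argument so endpoints carry the extrema |

## Limitations

- The algebra propagates, and can amplify, input error: near-degenerate
  denominators (SE+SP ≈ 1; the {SP, PPV} set at high SP) make derived
  parameters extremely sensitive — the OAT module exists to quantify
  exactly this.
- Only non-differential misclassification of a dichotomous status with an
  error-free gold standard is modelled; no risk/odds-ratio adjustment, no
  incidence rates.
- MC sampling is independent across inputs by design; when the inputs'
  true sampling correlation is strong, the UIs are conservative and the
  rejection percentages overstate incompatibility.
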