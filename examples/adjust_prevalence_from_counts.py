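"""Misclassification-corrected prevalence from a 2x2 validation table.

A validation study cross-tabulates the classifier against a gold standard;
the six linked parameters follow directly from the counts, and the
Rogan-Gladen estimator recovers the true prevalence from the observed one
once SE and SP are known.
"""

from prevalid import ConfusionTable, profile_from_counts, rogan_gladen

table = ConfusionTable(tp=80, fp=90, fn=20, tn=810)
profile = profile_from_counts(table)
print(f"2x2 table (N = {table.n}): {table.to_dict()}")
for name, value in profile.to_dict().items():
    print(f"  {name:>4} = {value:.4f}")
print(
    "Observed prevalence 0.17 overstates the true 0.10 because the 10%"
    " false-positive rate acts on the large non-diseased majority.\n"
)

pi_hat = rogan_gladen(p=profile.p, se=profile.se, sp=profile.sp)
print(f"Rogan-Gladen corrected prevalence: {pi_hat:.4f}")
print("Identical to the true prevalence computed from the counts above.")
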