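"""Derive the missing validity indices from P plus two known parameters.

A claims-based pneumonia case-finding algorithm flagged 2.02% of
emergency-department encounters, and its validation study reported
PPV = 80.8% and NPV = 99.1%.  From those three numbers alone the true
prevalence, sensitivity and specificity follow in closed form; sweeping
the true prevalence over a plausible interval instead gives ranges.
"""

from prevalid import derive_over_interval, solve

profile = solve(0.0202, {"ppv": 0.808, "npv": 0.991})
print("From P = 2.02%, PPV = 80.8%, NPV = 99.1%:")
for name, value in profile.to_dict().items():
    print(f"  {name:>4} = {100 * value:7.3f}%")
print(
    "The true prevalence (pi = 2.51%) exceeds the observed 2.02%: the"
    " algorithm misses more cases (imperfect SE) than it falsely flags.\n"
)

sweep = derive_over_interval(0.0202, ("ppv", 0.808), "pi", (0.02, 0.03))
print("Holding P and PPV fixed, with pi anywhere in [2.00%, 3.00%]:")
for name, (lo, hi) in sweep.ranges.items():
    print(f"  {name:>4} in [{100 * lo:6.2f}%, {100 * hi:6.2f}%]")
print(
    "SE is the parameter most affected by uncertainty about the true"
    " prevalence; SP barely moves."
)
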