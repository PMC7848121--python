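"""Proportion confidence intervals for report-level summary cells.

Given counts of reports with a feature (k of n), the Wilson score interval
gives a 95% CI that stays inside [0, 100]% and behaves well at small k —
the right tool for cells like "fatal reports: 17 of 381".
"""

from ddiscreen import mean_ci, round_pct, wilson_ci

print("share of a 2,195-report analysis set that is 381 reports:",
      round_pct(381 / 2195), "%")

for label, k, n in [("fatal", 17, 381), ("male", 179, 381),
                    ("physician-reported", 345, 381)]:
    ci = wilson_ci(k, n, 0.95)
    print(f"{label}: {k}/{n} -> {ci}")

ages = [81, 74, 69, 88, 77, 72, 90, 66, 79, 84]
print("age:", mean_ci(ages, 0.95))

# Each proportion line prints "point (low-high)" in percent: the point
# estimate and the 95% Wilson bounds; the age line is a t interval in years.
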