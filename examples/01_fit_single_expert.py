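"""Fit the eight candidate families to one expert's quartile judgment.

An expert believes the proportion of male patients is most plausibly 0.56,
with quartiles 0.50/0.62 and plausible limits 0.30/0.80. We standardize
the judgment (limits become the 1% and 99% quantiles), fit every candidate
family by least squares on the quantiles, and print each family's SSE —
the best fit is the family whose quantile function tracks the judgment
most closely.
"""

from elicitbn import (FAMILY_ORDER, NodeDescriptor, QuartileJudgment,
                      fit_best, fit_family, format_params,
                      standardize_intervals)
from elicitbn.errors import NoFitError

judgment = QuartileJudgment("E1", "gender", 0.30, 0.50, 0.56, 0.62, 0.80)
node = NodeDescriptor("gender", "proportion")
assessment = standardize_intervals(judgment, node, tail_probability=0.01)

print("family                 SSE        fitted parameters")
for family in FAMILY_ORDER:
    try:
        fit = fit_family(assessment, family)
    except NoFitError:
        continue
    print(f"{family.value:22s} {fit.sse:10.3g} {format_params(fit.params)}")

best = fit_best(assessment)
print(f"\nbest fit: {format_params(best.params)} (SSE {best.sse:.3g})")
print("lower SSE = the family's quantiles sit closer to the expert's five "
      "elicited values")
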