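"""The standardized treatment effect for binary endpoints.

Two event proportions (p_I, p_C) collapse into a single parameter
lambda = (p_I - p_C)/sqrt(pbar(1-pbar)) that fully indexes the law of the
normal-approximation test statistic: Z ~ N(lambda*sqrt(n/2), 1-lambda^2/4).
"""

import condscore as cs

# a 12-point improvement over a 30% control rate
lam = cs.lambda_from_proportions(0.42, 0.30)
print(f"p_I=0.42 vs p_C=0.30  ->  lambda = {lam:.3f}")

# and back: which effect does lambda=0.25 mean at other control rates?
for pc in (0.1, 0.3, 0.5):
    d = cs.effect_from_lambda(0.25, pc)
    print(f"lambda=0.25 at p_C={pc}: effect p_I - p_C = {d:.3f}")

# the law of the test statistic at lambda=0.3, n=50 per group
mean, var = cs.asymptotic_z_law(0.3, 50)
print(f"Z law at lambda=0.3, n=50: mean {mean:.3f}, variance {var:.4f}")
print("The variance deficit lambda^2/4 is what distinguishes the binary-")
print("endpoint statistic from the unit-variance normal-endpoint case.")
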