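"""The five recalculation rules at one interim result.

Mid-trial the observed standardized effect lam_hat = Z1/sqrt(n1/2) drives
the choice of the per-group stage-2 size n2 (capped at n_max - n1 = 150).
"""

import numpy as np

import condscore as cs

design = cs.DesignSpec(n1=50, n_max=200)
z1 = 1.2
lam_hat = z1 / np.sqrt(design.n1 / 2.0)
print(f"interim: Z1 = {z1}, observed effect lam_hat = {lam_hat:.3f}")
cp50 = cs.observed_conditional_power(z1, lam_hat, 50, design)
print(f"observed conditional power of just running 50 more: {cp50:.3f}\n")

for kind in cs.RULE_KINDS:
    rule = cs.RuleSpec(kind, n_ini=50, gamma=0.005 / 4.0)
    n2, stopped = cs.recalculate([z1], [lam_hat], design, rule)
    if stopped[0]:
        print(f"{kind:10s}: stop for futility (target CP unattainable)")
        continue
    cp = cs.observed_conditional_power(z1, lam_hat, int(n2[0]), design)
    print(f"{kind:10s}: n2 = {int(n2[0]):3d}  ->  observed CP = {cp:.3f}")

print(
    "\nOCP chases conditional power 0.8 and hits the cap; the promising-zone"
    "\nrule only does so when the interim result is 'promising'; the"
    "\noptimization rule trades each extra patient against gamma = 0.00125."
)
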