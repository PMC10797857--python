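"""Two-stage design boundaries: Pocock local levels and interim zones.

The design rejects at the interim if Z1 >= q_{1-alpha1}, stops (binding)
for futility if Z1 < q_{1-alpha0}, and otherwise enters the recalculation
area.  The common local level alpha1 = alpha12 is solved so the global
one-sided level is maintained under the joint law of (Z1, Z_{1+2}).
"""

from scipy import stats

import condscore as cs

design = cs.DesignSpec(n1=50, n_max=200)  # alpha=0.025, alpha0=0.5 defaults
print(f"local levels  alpha1 = alpha12 = {design.alpha1:.4f}")
print(f"efficacy boundary   q = {design.efficacy_bound:.3f}")
print(f"futility boundary   q = {design.futility_bound:.3f}")

for z1 in (-0.5, 1.2, 2.5):
    print(f"Z1 = {z1:+.1f}  ->  {cs.classify_interim(z1, design)}")

# the combination test behind the final analysis
z12 = cs.combine_inverse_normal(1.0, 2.0, design.w1, design.w2)
print(f"stage statistics (1.0, 2.0) combine to Z12 = {z12:.4f}")
print(f"reject at stage two iff Z12 >= {design.final_bound:.3f}")
print(f"(local level check: q_{{1-alpha1}} -> {stats.norm.ppf(1-design.alpha1):.3f})")
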