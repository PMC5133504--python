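"""Gene-environment scan on SBP with co-dominant adjustment.

Age is cut into balanced tertiles and used as a discrete environmental
factor; a SNP whose high-risk genotype differs per age band is planted
on SBP.  The co-dominant adjustment removes each pair's main effects
before Steps 1-3, so only the non-additive pattern drives the hit.
"""

import numpy as np

from epistakit import (PenetranceModel, PermutationPlan, SimConfig, Trait,
                       categorize_age, scan_gxe, scan_main_effects,
                       compare_scans, simulate_blood_pressure_cohort)

table = 8.0 * np.eye(3)  # +8 mmHg when genotype index matches age band
cfg = SimConfig(n_samples=1500, n_snps=15, seed=41, maf_range=(0.3, 0.5))
g, pheno = simulate_blood_pressure_cohort(cfg, models_sbp=[PenetranceModel((2, "env"), table)])

sbp = Trait("sbp", "continuous", pheno.column("sbp"))
age3 = categorize_age(pheno, n_groups=3)

gxe = scan_gxe(g, sbp, age3, PermutationPlan(B=500, seed=42), adjust=True)
print(gxe.to_dataframe().nsmallest(3, "p_adjusted").to_string(index=False))

main = scan_main_effects(g, sbp, PermutationPlan(B=500, seed=43))
overlap = compare_scans(main, gxe, alpha=0.05)
print("\ninteraction hits also significant as main effects:")
print(overlap.to_string(index=False) if len(overlap) else "  (none)")

# snp00002 x age is recovered despite carrying no average effect in any
# genotype; compare_scans confirms the hit is not driven by a main effect.
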