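"""Simulate a blood-pressure cohort and inspect its structure.

Builds a genotype panel with an LD block, low-MAF SNPs, HWE-violating
SNPs and a related sample pair, plus an age/sex/SBP/DBP/medication
phenotype table, then derives binary hypertension status.
"""

import numpy as np

from epistakit import (SimConfig, simulate_blood_pressure_cohort,
                       derive_hypertension, categorize_age, maf)

cfg = SimConfig(n_samples=1800, n_snps=150, seed=7,
                maf_range=(0.01, 0.5), ld_blocks=[(5, 0.9)],
                hwe_violation_snps=3, related_pairs=(2, 0.5),
                missing_rate=0.0)
genotypes, phenotypes = simulate_blood_pressure_cohort(cfg)

hs = derive_hypertension(phenotypes)
age3 = categorize_age(phenotypes, n_groups=3)
freqs = maf(genotypes)

print(f"cohort: {genotypes.n_samples} samples x {genotypes.n_snps} SNPs")
print(f"hypertension cases: {int(np.nansum(hs.values))} "
      f"({100 * np.nanmean(hs.values):.1f}% prevalence)")
print(f"age tertile sizes: {np.bincount(age3.values.astype(int))}")
print(f"MAF range observed: {freqs.min():.3f} - {freqs.max():.3f}")

# The case count reflects the SBP>140 & DBP>90 | medication definition;
# balanced tertiles make age usable as a discrete environmental factor.
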