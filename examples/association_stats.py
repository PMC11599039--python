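"""Association statistics on the published allele-count tables.

Recomputes, from the printed counts alone: the two-sided Fisher exact tests
for three Gaucher-pathogenic variants in an MSA case series vs population
controls, the Mantel-Haenszel common-effects meta-analysis of the p.L483P
analogue across two independent series, its heterogeneity statistics, and
the per-group allele counts needed to power the single-series comparison.
"""

import paraclone as pc

r = pc.replicate_association_analysis()

print("Fisher's exact test (two-sided):")
for name, p in r["fisher_p"].items():
    print(f"  {name:24s} p = {p:.4f}")

m = r["meta"]
print("\nMantel-Haenszel common-effects meta-analysis (p.L483P analogue):")
print(f"  OR = {m.or_mh:.2f}  95% CI ({m.ci_low:.2f}, {m.ci_high:.2f})  p = {m.p_z:.4f}")
print(f"  heterogeneity: Q = {m.q:.3f}, p = {m.p_q:.2f}, I2 = {m.i2_pct:.0f}%, tau2 = {m.tau2_dl:.0f}")
print("\nForest-plot table:")
print(pc.forest_table(m).round(3).to_string(index=False))

print("\nTwo-proportion sample size for AF 0.0030 vs 0.0011 (alpha 0.05, power 0.8):")
print(f"  normal approximation : {r['n_uncorrected']} alleles per group")
print(f"  continuity corrected : {r['n_continuity']} alleles per group")

print("""
The pooled odds ratio of ~2.85 with a CI excluding 1 is what the two
underpowered series (p ~ 0.12 and ~0.22 alone) support jointly; with zero
between-study variability the common-effects model is the appropriate
pooling. The ~9-10k alleles per group explain why a single ~500-case series
cannot reach significance for an allele at these frequencies.""")
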