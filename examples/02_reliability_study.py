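"""Between-platform reliability of radiomic features, with and without
settings harmonisation.

Extracts the panel from a small phantom cohort under the four platform
default profiles and under three profiles sharing the harmonised settings,
then computes the two-way absolute-agreement ICC per feature.  The contrast
is the point: harmonising the calculation settings is what makes features
interchangeable between platforms.
"""

from radharm import builtin_profile, extract, generate_phantom_cohort, reliability_study
from radharm.pipeline import category_counts

volumes, _ = generate_phantom_cohort(12, seed=5)

defaults = [builtin_profile(p) for p in
            ("lifex_default", "ibex_default", "pyradiomics_default", "cerr_default")]
base = builtin_profile("harmonised")
harmonised = [base, base.perturbed(name="harm_b"), base.perturbed(name="harm_c")]

table = extract(volumes, defaults + harmonised)

for label, raters in [("default settings", defaults), ("harmonised settings", harmonised)]:
    icc = reliability_study(table, [p.name for p in raters])
    print(f"\n{label} ({len(raters)} profiles): {category_counts(icc)}")
    worst = icc.nsmallest(3, "estimate")[["feature", "estimate", "ci_low", "category"]]
    print(worst.to_string(index=False))

# category counts always total 17; under heterogeneous defaults the
# discretisation-dependent texture features drop to poor while shape and raw
# intensity features remain excellent.
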