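"""Full cohort pipeline on a synthetic three-group study.

Generates a cohort emulating the observational design (euthyroid controls,
LT4-treated patients with a steeper gradient, and a two-visit longitudinal
follow-up group), then runs the range filter, the between-group comparison
and the longitudinal gradient-versus-function correlation.
"""

from mimelog import (
    CohortConfig,
    filter_cross_sectional,
    generate_synthetic_cohort,
    group_comparison,
    phi_vs_function,
    select_longitudinal,
)

records, truth = generate_synthetic_cohort(CohortConfig(), seed=1)
print(f"generated {records['patient_id'].nunique()} patients, {len(records)} records")

filtered = filter_cross_sectional(records)
print(f"range filter kept {len(filtered.records)} records; "
      f"exclusions: {filtered.exclusion_counts}")

control = filtered.records[filtered.records["group"] == "control"]
treated = filtered.records[filtered.records["group"] == "treated_benign"]
report = group_comparison(control, treated)
slopes = report["tsh_ft4"]["slopes"]
print(f"ln(TSH)~FT4 slopes: control {slopes['control']:.3f}, "
      f"treated {slopes['treated']:.3f} "
      f"(contrast p = {report['tsh_ft4']['slope_contrast_p']:.3g})")
tau_dose = report["spina_gd"]["treated"]["tau_gd_dose_per_kg"]
print(f"G_D vs weight-adjusted LT4 dose (treated): tau = {tau_dose['tau']:.2f}, "
      f"p = {tau_dose['p']:.2g}")

longitudinal = records[records["group"] == "carcinoma_longitudinal"]
selections, exclusions = select_longitudinal(longitudinal)
print(f"\nlongitudinal selection: {len(selections)} qualifying patients; "
      f"excluded {exclusions['reason'].value_counts().to_dict()}")
result = phi_vs_function(selections)
t = result["tau_phi_ft4"]
print(f"phi vs mean FT4: tau = {t['tau']:.2f}, p = {t['p']:.2g} (n = {t['n']})")
print(
    "\nThe negative tau recovers the constructed linkage: the feedback\n"
    "gradient steepens toward the hypothyroid (low-FT4) range."
)
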