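"""Map trial outcomes reported as BMI, BMI percentile or prevalence onto zBMI.

Builds three arm summaries on different scales and runs each through the
matching mapper. The printed mean zBMI values are what would enter the
meta-regression dataset for trials that did not report zBMI directly.
"""

from metareg import (
    ArmSummary,
    bmi_to_zbmi_sampling,
    percentile_to_zbmi_analytic,
    prevalence_to_zbmi,
    synthetic_reference,
)

ref = synthetic_reference()  # bundled smooth LMS table (not a population chart)

# 1. Unstandardised BMI: Monte-Carlo cohort through the LMS transform.
bmi_arm = ArmSummary(scale="bmi", mean=19.8, sd=3.1, n=240,
                     age_mean=10.2, age_sd=0.9, prop_male=0.52)
res = bmi_to_zbmi_sampling(bmi_arm, ref, n_samples=10_000, seed=1)
print(f"BMI 19.8 (SD 3.1)        -> mean zBMI {res.mean_zbmi:+.3f} "
      f"(MC SE {res.mc_se:.4f}, {res.method})")

# 2. BMI percentile: exact analytic inversion of the percentile moments.
pct_arm = ArmSummary(scale="percentile", mean=63.8, sd=27.4)
res = percentile_to_zbmi_analytic(pct_arm)
print(f"percentile 63.8 (SD 27.4) -> mean zBMI {res.mean_zbmi:+.3f} "
      f"(sigma {res.sd_zbmi:.3f}, {res.method})")

# 3. Prevalence above the overweight/obesity thresholds: normal-tail solve.
prev_arm = ArmSummary(scale="prevalence",
                      proportions={1.036: 0.24, 1.645: 0.10})
res = prevalence_to_zbmi(prev_arm)
print(f"prev 24%/10% above z=1.04/1.64 -> mean zBMI {res.mean_zbmi:+.3f} "
      f"(sigma {res.sd_zbmi:.3f}, {res.method})")

# A mean zBMI near 0 means the arm sits at the reference median; positive
# values indicate heavier-than-reference cohorts. Differences in these means
# (intervention minus control, follow-up minus baseline) are the model's
# observations.
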