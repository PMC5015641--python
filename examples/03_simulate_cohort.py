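"""Generate the default synthetic two-centre cohort and tabulate prevalence.

The default configuration emulates a general-population sample: strata
of 633 and 695 subjects (45.0 % male), ages 21-74, with healthy lung
indices standard normal under the truth model plus a 5 % obstructive
subpopulation.  Prevalence of each spirometric pattern is tabulated at
the 2.5th-percentile LLN.
"""

from spiroref import (
    CohortConfig,
    StratumSpec,
    generate_cohort,
    generate_fixture_equation_set,
    interpret_cohort,
    prevalence,
)

truth = generate_fixture_equation_set(seed=1, family="lms")
config = CohortConfig(
    seed=7,
    disease_components=[{"type": "obstructive", "prevalence": 0.05,
                         "z_shift_mean": -3.0, "z_shift_sd": 0.5}],
)
cohort, labels = generate_cohort(config, truth)
print(f"cohort: n={len(cohort)}, "
      f"male share={100 * (cohort.sex == 'male').mean():.1f}%, "
      f"{len(labels)} subjects carry injected obstruction")

interp = interpret_cohort(cohort, truth)  # 2.5th percentile, convention z=-2
strata = StratumSpec(age_bins=((21, 65),))
for pattern in ("obstruction", "possible_restriction", "decreased_vc"):
    table = prevalence(interp, pattern, strata)
    row = table[(table.sex == "all") & (table.age_stratum == "all")]
    print(f"{pattern:22s} {row['prevalence'].item():5.1f} % "
          f"({row['count'].item()}/{row['n'].item()})")
print()
print("Healthy subjects sit below the z=-2 limit ~2.3% of the time by")
print("construction; the obstruction excess over that reflects the")
print("injected diseased subpopulation.")
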