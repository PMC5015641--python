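"""Pattern classification and severity grading at configurable LLNs.

Classifies one obstructed subject under both LLN percentiles in common
use (2.5th for screening, 5th for clinical evaluation) and shows the two
severity scales: z-score bands for LMS-family models, and classical
percent-of-predicted bands for linear-SD models.
"""

from spiroref import (
    LLNPolicy,
    SpirometryMeasurement,
    Subject,
    classify_pattern,
    generate_fixture_equation_set,
    grade_severity_viljanen,
    grade_severity_z,
    predict_index,
)

truth = generate_fixture_equation_set(seed=1, family="lms")
subject = Subject(id="demo", sex="female", age=62.0, height=161.0)
# airflow limitation: low FEV1, relatively preserved FVC
measurement = SpirometryMeasurement(fev1=1.45, fvc=2.85)

for policy in (LLNPolicy(2.5, "convention"), LLNPolicy(5, "convention")):
    results = {index: predict_index(truth, subject, measurement, index,
                                    policy.percentile, policy.z_limit)
               for index in ("fev1", "fvc", "ratio")}
    call = classify_pattern(results["fev1"], results["fvc"],
                            results["ratio"], policy)
    grade = grade_severity_z(results["fev1"].z, policy)
    print(f"LLN policy: {policy.percentile}th percentile "
          f"(z-limit {policy.z_limit})")
    print(f"  z(FEV1)={results['fev1'].z:+.2f}  "
          f"z(FVC)={results['fvc'].z:+.2f}  "
          f"z(ratio)={results['ratio'].z:+.2f}")
    print(f"  obstruction={call.obstruction}  "
          f"possible_restriction={call.possible_restriction}  "
          f"decreased_vc={call.decreased_vc}")
    print(f"  severity of reduced FEV1 (z scheme): {grade}")
print()
pct = 100 * measurement.fev1 / 2.60  # against some classical prediction
print(f"classical scale at {pct:.0f}% predicted: "
      f"published={grade_severity_viljanen(pct, 'published')}, "
      f"harmonized={grade_severity_viljanen(pct, 'harmonized')}")
print()
print("Tightening the LLN from the 5th to the 2.5th percentile can only")
print("remove abnormal flags, never add them.")
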