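"""Evaluate a reference model for one subject.

Builds a fixture LMS reference set (the same model family as modern
all-age spirometry references), evaluates a 48-year-old man's FEV1
against it, and prints the predicted median, z-score, percent predicted,
percentile and the 2.5th-percentile lower limit of normal (LLN).
"""

from spiroref import (
    SpirometryMeasurement,
    Subject,
    generate_fixture_equation_set,
    predict_index,
)

truth = generate_fixture_equation_set(seed=1, family="lms")
subject = Subject(id="demo", sex="male", age=48.0, height=176.5)
measurement = SpirometryMeasurement(fev1=3.2, fvc=4.9)

result = predict_index(truth, subject, measurement, "fev1",
                       lln_percentile=2.5)

print(f"measured FEV1          {measurement.fev1:.2f} L")
print(f"predicted median       {result.predicted:.2f} L")
print(f"z-score                {result.z:+.2f}")
print(f"percent predicted      {result.percent_predicted:.1f} %")
print(f"percentile             {result.percentile:.1f}")
print(f"LLN (2.5th centile)    {result.lln:.2f} L")
print(f"extrapolated           {result.extrapolated}")
print()
print("The z-score counts skew-adjusted SDs from the predicted median;")
print("a value below the LLN (z < -1.96 at the 2.5th centile) would be")
print("called abnormally reduced under the screening policy.")
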