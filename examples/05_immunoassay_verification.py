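"""Process a synthetic immunoassay run end to end.

Simulates plates for a 100-vs-25 verification cohort with planted group
medians 0.28 (SCD) and 0.12 ng/mL (control), fits the 4PL standard curve
(40 down to 0.055 ng/mL), back-calculates duplicates, applies the CV% > 20
repeat rule and LLOQ/LOD censoring, and compares the groups by rank-sum.
"""

from brainmark import assay
from brainmark.synthetic import (
    CohortSpec, PlantedTruth, generate_assay_plates, generate_cohort,
)

cohort = generate_cohort(CohortSpec(50, 50, 25, seed=42))
plate, standards = generate_assay_plates(cohort, PlantedTruth(), seed=42)

curve = assay.fit_calibration(standards)
print(f"4PL fit: asymptotes {curve.lower:.0f}-{curve.upper:.0f}, "
      f"inflection {curve.inflection:.2f} ng/mL, slope {curve.slope:.2f}")

measurements = assay.process_plate(plate, curve)
flagged = sum(m.repeat_required for m in measurements)
print(f"{len(measurements)} subject-visits; {flagged} duplicates flagged for repeat")

scd = [m.concentration for m in measurements if m.group != "control"]
ctrl = [m.concentration for m in measurements if m.group == "control"]
c = assay.compare_groups(scd, ctrl)
print(f"median {c.median_a:.2f} vs {c.median_b:.2f} ng/mL "
      f"(IQR {c.iqr_a[0]:.2f}-{c.iqr_a[1]:.2f} vs {c.iqr_b[0]:.2f}-{c.iqr_b[1]:.2f}), "
      f"p = {c.p_value:.2g}")

retained = assay.sensitivity_filter(measurements, max_days=4)
print(f"sensitivity analysis retains {len(retained)} samples "
      f"(processing time < 4 days)")
# The recovered medians track the planted 0.28 / 0.12 ng/mL; the p-value
# tests whether the two concentration distributions differ in location.
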