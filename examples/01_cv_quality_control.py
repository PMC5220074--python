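"""CV-map quality control on a phantom cohort with stripe artifacts.

Builds a 25-subject cohort in which five subjects carry a stripe-like
slice artifact, constructs a normative CV reference from a separate
clean cohort, scores every run against it and prints the QC report.
"""

from cvqc import generate_cohort, generate_normative_cohort
from cvqc.pipeline import StudyConfig, run_qc
from cvqc.scenarios import STRIPE_SUBJECTS, qc_detection_spec

spec = qc_detection_spec(seed=1)
cohort = generate_cohort(spec)
normative = generate_normative_cohort(spec, 60)

result = run_qc(cohort, normative, StudyConfig(seed=1))

print(result.report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print(f"flagging thresholds (normative median + 5 MAD): "
      f"stripe={result.thresholds['stripe']:.3f} "
      f"defect={result.thresholds['defect']:.4f}")
print(f"flagged subjects: {sorted(result.flagged)}")
print(f"true artifacted subjects: {sorted(STRIPE_SUBJECTS)}")
print(f"mean tSNR, flagged vs retained: Mann-Whitney p = "
      f"{result.tsnr_pvalue:.4f}")
print()
print("Artifacted runs show stripe scores orders of magnitude above the")
print("clean runs (one or a few slices deviate en bloc from the normative")
print("CV reference) and a lower mean tSNR, so the flag column recovers")
print("the runs a radiologist would discard on visual inspection.")
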