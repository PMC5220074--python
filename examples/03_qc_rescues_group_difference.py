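"""The central mechanism: CV-based exclusion rescues a true group
connectivity deficit that artifacts mask in gray-matter ICA.

A 24-subject cohort carries a genuine patient deficit in one network
plus high-amplitude stripe artifacts in four subjects.  The gmICA +
dual-regression arm is run three ways: with all subjects, after
excluding CV-flagged subjects, and after excluding the same number of
randomly chosen subjects.
"""

from cvqc.evaluation import mechanism_summary

summary = mechanism_summary(seed=0)

print(f"significant deficit-network voxels (voxelwise FWE p < 0.05):")
print(f"  all subjects (before QC):      {summary['sig_voxels_before_qc']}")
print(f"  after CV-QC exclusion:         {summary['sig_voxels_after_qc']}")
print(f"  after random exclusion:        {summary['sig_voxels_random_exclusion']}")
print(f"  subjects flagged by QC:        {summary['n_flagged']}")
print()
print("Only the arm that removes the CV-flagged runs detects the deficit:")
print("the artifacted minority inflates within-group variance and corrupts")
print("the group decomposition, and removing an equal number of clean")
print("subjects does not reproduce the gain — the detection improvement")
print("comes from removing artifacts, not from the change in sample size.")
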