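"""Gray-matter masking keeps CSF pulsation out of the decomposition.

The phantom injects a shared high-frequency pulsation regressor into
CSF voxels.  Group ICA is run twice with matched seeds — on all brain
voxels (wbICA) and on gray matter only (gmICA) — and the maximal
correlation between any component time course and the injected
regressor is compared.
"""

from cvqc.evaluation import csf_contrast_summary

summary = csf_contrast_summary(seed=0)

print(f"max |corr(component time course, CSF pulsation regressor)|:")
print(f"  whole-brain ICA:  {summary['max_csf_corr_wbica']:.3f}")
print(f"  gray-matter ICA:  {summary['max_csf_corr_gmica']:.3f}")
print()
print("With CSF voxels present, one component locks onto the pulsation;")
print("restricting the decomposition to gray matter removes that source,")
print("which is the mechanism by which gmICA minimises spurious CSF")
print("fluctuations in connectivity analyses of atrophic brains.")
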