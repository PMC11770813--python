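"""Correct a glucose isotopologue spectrum for natural abundance.

Builds the forward convolution matrix for the deprotonated glucose ion
C6H11O6 at 99% tracer purity, pushes a known truth through it, and
corrects a measured-looking spectrum back to molar fractions.
"""

import numpy as np

from deutg import (
    CorrectionOptions,
    IonFormula,
    IsotopologueSpectrum,
    build_correction_matrix,
    correct_spectrum,
    enrichment_from_fractions,
)

matrix = build_correction_matrix(IonFormula(), CorrectionOptions())
print("Correction matrix (columns = 0/1/2 tracer labels):")
print(np.round(matrix, 5))

# a blood sample that is truly 30% tracer glucose
truth = np.array([0.70, 0.0, 0.30])
observed_areas = 1e6 * (matrix @ truth)  # what the MS integrates
print("\nObserved peak areas M+0..M+2:", np.round(observed_areas, 1))

spec = IsotopologueSpectrum("mouse1_t15", time_min=15.0, areas=observed_areas)
fractions, residual, flagged = correct_spectrum(spec, matrix)
point = enrichment_from_fractions(fractions, spec.time_min)

print(f"\nCorrected fractions: {np.round(fractions, 6)}")
print(f"Tracer enrichment:   {point.enrichment:.4f}  (true value 0.30)")
print(f"NNLS residual:       {residual:.2e}  (QC flag: {flagged})")
print(
    "\nThe enrichment is the molar share of circulating glucose that came\n"
    "from the injected [6,6-2H2]glucose bolus; natural 13C/18O background\n"
    "at M+2 and tracer impurity have been removed by the matrix inversion."
)
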