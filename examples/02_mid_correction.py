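"""Correct raw isotopologue peak areas for natural isotope abundance.

Builds the correction matrix of a pyruvate-like C3H4O3 ion, convolves a
known labeling pattern into "measured" space, and recovers it.
"""

import numpy as np

from cellflux.midcorr import (
    ElementComposition,
    build_correction_matrix,
    convolve_natural_abundance,
    correct_natural_abundance,
)

comp = ElementComposition.from_formula("C3H4O3")
M = build_correction_matrix(comp)
print("correction matrix (column j = measured MID of a j-labeled molecule):")
print(np.round(M, 4))

clean = np.array([0.55, 0.05, 0.10, 0.30])  # true biological MID
raw = convolve_natural_abundance(clean, comp)
corrected = correct_natural_abundance(raw, comp)

print("\ntrue MID:      ", clean)
print("measured MID:  ", np.round(raw / raw.sum(), 4))
print("corrected MID: ", np.round(corrected.fractions, 6))
print(
    "\nThe measured M1 fraction is inflated by ~3.5% naturally occurring"
    "\nheavy isotopes; nonnegative least squares against the matrix"
    "\nrestores the biological distribution to machine precision."
)
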