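"""Correlate objective and metacognitive accuracy across the model's
parameter space.

Simulates the dual-stage SDT observer over a grid of mean separations M and
stage-1 noise levels sigma_I, computes the rating-based Type-I (objective)
and Type-II (metacognitive) AUC in every cell, and correlates the two
surfaces — once without confidence-stage noise and once with it.
"""

import numpy as np

from metavpl import compute_surface, correlate_surfaces

# a coarser grid than the canonical 65x65 so this demo runs in seconds
M = np.linspace(0.0, 6.5, 33)
SIGMA = np.linspace(0.5, 2.0, 33)

for sigma_ii in (0.0, 0.5, 1.0):
    surf = compute_surface(M, SIGMA, sigma_II=sigma_ii, n_per_alt=2000, seed=1)
    r = correlate_surfaces(surf)
    print(f"sigma_II = {sigma_ii:4.2f}:  r(Type-I, Type-II) = {r:.3f}")

print(
    "\nWithout stage-2 noise the two accuracies are nearly collinear"
    " (r ~ 0.99): any staircase that clamps one clamps the other."
    "\nAdding noise to the confidence stage progressively decouples them,"
    " which is what lets metacognition fall while objective accuracy"
    " stays fixed."
)
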