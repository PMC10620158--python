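"""Nascent-transcription positivity from a nuclear mask / label channel pair.

Builds a field of 77 nuclei of which 70 carry a high nascent-RNA label
(the separable bimodal case), segments nuclei from the stain channel,
averages the label inside each mask and splits the per-nucleus means at
their Otsu threshold.
"""

import epiwound as ew

field, truth = ew.make_uptake_images(
    ew.SpotFieldParams(n_particles=0, n_nuclei=77, seed=5, field_size_um=300),
    eu_positive_fraction=70 / 77,
)
fraction, table = ew.eu_positive_fraction(field.eu, field.nuclei)

n_pos = int(table["positive"].sum())
print(f"nuclei scored: {len(table)}")
print(f"positive nuclei: {n_pos}")
print(f"positive fraction: {fraction:.4f} ({100 * fraction:.1f}%)")
print(f"generated positives: {int(truth.eu_positive_flags.sum())}")
print("\nA nucleus is positive when its mean label intensity exceeds the")
print("Otsu split of the per-nucleus means; 70/77 recovered exactly means")
print("the two intensity modes were separated without any tuned threshold.")
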