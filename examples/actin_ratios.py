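"""Cortical-actin ratio analysis on a synthetic wounded epithelial sheet.

Renders a sheet of ~50 µm cells around a 0.02 mm² wound whose cell-edge
amplitudes decay with rank from the margin (200, 100, 80, 60 a.u.),
draws six wound-perpendicular lines, and runs the full profile pipeline:
baseline correction, width-constrained peak detection, rank assignment
and line -> wound -> animal averaging.
"""

import numpy as np

import epiwound as ew

params = ew.SheetParams(wound_area_mm2=0.02, pixel_size_um=1.0, seed=42,
                        edge_amplitudes=(200, 100, 80, 60, 10))
image, truth = ew.make_epithelial_sheet_image(params)
rois = ew.radial_line_rois(image, truth, n_lines=8, seed=42)

records = []
for roi in rois:
    profile = ew.extract_profile(image, roi)
    series = ew.analyze_profile(profile)
    records.append(ew.LineRecord("animal-1", "wound-1", series))
    print("line ratios:", [None if r is None else round(r, 3)
                           for r in series.ratios])

per_animal = ew.aggregate_ratios(records)
print("\nper-animal mean ratios (margin, cell1, cell2, cell3):")
print(per_animal[["ratio_margin", "ratio_cell1",
                  "ratio_cell2", "ratio_cell3"]].round(3).to_string(index=False))

amps = np.asarray(truth.true_edge_amplitudes[:4])
print("\ngenerator truth ratios:", np.round(amps / amps[0], 3))
print("Each ratio is a submarginal cell's peak cortical intensity relative")
print("to the wound-margin cell; agreement with the truth row shows the")
print("pipeline recovers the rank-dependent actin gradient.")
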