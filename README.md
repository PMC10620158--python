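# epiwound

Quantification of in-vivo epithelial wound healing from fluorescence
microscopy, built for the exumbrella epithelium of the jellyfish *Clytia
hemisphaerica* — a monolayer of large (~50 µm) squamous cells over a
transparent ECM gel in which small wounds (0.02–0.125 mm²) heal within
tens of minutes — but applicable to any epithelial sheet imaged the same
way. It is a library first (see `examples/`), with a thin CLI
(`epiwound`) for shell-driven runs.

The package implements four assays and the statistics used to compare
treatment groups:

1. **Cortical-actin line profiles.** Lines drawn perpendicular from the
   wound edge into the field of cells yield intensity profiles
   *I(x)*. After subtracting a morphological-opening baseline (flat
   80 µm window), local maxima with width-at-half-prominence in the
   20–40 µm band are taken as cell edges. With `a₀` the wound-margin
   peak and `aᵢ` the *i*-th submarginal peak, the per-line statistic is
   the ratio vector `rᵢ = aᵢ / a₀`; lines are averaged within a wound
   (4–8 lines) and wounds within an animal (1–5 wounds), giving one
   datapoint per animal per rank.
2. **Dye-uptake puncta per nucleus.** Cationic-dye particles are
   detected with a difference-of-Gaussians band-pass, an intensity
   threshold and an equivalent-diameter gate; counts are divided by the
   number of Otsu-segmented stained nuclei in the same field and
   averaged over four fields per animal.
3. **Nascent-transcription positivity.** Nuclear masks from the stain
   channel are applied to the nascent-RNA label channel; a nucleus is
   positive when its mean label intensity exceeds the Otsu split of the
   per-nucleus means, and the readout is positives/total.
4. **Wound-closure kinetics.** Per-frame wound areas (frames every
   11 s, areas measured every 10th frame) become percent-of-original
   curves `100·A(t)/A(0)`, summarized per group as mean ± SEM with an
   unpaired two-tailed t test (two groups) or one-way ANOVA (more) at
   each timepoint; Tukey's HSD handles pairwise contrasts.

A seeded synthetic generator (`epiwound.synthetic`) renders epithelial
sheets, 1-D profiles, spot/nucleus fields and closure series with known
ground truth, so every estimator has an exact recovery test without any
external data.

## Worked example

```sh
python examples/transcription_positivity.py
```

```
nuclei scored: 77
positive nuclei: 70
positive fraction: 0.9091 (90.9%)
generated positives: 70
```

A 77-nucleus field is generated with 70 nuclei carrying a high
nascent-RNA label; the pipeline segments the nuclei, averages the label
inside each mask and splits the per-nucleus means at their Otsu
threshold. Recovering 70/77 = 90.9% exactly shows the positivity call
does not depend on a hand-tuned cutoff while the two intensity modes
are separable. The other examples (`actin_ratios.py`, `dye_uptake.py`,
`wound_closure.py`) walk through the remaining assays the same way, and

```sh
epiwound simulate --out demo --seed 1
epiwound closure --areas demo/closure_areas.csv --out demo/closure
```

runs the closure pipeline end to end from the shell.

## Layout

- `src/epiwound/types.py` — calibrated image / line-ROI / profile containers
- `src/epiwound/io.py` — TIFF + sidecar, profile/area/result CSV, ROI JSON
- `src/epiwound/profiles.py` — baseline, peak detection, ranks, aggregation
- `src/epiwound/spots.py` — particle counting, nuclei, transcription scoring
- `src/epiwound/closure.py` — percent-of-original curves, rates, group tables
- `src/epiwound/stats.py` — t / ANOVA / Tukey / SEM from their definitions
- `src/epiwound/synthetic.py` — seeded generators with ground truth
- `src/epiwound/cli.py` — the `epiwound` command
- `docs/methods.md` — models, parameters, numerical choices, limitations
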