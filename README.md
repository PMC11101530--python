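# mpecmorph

Quantitative morphometry and metabolite-enhancement analysis for
microparticle-enhanced cultivations (MPEC) of filamentous microorganisms
such as *Streptomyces rimosus*.

Adding inert talc microparticles (~10 µm) to a submerged *Streptomyces*
culture reshapes its morphology — spores germinate into pellets that the
particles deform, shrink or break up into clumps and free hyphae — and
those shape changes correlate with the production of secondary
metabolites (oxytetracycline and friends) and with glucose consumption.
This package implements the complete analysis chain for such experiments:

* **image_pipeline** — median + Sobel filtering and automatic-threshold
  segmentation of calibrated phase-contrast images into per-object masks;
* **morphometrics** — per-object shape descriptors and classification:
  projected area *A* (µm²), elongation *E*, solidity/roughness *S = R*,
  maximum Feret diameter *D* (µm), and the morphology number

  $$\mathrm{Mo} = \frac{2\sqrt{A}\,S}{\sqrt{\pi}\,D\,E} \in (0, 1],$$

  which is 1 for a perfect circle and decreases for elongated or
  irregular objects; objects are grouped into spores, pellets
  (*A* ≈ 10⁴–10⁶ µm²) and clumps/hyphae (*A* ≤ ~164 µm²);
* **metabolics** — the enhancement factor
  EF = mean amount (talc run) / mean amount (control) per metabolite,
  time and dose, with delta-method confidence bands and Welch t-tests;
  and the volumetric glucose uptake rate −dc/dt from a differentiated
  cubic B-spline fit of the concentration curve;
* **stats** — replicate means, n−1 SDs and Student-t confidence bands at
  α = 0.05;
* **synthetic_data** — a ground-truth generator for both images (spores,
  rough/elongated pellets, branched filaments, talc distractors) and
  replicate time series, so the whole chain is testable without any
  microscope;
* **cli_io** — the `run_pipeline` orchestrator and the `mpecmorph` CLI
  (`simulate`, `segment`, `measure`, `metabolics`, `run`).

No raw images or chromatograms accompany studies of this kind, so the
package is exercised end-to-end on synthetic scenes with known per-object
truth; the `analysis/` scripts are the narrative drivers.

## Worked example

```bash
python analysis/01_simulate.py     # scenes + replicate time series
python analysis/02_morphometry.py  # segment, measure, classify, summarise
python analysis/03_metabolics.py   # EF table + glucose uptake rates
```

`02_morphometry.py` prints the group summary of the simulated
cultivation (abridged):

```
 class  time_h  talc_g_per_L  n    A_mean  E_mean  Mo_mean
pellet    24.0           0.0  3 37141.000   1.214    0.750
pellet    96.0           0.0  3 19650.000   1.443    0.625
pellet    96.0           5.0  3 25438.667   2.037    0.390
pellet    96.0          12.0  3 12766.000   3.710    0.172
 spore     0.0           0.0 35    70.943   1.000    0.843

spore Mo (0 h): 0.84; pellet Mo at 96 h: 0 g/L -> 0.63, 5 g/L -> 0.39, 12 g/L -> 0.17
```

Spores are the roundest objects (Mo near 1, E ≈ 1); with increasing talc
dose the recovered pellets are smaller, more elongated and less regular,
so their morphology number falls — the dose response the descriptors are
designed to resolve. `03_metabolics.py` prints the late-cultivation
enhancement factors (oxytetracycline peaking near its 9-fold design
value at 5 g L⁻¹ talc, suppressed metabolites below 1) and the final
uptake rates, which drop from 0.42 g GLU L⁻¹ h⁻¹ (control) to
~0.14 g GLU L⁻¹ h⁻¹ under heavy talc load.

All tables land under `results/analysis/` as plain CSV, next to the
16-bit TIFF scenes and labelled masks; `run_log.json` records the
configuration, seed and per-stage counts of every run.

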