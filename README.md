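# phasortrack

Label-free metabolic imaging with fluorescence lifetime microscopy (FLIM)
can distinguish glycolytic from oxidative (OxPhos) cancer cells in real
time: free NADH has a short fluorescence lifetime, enzyme-bound NADH a long
one, and the proportion of the two reports which ATP-production mode a cell
is running. `phasortrack` is a tested, reusable implementation of that
analysis for single-cell studies of metabolic plasticity — for example,
bladder cancer cells shifting spontaneously (or under cisplatin pressure)
into a drug-resistant OxPhos state, and back under the OxPhos inhibitor
phenformin.

The package covers, end to end:

- **Phasor analysis of TCSPC decay stacks.** Every pixel's photon-arrival
  histogram is Fourier-transformed to phasor coordinates
  g = Σc·cos(ωt)/Σc, s = Σc·sin(ωt)/Σc. Monoexponential decays fall on the
  universal semicircle at g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures
  combine intensity-linearly.
- **Bound/total-NADH ratio (BTNR).** The intensity-weighted center of mass
  of each cell's phasor cloud is projected onto the tie line between the
  free-NADH (τ = 0.4 ns) and bound-NADH (τ = 3.4 ns) reference phasors;
  the normalized position along that line is the BTNR. Cells with
  BTNR > 0.8 are classified OxPhos, < 0.8 Glycolytic.
- **Denoising.** Intensity thresholding removes bright nuclear Hoechst
  contamination; a complex-wavelet shrinkage of G + iS tightens the phasor
  cloud without biasing ROI centers of mass.
- **Single-cell tracking.** Nearest-centroid frame linking, detection of
  Glycolytic↔OxPhos transition events, and population timecourses
  (percent OxPhos, survival).
- **¹³C isotope-tracing statistics.** Natural-abundance correction
  (binomial matrix, nonnegative least squares), TIC normalization,
  fractional contribution Σi·xᵢ/n, the M4 (oxidative flux) vs M5
  (reductive carboxylation) readout for citrate/isocitrate and aconitate
  under [U-¹³C]-glutamine, per-experiment t-tests combined with Fisher's
  method, Benjamini–Hochberg FDR, and rank-based metabolite set enrichment
  (unweighted KS running sum, label permutation).
- **Drug synergy.** The coefficient of drug interaction
  CDI = (combo/control) / ((A/control)·(B/control)); CDI < 1 synergy,
  CDI < 0.7 significant synergy.
- **A synthetic-data generator** that simulates the whole study with known
  ground truth: biexponential NADH decays with Poisson photon statistics
  and a Gaussian IRF, Hoechst-bright nuclei, scripted or Markov state
  transitions in time lapse, cisplatin death, isotopologue tables convolved
  with natural abundance, and cell-count tables.

## Worked example

Generate 20 OxPhos-like cells (true bound fraction 0.85, 10⁵ photons/cell),
run the full pipeline, and recover their BTNR:

```python
import numpy as np
from phasortrack.synthetic import SceneConfig, generate_flim_scene
from phasortrack.pipeline import PipelineConfig, analyze_scene

cfg = SceneConfig(n_cells=20, f_bound=0.85, photons_per_cell=1e5, seed=1)
stack, truth = generate_flim_scene(cfg)
measurements = analyze_scene(stack, truth.label_mask, PipelineConfig(seed=1))
btnr = np.array([m.btnr for m in measurements])
n_ox = sum(m.state == "OxPhos" for m in measurements)
print(f"mean BTNR  : {btnr.mean():.3f} +/- {btnr.std():.3f}")
print(f"classified : {n_ox} OxPhos / {len(measurements) - n_ox} Glycolytic")
```

prints

```
mean BTNR  : 0.850 +/- 0.004
classified : 20 OxPhos / 0 Glycolytic
```

The pipeline recovers the generated bound fraction (0.85) to three decimal
places at this photon budget, and every cell lands above the 0.8 cutoff.

A command-line interface mirrors the library:

```sh
phasortrack simulate flim --out-dir scene --seed 1 --n-cells 20
phasortrack phasor transform scene/stack.tif --out scene/phasor.tif
phasortrack btnr scene/phasor.tif --mask scene/labels.tif --out scene/rois.csv
phasortrack cdi counts.csv --control control --a cisplatin --b phenformin --combo combo
phasortrack run pipeline_config.json
```

## Layout

| module | contents |
| --- | --- |
| `phasortrack.phasor` | TCSPC stacks, phasor transform, calibration, universal circle |
| `phasortrack.denoise` | Hoechst thresholding, complex-wavelet filtering |
| `phasortrack.btnr` | ROI centers of mass, BTNR projection, state calls, segmentation |
| `phasortrack.tracking` | frame linking, transition events, population timecourses |
| `phasortrack.metabolomics` | NA correction, differential stats, MSEA |
| `phasortrack.synergy` | CDI computation |
| `phasortrack.synthetic` | ground-truth generators for all of the above |
| `phasortrack.scenarios` | canonical recovery experiments |
| `phasortrack.pipeline`, `.io`, `.cli` | end-to-end runs, formats, CLI |

See `docs/methods.md` for the models, parameter choices, and limitations.
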