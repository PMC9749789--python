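# nucleoquant

Quantitative image analysis of nucleolar condensates — for cell
biologists and biophysicists measuring how drugs perturb liquid-liquid
phase separation in the nucleus.

The nucleolus is a multi-layered biomolecular condensate. When a drug
(e.g. a platinum compound) changes how scaffold proteins such as NPM1,
FBL or SURF6 partition into it, that change shows up in fluorescence
images as shifts in dense/dilute intensity ratios, interface
fluctuations, and shape. `nucleoquant` turns two-channel images and
time-lapse movies into the corresponding physical quantities:

* **Partition thermodynamics** — per-nucleolus partition coefficient
  K = I^dense / I^dilute, transfer free energy ∆G^tr = −RT ln K, and
  condition-versus-reference ∆∆G^tr; phase-diagram summaries
  (median ± median deviation of dense and dilute intensities per dose).
* **Surface tension by flicker spectroscopy** — mean-square contour
  fluctuation u² averaged over time and polar angle (Fourier modes 0–1
  removed), then γ = k_B T / u².
* **Morphometry and signals** — area and moment eccentricity of
  nucleoli, rim enrichment of surface markers (KI67), per-area nucleolar
  and nucleoplasmic signal means (5-EU, FISH) with time-course
  normalization and linear / one-phase-association fits.
* **Assay statistics** — EC50 from Hill fits
  I(c) = I_min + (I_0 − I_min)/(1 + (c/EC50)^n) with n = 2 of MTT
  viability or live-cell counts, ∆∆Ct fold changes (2^−∆∆Ct), and
  expression-versus-resistance Pearson correlation with OLS trend and
  90% confidence band, optionally stratified by cancer lineage.

Every estimator has a matching generator in `nucleoquant.synthetic`
that produces inputs with known ground truth (prescribed K, γ, EC50,
fold change, ρ), so the whole pipeline is testable end to end without
microscope data. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

Simulate a field of nuclei whose nucleoli carry a true partition
coefficient K = 5, segment it, and recover the thermodynamics:

```python
import numpy as np
from nucleoquant import synthetic, thermo
from nucleoquant.segmentation import (
    segment_nuclei, segment_nucleoli, measure_regions,
)

stack, truth = synthetic.simulate_condensate_image(
    n_nuclei=4, K_true=5.0, noise_sd=0.02, seed=1,
)
nuclei = segment_nuclei(stack, "dna")
nucleoli = segment_nucleoli(stack, "marker", nuclei)
foci, nucs = measure_regions(stack, "marker", nuclei, nucleoli)
estimates = thermo.estimates_from_records(foci, nucs, condition="untreated")

print(f"{len(estimates)} nucleoli, median K = "
      f"{np.median([e.K for e in estimates]):.3f}")
print(f"median dG_tr = {np.median([e.dG_tr for e in estimates]):.3f} kJ/mol")
```

prints

```
9 nucleoli, median K = 4.998
median dG_tr = -4.149 kJ/mol
```

The median K recovers the simulated ground truth of 5 to 0.05%, and the
transfer energy is −RT ln 5 at 310.15 K: partitioning into the dense
phase is favourable by ≈ 4.15 kJ/mol. A treated condition is compared
with `thermo.delta_delta_g(treated, reference)`: if the drug halves K,
∆∆G^tr comes out at +RT ln 2 ≈ +1.79 kJ/mol (positive = weakened
partitioning).

The same round trip is available from the shell:

```sh
nucleoquant simulate --what image --seed 1 --out sim/img
nucleoquant segment sim/img.tif --pixel-size 0.2 --out sim/seg
nucleoquant thermo sim/seg_nucleoli.csv sim/seg_nuclei.csv \
    --condition untreated --out sim/thermo
```

Other subcommands: `flicker` (surface tension from a movie), `signals`
(nucleolar signal and rim enrichment), `dose` (EC50 fits), `qpcr`
(∆∆Ct), `corr` (expression-resistance correlation), each reading the
CSV/TIFF formats documented in `--help`.

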