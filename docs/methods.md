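# Methods

`nucleoquant` quantifies liquid-liquid phase separation of nucleolar
condensates from fluorescence microscopy and ties those measurements to
the downstream assays used to characterize drug effects on nucleoli.
This note describes the models, the estimators, the synthetic-data
generators used to validate them, and the design choices made where more
than one reasonable convention exists.

## Partition thermodynamics

A fluorescently tagged scaffold protein (e.g. NPM1, FBL or SURF6)
distributes between the condensed (dense) phase of the nucleolus and the
surrounding nucleoplasm (dilute phase). Treating fluorescence intensity
as proportional to concentration, the partition coefficient of one
nucleolus is

    K = I_dense / I_dilute,

and the molar free energy of transfer from dilute to dense phase is

    dG_tr = -R T ln K,

reported in kJ/mol with R = 8.314462618 J/(mol K). A per-molecule mode
(units of kBT, i.e. `-ln K`) is available through configuration. The
temperature defaults to 310.15 K — live cells imaged at 37 °C — and is
configurable; fixed samples imaged at room temperature shift RT by ~4%.

Drug effects are summarized per condition as

    ddG_tr = median(dG_tr | treated) - median(dG_tr | reference).

The median (not the mean of K) aggregates the per-nucleolus energies,
because per-nucleolus K distributions are right-skewed and the
downstream comparisons report medians throughout. Sign convention: a
drug that weakens partitioning (K falls) gives ddG_tr > 0.

**Measurement convention.** `I_dense` is the *mean* intensity inside the
nucleolus mask. `I_dilute` is the *median* over the nucleoplasm — the
nucleus minus all nucleoli — after eroding 2 px from the nucleus
boundary and dilating every nucleolus by 2 px, so partial-volume pixels
at either boundary cannot contaminate the dilute estimate; the median
further suppresses residual bright pixels. No background subtraction is
applied by default (intensities stay in arbitrary units, and the ratio
K cancels a multiplicative gain); a `background` offset parameter is
available where a camera pedestal matters.

**Phase diagrams.** Per dose, the dense and dilute intensities are
summarized by the median and the median absolute deviation from the
median (MAD). A mean-absolute-deviation variant is available by flag;
the two differ only in how dispersion is weighted, not in the medians.

## Segmentation

No part of the scientific claim rests on a sophisticated segmentation,
so the pipeline uses deliberately standard, parameter-light operations:

* **Nuclei** — Gaussian smoothing (sigma 2 px) of a nuclear-filling
  channel, Otsu threshold, hole filling, distance-transform watershed to
  split touching nuclei, then removal of regions below 50 µm² and of
  regions touching the image border (their geometry is censored).
* **Nucleoli** — per-nucleus Otsu on the condensate channel, computed on
  the nucleus interior eroded by 3 px so dim pixels swept in at the
  smoothed nucleus boundary cannot pose as the dilute phase. A nucleus
  whose putative dense phase exceeds its dilute phase by < 20% relative
  contributes nothing: there is no detectable condensed phase (this is
  what the K = 1 limit looks like to a thresholder). Nucleoli below
  0.2 µm² are discarded; each is assigned to the nucleus containing its
  centroid.

Eccentricity is that of the ellipse with identical second central
moments, `sqrt(1 - (b/a)^2)`; single-pixel regions report 0. On
rasterized test ellipses with semi-minor axis ≥ 20 px this agrees with
the analytic value within 2%. Near circularity the statistic is very
sensitive to rasterization asymmetry (eccentricity grows like the square
root of a moment perturbation), which is why the generator places
circular nucleoli on integer pixel centres.

## Flicker spectroscopy

A liquid droplet's interface fluctuates thermally; the mean-square
amplitude of those contour fluctuations is inversely proportional to the
interfacial tension:

    gamma = kB T / u2.

The estimator defines u² operationally as follows. Per frame the
condensate is re-segmented (Otsu), lightly smoothed (sigma 1 px, to
suppress pixel-locking), and its boundary is taken as the sub-pixel
iso-intensity contour at the half-max level between object and
background. The boundary is expressed as radius versus polar angle about
the frame's intensity-weighted centroid and resampled at M equal angles
(default 256) by periodic linear interpolation; non-star-shaped
boundaries take the outermost crossing, with a warning. The deviation

    h(theta, t) = r(theta, t) - rbar(theta),

where `rbar` is the per-angle time mean, is Fourier-decomposed in the
angle per frame; modes 0 and 1 are zeroed (mode 0 is area/segmentation
drift, mode 1 residual translation of the centroid — neither reflects
interfacial fluctuation); and u² is the time- and angle-average of the
filtered h², multiplied by N/(N-1) to restore the variance absorbed by
the time-mean reference contour. Frames where segmentation fails are
dropped; losing more than 10% of frames aborts the measurement as
unstable rather than silently extrapolating.

The acquisition this is designed for is a 100-frame single-channel
movie at 250 ms intervals, and the recovery tests use exactly that frame
count.

## Synthetic data

Every estimator is validated against a generator whose governing
quantity is prescribed exactly. The generators define the package's test
conditions; their defaults are fixed and are not tuned per test.

* **Condensate images** — elliptical nuclei (non-overlapping, off the
  border) each containing 1–4 elliptical nucleoli with ≥ 2 px clearance;
  a "dna" channel uniformly fills the nucleus, a "marker" channel has
  nucleoplasm at `dilute_level` (default 1000 AU on a 16-bit scale) and
  nucleoli at `K_true x dilute_level`. Noise is additive Gaussian at a
  fraction of the dilute level (detector-dominated regime), default 2%.
  Edges are hard (no optical blur): the K contract is stated on the
  unblurred image, and the measurement margins (erosion/dilation) are
  exercised by the thresholding geometry rather than by a PSF model.
  This is the generator's main departure from real microscope data,
  along with uniform within-phase intensity; recovery results bound
  estimator error only under these conditions.
* **Contours** — r(theta, t) = R0 + sum of angular Fourier modes
  q = 2..20, cosine/sine amplitudes i.i.d. zero-mean Gaussian redrawn
  per frame, total variance kB T / gamma_true split equally across
  modes (no fluctuation spectrum is imposed; equal-per-mode is a
  declared stand-in). Fluctuations are white in time; the estimator
  averages over frames, so temporal correlation does not enter the u²
  contract — a documented limitation, since real droplet modes relax at
  finite rates.
* **Dose-response** — the decreasing Hill curve (below) on the 12-point
  assay grid 0–200 µM with four replicates and 5% multiplicative noise.
* **qPCR** — Ct_target = base − log2(fold change) + noise, reference
  gene constant + noise, additive in cycles.
* **Cohorts** — (log2 TPM, AUC) bivariate Gaussian with prescribed
  correlation; the `tpm` column is `2**log2_tpm`, so the prescribed
  correlation holds exactly on the log scale and approximately on the
  linear scale.

Same seed, same bits: all generators are deterministic given their seed.

## Dose-response fitting

MTT intensity is the background-corrected absorbance
`I(c) = Abs570(c) − Abs690(c)` (negative values on noisy blanks are kept,
not clipped). The dose dependence is fitted by least squares with

    I(c) = I_min + (I_0 - I_min) / (1 + (c / EC50)^n),

with the Hill exponent fixed at n = 2 by default (`free_hill` releases
it). Initialization: ceiling = max response, floor = min response,
EC50 = concentration nearest the half-response; EC50 bounded in
(0, 10 × max c]. Concentration 0 enters the model directly — the curve
is well defined there — rather than through a log transform. A response
set that is flat beyond its noise raises "EC50 unidentifiable" instead
of returning an arbitrary number. Live-cell counts from rescue assays
(ten-point two-fold dilution grid topping at 100 µM) use the identical
model; EC50 shifts are reported as ratios with standard errors
propagated in quadrature.

## Signals and time courses

* **Rim enrichment** (e.g. KI67, which coats the nucleolar surface):
  mean marker intensity in a morphological band of width 0.5 µm
  (default) around each nucleolus, divided by the mean nucleoplasmic
  intensity. A whole-nucleolus variant is available by flag; the rim
  definition is the default because surface-localized markers dilute the
  whole-nucleolus mean. The ratio is invariant to global gain.
* **Nucleolar signal** (5-EU, FISH): the per-area mean — total signal
  over all nucleolar pixels divided by total nucleolar area — plus the
  total (area-weighted) signal. The two answer different questions:
  per-area mean tracks concentration and is unchanged when nucleoli
  shrink at constant brightness; the total tracks output and halves when
  the area halves.
* **Normalization**: each compartment of a time course is divided by its
  own value at a reference measurement (by default the earliest
  measurement of the reference condition).
* **Time-course fits**: ordinary least squares for the linear model; for
  one-phase association `y(t) = y0 + (plateau − y0)(1 − exp(−k t))`,
  bounded least squares with k ≥ 0, initialized from the linear fit.
  When the fitted amplitude vanishes the rate is unidentifiable; it is
  reported as the k = 0 boundary with a warning.

## Cohort statistics

∆∆Ct uses amplification efficiency 2 (fold = 2^(−∆∆Ct)); replicates are
averaged in Ct space before differencing, and the computation is pure
arithmetic — no fitting, bit-reproducible. Expression-resistance
correlation is Pearson's rho between AUC and TPM per transcript, with an
OLS trend line and a 90% confidence band for the mean trend; raw TPM is
the default axis, log2(TPM+1) a flag (conventions differ between
expression releases). Stratified analysis repeats this per cancer
lineage, skipping groups below 3 lines.

## Numerical choices and test scales

* Tolerance choices follow the information content: closed-form
  identities are tested at 1e-6 to 1e-9 relative; Monte-Carlo
  recoveries at 5–20% depending on the estimator's sampling variance at
  the simulated problem size.
* Recovery test scales: 256×256 px images with 4 nuclei (3–5 seeds per
  condition); 100-frame, 256-angle contour series (50–200 seeds);
  48-well dose tables (50–100 seeds); 371-line cohorts. These sizes keep
  the full validation suite in the tens of seconds while leaving the
  Monte-Carlo intervals comfortably narrower than the tolerances tested.
* Ties and degenerate inputs: nucleoli straddling two nuclei go to the
  nucleus containing the centroid; a nucleus left without nucleoplasm
  reports I_dilute = NaN and is excluded from K estimates with a
  warning; u² = 0 (a static contour) is an error for tension estimation,
  since it only bounds gamma from below.

## Known limitations

* Segmentation is 2D, threshold-based and untracked; it is adequate for
  high-contrast condensates and the generator's geometry but is not a
  general nucleolus detector for crowded or low-contrast fields.
* The flicker estimator reports a single scalar tension; it does not fit
  a mode-resolved fluctuation spectrum and therefore cannot separate
  tension from bending rigidity or viscous relaxation.
* Intensities remain in arbitrary units throughout; no absolute
  concentration calibration is attempted, so dG_tr values are comparable
  within an imaging configuration, not across instruments.
* The generators omit photobleaching, shot noise, optical blur and
  spatial intensity gradients; passing recovery tests demonstrates
  estimator correctness under the stated models, not robustness to every
  real-world artifact.
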