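# Methods

## Decay model and phasor estimation

A pixel's TCSPC histogram is modeled as photon micro-times drawn from a
two-component mixture of exponential decays wrapped modulo the laser period
T: with probability f_bound from the bound-NADH component (lifetime
τ_bound) and otherwise from the free-NADH component (τ_free), convolved
circularly with a Gaussian instrument response of width σ_IRF centered at
t₀, and binned into n_bins micro-time bins. Periodic wrapping (rather than
truncation at T) is used deliberately: the single-period Fourier
coefficient of a wrapped exponential equals the analytic 1/(1 + iωτ)
exactly, so the universal-circle formulas hold without tail corrections.

The phasor transform uses bin centers t_k = (k + ½)Δt, which cancels the
first-order discretization bias of left-edge timestamps; the residual
binning error of a monoexponential phasor is below 10⁻³ at 256 bins
(verified against a 16×-oversampled numerical integration of the same
wrapped decay). Zero-intensity pixels are excluded through a validity mask
instead of NaN sentinels so that downstream statistics never ingest them.

Defaults, configurable throughout:

| parameter | default | rationale |
| --- | --- | --- |
| laser period T | 12.5 ns | 80 MHz Ti:Sapphire repetition rate, standard for 740 nm two-photon NADH excitation |
| micro-time bins | 256 | bin width T/256 ≈ 49 ps |
| τ_free / τ_bound | 0.4 / 3.4 ns | literature NADH lifetimes; generator and analysis share the pair |
| σ_IRF, t₀ | 0.1 ns, 0.5 ns | typical hybrid-detector response; removed by calibration |
| harmonic | 1 | first harmonic is the analysis harmonic; higher harmonics exposed for cross-checks |

## Calibration

Instrument effects (IRF phase and modulation loss, plus the common binning
factor) are divided out by complex division: each phasor is multiplied by
z_expected/z_measured, where z_measured is the phasor of a reference
acquisition of a known monoexponential (default reference lifetime 2.0 ns)
processed identically, and z_expected its universal-circle value. In
simulation the reference is itself generated with the scene's timing
parameters, which mirrors the usual practice of imaging a reference dye
under the experimental configuration.

## BTNR and state classification

The bound/total-NADH ratio of an ROI is the normalized position of its
intensity-weighted phasor center of mass along the segment from the free
reference phasor to the bound reference phasor (orthogonal projection,
clamped to [0, 1] because photon noise can push a center of mass slightly
off the tie line). Because phasors mix linearly in photon fractions, a cell
whose photons are a fraction f from the bound component sits at BTNR = f;
BTNR is therefore a fractional-intensity quantity, not a molar fraction
(converting to molar bound fraction would require quantum-yield
corrections that are out of scope). Classification uses strict
inequalities around the cutoff (default 0.8): above → OxPhos, below →
Glycolytic, exactly equal → Indeterminate rather than a silent tie-break.

## Hoechst thresholding and wavelet denoising

Nuclear Hoechst dye emits into the NADH detection band and is far brighter
than cytoplasmic NADH; pixels above an intensity cutoff (default: 98th
percentile of valid-pixel intensities; Otsu thresholding available for
strongly bimodal images) are dropped from the validity mask. The threshold
level is per image; no numeric cutoff is canonical, so it is exposed in
the configuration.

The phasor image is denoised as the complex image Z = G + iS with an
undecimated (stationary) 2-D wavelet decomposition, soft-thresholding the
detail coefficients with complex magnitude shrinkage (phase preserved) at
the universal threshold σ√(2 ln N). Two details matter on sparse scenes:

- **Signal region.** Near-empty background pixels carry essentially pure
  shot noise in (g, s). Foreground is identified by Otsu on the intensity
  plane; non-foreground pixels are inpainted with their nearest foreground
  neighbor before the transform and restored afterwards.
- **Noise scale.** σ is the median absolute deviation (÷0.6745) of the
  finest-level detail coefficients *on the signal region* — the stationary
  transform keeps a 1:1 coefficient-to-pixel correspondence, which makes
  this restriction possible. Estimating σ over the whole frame lets the
  background dominate and mis-sizes the threshold by an order of
  magnitude in either direction depending on scene sparsity.

The filter never touches the intensity plane or the validity mask. Its
contract, enforced by tests: per-pixel RMS phasor error strictly decreases
on homogeneous 500-photon/pixel scenes; ROI centers of mass move < 0.02 in
(g, s) for homogeneous ROIs with ≥ 10⁴ photons; a second pass changes
< 5% of the first pass's detail energy; constant images are fixed points.
A 3×3 median filter on the same inpainted image is provided as a fallback
for images too small for the configured decomposition depth. The filter is
a wavelet-shrinkage design in the spirit of published complex-wavelet FLIM
filters, not a coefficient-level replication of any particular one.

## Tracking and transitions

ROIs are linked across frames by greedy nearest-centroid matching within a
displacement gate (default 10 px/frame), ties broken by smaller ROI id —
adequate for low-density, low-motility adherent cultures; global
assignment and lineage/mitosis handling are out of scope (a splitting ROI
opens a new track). A transition event is emitted when the state label
changes between consecutive measured frames and persists for the debounce
window (default 1 frame, matching reporting at the acquisition interval
without smoothing); Indeterminate frames carry the last definite state.
Population summaries report per-frame counts, percentages and survival
relative to the first frame.

## Synthetic scenes and what they do not model

Cells are ellipses (axis ratio 0.85–1.15) on a jittered grid, nucleus a
concentric region at 40% radius — the simplest geometry that exercises
masking, thresholding and segmentation. Per-pixel photon counts are
Poisson around the per-cell budget divided by cell area; the generator
logs every cell's bound/free component draw so recovery tests have an
exact oracle. Hoechst nuclei add a short-lifetime (1.4 ns) component at
10× the cytoplasmic intensity. Background photons have uniform
micro-times. Not modeled: optical PSF blur, photobleaching, detector
afterpulsing, spectral cross-talk, cell divisions, realistic motility.
Passing recovery tests therefore demonstrates correctness of the
estimation chain under the stated statistical model, not robustness to
every instrumental artifact of real acquisitions.

Scale choices for the standard experiments: BTNR recovery uses 20 cells ×
10⁵ photons/cell (per-cell BTNR noise ≈ 0.004); the population-fraction
experiments use 100 cells with deterministic composition (round(p·n)
OxPhos cells), so the measured percentage isolates classification
performance; the scripted 48-h time lapse uses 35 cells × 8000
photons/cell at 3-h frames, a budget at which per-cell BTNR noise
(≈ 0.01) leaves a > 4σ margin between the state values (0.70/0.85) and
the 0.8 cutoff, making scripted event-count recovery deterministic in
practice.

## Isotope-tracing statistics

Natural-abundance correction solves C·x = m by nonnegative least squares,
where C[i,j] = Binom(n−j, i−j) p^(i−j) (1−p)^(n−i) is the probability that
a molecule with j tracer carbons is observed as M_i given natural ¹³C
abundance p = 0.0107; columns of C sum to 1 and C is invertible for
p < 0.5. Only the carbon skeleton is corrected (no N/H/O isotopes, no
tracer-purity term). NNLS rather than direct inversion keeps corrected
distributions nonnegative under noise; the residual is reported.

Fractional contribution is Σᵢ i·xᵢ/n, the standard tracer-derived carbon
fraction; it depends only on the within-metabolite distribution and is
invariant under TIC normalization. The M4/M5 readout extracts x₄ and x₅
for citrate/isocitrate and aconitate under [U-¹³C]-glutamine: M4 marks
oxidative TCA flux (one heavy carbon lost at the α-ketoglutarate →
succinyl-CoA step), M5 marks reductive carboxylation (all five retained).
Unresolved isomer pairs are treated as single pooled species.

Differential pool-size statistics per experiment use the classic
pooled-variance two-sample two-tailed t-test on TIC-normalized pool sizes;
p-values are combined across experiments with Fisher's method
(X² = −2Σ ln p on 2k df) and then BH-corrected across metabolites — the
combine-then-correct order. The "average weighted log₂ fold change" uses
inverse-variance weights with the delta-method variance of log₂(mean
ratio); equal weighting is available since no canonical weighting exists
for this summary. Zero-variance ties return p = 1.0 with a warning rather
than NaN.

MSEA ranks metabolites by signed log₁₀ FDR q (descending, ties broken by
name for determinism) and computes the unweighted Kolmogorov–Smirnov
running-sum enrichment score (hit step 1/G, miss step −1/(N−G), ES = signed
extremum). Significance is by metabolite-label permutation with an explicit
seed; p = (1 + exceedances)/(n_perm + 1), so the smallest attainable p is
1/(n_perm + 1) at the default 1000 permutations; BH across sets. Sets that
do not intersect the ranked list get an undefined ES and are excluded from
the correction.

## Drug synergy

CDI is computed on arm means; per-replicate CDIs are also emitted for
dispersion reporting. Labels follow the strict rule: < 0.7 significant
synergy, < 1.0 synergy, else none. The p-value reported alongside a CDI is
operationalized as a two-tailed two-sample t-test of combination counts
against per-replicate product-expectation counts Aᵢ·Bᵢ/mean(control); this
pairing is one reasonable reading of common practice and is recorded in
the result metadata so downstream users know exactly what was tested.

## Determinism and degenerate inputs

Every stochastic component takes an explicit seed; fixing seeds makes
generators bit-reproducible and pipeline CSV outputs byte-identical across
reruns. Degenerate inputs have defined behavior rather than crashes:
all-zero stacks produce empty validity masks; empty validity masks pass
through thresholding; uniform-intensity images are not thresholded (with a
warning); blank images segment to zero labels (with a warning); an ROI
with no valid pixels raises an error naming the ROI; a zero-total sample
raises an error naming the sample.
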