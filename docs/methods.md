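# Methods

This note documents the models, parameter choices and numerical conventions
behind `mycoftir`, and what the synthetic campaigns do and do not emulate.

## Conventions

Wavenumber axes are ascending, in cm⁻¹, stored float32 on disk and float64
in memory. Spectra are delivered on grids twice as fine as the nominal
optical resolution (3 cm⁻¹ spacing at 6 cm⁻¹ resolution for transmission,
2 cm⁻¹ at 4 cm⁻¹ for ATR), the usual consequence of interferogram
zero-filling; the window-15 Savitzky–Golay (SG) filters then span 30–45 cm⁻¹,
enough to reject channel noise while resolving the 2925/2955 cm⁻¹ pair.
Images are row-major with origin top-left; AFM scan lines are rows.
SG derivatives are per cm⁻¹ (the filter's `delta` is the grid step), so the
second derivative of a·ν̃² is the constant 2a. Edges use nearest-point
extension to keep map pipelines length-preserving.

## EMSC

Each spectrum is modelled as s ≈ a + b·m + d₁t + d₂t² against a reference m
(default: the collection mean), with t the wavenumber axis mapped affinely
onto [−1, 1] for conditioning; the correction is (s − a − d₁t − d₂t²)/b.
Coefficients are reported per spectrum; |b| below 10⁻⁸ (flat, degenerate
input) flags the spectrum and leaves it uncorrected. The correction is
idempotent with a fixed reference and maps the reference to itself. Note a
structural property that shapes the synthetic design below: a *purely
multiplicative* chemical difference between groups is indistinguishable
from the physical scaling EMSC removes, and is absorbed into b.

## ANOVA-PCA

For a two-factor design the matrix is partitioned by cell means:
effect rows are (level mean − grand mean), the interaction is
(cell mean − A mean − B mean + grand mean), and the residual the remainder.
Reconstruction is exact by construction; for balanced designs the
partitions are mutually orthogonal so the centred total sum of squares is
additive, and each partition's share of it is reported as its contribution.
Unbalanced designs fall back to the same cell-mean estimates without the
orthogonality guarantee; empty design cells are an error (the interaction
is undefined there). Each factor's effect matrix plus the residual is
column-centred and decomposed by SVD; scores carry the level labels for
plotting. Contributions of a pure-noise design concentrate on the residual
in proportion to degrees of freedom — the unit tests verify this against
the closed form.

## ATR optics and the dispersive shift model

Penetration depth follows the standard evanescent-wave formula
d_p = λ / (2π n₁ √(sin²θ − (n₂/n₁)²)) with diamond n₁ = 2.40, sample
n₂ = 1.50, θ = 45°; at 1742 cm⁻¹ this gives 1.151 µm and at 1100 cm⁻¹
1.823 µm. Synthetic ATR spectra weight every band by d_p(centre)/d_p(1742),
so low-wavenumber bands gain intensity relative to transmission spectra of
the same material. Refractive-index dispersion additionally displaces ATR
band positions toward lower wavenumbers; rather than solving the
Kramers–Kronig problem, the generator uses a phenomenological displacement
δ(ν̃) = δ₀ (ν̃₀/ν̃)² with ν̃₀ = 1375 cm⁻¹ and δ₀ = 7 cm⁻¹, giving ≈1.5 cm⁻¹
at 2925 cm⁻¹ and 7 cm⁻¹ at 1375 cm⁻¹ — the observed pattern of larger
shifts at the low-frequency end. The exponent 2 (not 1) is needed for both
magnitudes to hold simultaneously; it is a modelling convenience, not
derived optics.

## Band library and composition model

Spectra are sums of Gaussian bands (half-widths are HWHM; stretching bands
10–20 cm⁻¹, the water O–H band 150 cm⁻¹) grouped by chemical component:
TAG ester carbonyl at 1742, FFA dimer carbonyl at 1708, ionized-FFA COO⁻ at
1600, amide I/II at 1650/1545, polysaccharide C–O–C near 1030–1150,
polyphosphate P=O at 1265, the acyl CH manifold at 2855/2925/2955 plus
bending modes, and =C–H at 3010. Acyl-chain and unsaturation band weights
derive from the TAG + FFA fraction (factors 0.8 and 0.25). Absolute
amplitudes per unit mass fraction are order-of-magnitude choices — no
published molar absorptivities exist for intact biomass — so only relative
and ratio quantities are meaningful.

## Bulk campaign generator

The emulated design is 6 phosphate conditions (Pi4 … Pi0, KH₂PO₄/Na₂HPO₄ at
7×/2× the level in g/L) × 3 replicates, once for HTS (18 spectra) and over
7 storage days for ATR (126 spectra). Lower phosphate drives lipogenesis:
the TAG weight scales as 1 + 0.6·x and the unsaturation index as
1 + 0.48·x across the series (x ∈ [−0.5, 0.5], monotone in condition rank),
while stored polyphosphate scales oppositely; the FFA fraction is constant.
The day effect is film drying (water weight down by up to 6%) plus a small
TAG/unsaturation drift at one fifth of the condition amplitudes. Because
the responses change band *shape* (TAG vs FFA vs unsaturation), they
survive EMSC; a pure amplitude response would not (see above). Replicate
noise is i.i.d. 0.002 AU per channel — typical for 32-scan-averaged
absorbance — plus random per-spectrum offset/slope baselines of 0.01 AU
that EMSC is expected to remove. What this does *not* emulate: correlated
water-vapour line structure, detector nonlinearity, and real biological
replicate-to-replicate composition variance; passing tests therefore show
the chemometric machinery recovers planted structure, not that the
biological effect sizes are realistic.

## FPA scenes and pipeline

Scenes are 128×128 px (0.7 µm/px) absorbance cubes on a 10 cm⁻¹ grid with
300 bands (trimmed to 3200–1000 cm⁻¹ in the pipeline, 220 bands). Default
scenes are densely covered (≈40–60% foreground: a bundle of parallel
oblique hyphae or a cluster of yeast cells), as areas of interest are in
practice; lipid-to-protein scalars default to 0.5 / 1.1 / 2.2 for flat
hyphae / swollen hyphae / yeast, with TAG-enriched droplet inclusions.
Every pixel carries a smooth random quadratic baseline (0.005 AU scale,
doubled on cells) and 0.02 AU channel noise; planted hot pixels displace
the true value by 10 scaled MADs of their band.

Outlier flagging is the scaled-MAD rule (|x − median| > 3·1.4826·MAD per
band image, σ-consistent constant 1.4826), with two refinements. First,
pixels flagged in more than half the bands are global outliers (dead/hot
detector elements). Second, 8-connected flagged clusters larger than 12 px
are released unless a member is also a spike against the median of its own
8 neighbours: the MAD criterion has a 50% breakdown point, so whenever
strongly absorbing cells are a minority at a band the raw rule flags — and
repair would erase — entire genuine structures, which is not the artifact
class (isolated dead pixels, noisy spectra) the rule targets. Repair
replaces flagged values with the mean of clean 8-neighbours, sweeping
until closed. On structure-free Gaussian maps the flagged fraction matches
the two-sided normal tail 2Φ(−3) ≈ 0.27%.

Segmentation standardises the seven marker bands (3010, 2955, 2925, 2855,
1742, 1708, 1650 cm⁻¹, nearest grid point within ±4 cm⁻¹), keeps principal
components to 99% cumulative variance, and clusters with k-means (k = 2,
k-means++ with fixed seed, 10 restarts); the cluster with the higher amide-I
mean is the cell foreground. Note an ordering caveat: segmentation runs
*before* descattering, so strong common-mode baselines (which move pixels
along the very direction separating cells from slide) degrade the mask;
the default scene baseline is accordingly modest, and the descattering
stage — EMSC against the foreground mean with quadratic baseline, then
SG(5,2) smoothing, background untouched — is tested against larger planted
ripple separately. The descatter interface (cube + mask in, cube out) is
frozen so a learned descattering model can replace the EMSC stand-in.
Ratio maps divide nearest-band images on the foreground with a denominator
floor of 10⁻³ AU; pixels below it are masked and counted, never divided.

## AFM-IR scenes and pipeline

A scene holds topography (µm), deflection and photothermal absorption maps
at 1600, 1708 and 1742 cm⁻¹ on a 96×96 grid over 5 µm. The hypha body is an
oblique (45°) band with a parabolic cross-section, ≈150 nm (flat) or 200 nm
(swollen) high — cell-wall-dominated thickness — with Gaussian droplet
swellings near the body edges (flat form) or at the centre (swollen form).
Droplet absorption splits a total carbonyl amplitude between TAG (1742) and
FFA (1708) by the planted TAG:FFA ratio, with the cell-wall matrix
absorbing only at 1600 (β-glucan COO⁻); the carbonyl bands are treated as
fully resolved at QCL linewidth, which is what makes
log₁₀(A₁₇₄₂/A₁₇₀₈) an unbiased readout of the planted ratio. Artifacts, in
acquisition order: a tilt plane, per-scan-line height offsets (10 nm),
per-wavenumber rigid drift, contact-loss dropouts (5-px scan-line segments
zeroed on high-signal stretches), laser-power scaling of the raw
absorption, and channel noise. The oblique body orientation keeps substrate
in every scan line (needed for line leveling) and breaks the translation
degeneracy a frame-spanning horizontal band would have.

Corrections: (1) topography leveling fits the polynomial background
(default a plane) robustly — protrusions beyond 2 scaled MADs above the fit
are iteratively excluded so the fit tracks the substrate, not the cells —
then subtracts per-line medians computed over substrate pixels only (lines
with no substrate keep their offset, as it is unobservable); (2)
contact-loss repair detects dropouts one-sidedly on 3×3-median-filter
residuals, threshold max(3 scaled MADs per line, 10% of the robust map
range) — detecting on raw per-line values would flag smooth genuine droplet
signal — and fills them from clean 8-neighbours; (3) drift registration
estimates rotation by coarse-to-fine grid search scored by FFT
cross-correlation (plain normalisation; spectral whitening is unstable on
smooth maps), then refines (dx, dy, θ) with Nelder–Mead on a masked SSD
from which a residual plane is projected (independent leveling leaves
slightly different backgrounds) and which compares lightly smoothed images
(bilinear resampling attenuates noise in a shift-dependent way that
otherwise biases the optimum by up to half a pixel); transforms below
0.02 px / 0.01° are treated as identity and not applied, so artifact-free
scenes pass through bitwise; (4) topography is shifted non-negative with a
5th-percentile floor (linear-interpolation percentile convention), and
(5) absorption divided by the interpolated laser power. Accuracy on the
default scenes: drift recovered within ≈0.35 px and 0.1° (bound 0.5/0.5
asserted over 20 seeded scenes).

Segmentation clusters all nine maps jointly (standardised, k-means k = 2,
fixed seed); the higher-topography cluster is the hypha, out-of-frame
pixels from registration are excluded. Log-ratio maps are computed on the
foreground only, with nonpositive operands masked rather than clipped.
Samples flagged as thicker than ~2–3 µm in z (yeast-like cells) are refused
by the correction chain: the tip loses contact on such samples and the
absorption signal is unreliable.

Point spectra (1800–1510 cm⁻¹, 1 cm⁻¹ step) are averaged per acquisition
point, SG(15, 1)-smoothed and EMSC-corrected against the group mean; a
second-derivative variant (SG 15, order 2) is available for resolving the
1735 cm⁻¹ MAG/DAG shoulder from the 1742 cm⁻¹ TAG carbonyl.

## Problem sizes and determinism

Every generator is deterministic given its seed, and different seeds change
only noise realisations. Test-suite problem sizes follow the emulated
campaigns directly (126/18 bulk spectra, 128×128×300 cubes, 96×96 scenes);
the whole suite runs in well under a minute, and `scripts/acceptance.py`
re-derives all headline quantities in ~20 s.

## Known limitations

* No Mie/resonant-Mie scattering physics; the descattering stage is an
  EMSC stand-in with the interface of a learned model.
* The dispersive ATR shift is phenomenological, not Kramers–Kronig.
* Band amplitudes per component are relative; absolute absorbance scales
  are arbitrary.
* AFM-IR thermomechanics (cantilever resonance, PLL tracking) is not
  modelled; absorption maps are generated directly from composition.
* Line-offset correction cannot recover offsets of scan lines fully covered
  by sample; the generators avoid that geometry, real data may not.
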