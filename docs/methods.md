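# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic validation does and does not establish.

## Decay model and fitting

**Forward model.** A pixel's (or pooled ROI's) expected TCSPC histogram is a
two-component exponential under periodic excitation. With repetition period
T (12.5 ns at 80 MHz) a component of lifetime τ contributes
`a·exp(−t/τ)/(1 − exp(−T/τ))` on t ∈ [0, T): the geometric factor sums the
tails of all preceding pulses in closed form ("incomplete decay" handling,
on by default). The periodic decay is circularly convolved with the
discretised, unit-sum IRF and a constant background is added. Lifetimes at
or beyond 50×T are rejected as numerically degenerate. The record is
assumed to tile the full period (the default 256 bins × T/256); a record
shorter than the period would make the circular convolution an
approximation at the wrap point.

**IRF.** Default Gaussian, center 1.0 ns, FWHM 0.2 ns — representative of
hybrid-detector multiphoton TCSPC. A measured per-bin curve can be supplied
instead; it is normalised to unit sum.

**Objective.** Poisson maximum likelihood by default, correct at the low
counts of single-pixel TCSPC; Neyman-weighted least squares (weights
1/max(counts, 1)) as an option. The optimizer is L-BFGS-B with analytic
gradients; amplitudes are internally rescaled to order 1 so all coordinates
move on comparable scales.

**Background.** Fitted as a free parameter by default (bounded by the mean
bin count), initialised from the pre-rise bins. It is *not* simply read off
the pre-rise region: under periodic excitation those bins contain the
previous pulse's tail, which the model describes, and treating them as
background biases the amplitude fractions by several percent.

**Initialisation.** τ2 from a log-linear fit to the last 40 % of bins above
background, τ1 = τ2/5, amplitudes by non-negative least squares given the
lifetimes — deterministic and derivative-free.

**Bounds and identifiability.** Default lifetime bounds are disjoint:
τ1 ∈ [0.05, 0.8] ns, τ2 ∈ [0.8, 8] ns (configurable). When one component
carries only a small photon share, overlapping bounds let the optimizer
trade the short lifetime against the amplitude split along a nearly flat
likelihood ridge, biasing a2% low by up to ~0.07; disjoint bounds pin the
labels and restore |bias| < 0.02 across the physiological grid. Fits whose
two lifetimes converge within 0.05 ns are flagged effectively
mono-exponential; the amplitude split then follows the canonical
τ1 ≤ τ2 sort. Results are always canonicalised to τ1 ≤ τ2.

**Goodness of fit.** Pearson reduced χ²: Σ(obs − exp)²/exp over bins with
expected counts ≥ 1 (configurable floor), divided by (included bins − free
parameters; 5 with fitted background, 4 with fixed). On Poisson
realisations of the true model the statistic averages 1 within [0.9, 1.1].

**Statistical limits.** The Cramér–Rao bound for a2% at 10⁴ photons rises
from ~0.005 (a2% = 0.1) to ~0.043 (a2% = 0.9) — photon-poor components are
intrinsically hard. Recovery quality is therefore quoted pooled across the
truth grid (bias ≈ −0.007, RMSE ≈ 0.028 at 20 replicates/point), not at the
hardest single point, where no unbiased estimator could beat ~0.043 RMSE.

**Photon floor.** Histograms below a configurable minimum (default 300
photons; 100 for pooled FAD ROIs in the pipeline config, whose cytosolic
pools are intrinsically dim) raise an explicit insufficient-photons error
rather than returning a silent bad fit.

## ROI assay

ROIs are non-overlapping 2×2-pixel blocks tiling the image from pixel
(0, 0) (0-based, row-major, half-open blocks). A block is emitted iff all
four pixels share one nonzero cell label, none is nuclear, and the *mean*
NAD(P)H count of the four pixels lies in the closed threshold interval.
The mean (not per-pixel counts) was chosen as the membership statistic for
robustness to single-pixel spikes. Blocks straddling two cells or
cell/background are dropped entirely so every data point belongs to exactly
one cell. Nuclear exclusion is mask-based and applied regardless of
thresholds. FAD and Trp inherit the NAD(P)H-defined footprint. Two presets
give the two morphologies: whole-cell [30, 5000] and mitochondrial
[150, 5000] in the synthetic photon units of the default scene (config
values, scaled with acquisition depth). With equal upper thresholds and the
mitochondrial lower threshold at or above the whole-cell one, the
mitochondrial ROI set is a subset of the whole-cell set.

Aggregation per ROI is either the photon-weighted mean of the four
per-pixel fitted parameters (`pixel_mean`) or a single refit of the four
summed histograms (`pooled_refit`). Pooling quadruples the photons per fit
and measurably lowers a2% RMSE at low counts, so the end-to-end pipeline
defaults to it. Both modes preserve a1% + a2% = 1. ROIs containing
unfitted or unconverged pixels are flagged invalid, not dropped silently.

## Redox metrics

FLIRR = NAD(P)H-a2% / FAD-a1% per ROI; a zero FAD bound fraction marks the
ROI invalid rather than emitting infinity. The intensity ratio uses raw ROI
photon sums (FAD/NAD(P)H) without any normalisation — deliberately, so the
attenuation sensitivity of the classical readout is visible. E% =
(1 − τm/τ_D)·100 with τ_D = 3.1 ns as a configurable constant; negative E%
(τm above the donor reference) is returned as computed and flagged so
miscalibration stays visible. Per-pixel FLIRR images are rendered from the
a2%/a1% maps with a fixed value→colour range shared across panels
(default [0, 1.2], perceptually uniform colormap) so control/treatment
shifts are visually comparable; invalid pixels take a reserved colour and
out-of-range values clamp (counted in the log).

## Cohort statistics

The cell-level statistic is the median over ROI values throughout (means
are also emitted). Cells need a configurable minimum of valid ROIs
(default 5); control and treatment join on (FoV, cell) since the same
field of view is re-imaged. Responder categories are half-open intervals
[low, high) with the last interval closed — the shipped example scheme
25–55 / 55–85 / 85–125 % shares endpoints, so a deterministic boundary rule
is mandatory; an equal-count tertile auto-scheme is available. Values
outside all intervals are "uncategorized", a value rather than an error.
Frequency histograms use the same half-open/last-closed convention. The
FLIRR–E% correlation is Pearson's r on per-cell medians (a per-ROI variant
exists behind the same function's inputs); fewer than 3 pairs or zero
variance yields a flagged NaN. Glycolysis attribution reports the
whole-cell minus mitochondrial percent-change increment with a qualitative
call at a configurable margin (default 5 percentage points).

## Synthetic scenes

Scenes emulate the assay's specimen structure, not its optics: elliptical
non-overlapping cells (rejection-sampled), a concentric nuclear ellipse,
and mitochondria as dilated random-point blobs in the cytosol. Blob
defaults (seed density 0.02 of cytosol pixels, disk radius 2) make
aggregates resolvable at the 2×2-pixel ROI scale — a requirement of the
thresholded-ROI premise itself: sub-ROI granularity would make every block
a mixture and mitochondrial isolation impossible for any fitter.
Channel physiology is built in: FAD is effectively mitochondria-only
(cytosolic brightness a tenth of mitochondrial, small but nonzero so
whole-cell ROIs retain a FAD denominator), NAD(P)H reports both
compartments, and the nucleus emits low but nonzero NAD(P)H so nuclear
exclusion must come from the mask, not the threshold.

Decay truths are synthetic conventions, order-of-magnitude consistent with
the autofluorescence literature: NAD(P)H 0.4 ns free / 2.5 ns bound (bound
= a2%), FAD 0.3 ns bound / 2.8 ns (bound = a1%), Trp 1.0 ns quenched /
3.1 ns unquenched (quenched = a1%). Default bound fractions: mitochondrial
NAD(P)H 0.30, cytosolic 0.20, FAD 0.60, Trp quenched 0.30. Default
brightness (photons/pixel): NAD(P)H 400 mito / 80 cytosol / 20 nucleus;
FAD 300 / 30 / 15; Trp 150 / 100 / 50; background 0.5. An `exposure`
multiplier emulates acquisition depth; the recovery and heterogeneity
studies run at exposure 6.25, i.e. ~10⁴ NAD(P)H photons per pure
mitochondrial ROI, the signal scale those studies are stated at
(thresholds scale with exposure).

A treatment shifts bound fractions per cell through one response
multiplier m (defaults: mitochondrial NAD(P)H +0.10·m, cytosolic NAD(P)H
+0.10·m, mitochondrial FAD −0.08·m, Trp quenched +0.12·m), drawn from
Normal(1, spread) or set explicitly; post-effect fractions clip to
[0.01, 0.99] with logging. Because the deltas are linear in m, the
multiplier that produces an exact target mitochondrial FLIRR change has a
closed form, which is how strata with known ground-truth categories are
built. Optional per-channel brightness factors emulate the intensity-side
redox response (NAD(P)H photons down, FAD up) that the fraction deltas
alone cannot produce. Coupling the Trp quench to the same multiplier makes
the FLIRR–E% correlation positive by construction — the synthetic
validation therefore shows the pipeline *recovers* an implanted coupling,
not that such coupling exists in any real specimen.

**What passing tests show.** Ground-truth recovery through simulated
Poisson data validates the estimator chain (fit → ROI → metric → cohort)
under the generator's assumptions: piecewise-constant compartment truths,
known Gaussian IRF, no scattering/PSF blur, no photobleaching, no motion,
manual-quality masks. Depth attenuation is modelled only as channel-wise
photon scaling, sufficient for the FLIRR-vs-intensity robustness property
but silent on wavelength-dependent IRF or spectral bleed-through. Real
acquisitions violate these idealisations to unknown degrees; passing tests
bound implementation error, not biological validity.

## Problem sizes

Validation studies use scaled-down scenes chosen to exercise every code
path with comfortable statistics: 80×80 or 96×96 fields with 3–5 cells and
128-bin histograms for end-to-end studies (pooled-refit aggregation;
~100–130 mitochondrial ROIs per field), 256-bin single-decay studies with
100–270 replicates, and 20-seed cohorts (60 cells) for category recovery.
The generator's 256×256 / 5-cell defaults remain available and are used by
the CLI's default configuration at smaller scene sizes for speed.

## Known limitations

- No phasor analysis, no 3-component fits, no global lifetime linking.
- No automatic segmentation; label masks are inputs.
- NADH/NADPH are pooled as NAD(P)H (spectrally inseparable); no attempt to
  identify FRET-competent enzymes.
- The intensity ratio is deliberately un-normalised; absolute values are
  not comparable across instruments.
- SPCImage-equivalence is not claimed; the fitting contract is
  "two components at reduced χ² ≈ 1" with an explicit, documented model.
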