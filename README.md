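# flimredox

A segmented-cell FLIM redox assay for multiphoton autofluorescence imaging of
cellular metabolism. The package fits per-pixel TCSPC decays of the three
metabolic autofluorophores — tryptophan (Trp), NAD(P)H and FAD — and analyses
them in 2×2-pixel thresholded regions of interest inside manually segmented
cells, separating mitochondrial (OXPHOS) from whole-cell-minus-nucleus signal
so that the cytosolic (glycolytic) contribution can be read off as the
difference.

## Who it is for

Microscopists and image analysts working with time-correlated single photon
counting (TCSPC) FLIM of live cells or tissue who want intensity-independent
redox readouts, per-cell response statistics under treatment, and a fully
synthetic test bed (ground-truth scenes) for validating each analysis stage.

## The model and the readouts

Each pixel's photon-arrival histogram is modelled as a two-component
exponential decay convolved with the instrument response function (IRF),
with the tails of all preceding laser pulses (80 MHz, 12.5 ns period)
summed in closed form:

    I(t) = [ a1·e^(−t/τ1) + a2·e^(−t/τ2) ] ⊛ IRF + background,

fitted by Poisson maximum likelihood (Neyman-weighted least squares as an
option) and reported with the Pearson reduced χ². The intensity-normalised
amplitude fractions

    a1% = a1/(a1+a2),   a2% = a2/(a1+a2)

remove overall brightness from the parameters. For NAD(P)H the long-lived
component is the enzyme-bound species (a2% = bound fraction); for FAD the
bound species is short-lived (a1%). From these the package computes, per
2×2-pixel ROI:

- **FLIRR** (fluorescence lifetime redox ratio) = NAD(P)H-a2% / FAD-a1%.
  Rises with OXPHOS activity and, unlike the classical intensity redox ratio
  FAD/NAD(P)H, is insensitive to scattering, attenuation and illumination
  drift — the property that makes it usable deep in tissue.
- **Intensity redox ratio** = FAD photons / NAD(P)H photons, for comparison.
- **Trp FRET efficiency** E% = (1 − τm/τ_D)·100 with
  τm = τ1·a1% + τ2·a2% the amplitude-weighted donor lifetime and
  τ_D = 3.1 ns the unquenched Trp reference; enzyme-bound NAD(P)H quenches
  Trp, so E% tracks metabolic activity alongside FLIRR.

Per cell, ROI values are reduced to medians; the percent median FLIRR change
from control to treatment assigns each cell to a responder category
(low / medium / high, e.g. 25–55 / 55–85 / 85–125 %), and the whole-cell
excess over the mitochondrial change is attributed to glycolysis.

## Worked example

```python
import numpy as np
from flimredox import (BiExpParams, FitOptions, IRFModel, TimeAxis,
                       simulate_decay, fit_biexp, flirr, fret_efficiency)

axis = TimeAxis()                      # 256 bins over a 12.5 ns (80 MHz) period
irf = IRFModel(center=1.0, fwhm=0.2)   # Gaussian instrument response

# NAD(P)H decay: 30% enzyme-bound (tau2 = 2.5 ns), 70% free (tau1 = 0.4 ns)
truth = BiExpParams(a1=7000, a2=3000, tau1=0.4, tau2=2.5)
hist = simulate_decay(truth, irf, axis, total_photons=10_000, seed=1)
fit = fit_biexp(hist, irf, FitOptions(background=0.0))
print(f"a2% = {fit.a2_pct:.3f}   tau1 = {fit.params.tau1:.3f} ns   "
      f"tau2 = {fit.params.tau2:.3f} ns   chi2_r = {fit.chi2_reduced:.2f}")

ratio = flirr(nadh_a2_pct=fit.a2_pct, fad_a1_pct=0.60)
print(f"FLIRR = {ratio:.3f}")
print(f"Trp E% at tau_m = 2.47 ns: {fret_efficiency(2.47):.1f}%")
```

prints

```
a2% = 0.293   tau1 = 0.426 ns   tau2 = 2.526 ns   chi2_r = 1.09
FLIRR = 0.488
Trp E% at tau_m = 2.47 ns: 20.3%
```

The recovered bound fraction (0.293 vs the simulated 0.30) carries the
expected shot-noise uncertainty at 10⁴ photons; dividing by a mitochondrial
FAD bound fraction of 0.60 gives a FLIRR near the 0.5 ground truth, and a
Trp mean lifetime of 2.47 ns corresponds to ~20 % transfer efficiency
against the 3.1 ns donor reference.

The full pipeline — synthetic field of view, TCSPC cubes, per-ROI fits,
redox metrics, responder categories, colour-coded FLIRR panels — runs from
the command line:

```bash
flimredox run-all --out-dir out/            # defaults; or --config my.yaml
```

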