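# mcdrs — inverse Monte Carlo diffuse reflectance spectroscopy

`mcdrs` models and inverts fiber-probe diffuse reflectance spectroscopy
(DRS) of layered, blood-bearing media. It is written for researchers in
biomedical optics who study the skin microcirculation: the quantities of
interest are the red blood cell tissue fraction (f_RBC), the hemoglobin
oxygen saturation (SO₂), the average vessel diameter (D), and the reduced
scattering coefficient μs′(λ), estimated from white-light intensity spectra
recorded at two source–detector separations (0.4 and 1.2 mm) over
475–850 nm.

## The model

A three-layer medium — epidermis of thickness *t*₍epi₎ over a 200 μm upper
dermis and a semi-infinite lower dermis — is parameterized by ten variables
(*t*₍epi₎, α, β, γ, c₍heme,1₎, c₍heme,2₎, SO₂, D, f₍mel₎, γ₍mel₎):

- reduced scattering, shared by all layers:
  μs′(λ) = α[(1−γ)λ^(−β) + γλ^(−4)]
- epidermal (melanin-like) absorption:
  μa,epi(λ) = f₍mel₎ · 6.6×10¹⁰ · λ^(−γ₍mel₎)
- dermal absorption with vessel packaging:
  μa,n(λ) = c₍heme,n₎ · c_vd(λ) · μa,heme(λ), where
  c_vd = (1 − e^(−D·μa,heme)) / (D·μa,heme) → 1 as D → 0, and
  μa,heme = (1−SO₂)·μa,Hb + SO₂·μa,HbO₂
- f_RBC = c₍heme₎ / 31 g/dl (mean cell hemoglobin concentration).

The forward problem is solved by "white" Monte Carlo: photon paths are
presimulated without absorption on a grid of epidermis thicknesses and
scattering levels, and Beer–Lambert attenuation over the recorded per-layer
path lengths yields the detected intensity for any absorption spectrum —
exactly, per photon record. The inverse problem is a box-constrained
trust-region least-squares fit of all model parameters at once to the
dual-distance spectra, with a coarse Latin-hypercube multistart and a
weighted error function that emphasizes the 500–600 nm hemoglobin bands.
Spectra whose hemoglobin signature is too weak for a reliable inversion are
excluded by the *heme-area* gate: the area between the 1.2 mm spectrum and
the chord connecting its values at 506 and 614 nm must exceed 1.5.

Because no public dual-distance phantom spectra exist, the package ships a
first-class synthetic experiment generator: yeast-deoxygenated
blood/intralipid liquid phantoms (pO₂ 160 mmHg decaying to ~1 mmHg,
converted to SO₂ by the Severinghaus dissociation curve), and a 20-piece
matrix of solid two-layered phantoms (coffee-surrogate epidermis slabs over
spectrally damped freeze-dried-hemoglobin dermis slabs, four replicate
probe placements each).

## Worked example

```python
import numpy as np
from mcdrs import (ProbeGeometry, build_lut, LiquidPhantomScenario,
                   simulate_liquid_experiment, FitConfig, fit_batch)

lut = build_lut(ProbeGeometry(), n_photons=150_000, seed=1)   # a few minutes
scenario = LiquidPhantomScenario(frbc=0.008, seed=5)          # 0.8% RBC
exp = simulate_liquid_experiment(scenario, lut)
results = fit_batch(exp.spectra, lut, FitConfig(seed=2), mode="liquid-phantom")
for t, truth, res in zip(exp.times_min, exp.so2_truth_percent, results):
    print(f"t={t:4.0f} min  SO2 true {truth:5.1f}%  fitted {res.so2_percent:5.1f}%"
          f"  fRBC {100*res.frbc1:.2f}%  D {res.d_um:.1f} um")
```

prints (abridged; the fitted values track the Severinghaus conversion of
the decaying pO₂ while the 0.8% RBC fraction and the zero vessel diameter
are recovered):

```
t=   1 min  SO2 true  99.4%  fitted  99.4%  fRBC 0.80%  D 0.6 um
t=   8 min  SO2 true  92.4%  fitted  92.6%  fRBC 0.80%  D 0.8 um
t=  12 min  SO2 true  43.1%  fitted  42.6%  fRBC 0.80%  D 0.5 um
t=  20 min  SO2 true   0.7%  fitted   0.6%  fRBC 0.80%  D 0.2 um
```

The same machinery is available from the shell:

```sh
mcdrs lut-build --out lut.h5 --n-photons 200000 --seed 1
mcdrs phantom-solid --lut lut.h5 --out-dir solids --seed 7
mcdrs qc-hemearea solids/solid_*.tsv
mcdrs evaluate --mode liquid --lut lut.h5 --seed 2 --out-dir report
```

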