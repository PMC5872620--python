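# Methods

This note records the modelling choices behind `mcdrs`, the assumptions
they rest on, and what the synthetic experiments do and do not demonstrate.

## Photon transport and the path-length table

Transport is simulated in a three-zone semi-infinite medium (epidermis /
200 μm upper dermis / semi-infinite lower dermis) with a Henyey–Greenstein
phase function at g = 0.8. Because the model prescribes one reduced
scattering spectrum for all layers, anisotropy enters only through the
similarity relation μs = μs′/(1−g), and the internal layer boundaries are
optically transparent; only the top surface refracts (tissue n = 1.4
against ambient n = 1.0 by default; both configurable, including a
probe-contact variant with silica above).

Photons launch uniformly over the 200 μm source-fiber face, uniformly in
solid angle inside the refracted NA = 0.37 acceptance cone. At the surface
the unpolarized Fresnel reflectance decides reflection versus escape;
escaping photons are detected if they exit within an annulus |r − ρ| ≤
r_det around either source–detector separation ρ ∈ {0.4, 1.2} mm and
inside the NA cone. The annulus-to-fiber-face area ratio r_det/(4ρ) is
folded into the per-node normalization so channel intensities are
per-fiber. Each detected record stores the per-layer path lengths (their
sum is the total path exactly; the rounding residue is assigned to the
deepest layer), the maximum depth reached, and the photon weight.

"White" simulations carry no absorption; Beer–Lambert applied to the raw
records afterwards is then exact per record, which a direct absorbing run
verifies within Monte Carlo error in the test suite. Tracking stops when
the total path exceeds 200 mm or the photon strays 20 mm from the source;
at the smallest absorption the model evaluates (~0.01 mm⁻¹ at 800 nm)
the truncated tail carries ~2% of Beer–Lambert weight, and since the same
table generates and inverts the synthetic spectra the truncation cancels
from recovery comparisons. Records are reservoir-thinned above a 6000 per
node/channel cap (never reached at the default photon counts) with the
thinning factor kept in the normalization.

The lookup table covers t_epi ∈ {0, 75, 150, 300, 600} μm ×
μs′ ∈ {0.5, 1, 2, 4} mm⁻¹; queries interpolate bilinearly in (t_epi, μs′)
per wavelength and refuse to extrapolate. Node seeds derive
deterministically from the table seed and grid indices, so tables,
spectra, and whole evaluation reports are bit-reproducible. The library
default is 10⁶ photons per node; the shipped evaluation script uses
1.5×10⁵ and the test suite 3×10⁴, which leaves a few-percent Monte Carlo
texture in the table that cancels out of generation-versus-fit
comparisons.

## Forward spectra and the sampling volume

The detected intensity at wavelength λ is the node-mixed Beer–Lambert sum
I(λ) = Σ w·exp(−Σ_l μa,l(λ)·s_l). Intensities are relative (per launched
photon); no absolute radiometric calibration or spectral instrument
response is modelled. The 770–810 nm notch band (laser-suppression filter
in the instrument this emulates) is excluded from all fitting and metrics;
the default grid is 475–850 nm at 2 nm (1 nm available).

Where the detected light samples the medium is summarized per layer in two
ways, both Beer–Lambert weighted and averaged over included wavelengths
and both channels:

- **depth partition** (default): the share of detected weight whose
  deepest excursion ends in each layer — a spatial reading of the
  interrogated region;
- **path share**: each layer's share of the weighted path length,
  Σ w·e^(−μ·s)·s_l / Σ w·e^(−μ·s)·s_tot.

The path share systematically attributes 30–45% of the short-separation
signal to a 250–300 μm epidermis (every detected photon must cross it
twice, and surface re-reflections recross it), which contradicts the
behaviour expected of these probes — at least three quarters of the
sampling volume in the dermis for epidermis layers up to 300 μm. The depth
partition reproduces that behaviour and the expected orderings (dermis
share lowest for strongly absorbing dermis, lower for thicker epidermis,
higher for more absorbing epidermis), so it is the default; the expected
μs′ of a layered medium is the fraction-weighted layer average in either
convention (a no-op here, since the model shares μs′ across layers).

## The inverse fit

The residual compares log-intensities per channel, weighted ×3 inside the
500–600 nm hemoglobin bands and zero in the notch band. Two intensity
conventions are supported:

- **mean-normalized** (default): each channel is divided by its mean over
  the included band before the log, making fits invariant to per-channel
  gain — appropriate for uncalibrated instruments, and the convention the
  scale-free heme-area threshold relies on;
- **calibrated** (`FitConfig(normalize=False)`): absolute log-intensities.
  The solid-phantom evaluation uses this, because its hemoglobin
  signatures are only a few percent of the signal and the shape-only fit
  then loses the μs′/c_heme scale (errors of tens of percent), while the
  synthetic acquisitions share the forward model's absolute scale exactly
  as a radiometrically calibrated instrument would.

Internally the optimizer works on bound-scaled variables in [0,1]^n with
the scattering magnitude parameterized by μs′(600 nm) and the epidermal
absorber by μa,epi(525 nm) (α and f_mel are recovered afterwards); both
substitutions decorrelate the box. Default bounds: t_epi ∈ [25, 600] μm
in vivo and [0, 600] μm for solid phantoms (bare slabs occur in that
matrix), μs′(600) ∈ [0.55, 3.9] mm⁻¹, β ∈ [0, 4], γ ∈ [0, 1], c_heme ∈
[0, 10] g/dl, SO₂ ∈ [0, 1], D ∈ [0, 200] μm, μa,epi(525) ∈ [0, 5] mm⁻¹,
γ_mel ∈ [2, 5]. If a candidate's μs′(λ) leaves the table hull it is
evaluated at the clipped value and the excess joins the residual as a
linear penalty, keeping the trust-region step well-defined while pushing
back inside.

The multistep search screens 32 Latin-hypercube starts on a 4×-thinned
grid, refines the best 3 by trust-region-reflective least squares on a
2×-thinned grid (≤600 residual evaluations), and polishes the winner at
full resolution (≤300); ties break on the smaller bound-scaled parameter
norm, tolerances are 10⁻⁸, and finite differences use a 10⁻⁴ step on the
unit box. All counts are configurable; one seed fixes the whole procedure.
Degenerate inputs (non-positive or flat spectra) raise a quality error;
batch fits isolate per-item failures and reuse the same seed per item, so
identical spectra give identical results.

## Heme-area gate

The heme-area divides the 1.2 mm spectrum by its mean over the included
band, draws the chord between the values at 506 and 614 nm, and integrates
|chord − spectrum| by the trapezoid rule (endpoints interpolated). Spectra
with area ≤ 1.5 are excluded. Mean normalization makes the statistic
scale-free, but the absolute calibration of the 1.5 cutoff in the
instrument convention it originates from is not documented; this
implementation reproduces the orderings and the threshold partition of the
fabricated phantom matrix, not necessarily the original absolute scale.

## Synthetic experiments: what they emulate

**Chromophores.** The shipped Hb/HbO₂ tables are synthetic
re-tabulations: monotone (PCHIP) interpolations through widely published
visible/NIR extinction anchors with the isosbestic points pinned at
506/522/548/569/586/~800 nm, at a 15 g/dl whole-blood reference. They are
swappable text files; absolute band-shape details differ from any single
published compilation.

**Liquid phantoms.** A homogeneous blood/intralipid medium at f_RBC 0.8%
or 1.6% (c_heme = 31·f_RBC g/dl), intralipid-like scattering
(μs′(500) = 2.8 mm⁻¹, β = 2.4), pO₂ starting at 160 mmHg and decaying as
dpO₂/dt = −k·(cumulative yeast dose)·pO₂ with doses of 0.3 packet every
2 min and k = 0.15 min⁻¹packet⁻¹ — a smooth monotone decay to ~1 mmHg
over a 20-minute, 20-acquisition run, spanning SO₂ ≈ 99% → 1% through the
Severinghaus conversion. Temperature is held at 37 °C and the dissociation
curve is used at its standard calibration; pH and pCO₂ drifts that shift
the real curve are not modelled.

**Solid phantoms.** Twenty combinations: two dermis slabs with spectrally
damped hemoglobin (a convex blend of the Hb table with its own 60 nm
running-mean baseline, damping 0.7), bare or under one of nine epidermis
slabs (three coffee-surrogate absorber levels × three thicknesses as
fabricated: none 90/155/270 μm, low 75/160/260 μm, high 70/160/210 μm),
TiO₂-like scattering μs′(500) = 2.5 mm⁻¹, β = 0.9 in all slabs, four
replicates with 1% multiplicative noise plus a 10⁻⁴ relative dark floor.
The "saturated" counterpart table transplants the liquid HbO₂/Hb ratio
onto the damped spectrum, so ground-truth SO₂ is zero by construction.

The effective dermis concentrations (0.005 and 0.010 g/dl, the 2:1
fabrication ratio) and coffee levels (μa(500) = 0.6 / 1.2 mm⁻¹, decay
constant 140 nm) were calibrated once so the replicate-averaged heme-areas
reproduce the fabricated matrix's reported scale and threshold partition
(bare dermis well above the gate, roughly half of the coffee-covered
combinations below it, with the observed orderings). The implied optical
weakness is a real property of freeze-dried hemoglobin in silicone — the
particles act as pigment, not dye — and is precisely why the gate exists.

**What passing tests do and do not show.** Generation and inversion share
the forward model and the path-length table, so recovery experiments
measure the estimator's conditioning under the stated noise, not model
error against a real instrument: real measurements add calibration drift,
probe-pressure and contact artifacts, chromophore-table mismatch, and
layer-dependent scattering that the shared-μs′ model cannot represent. The
coffee-versus-melanin shape mismatch in the solid fits is deliberate and
produces the expected small biases (noiseless SO₂ recovery within
~2 %-units on coffee-covered slabs, exact on coffee-free ones; the test
suite computes these).

## Known limitations

- With the gate calibrated to the fabricated matrix's heme-area scale, the
  included solid spectra carry only 2–5% hemoglobin modulation; under the
  prescribed 1% per-sample noise the SO₂ of a single measurement is then
  determined only to several %-units (the acceptance run computes the
  realized RMS). This is an information limit of the weighted
  least-squares estimator at these signal levels, not an optimization
  failure: noiseless recovery is sub-percent, and stronger multistarts
  reproduce the same noisy optima.
- Epidermis thickness and the epidermal absorber are weakly identified —
  expected for this probe geometry — and carry no acceptance bound.
- The path-length table's Monte Carlo noise (test and desk scales) cancels
  from recovery comparisons but would appear as model error against data
  generated by any other transport code.
- The heme-area's absolute calibration and the original sampling-volume
  definition are reconstructed conventions (documented above), chosen to
  reproduce reported orderings and partitions.
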