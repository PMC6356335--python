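# scaffoldscope

Quantitative analysis of spatial periodicity in histological sections of
degrading biopolymer (chitosan / allylchitosan) films, plus the supporting
measurements that characterize such films: X-ray diffractogram d-spacings,
pore morphometry of scaffold surfaces, degree of substitution from ¹H NMR
integrals, and tensile-property deltas.

## Who this is for

Materials scientists and biomedical researchers who implant biodegradable
polysaccharide films/scaffolds and want to ask, from a stained section
image: *are the degradation bands placed periodically, at which spatial
scales, and are those scales linked?* The same toolbox covers the routine
desk analyses around that question (Bragg's law, pore statistics, DS
arithmetic) so the whole workflow is scriptable and testable.

## The method

A section image is reduced to a calibrated 1D profile of averaged pixel
intensities versus position x (µm). The profile f(x) is analyzed with a
continuous wavelet transform using the Mexican-hat (MHAT) basis

    ψ(t) = 2/(√3·π¼) · (1 − t²) · e^(−t²/2)

    W(a, b) = a⁻ᵖ ∫ f(x) ψ((x − b)/a) dx ,   p = 1 (L1) or ½ (L2)

over a log-spaced grid of scales a. The matrix of coefficients over
(spatial period λ, position b) is the *waveletgram*; averaging |W| along
the position axis (inside the cone of influence) gives the *integral
spatial spectrum*, whose pronounced maxima are the dominant banding
periods. Scale is converted to period via λ = a·2π/√2 (L1) or a·2π/√2.5
(L2) — the period of peak sinusoidal response under each normalization.
Chains of coefficient maxima linked across scales ("ridges") are
classified as **tree** structures when they span several octaves
(cascade-linked periodicities) or **grass** when they stay in one scale
band (isolated periodicity).

Supporting analyses: Bragg's law d = nλ/(2 sin θ) for diffractogram maxima;
Otsu segmentation + connected-component pore tables (area fraction,
equivalent-circle diameters, size-bin fractions); degree of substitution
DS = 100·u/T from proton-count-normalized NMR integrals; elongation-at-break
deltas against a reference film.

Because no public datasets accompany these analyses, `scaffoldscope.synthgen`
generates every input with known ground truth — banded profiles/images,
porous surfaces, diffractograms, NMR integral sets — so the full pipeline is
exercised end to end and every estimator is validated against planted truth.

## Worked example

```python
from scaffoldscope import synthgen, profiles
from scaffoldscope.mhat_cwt import cwt
from scaffoldscope.spectral import integral_spectrum, find_peaks
from scaffoldscope.xrd import bragg_d

# banded section profile: 3 mm long, 2 µm sampling, periods 10/80/420 µm
profile, truth = synthgen.make_stripe_profile(synthgen.histology_stripe_spec(), seed=1)
profile = profiles.detrend(profile, "linear")

peaks = find_peaks(integral_spectrum(cwt(profile)), prominence_frac=0.2)
for p in peaks:
    print(f"period {p.period_um:7.2f} um   power {p.power:.3f}   prominence {p.prominence:.3f}")

for tt in (10.0, 15.0, 20.0):
    print(f"2theta = {tt:4.1f} deg  ->  d = {bragg_d(tt):.3f} A")
```

prints

```
period    9.96 um   power 1.043   prominence 0.274
period   79.87 um   power 1.023   prominence 0.663
period  421.00 um   power 1.005   prominence 0.632
2theta = 10.0 deg  ->  d = 8.838 A
2theta = 15.0 deg  ->  d = 5.901 A
2theta = 20.0 deg  ->  d = 4.436 A
```

The three spectrum maxima recover the planted banding periods to within 1%;
the d-spacings are the interplanar distances of the film's pseudocrystalline
reflections at 2θ = 10°, 15°, 20° (Cu Kα₁), with d(10°)/d(20°) ≈ 2 — two
diffraction orders of the same ≈4.4 Å plane stack.

The same stages are available from the shell:

```sh
scaffoldscope simulate stripes --out section --seed 1
scaffoldscope profile section.png --pixel-size-um 2 --out profile.csv
scaffoldscope cwt profile.csv --out wg.npz
scaffoldscope spectrum wg.npz --out spectrum.csv
scaffoldscope report --seed 1 --out report.json   # all of the above in one go
```

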