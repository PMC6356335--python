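# Methods

## Profile extraction

A stained section image is collapsed to one channel (Rec. 709 luminance by
default; a single channel — typically red for picrosirius-type stains — can
be selected instead, since the analysis is agnostic to which contrast the
user trusts) and averaged perpendicular to the film axis to give intensity
versus position in µm. Positions are pixel-center based and start at 0; the
film's long axis is assumed to be the longer image dimension unless the
caller overrides it, because section micrographs do not themselves declare
an orientation. Profiles are detrended ("linear" by default) before the
wavelet stage: the Mexican hat is blind to constants, but a strong linear
trend leaks into the largest scales of the spectrum.

## Mexican-hat continuous wavelet transform

The transform is computed from scratch (it is the package's core), by
per-scale FFT convolution with the sampled wavelet truncated at ±6a
(tail < 2·10⁻⁸). The sampled kernel is re-centered to sum exactly to zero
(discrete admissibility), so a constant profile transforms to numerical
zero at every scale; a direct-quadrature oracle and a cross-check against
PyWavelets' `mexh` transform validate the implementation in the tests.

Normalization and the scale→period map. With L1 normalization
(W = a⁻¹∫f·ψ(·/a)) a unit sinusoid's matched-scale amplitude is
independent of its period, so equal-amplitude banding at different scales
produces equal spectral peaks; with L2 (a^{-1/2}) the matched response
grows as √a and large-scale peaks dominate the spectrum. L1 is therefore
the default for spectra whose peak heights are compared across scales.
The period of peak response differs between the conventions: the response
to period λ is maximal at aω = √2 under L1 and aω = √2.5 under L2, giving
Fourier factors λ/a of 2π/√2 ≈ 4.4429 and 2π/√2.5 ≈ 3.9738 respectively.
The transform maps its period axis with the factor matching its
normalization; with a single shared factor, L1 spectra would recover all
planted periods with a systematic −10.5% bias (√2/√2.5 − 1), which we
verified empirically before making the mapping normalization-aware.

Boundaries. Profiles are extended by reflection (default) or zeros by one
kernel half-width. The cone of influence marks, per scale, positions at
least λ/√2 from either edge (the e-folding distance √2·a expressed in
periods); it is carried as a mask and respected by the spectrum, never
applied destructively. Exact translation covariance holds in the stricter
region where the ±6a kernel support never touches the padding; inside the
e-folding cone, edge effects are below ~0.5% of the peak coefficient.

Scale grid. Default: 64 log-spaced periods from 2·Δx (Nyquist) to L/4,
which spans the 5–500 µm banding range of film sections at 1–2 µm
sampling. Periods below 2·Δx raise an error; the upper bound corresponds
to scale ≤ L/4, beyond which almost no position lies inside the cone.

## Integral spatial spectrum and peaks

The spectrum is the position-average of |W| ("mean_abs", default) or W²
("mean_square") at each period, using in-cone positions only; a scale with
no in-cone position gets NaN (missing, not zero). Signed averages would
cancel the oscillations, and the spectra being emulated are everywhere
positive. Pronounced maxima are strict local maxima (endpoints excluded)
with topographic prominence ≥ 20% of the global maximum by default — the
threshold is an explicit parameter, since "pronounced" is not a defined
quantity. Peak periods are refined by parabolic interpolation on the
log-period axis, which brings single-tone recovery from the ~8% voice
spacing down to ≈1–3%.

## Ridges and tree/grass classification

At each scale the strict positive local maxima of the signed coefficients
(inside the cone, above 15% of the global maximum coefficient) mark the
bright bands; maxima at adjacent scales are linked into chains when the
position drift is at most 0.5·λ, nearest-first and one-to-one, which makes
the linking deterministic. A chain's period span in octaves classifies it:
**grass** below 3.5 octaves, **tree** at or above.

The 3.5-octave threshold is set by the wavelet's own scale bandwidth: a
single pure tone's response (s²e^{−s²/2}, s = aω) stays above 15% of its
maximum across ≈3.1 octaves of scale, so its (perfectly vertical) ridge
chains span ≈3 octaves even though only one periodicity exists. Only
chains that bridge *distinct* scale bands — as amplitude-modulated
(cascade-linked) banding produces — exceed the threshold. Consequences to
be aware of: two independent tones closer than ≈2.5 octaves have
overlapping response bands and can merge into one chain (the classifier
cannot distinguish adjacency from modulation at that separation), and
strong noise creates spurious maxima that let chains wander across scales
— the classification is meant for clean or strongly banded profiles, and
its tests construct exactly those.

## Bragg / diffractogram analysis

d = nλ/(2 sin θ) with λ = 1.5406 Å (Cu Kα₁) by default. Peaks are local
maxima with prominence ≥ 10% of the intensity range, parabolically refined
on the 2θ grid and annotated with d. The "reverse similarity" between a
spatial spectrum (period axis, µm) and a diffractogram (d axis, Å) is
quantified as the Pearson correlation of the two z-scored curves after
each log-length axis is affinely mapped to [0, 1] and both are resampled
on a shared 64-point grid. The two length ranges differ by four orders of
magnitude, so only this shape-level comparison is computable; it is an
interpretation of a qualitative visual comparison, not a claim about any
particular physical mapping between the axes.

## Pore morphometry

Pores are the below-threshold class of an Otsu (or fixed) threshold —
dark-pores convention, invertible by flag — labelled with 8-connectivity.
Components under `min_area_px` (default 4) are dropped from the table as
noise, but the image-level area fraction is computed from the raw mask
first, so Σ per-pore areas / image area equals the reported fraction
exactly whenever nothing is filtered (and the tests that assert the exact
identity pass `min_area_px=1`). Pore size is the equivalent-circle
diameter 2·√(area/π); size-bin fractions use half-open bins [lo, hi) and
are counts of pores, not area-weighted. Feret-type descriptors are not
implemented; equivalent diameter is the single documented size measure.

## NMR degree of substitution

Integrals are converted to unit amounts by dividing by the proton count of
each signal (H2 of free-amine units: 1H; N-acetyl methyl: 3H; N- and
O-allyl vinylidene: 2H each). The unit total T = u_H2 + u_acetyl +
u_N-allyl partitions the backbone by its nitrogen state; O-allylation is
modeled as an independent event on the same population (an O-allyl group
does not remove its own unit's H2 proton), so DS_O = 100·u_O/T can
approach 100 independently of DS_N and is capped there with a warning.
This is the simplest model consistent with the signal assignments; the
synthetic forward model mirrors it exactly, and a property test verifies
that compute_ds inverts it to machine precision over the whole fraction
grid. Multiple O-substitution per unit is out of scope.

## Synthetic generators: what they emulate, what they do not

* **Stripe profiles/images** — sums of sinusoids (period, amplitude,
  phase) on a baseline with additive i.i.d. Gaussian noise; in cascade
  mode every shorter-period component is multiplied by
  (1 + m·envelope of the longest period), m = 0.8 by default, which
  produces scale-linked ridges without asserting any particular physical
  mechanism for the linkage. The canonical section emulation is 3 mm long
  at 2 µm sampling with equal-amplitude banding at 10, 80 and 420 µm and
  noise σ = 0.2 (SNR 5 per component). Real sections add non-stationary
  amplitude, stain variability and structured (non-Gaussian) texture, so
  passing tests demonstrate estimator correctness on the stated model, not
  performance on arbitrary histology.
* **Pore images** — hard (non-overlapping, by default) disks with
  diameters from a normal distribution truncated at 2·pixel_um, placed by
  rejection sampling; a drawn disk keeps its diameter while retrying
  positions, because redrawing on collision would bias accepted disks
  small (we measured the planted mean dropping from 4.5 to ≈3.9 µm at 30%
  packing before fixing this). Defaults: 384² px at 0.5 µm/px, target
  fraction 0.30, diameters N(4.5, 1.5) µm, which puts ≈⅔ of pores in the
  3–6 µm bin. Real SEM pores overlap, have irregular shapes and graded
  rims; none of that is emulated.
* **Diffractograms** — Gaussian peaks (not pseudo-Voigt) over a polynomial
  background, noiseless; sufficient for position/ratio recovery, not for
  profile-shape work. The film-like recipe has maxima at 10°, 15° (weak)
  and 20° with the 15° width kept narrow enough that the 20° tail shifts
  its apex by ≪0.1°.
* **NMR integral sets** — the exact forward model above, with an arbitrary
  common scale factor; no peak shapes, baselines or overlap.

All generators take explicit integer seeds (bit-identical outputs per
seed) and return a JSON-round-trippable ground-truth record.

## Problem sizes and numerical choices

The test suite and the acceptance script run the banding analysis on
1500-sample profiles (64–96 voices), the recovery-rate study on 100 seeded
400-sample runs, and pore morphometry on 384² images (~600 disks); these
sizes give sampling errors comfortably below the tolerances being checked
while keeping the whole suite in the tens of seconds on one core. Peak
ties are broken toward larger period by the refinement's concavity guard;
degenerate inputs (constant images for Otsu, empty pore tables, all-masked
scales, sub-Nyquist periods) raise errors naming the violated constraint
rather than returning silent zeros.

## Known limitations

Single-channel reduction only (no stain unmixing); 1D transform only (no
2D CWT); ridge classification degrades under heavy noise and for tones
closer than ≈2.5 octaves (above); pore segmentation has no watershed
splitting, so touching real-world pores would merge; the DS formula is one
consistent reading of the signal assignments, not a community standard;
and the spectrum–diffractogram correlation compares shapes on normalized
axes, deliberately avoiding any physical scale correspondence.
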