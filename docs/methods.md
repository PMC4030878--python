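# Methods

This note documents the models, defaults and numerical choices behind
spectramix, and what the synthetic experiments do and do not demonstrate
about real spectral-imaging data.

## Wavelength grid and spectra

All spectra live on an evenly spaced emission grid; the default spans
450–800 nm in 36 bands (10 nm spacing), the working range of the
instrument class being emulated. Intensities are nonnegative reals in
arbitrary "counts" units — only relative quantities are ever reported, so
no camera gain model is applied. Grid equality is strict (same start,
stop and band count); combining objects on different grids requires an
explicit linear-interpolation resample, which prevents silent band
misalignment. Library reference spectra are **area-normalized** (sum to
one) rather than peak-normalized, so unmixing coefficients carry
total-signal meaning: a coefficient is the total number of counts that dye
contributes to the pixel.

## Synthetic scenes

The generator emulates the two specimen types used to validate this kind
of pipeline.

**Emission model.** Each fluorochrome is a single Gaussian centered on its
catalogued emission peak, default FWHM 30 nm, sampled at band centers and
normalized to unit sum. The catalog carries the reporter dyes (FITC 528,
Cy3 565, Cy3.5 596, Texas Red 620, Cy5 667, Cy5.5 703, DAPI 461 nm) and
the calibration beads (515, 560, 605, 660 nm, plus the red/infrared 645,
680, 695 nm set). Real dye spectra are asymmetric with long red tails; a
Gaussian keeps the overlap structure (neighbouring dyes 20–40 nm apart)
while staying fully parametric. Excitation and filter physics are
collapsed into per-object brightness scalars.

**Bead fields.** Four beads (one dye each, 8 px diameter disks ≈ 2.5 µm
at the emulated magnification) at fixed positions in a 64×64 field.
Replicates share the layout and brightness but receive independent noise
and an integer stage-jitter translation of ≤ 2 px. Default peak-band
signal is 5000 counts (10000 for the brighter red/infrared panel), chosen
so shot-noise-limited CVs land well below the few-percent reproducibility
reported for physical beads.

**Cell mixtures.** Cells are disks (radius 5 px) with a concentric
nucleus (radius 3 px) whose DAPI signal is rendered into a separate
reference image, mirroring the separate DAPI filter acquisition of the
real workflow. Two populations differ only in mean per-dye brightness:
the majority profile has the ABL/PTK6-analogue reporters high and the
RET-analogue (FITC) low; the rare profile inverts this, mirroring the
breast-cancer vs. thyroid-cancer expression contrast. The number of rare
cells is exactly `round(rare_fraction × n_cells)`, and a `rare_elevation`
of e % multiplies the rare population's target-dye mean by (1 + e/100).
Per-cell biological variability is a mean-one log-normal factor per cell
and dye, default CV 20% (cell-cycle-scale variation; the source
observations note it qualitatively without quantifying it).

**Signal composition.** Noiseless signal = flat background +
optional broad autofluorescence spectrum + Σ objects Σ dyes brightness ×
emission; ground-truth totals are the exact noiseless per-object sums.
Optional band-sequential photobleaching multiplies band *b* by
(1 − rate)^b, reflecting fading over the time a full spectrum takes to
record; default off. Shot noise is Poisson on counts; read noise is
additive Gaussian. What the generator does **not** model: optical PSF and
diffraction, 3-D structure, chromatin texture, cell clumping, focus drift
and ROI-definition ambiguity. Those are precisely the error sources that
dominate physical replicate CVs, so the simulated CVs (≈ 0.5%) should be
read as a shot-noise floor consistent with, not a reproduction of, the
2–6% measured on real beads.

## Interferometric acquisition

Forward model: I(d) = Σ_b S(λ_b)(1 + cos(2π d/λ_b))/2 on a one-sided OPD
schedule from 0 to max OPD, default 128 frames (instrument range 80–130)
with step 180 nm = 450/2.5 nm, comfortably above the Nyquist requirement
(step < λ_min/2); schedules violating Nyquist raise an aliasing error.
Shot noise, when enabled, is applied per frame — at the detector, where it
physically arises.

Reconstruction subtracts the interferogram mean, applies a Hann window
(suppressing ringing from the finite OPD range), and evaluates the cosine
transform at the band wavenumbers 1/λ_b. A finite one-sided OPD range of
~23 µm cannot fully resolve 10 nm bands at the red end of the grid (the
band spacing in wavenumber, ~1.6×10⁻⁵ /nm at 800 nm, is below the window
mainlobe width), so the raw transform carries known cross-talk between
neighbouring bands. Because the pre-clamp pipeline is linear, this
cross-talk is exactly the response matrix K obtained by pushing unit band
spectra through the same transform; reconstruction solves K·s = c with a
truncated pseudoinverse (relative singular-value cutoff 1e-9). At 128
frames K is well conditioned (~5×10³) and the solve is exact to machine
precision; at 80 frames K is numerically singular and truncation yields a
blurred but stable estimate, so more frames never reconstruct worse.
Negatives (tiny at 128 frames) are clamped to zero and the spectrum is
rescaled so its total equals I(0), which makes integrated intensities
robust even where band-level noise is amplified. The whole pipeline also
runs with acquisition bypassed (synthetic cube used directly); downstream
results agree within the reconstruction tolerance.

## Unmixing

The default `clamp` mode reproduces the instrument software's documented
behaviour — unconstrained least squares with negative coefficients
reported as zero; `nnls` (scipy's Lawson–Hanson solver) is the
statistically preferable alternative and is verified in the tests against
an independent exhaustive grid-search oracle. The residual L2 norm is
computed with the *reported* (post-clamp) coefficients and kept per pixel
so unmodelled autofluorescence is visible downstream. A background
spectrum in the library is fitted as an extra component and excluded from
the named abundances; pre-subtracting an estimated background spectrum is
also supported, and applying both is allowed but logged. Libraries whose
normalized reference matrix has condition number above 10⁶ are rejected
with the most-similar pair named — two references that close are not
distinguishable at realistic noise levels.

## Segmentation

Seeded region growing admits 4- or 8-connected pixels whose total
intensity lies within a relative tolerance of the seed's and whose
spectral angle to the seed spectrum is below a threshold; spectral angle
is brightness-invariant, so the two criteria are complementary. Admission
is breadth-first and capped by a pixel budget. DAPI-guided cell
segmentation takes connected components above the Otsu threshold
(minimum nucleus area 20 px to reject specks), orders nuclei by raster
position of their centroids for stable labels, and expands each nucleus
by 6 px (default) with contested pixels going to the nearest nucleus,
ties resolved deterministically. This is a compact stand-in for watershed
segmentation, adequate for disk-shaped synthetic cells; it makes no
attempt to declump aggregates beyond nearest-nucleus assignment.

## Quantification and detection

Per-ROI totals are reported as area × average so the headline identity
holds exactly in floating point; relative percentages are per-dye shares
of the summed dye signal, excluding the background component and the
residual. Replicate CVs use the sample standard deviation (n−1), the
right choice at the replicate counts involved (~9). Cross-replicate
object matching removes the best global translation and then pairs
nearest centroids within 10 px, erroring loudly on any unmatched object.
Rare-cell detection baselines on the **median** of target-dye totals
(robust to the rare cells themselves) and flags cells at or above
baseline × (1 + threshold/100), with a five-cell minimum.

A caveat worth stating plainly: flagging a cell whose mean is elevated by
exactly e % with a threshold set to that same e places the cell on the
decision boundary — with any per-cell biological variability, detection
probability is ~50% regardless of e. Reliable detection requires the
true difference to exceed the threshold with margin (as in the worked
detection example, 60% above baseline against a 50% threshold), or a
threshold set below the smallest difference one wants to catch. The
elevation scan in `scripts/acceptance.py` deliberately keeps
threshold = elevation to characterize this boundary behaviour honestly.

## Problem sizes and determinism

The validation protocols use 64×64 bead fields (4 beads, 9 replicates,
median over 20 seeds) and ~150×150 cell fields (100 cells); these sizes
give per-object photon statistics comparable to the emulated experiments
while keeping a full protocol run in the tens of seconds on one CPU. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration and seed give
byte-identical outputs, and noise-free rendering is fully deterministic.
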