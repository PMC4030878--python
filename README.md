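# spectramix

Simulation and analysis of multispectral fluorescence image cubes, built
around the workflow of Sagnac-interferometer spectral imaging: record a full
emission spectrum at every pixel, decompose it into known fluorochrome
contributions, and quantify per-cell reporter levels — down to detecting a
single aberrant cell among a hundred.

The package is aimed at people developing or validating multiplexed
RNA-FISH / spectral-imaging analysis: it provides a synthetic ground-truth
generator (calibration bead fields, two-population cell mixtures), a
physically motivated acquisition model, and the complete downstream
analysis chain, so every stage can be tested against known truth.

## The model

**Acquisition.** A Sagnac interferometer splits the light at each pixel
into two beams with a stepped optical path difference (OPD) *d*. For band
intensities *S*(λ<sub>b</sub>) the recorded interferogram is

> I(d) = Σ<sub>b</sub> S(λ<sub>b</sub>) · (1 + cos(2π d / λ<sub>b</sub>)) / 2,

so I(0) is the total intensity. The default schedule takes 128 frames with
an OPD step of 180 nm (safely above Nyquist for the 450 nm grid edge).
Reconstruction mean-subtracts and Hann-apodizes the interferogram,
evaluates the cosine Fourier transform at the band wavenumbers
1/λ<sub>b</sub>, and corrects the residual band cross-talk with the
schedule's known response matrix; negatives are clamped to zero and the
total is rescaled to I(0).

**Unmixing.** Each pixel spectrum **y** is modelled as **y** ≈ R **a**
with R the matrix of area-normalized reference spectra (up to 9, plus an
optional background component) and **a** ≥ 0 the per-dye abundances.
`clamp` mode fits ordinary least squares and zeroes negative coefficients
(the behaviour of the original instrument software); `nnls` mode solves the
true nonnegative least-squares problem.

**Quantification.** An ROI is reported as area, per-dye average intensity
per pixel, total (= area × average), and relative contribution in percent
of the summed dye signal. Reproducibility across replicate images is the
coefficient of variation CV = 100·sd/mean (sample sd) of per-object totals.
Rare-cell detection flags cells whose target-dye total is at least
(1 + threshold/100) × the cohort median.

## Worked example

Nine replicate images of a four-bead calibration field, acquired through
the interferometric forward model with shot noise, unmixed and integrated
over ground-truth ROIs:

```python
import spectramix as sm
from spectramix.protocols import bead_reproducibility

per_bead, avg = bead_reproducibility(seed=1)
for dye, cv in zip(sm.BEAD_PANEL, per_bead):
    print(f"{dye:15s} CV = {cv:.3f}%")
print(f"average CV = {avg:.3f}%")
```

```
bead_green      CV = 0.442%
bead_orange     CV = 0.721%
bead_red        CV = 0.676%
bead_deep_red   CV = 0.648%
average CV = 0.622%
```

Each CV is the replicate-to-replicate variability of one bead's total
fluorescence; under pure shot noise at ~5000 peak counts the simulated
system reproduces totals to well under 1%, comfortably inside the few-
percent reproducibility a physical instrument achieves (where focus drift
and ROI-definition variability dominate).

The same pipeline is scriptable from the shell:

```sh
spectramix simulate --kind beads --replicates 9 --noise shot --seed 1 --out sim/
spectramix unmix --cube sim/rep000.tiff --library lib.json --out unmixed/
spectramix quantify --abundance unmixed/ --labels sim/rep000_labels.tiff --out quant/
```

Every run writes a `manifest.json` recording the exact configuration, seed
and package versions.

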