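# imatct

Quantification of **intramuscular adipose tissue (IMAT)** — myosteatosis —
from calibrated CT volumes of the lower leg, for researchers studying
sarcopenia and muscle quality with ex-vivo micro-CT (8.4 µm) or in-vivo
HR-pQCT (82 µm) scans. The package also ships the two companion tools such a
study needs: an Oil-Red-O histology morphometer for validating the imaging
readout against stained sections, and the statistical layer (Pearson
correlation tables, pooled t-test, power-based group sizing) used to relate
imaging metrics to age and physical function.

Because clinical and animal scan data of this kind are rarely shareable, the
package includes a first-class synthetic phantom generator with voxel-exact
ground truth; every pipeline guarantee is stated — and tested — against it.

## Method

A denoised volume (separable truncated Gaussian, σ = 2.5, support = 5
voxels; HR-pQCT scans are then block-averaged ×2 to 164 µm) is segmented by
an STA-style protocol: bone (≥ 600 HU) and skin (a fixed depth from the
exterior air) are excluded, seed volumes are planted by closed-interval HU
bands (muscle 100–600 HU, fat −600…−200 HU), and both compartments are grown
for 20 deterministic region-growing iterations. The muscle region of
interest (ROI) is the filled muscle contour; it is **peeled by 3 voxels**
(6-connected erosion) to discard partial-volume borders. IMAT is then the
fat-band intersection with the peeled ROI — band (−600, 100) HU for
micro-CT, (−600, −20) HU for HR-pQCT — and the outcome record is

    MV      muscle ROI volume after peel            [mm³]
    MD      mean attenuation over the ROI           [HU]
    IMAT%   100 · IMAT volume / MV
    IMAT/MV IMAT volume / lean volume
    MCSA    MV / stack height                       [mm²]

plus TV, MV/TV and the subcutaneous fat density FD. Histological lipid
content is quantified as the percentage of pixels inside fixed HSB intervals
(hue 228–255, saturation 167–255, brightness 0–255 on the 0–255 ImageJ
scale), averaged over four fields per specimen.

## Worked example

Generate a synthetic leg with 10 % intramuscular fat and 30 HU acquisition
noise, then run the clinical pipeline on it:

```sh
$ imatct phantom --fat-fraction 0.10 --noise-sd 30 --seed 7 --out leg.nii.gz
wrote leg.nii.gz (true fat fraction 0.0981)

$ imatct imat leg.nii.gz --preset HRpQCT --out-dir out --specimen-id leg
MV=3206.055 mm^3  MD=225.94 HU  IMAT%=9.690  MCSA=407.273 mm^2
```

The true fat fraction of this phantom is 9.81 %; the pipeline recovers
9.69 % — within the ±2 percentage-point envelope the phantom study
guarantees. MD sits below the pure-muscle mean (300 HU on this scanner's
effective scale) exactly because a tenth of the ROI is fat at −400 HU. The
CSV row in `out/leg_metrics.csv` carries the full record together with a
hash of the effective configuration; re-running the same command reproduces
it bitwise.

The same library surface is importable directly
(`imatct.run_phantom_validation()`, `imatct.pearson()`, …); the CLI
subcommands `segment`, `oro`, `validate` and `cohort-stats` cover the
remaining workflows.

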