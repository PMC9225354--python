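# Methods

## Imaging model and units

All volumes are handled as 3-D scalar fields in Hounsfield-like units (HU)
with isotropic voxels. The segmentation bands this protocol inherits
(muscle 100–600 HU, fat −600…−200 HU) sit far above diagnostic-CT
soft-tissue attenuation (~50 HU muscle), which implies a vendor-specific
effective HU scale; the package adopts that scale as-is and makes no claim
that it equals clinical HU. An optional linear map to hydroxyapatite
density (mgHA/cm³) is carried as metadata only, since no conversion
constants are fixed by the protocol.

## Denoising and downscaling

The denoising filter is a separable truncated Gaussian with σ = 2.5 voxels
and truncation radius ("support") 5 voxels per side, giving 11-tap axis
kernels renormalised to unit sum — so constants are preserved exactly.
"Support" is read as the truncation radius (the Scanco convention for
σ/support pairs). Borders are mirror-reflected; the protocol leaves the
border policy open, and reflection avoids attenuation bias at the skin/air
interface. The HR-pQCT workflow downscales 82 µm → 164 µm by non-overlapping
2³ block averaging (trailing voxels dropped) — averaging, not interpolation,
because the step exists to reduce noise. Filtering is applied at
acquisition resolution before downscaling (the order is exposed as
`RunConfig.downscale_first` for users who prefer the reverse); the combined
point-spread at the 164 µm working grid is then σ ≈ 1.35 working voxels.

## Segmentation

All thresholds are closed intervals (lo ≤ x ≤ hi), consistent with the
inclusive phrasing of lower/upper thresholds throughout.

1. **Exterior air**: voxels ≤ −800 HU connected to the volume border.
   Enclosed gas pockets are not exterior.
2. **Bone**: components ≥ 600 HU larger than `min_seed_size_vox`,
   morphologically closed (radius 1) to bridge trabecular gaps.
3. **Skin**: non-air voxels within `skin_depth_vox` (default 4) restricted
   dilation steps of the exterior air.
4. **Seeds**: band threshold ∩ allowed voxels, eroded once, components
   < `min_seed_size_vox` (default 27) removed.
5. **Region growing**: exactly `iterations` (default 20) synchronous
   rounds. Each round every unassigned voxel adjacent (6- or
   26-connectivity, default 6) to a grown region whose relaxed band (band
   widened by `relaxed_margin_hu`, default 100 HU) contains its HU joins
   that region; a voxel eligible for both goes to the region whose nominal
   band midpoint is closer, ties to muscle. The update is computed
   volume-wide per round, so the result is independent of voxel traversal
   order; with zero margin and enough iterations it equals a breadth-first
   flood fill of the band-restricted component containing the seeds (tested
   against exactly that oracle).

The vendor's STA v2.0 algorithm is proprietary; this module is a documented
approximation built from its published knobs (bands, seed planting,
20 iterations). Every unstated constant lives in `SegmentationConfig` with
the defaults above and is serialised with every run.

**Muscle ROI.** The grown muscle label excludes intramuscular fat (fat-band
voxels) by construction, but the ROI a reader would contour encloses it.
The ROI is therefore derived per axial slice: the muscle label is
morphologically closed (`roi_closing_vox` = 4 rounds, bridging small gaps
where fat approaches the fascia) and its enclosed 2-D holes are filled;
bone, skin and air are always subtracted afterwards. Slice-wise filling is
used because an inclusion clipped by the first or last slice is still
enclosed in-plane, whereas a 3-D fill would treat it as open.

## IMAT quantification

The ROI is peeled by `peel_vox` = 3 rounds of 6-connected binary erosion
(anti-extensive; peel(m, a+b) = peel(peel(m, a), b)), discarding the
partial-volume border. IMAT = fat-band ∩ peeled ROI, with band presets
(−600, 100) HU for 8.4 µm micro-CT and (−600, −20) HU for HR-pQCT. The
(−600, −20) default follows the two consistent statements of the adjusted
human band over a third conflicting one ("−20 to 100 HU"), which remains
reachable via configuration. MD is the mean HU over the peeled ROI
*including* IMAT voxels (MD and IMAT% are two characteristics of one ROI); a
lean-only density `MD_lean` is exposed as auxiliary output. Denominators:
IMAT% = 100·IMAT/MV uses the peeled ROI volume; IMAT/MV uses the lean
volume (ROI − IMAT), making the two ratios distinct outputs. MCSA divides
MV by the full axial stack height. An empty ROI yields a record flagged
undefined rather than a division error.

## The phantom generator

The phantom emulates what the scanner sees, at acquisition resolution
(default 96×384×384 voxels at 82 µm ≈ 7.9 mm of a ~31 mm-wide leg):
concentric cylinders of bone (1500 HU), muscle (300 HU), subcutaneous fat
(−400 HU), skin (0 HU) and air (−1000 HU), with ellipsoidal IMAT inclusions
(−400 HU) and i.i.d. Gaussian HU noise per acquired voxel. Tissue means sit
mid-band on the scanner's effective scale.

Design choices that matter, and why:

* **Uniform fat density.** Inclusion centres are sampled with uniform areal
  density (radius drawn as √U, axial positions overhanging the faces) and
  voxels clipped to the muscle compartment, so the expected fat density is
  flat across the compartment — the fraction measured in any peeled
  sub-region is then an unbiased estimate of the true fraction.
* **Fascia clearance.** Inclusions keep `fascia_clearance_vox` = 5
  acquisition voxels (≈ 0.4 mm, i.e. 2.5 working voxels) clear of the
  subcutaneous interface. Real IMAT is enclosed by the fascia; without the
  clearance, inclusions merge seamlessly into subcutaneous fat, a topology
  no anatomy exhibits and no contour-based method can resolve. The wall is
  just thick enough that, after the protocol's blur, it stays inside the
  relaxed muscle band, keeping the muscle contour closed regardless of how
  inclusions cluster.
* **Inclusion size.** Semi-axes are uniform integers in 7–11 acquisition
  voxels (0.6–0.9 mm). A numerical characterisation of the blur transfer
  (thresholding a blurred ball at the band edge) shows inclusions below
  ~0.3 mm radius vanish entirely at the working point spread — a physical
  property of the imaging chain — while the chosen sizes are recovered at
  85–95 % of their volume, which offsets the small fat-free fascia shell in
  the truth denominator. Both effects are at the percentage-point level and
  are covered by the ±2 pp recovery envelope.
* **Exact bookkeeping.** Placement stops when the achieved fraction is
  within 0.002 of the target (error if the geometry cannot reach it); the
  achieved fraction, not the request, is the recorded truth.

What the phantom does **not** model: scanner physics (beam hardening, ring
artefacts, motion), anatomical shape variation, multiple muscle groups,
marrow, and spatially correlated noise. Passing the recovery study
therefore demonstrates correctness of the segmentation/quantification chain
under controlled contrast and noise, not clinical accuracy on real legs.

The ORO image generator thresholds a smoothed random field at an exact
pixel count (blob-shaped droplets, exact ground truth) and colours positive
pixels strictly inside the protocol's HSB bands — with margin for 8-bit
rounding — and background strictly outside (low saturation), so the fixture
fraction is recovered exactly under default thresholds.

The cohort simulator is a linear-Gaussian chain: age ~ U(18, 81); MD, IMAT%
and MV are linear in age; chair-rise time is linear in IMAT%; quadriceps
strength is linear in MD; all with independent Gaussian noise. Default
slopes/noise (MD −1.2 HU/yr, sd 18.5 HU; IMAT +0.15 pp/yr, sd 4.05 pp) give
closed-form correlations r(age, MD) ≈ −0.76 and r(age, IMAT%) ≈ +0.56,
matching the magnitude of reported ageing effects; chained pairs follow
r(X,Z) = r(X,Y)·r(Y,Z). `CohortSpec.closed_form_correlations()` returns the
analytic values the sample estimates are tested against (±0.03 at
n = 5000).

## Statistics

Pearson r with the two-tailed t-distribution p (t = r√((n−2)/(1−r²)),
n−2 df), simple least squares (R² ≡ r² checked to 1e−12), and the
pooled-variance (not Welch) two-sample t-test, cross-checked against an
exhaustive C(8,4) = 70-relabeling permutation oracle on 4-vs-4 fixtures; in
the far tail the permutation distribution is quantised at 1/70, so
agreement is asserted on fixtures away from that resolution floor. Group
sizing uses the two-sided normal approximation
n = ⌈2(z₁₋α/2 + z_power)²(σ/δ)²⌉ — the reading under which δ = 30, σ = 15,
80 % power, α = 0.05 gives n = 4 — with an exact noncentral-t option that
never returns fewer subjects. Correlation tables star p < 0.05 and
p < 0.01 without multiple-testing correction, mirroring observational
practice; Benjamini–Hochberg adjustment is available but off by default.
Normality testing is delegated to standard library routines and is not part
of this surface.

## Numerical and engineering choices

* Degenerate inputs fail loudly: zero-variance correlation input, inverted
  bands, 2-D volumes, missing voxel-size metadata, volumes with no exterior
  air.
* Every pipeline run serialises its effective configuration and a 12-hex
  SHA-256 config hash into its outputs; identical config + input reproduce
  outputs bitwise.
* Problem sizes: the recovery study uses 96×384×384 phantoms (≈ 14 M
  voxels, ~2.5 s per pipeline run after generation), chosen so that
  boundary discretisation contributes well under a percentage point to the
  recovered fraction while a full 4 × 3 grid completes in about half a
  minute on one CPU.
* CLI exit codes: 0 success, 2 configuration error, 3 I/O error, 4 stage
  failure; logs go to stderr, results to files/stdout.

## Known limitations

* The STA approximation is documented, not vendor-faithful; absolute
  agreement with µCT Evaluation Program outputs is not claimed.
* The HR-pQCT IMAT band (−600, −20) was set visually in the source
  protocol; its accuracy on real tissue is inherently subjective, and the
  phantom can only show self-consistency under the stated contrast model.
* Histology quantification assumes the stain's hue lies in the non-wrapping
  228–255 interval; a wrap-around option exists for other stains but is
  untested against real slides.
* Single-muscle-group ROI only; inter-muscular (between-group) fat and
  myotendinous tissue are out of scope.
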