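# Methods

This note records the models behind `shgmorph`, the parameter choices
that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want explained.

## Imaging model and channel semantics

A stack is a 3-channel nonnegative intensity volume on an anisotropic
voxel grid `(dx, dy, dz)` µm, slice `k` at depth `k·dz` with `k = 0` at
the objective-facing surface. Channels are addressed by name in the
canonical order **(AF, bSHG, fSHG)**:

* **AF** — two-photon autofluorescence (~525 nm band), the broadest
  tissue marker; largely preserved in necrotic fibers.
* **bSHG** — backward-detected second harmonic (405 nm), dominated by
  fibrous collagen of the extracellular matrix.
* **fSHG** — forward-detected second harmonic, dominated by the
  myosin-II thick filaments of intact myofibrils; it carries the
  sarcomere striation and vanishes when myofibrillar order is lost.

On disk stacks are OME-TIFF (CZYX, uint16, physical sizes in the OME
metadata); readers never invent voxel sizes — a file without them
requires an explicit override or errors.

## Synthetic muscle generator

The generator produces the study conditions every analysis stage is
validated against. Its content model, with defaults:

* **Geometry.** Quasi-cylindrical myofibers run in-plane at a
  configurable axis angle; their circular cross-sections are packed on a
  jittered hexagonal lattice in the (cross-axis, depth) plane, tilted
  19° against the slice plane so single slices sample all packing
  phases. Diameters are 24 ± 3 µm (mouse EDL range), separated by an
  endomysial gap of 1.5 in-plane voxels and wrapped in a 1.5 µm collagen
  sheath. Fibers undulate laterally (amplitude 5 µm, period 60 µm along
  the axis, drifting slowly with depth). The waviness is not cosmetic:
  perfectly straight fibers concentrate all boundary-edge spectral power
  on a single cross-fiber ridge in frequency space, which a periodicity
  detector will find, and they align fiber-free bands with any axis-
  aligned tile grid. Assignment is nearest-center with radii capped so
  neighbours keep the gap.
* **Channels.** fSHG inside fibers is a raised sinusoid along the fiber
  axis, `gain·(1 + c·cos(2π a / SL_i + φ_i))`, with default contrast
  c = 0.35, per-fiber random phase and 1% per-fiber sarcomere-length
  jitter (biological variability; it also gives slice-level statistics
  genuine within-group variance). bSHG fills the sheath. AF fills the
  tissue with a smooth ±10% seeded texture, at full level in the
  myofiber cytoplasm and 0.5× in the collagen sheath (cellular NAD(P)H/
  FAD autofluorescence differs from collagen autofluorescence; a
  uniform AF would make fiber-poor regions indistinguishable from
  necrosis in the fSHG:AF ratio). All channels pass a lateral Gaussian
  resolution kernel of σ = 0.5 µm — the instrument's diffraction-limited
  lateral resolution; without it, hard sarcolemma edges alias square-
  wave harmonics into the sarcomere frequency band.
* **Necrosis.** A lesion (ellipsoid by center/radii, radii relative to
  the volume, or an explicit mask; optionally sized by bisection to hit
  a target tissue fraction) in which myofibrillar order is lost: the
  fSHG banding is removed and the level drops to `gain × 0.02`, while
  AF and bSHG are multiplied by their ablation factors (default 1.0).
  The flat residual, rather than a scaled copy of the banding, reflects
  the biology — necrotic fibers are void of coherent striation — and is
  required for the periodicity detector to flag necrotic slices invalid:
  a coherent 2% residual grating integrated over ~5·10⁴ pixels would
  still be detected with enormous prominence.
* **Attenuation and noise.** Slice `k` of channel `c` is scaled by
  `exp(−k·dz/d_c)`; `d = 200 µm` in the "native" preset (uncleared
  muscle), `d = 5000 µm` in the "cleared" preset (TDE-like, flat over a
  millimetre). Detector noise is Poisson on the photon counts
  (channel gains 80/60/120 photons for AF/bSHG/fSHG) plus Gaussian read
  noise (sd 1.0 counts) and an optional constant offset (default 0:
  photon-counting PMT detection; a non-zero offset floors the
  exponential depth profile and is deliberately opt-in).
* **Determinism and paired controls.** Every stochastic ingredient
  draws from a stream keyed by `(seed, purpose)`, channel streams by
  channel identity. Identical config + seed is bit-identical; a config
  differing only in its necrosis specification shares the exact AF and
  bSHG realisations — `sham_twin()` exploits this to build matched
  CTX/sham pairs (common random numbers). Under independent seeds a
  rank test between two healthy stacks has a uniform p-value by
  construction, so "no difference" claims are made against the matched
  control, as in a paired experiment.
* **Presets.** "native" (d = 200 µm), "cleared" (d = 5000 µm), "ctx"
  (cleared + a laterally wide, depth-bounded lesion — relative radii
  (1.4, 1.4, 0.55), depth-extent bisected to cover 30% of tissue).

What the generator does **not** emulate: optical physics beyond the one
resolution kernel (no scattering, polarization or 3D PSF), vessels,
nuclei, inflammation, fascicle-scale architecture, regeneration time
courses, or coupling of fSHG yield to sarcomere length. Passing tests
therefore demonstrate correct recovery of the generative model's
parameters under realistic noise — not performance on real tissue with
its unmodelled heterogeneity.

## Tissue mask

The mask thresholds the smoothed AF channel (in-plane Gaussian,
σ = 2 µm) in two passes: a provisional global Otsu establishes the
typical tissue level; each slice is then rescaled by its own 99th
percentile and a second global Otsu on the normalised volume gives the
final mask. The per-slice scale must not be conditioned on the
provisional mask: in an attenuating stack the provisional mask keeps
only the brightest deep-slice voxels, any within-mask statistic drifts
bright with depth, and the resulting mask shrinks toward fiber cores —
which biased the fitted depth constant by +5–20% in testing. The
whole-slice percentile carries no such selection. Slices whose 99th
percentile falls below 5% of the provisional tissue level are treated
as beyond the sample and left empty, which keeps mounting-medium slices
out of downstream fits. Degenerate volumes (constant AF) yield all-true
or all-false masks without error.

## Depth profiles and attenuation fits

Per-slice means are taken over mask voxels (whole-frame without a
mask); slices with no mask voxel get NaN. The fit is ordinary least
squares of `ln(mean)` against depth over slices with tissue fraction
≥ 0.2 (default) and positive means; `d = −1/slope`, with `I₀`, r² and
the slice count reported. Log-linear rather than nonlinear least
squares: deterministic, initialisation-free, and exactly the
mono-exponential hypothesis. A slope above −10⁻⁶ µm⁻¹ reports the
infinite-depth-constant sentinel (cleared-like profile) rather than a
meaningless huge number. Fewer than 3 qualifying slices is an error.
Measured recovery at desk scale: median relative error 0.2–0.5% across
generative d ∈ {100, 200, 400} µm.

## Sarcomere-length estimation

Per slice, on fSHG: Hann window → 2D FFT power spectrum with physical
frequency axes → search annulus `1/4.0 … 1/1.5` cycles/µm (the
physiological and fixed-tissue SL band; configurable) on a 5×5
mean-filtered spectrum → peak must reach 5× the median annulus power →
parabolic sub-bin refinement of log-power along each frequency axis →
`SL = 1/f_peak`, orientation = wave-vector angle mod 180°.

Numerical choices:

* **5×5 smoothing before peak picking.** The Hann window correlates
  neighbouring bins; a 3×3 block leaves the white-noise maximum near
  12× the median (false "valid"), 5×5 brings it to ≈ 4, so the default
  threshold of 5 yields a measured white-noise false-valid rate < 1%.
* **Sub-bin refinement** is required for the ±0.05 µm recovery target:
  at 256 px and 0.5 µm pixels the raw bin spacing near SL 2.8 µm is
  ~0.08 µm. Measured recovery error across SL ∈ {1.8, 2.2, 2.8} µm and
  rotations 0–45° is ≤ 0.02 µm.
* **Degenerate guard.** A near-constant image leaks only numerical
  noise into the annulus; the peak must also carry ≥ 10⁻⁹ of total
  spectral power to count.
* **Estimation unit** is the whole slice; stack aggregation averages
  valid slices only and reports `n_valid`.

Known limitation: at zero banding contrast but full signal level the
detector can lock onto residual fiber-packing texture at the band edge
(prominence ≈ 5–6), so the valid fraction degrades monotonically toward
zero contrast but need not reach zero. Necrotic tissue is flagged
invalid because ablation removes the signal level as well as the
structure.

## Ratios, necrosis tiles and group statistics

Per-slice mean intensities (tissue-masked by default) form the four
ratios fSHG:AF, bSHG:AF, bSHG:fSHG and (fSHG+bSHG):AF; zero-denominator
entries are undefined, counted, and excluded — never imputed.
Normalising to AF cancels slice-level intensity fluctuations, which is
why ratios rather than raw means carry the group statistics.

The necrosis map tiles each slice in 25 µm (default) in-plane tiles —
about one fiber diameter, fine enough to resolve a demarcation line
between neighbouring fibers. Tiles under 50% tissue are background; the
rest are necrotic when their tissue-restricted mean-fSHG:mean-AF falls
below the threshold rule: Otsu on the tile-ratio histogram (needs a
genuinely bimodal stack), `fixed:V`, or `reference` — half the median
tile ratio of a healthy reference stack, the recommended rule and the
right one for possibly-homogeneous stacks. The necrotic volume fraction
is the necrotic share of tissue tiles. Measured at desk scale: mean
absolute fraction error ≈ 0.03 over lesion fractions {0.1, 0.3, 0.5},
voxelised tile-label Jaccard vs truth ≈ 0.78–0.87.

Group comparisons use the two-sided Mann–Whitney U on per-slice ratios
(robust to the skewed ratio distributions; the test identity is recorded
in every result object), requiring ≥ 10 defined slices per group.
Sarcomere-length groups are compared by one-way ANOVA plus Tukey HSD.
**Statistical unit caveat:** slices from one contiguous stack share a
fiber population; treating them as independent pseudo-replicates that
population and inflates F. For protocol comparisons the simulated
experiments sample slices ≥ one fiber diameter apart in depth (fresh
fibers per slice); with real data the same caution — muscles, not
slices, as the replication unit — applies.

## Spectra

`restrict_band` truncates to 400–800 nm (below 400 nm the measurement is
scattering-dominated); `transmittance_fold_change` computes per-λ
`fold = 10^(A_native − A_cleared)` on identical grids (mismatch is an
error — no silent interpolation) and reports both the band mean of the
per-λ fold (headline) and the fold of the band-mean absorbance
difference. The packaged native/TDE preset spectra are seeded synthetic
stand-ins — a smooth scattering-like OD decrease with wavelength, the
TDE curve offset by a 2.3–2.6× transmittance gain growing toward long
wavelengths — generated by a function, not shipped data files.

## Pipeline

`run_pipeline` executes simulate/load → mask → depth fits → sarcomere
table → ratios → necrosis map (+ optional spectra) from one config
mapping, writing CSVs, a tile-label TIFF and `summary.json` stamped with
seed, SHA-256 config hash and package version. With a fixed config and
seed all text outputs are byte-identical across reruns. Any stage
failure aborts with the stage name attached.

## Problem sizes

Default validation volumes are 128–256 px in-plane (90–180 µm at 0.7 µm
pixels) and 60–150 slices at dz = 4 µm (240–600 µm depth), with the
depth-constant recovery run at 256×256×150. These sizes keep every
simulated experiment on a laptop-class CPU while leaving ≥ 4–6 fibers
per field and ≥ 2.4 attenuation lengths of depth leverage — the two
quantities that actually control recovery accuracy at this scale.
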