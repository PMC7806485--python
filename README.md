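# shgmorph

Label-free 3D multiphoton morphometry of whole skeletal muscle.

Two-photon imaging of optically cleared muscle yields three intrinsic,
stain-free contrasts per voxel: autofluorescence (**AF**, ~525 nm),
backward-scattered second harmonic generation (**bSHG**, 405 nm,
dominated by fibrous collagen) and forward-scattered SHG (**fSHG**,
dominated by myofibrillar myosin-II). `shgmorph` turns such 3-channel
volumes into quantitative morphometry:

* **Depth attenuation** — per-slice tissue-masked mean-intensity
  profiles and a log-linear fit of `I(z) = I₀·exp(−z/d)`. Uncleared
  muscle decays with a depth constant `d` around 200 µm; clearing agents
  such as 2,2'-thiodiethanol (TDE) push `d` far beyond the sample
  thickness.
* **Sarcomere length (SL)** — the myosin-II striation gives each fSHG
  slice a spatial period of ~2 µm; its peak in the Hann-windowed 2D FFT
  power spectrum at radial frequency `1/SL` cycles/µm is detected in a
  1.5–4.0 µm search band, refined to sub-bin precision, and screened by
  a prominence test so structureless (e.g. necrotic) slices are flagged
  invalid.
* **Necrosis mapping** — necrotic fibers lose fSHG almost completely
  while AF and bSHG persist, so the fSHG:AF ratio collapses locally.
  Per-slice ratios (fSHG:AF, bSHG:AF, bSHG:fSHG, totalSHG:AF) feed
  Mann–Whitney group statistics; a 25 µm tile grid labelled by
  thresholded fSHG:AF yields a necrotic volume fraction and lesion map.
* **Clearing spectra** — absorbance spectra A(λ) are compared as a
  transmittance fold change `10^(A_native − A_cleared)` over 400–800 nm.
* **Synthetic muscle simulator** — seeded, parameterised 3-channel
  volumes (packed wavy myofibers, collagen sheaths, sarcomere banding,
  necrotic lesions, exponential depth attenuation, Poisson + Gaussian
  detector noise) with full ground truth, so every stage above is
  testable without microscope data.

Input stacks are OME-TIFF (CZYX, voxel size in metadata); spectra are
two-column CSV. All analysis is keyed to the canonical channel order
(AF, bSHG, fSHG) by name.

## Worked example

The built-in demo simulates a cardiotoxin-injured (CTX) muscle — a
lesion covering 30% of the tissue in which only fSHG is ablated — plus
its matched sham control (same seed, lesion disabled), and runs the full
analysis:

```bash
shgmorph demo --seed 1 --out demo_out
# necrotic fraction 0.308 (truth 0.300); fSHG:AF CTX vs sham p = 0.00261
```

`demo_out/summary.json` holds the complete report. With seed 1:

* the tile map labels 120 of 389 tissue tiles necrotic — a volume
  fraction of **0.308** against a generative truth of **0.300**;
* per-slice ratio comparisons (Mann–Whitney, n = 60 slices per group)
  find the fSHG-bearing ratios significantly lower in CTX (fSHG:AF
  p = 2.6·10⁻³, totalSHG:AF p = 5.6·10⁻⁴), bSHG:fSHG significantly
  higher (p = 8.5·10⁻³), and bSHG:AF unchanged (p = 1.0, medians 0.056
  in both groups) — the collagen signal does not react to necrosis;
* the stack-level sarcomere length is 2.199 ± 0.017 µm over the 43
  valid (non-necrotic) slices, matching the generative 2.2 µm;
* the packaged native/TDE absorbance presets give a band-mean
  transmittance fold change of 2.50 over 400–800 nm.

The same stages are available as subcommands on real data:
`simulate`, `depth-profile`, `sarcomere`, `necrosis`, `compare`,
`spectra`, and `run` (YAML-configured pipeline). Outputs are CSV tables,
a tile-label TIFF and a JSON summary stamped with seed, config hash and
package version; reruns with the same config and seed are byte-identical.

## Library use

```python
from shgmorph import (preset_config, simulate, estimate_tissue_mask,
                      compute_depth_profile, fit_attenuation,
                      estimate_sarcomere_length_stack)

stack, truth = simulate(preset_config("native", seed=1))
mask, _ = estimate_tissue_mask(stack)
fit = fit_attenuation(compute_depth_profile(stack, mask), "fSHG")
sl = estimate_sarcomere_length_stack(stack)
```

See `docs/methods.md` for the models, parameter choices and known
limitations.
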