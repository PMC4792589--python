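# mirloc

Single-molecule localization microscopy (SMLM) analysis for mapping
individual miRNA molecules inside and around cells — from raw
blinking-fluorophore image stacks to localization tables, super-resolution
renderings, density-based cluster statistics, compartment segmentation, and
exosome co-localization. A full synthetic-acquisition simulator is included
so that every stage of the chain can be exercised and validated without a
microscope.

## Who this is for

Groups doing SMLM (dSTORM/PALM-style) imaging of labelled RNA molecules in
fixed cells who need a scriptable, testable replacement for ad-hoc
reconstruction and cluster-analysis code: localize sparse blinking events,
quantify clustering of the resulting point pattern, count molecules per
subcellular compartment, and relate extracellular signals to GFP-tagged
exosomes.

## The analysis chain

1. **Photon conversion** — EMCCD counts are converted to photon numbers via
   the camera model, `photons = max(0, counts − offset) / g`, with `g` the
   combined EM gain × AD conversion (counts/photon).
2. **Differential stack** — `D[t] = F[t] − F[t+1]`. A positive peak in
   `D[t]` marks a molecule whose emission ended with frame `t`, which
   temporally isolates single emitters.
3. **2D Gaussian fitting** — each detected spot is fitted on the original
   photon frame with a symmetric, pixel-integrated 2D Gaussian
   `b + A·exp(−((x−x₀)² + (y−y₀)²)/(2s²))` by Levenberg–Marquardt;
   the photon count is `N = 2π A s²`.
4. **Localization precision** — per event,

   σ_loc² = (s² + a²/12)/N + 8π s⁴ b² / (a² N²)

   with PSF width `s`, pixel size `a`, photons `N` and background `b`
   (photons/pixel).
5. **Rendering** — each localization is blurred with a unit-mass Gaussian
   of width equal to its own σ_loc, integrated over the target pixel grid.
6. **Cluster analysis** — density-based (DBSCAN-semantics) clustering: a
   core point has ≥ k neighbours within radius r. The two shipped presets,
   `results` (r = 120 nm, k = 5) and `methods` (r = 60 nm, k = 5),
   correspond to critical densities of ⌊(k+1)/(πr²)⌋ = 132 and 530
   molecules/µm² respectively. A Monte-Carlo test against complete spatial
   randomness (CSR) is included.
7. **Segmentation & co-localization** — localizations are counted per
   compartment (nucleus / cytoplasm+membrane / extracellular) through a
   label mask georeferenced to the wide-field image; GFP-exosome spots are
   segmented from a reference channel and miRNA signals are matched to them
   with per-exosome normalization.

The simulator generates CSR, Thomas-process (clustered) and
nanoruler-pair ground-truth layouts, memoryless per-frame blinking with
truncated-exponential photon yields, and EMCCD frames with Poisson shot
noise, camera offset, gain and Gaussian readout noise.

## Worked example

```bash
mirloc run --config demo.yaml --out demo_out
mirloc report --manifest demo_out/manifest.json
```

with a config simulating 8 molecule clusters plus background on a
64 × 64 px field (500 frames, ≥ 1000 photons/event):

```
mirloc run (seed 42)
localizations: n = 591
precision: mean = 2.90 nm, median = 2.73 nm
clusters: n = 20, density = 0.973 per um^2 (cell area 20.56 um^2)
compartments: nucleus 13.4%, cytoplasm 40.3%, extracellular 46.4%
```

591 blink events were localized with a mean theoretical precision of
2.9 nm (events here are bright; dimmer events give the 10–15 nm regime
typical of cellular imaging). The density criterion found 20 clusters —
the 8 simulated molecule clusters plus groups formed by repeated blinks of
single background emitters, the expected behaviour when one fluorophore
fires many times. The compartment fractions refer to the default
elliptical cell geometry of the demo scene.

Each stage is also available separately (`mirloc simulate`, `localize`,
`render`, `cluster`, `segment`, `coloc`), communicating through CSV/TIFF/
JSON files.

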