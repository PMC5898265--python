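# chromaflim

Pixelwise analysis of chromatin compaction by FLIM-FRET, built around
time-correlated single-photon counting (TCSPC) image stacks of a
histone-tagged donor fluorophore (H2B-GFP-style). When chromatin compacts,
nucleosomes carrying donor and acceptor fluorophores move within Förster
distance, FRET rises, and the donor lifetime τ drops — so a per-pixel
lifetime map is a label-density-independent readout of compaction.

The package covers the whole desk side of that experiment:

- **I/O** (`chromaflim.flimio`) — an open container for time-resolved stacks:
  multi-page TIFF (pages = time bins) plus a JSON sidecar with the time axis
  (`n_bins`, `bin_width_ps`, `rep_period_ps`).
- **Synthetic data** (`chromaflim.synthgen`) — nuclei phantoms (euchromatin
  disc + compact heterochromatin foci) with known ground-truth lifetimes,
  Poisson photon noise, IRF convolution and incomplete-decay wrap-around at
  20 MHz; also reference-dye stacks and an immunofluorescence co-stain
  channel. Everything downstream is validated against these phantoms.
- **IRF tools** (`chromaflim.irf_tools`) — parametric (Gaussian) instrument
  response estimated by Poisson maximum likelihood from a reference dye of
  known lifetime.
- **Preprocessing** (`chromaflim.preprocess`) — the fixed conditioning chain:
  temporal binning 4096 → 401 bins, 4×4 spatial binning (512×512 → 128×128),
  5×5 neighborhood photon pooling, and a strict 200-photon intensity
  threshold on unsmoothed per-pixel totals.
- **Decay fitting** (`chromaflim.decay_fit`) — the numerical core. Per pixel,
  expected counts follow a mono-exponential under periodic excitation:

      λ_k = A·s_k(τ) + b,   s(τ) ∝ IRF ⊛_P [e^(−t/τ) / (1 − e^(−P/τ))]

  with P the 50 ns repetition period (incomplete decay from previous pulses
  included), fitted by Poisson maximum likelihood with amplitude and offset
  profiled out; quality control via reduced Pearson χ² (ν = n_bins − 3).
- **Map products** (`chromaflim.chromatin_maps`) — FRET efficiency
  `E = 1 − τ_pixel/τ_ref` against a donor-only reference lifetime,
  intensity-weighted "merged τ" rendering, pixel-lifetime histograms, and
  equal-variance Student's t comparisons of per-nucleus means.
- **Nuclei & IF** (`chromaflim.nuclei_if`) — Otsu-based nuclear segmentation
  on the donor channel, per-nucleus area/mean-τ/co-stain tables, bicubic +
  affine registration of immunofluorescence channels onto the lifetime grid,
  and width-2 two-channel line profiles (e.g. heterochromatin mark vs τ).

## Worked example

Simulate one nucleus (radius 20 px, five compact foci; τ_open = 2600 ps,
τ_compact = 2100 ps; Gaussian IRF centered at 1 ns, FWHM 300 ps; 3000
photons/pixel on a 201-bin, 20 MHz axis), then fit and summarize:

```bash
chromaflim simulate --config sim.json --seed 4 --out stack.tif --if-out if.tif
chromaflim preprocess --in stack.tif --out binned.tif --tbins 201 --sbin 1
chromaflim fit --in binned.tif --irf irf.csv --out maps/
chromaflim fret --tau-map maps/tau.tif --tau-ref 2600 --out fret.tif
chromaflim nuclei --tau-map maps/tau.tif --intensity maps/intensity.tif \
    --if-image if.tif --min-area 200 --out nuclei.csv
```

which prints:

```
wrote stack.tif (4178228 photons)
wrote binned.tif (1256 pixels above threshold)
fitted 1256 pixels: mean tau 2541 ps, mean chi2 1.01
mean E = 0.023 -> fret.tif
1 nuclei -> nuclei.csv
```

Reading the numbers: 1256 map pixels exceed the 200-photon threshold; their
mean fitted lifetime is 2541 ps — between the open-chromatin truth (2600 ps)
and the focus truth (2100 ps), as expected for a nucleus that is mostly
euchromatin — and the mean reduced χ² of 1.01 says the single-exponential
model fits at the Poisson noise level. Against a donor-only reference of
2600 ps the nucleus-average FRET efficiency is 0.023, i.e. a few percent of
pixels are quenched by compaction. The per-nucleus CSV carries area (px),
mean τ (ps) and mean co-stain intensity for group statistics via
`chromaflim compare`.

The same operations are available as library calls (`make_phantom`,
`simulate_decay_stack`, `preprocess_stack`, `fit_image`, `fret_efficiency`,
`nucleus_stats`, `line_profile`, ...); see the module docstrings.

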