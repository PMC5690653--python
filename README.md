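# tubulometry

Quantitative tubule histomorphometry for micro-CT volumes of the renal
medullo-papillary complex.

The renal papilla is threaded by two families of roughly co-oriented tubules —
wide uriniferous tubules and narrow vasa recta (straight capillaries, roughly
10–50 μm across). Early pathological biomineralization appears inside and
around these tubules, so a central quantitative question is: *what is the
diameter distribution of the mineralized, contrast-stained, and patent (void)
tubule populations, how does it vary along the proximal-to-tip axis, and how
strongly do the populations co-localize across pre- and post-stain scans?*

`tubulometry` answers that question for 3-D tomograms (multi-page TIFF at
~5 μm/voxel) and 2-D histology label images:

- **segmentation** — density thresholding (fixed or Otsu), digital *void
  inversion* (patent tubules = organ ∖ tissue), and 26-connected instance
  labeling;
- **diametry** — the core measurement: estimate the common tubule direction
  from per-component principal axes, reslice the label volume perpendicular
  to it, and on every cross-section take the **minor axis of the minimum
  enclosing (Löwner–John) ellipse** of the section's pixels. An oblique cut
  of a circular cylinder is an ellipse whose *minor* axis equals the true
  diameter, so the estimate is tilt-invariant; the per-tubule summary is the
  median over usable sections. Formally, for section pixel set *P*, the
  ellipse minimizes area over {(x−c)ᵀA(x−c) ≤ 1 : P ⊂ ellipse} (solved by a
  Khachiyan/Wolfe–Atwood iteration) and the slice diameter is 2/√λ_max(A);
- **colocalization** — integer-translation registration by normalized
  cross-correlation, then per-tubule overlap fractions, global coverage
  |A∩B|/|A| and Dice 2|A∩B|/(|A|+|B|);
- **histomorphometry** — zone assignment (equal axial thirds I/II/III, or
  five zones), fixed-width diameter histograms with normalized fractions,
  strict-local-maximum mode detection, and an overlap coefficient
  Σ min(p_a, p_b) for comparing distributions;
- **phantom** — a synthetic generator producing two registered channels of
  non-overlapping, tilt-jittered cylinders with a known diameter mixture,
  wall mode (solid or hollow shell), controlled co-localization fraction and
  a ground-truth table, so every stage is testable against known geometry.

## Worked example

```python
import numpy as np
from tubulometry import (PhantomSpec, generate_phantom, run_pipeline,
                         build_histogram, find_modes)

spec = PhantomSpec(
    grid_shape=(128, 128, 128), spacing_um=5.0, n_tubules=40,
    diameter_mixture=[(0.5, 25.0, 2.0), (0.5, 45.0, 4.0)],  # bimodal, μm
    tilt_jitter_deg=20.0, noise_sd=60.0, seed=3,
)
channel_a, channel_b, truth = generate_phantom(spec)

result = run_pipeline(channel_a)          # threshold → label → reslice → MVEE
hist = build_histogram(result.measurements["summary_diameter_um"])
modes = find_modes(hist)
print(len(result.measurements), "tubules measured")
print("counts per 10 µm bin:", hist.counts.tolist())
print("modal bins:", [(hist.bin_edges_um[b], hist.bin_edges_um[b + 1]) for b in modes])
```

Output:

```
40 tubules measured
counts per 10 µm bin: [0, 2, 23, 1, 13, 1, 0, 0, 0, 0]
modal bins: [(np.float64(20.0), np.float64(30.0)), (np.float64(40.0), np.float64(50.0))]
```

All 40 phantom tubules are recovered and the histogram shows the two planted
diameter populations: a mode in the 20–30 μm bin (vasa-recta-like) and one in
the 40–50 μm bin (uriniferous-like). Against the ground-truth table the mean
absolute per-tubule diameter error in this run is 0.93 μm, well under one
voxel.

The same stages are available from the shell:

```sh
tubulometry phantom --config spec.yaml --out phantom/ --seed 7
tubulometry segment --in phantom/channel_a.tif --mode otsu --out labels.tif
tubulometry measure --labels labels.tif --spacing 5 --out measurements.csv
tubulometry coloc   --a labels_a.tif --b labels_b.tif --register --out coloc.csv
tubulometry histo   --measurements measurements.csv --bin-width 10 \
                    --out hist.csv --summary summary.json
```

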