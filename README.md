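# saxsgpa

Guinier peak analysis for small-angle X-ray scattering (SAXS) curves.

Plotting `q·I(q)` against `q²` turns the Guinier region of a scattering
curve into a peak. For an ideal Guinier scatterer the peak sits at
`q² = 1.5/Rg²`, and in dimensionless coordinates
(`qRg·I(q)/I(0)` vs `(qRg)²`) at `(1.5, 0.7428)` regardless of size or
scale. This package uses that identity for model-free validation of SAXS
data and annotations:

- **transforms** — windowed Guinier fits, the GPA transform family
  (linear/log/dimensionless/Kratky), peak-based `Rg`/`I(0)` estimation and
  sliding-window local-Rg diagnostics.
- **peakfind** — scale-space peak picking with a rank-product heuristic
  (criterion rank × height rank) and local polynomial smoothing; robust
  against single-bin spikes.
- **pr_metrics** — real-space `Rg`/`I(0)` from `P(r)` moments, the
  elongation ratio (ER = area after the `P(r)` maximum / area before it),
  and Rg-normalised unit-sum `P'(r')` vectors.
- **shape_cluster** — composite-angle distances between `P'(r')` vectors
  and hierarchical agglomerative shape clustering.
- **qc_screen** — end-to-end screening: locate the peak, map it to
  dimensionless coordinates, flag outliers with the Hampel identifier
  (k = 3) against the theoretical position, and triage into
  ok / elongated / annotation_suspect / problematic_guinier /
  no_guinier_region.
- **synth** — form-factor intensities for spheres, ellipsoids (of
  revolution and triaxial), cylinders and prisms, plus polydisperse
  populations, mixtures, a repulsion emulator, Monte Carlo pair
  distributions and reproducible noise — the test bed for everything else.
- **saxs_io** — permissive ASCII readers/writers for curves, `P(r)` files
  and JSON/CSV screening reports.

## Command line

```sh
# windowed Guinier fit (default qRg <= 1.3)
saxsgpa guinier curve.dat --qrg-max 1.3

# GPA transform + automated peak location and Rg/I0 estimate
saxsgpa gpa curve.dat --find-peak --rg 30 --i0 100

# elongation ratio and real-space Rg/I0 from a P(r) file
saxsgpa er profile_pr.dat

# cluster a directory of P(r) files into k shape groups
saxsgpa cluster prdir/ -k 3

# screen a collection (CSV manifest: path, rg, i0[, pr])
saxsgpa screen manifest.csv -o report.json

# generate synthetic reference data
saxsgpa simulate --kind cylinder -r 20 --v 8 --noise 0.02 --seed 7 \
    -o cyl.dat --pr-output cyl_pr.dat
```

All commands print JSON records; `--q-units nm` converts nm⁻¹ grids on
load.

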