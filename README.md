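# vitisense

Proximal canopy-sensing toolkit for trellised vineyards. It implements the
full computational chain of a tractor-mounted, side-view canopy sensor:

* **`canopyct`** — vegetation segmentation of side-view RGB frames
  (HSL + RGB features → per-image PCA projection → two-class Jenks
  natural-breaks split) and the **Canopy Index** (CI), a pure number on a
  0–1000 scale equal to the scaled vegetation pixel fraction.
* **`sector_geometry`** — the 15-sector CI / 16-sector ST canopy-wall
  layout from the survey geometry (equal viewing-angle slices, sector 1
  anchored at the support wire), linear CI interpolation to arbitrary
  heights and repositioning onto the 18 point-quadrat levels.
* **`canopy_indices`** — center of gravity (COG) and moment of inertia
  (MOI) of the vertical CI distribution, and CI-normalized surface
  temperature per macro-sector (background-elimination inversion or plain
  ST/CI ratio).
* **`pqa`** — point-quadrat ground truth: leaf layer number (LLN), percent
  canopy gaps (%CG), percent interior leaves (%IL); canopy porosity from
  below/above-canopy light scans.
* **`calibration`** — linear and (log-linear) exponential CI-to-ground-truth
  fits with R², at per-sector / per-vine / per-date / pooled scopes.
* **`field_mapping`** — survey-log CSV I/O, RH/AT smoothing + de-trending,
  extraneous-reading filtering (boundary polygon + running-MAD rule),
  inverse-distance-weighted rasters and a ~50-entry thematic map catalog
  (ESRI ASCII grids, GeoJSON track, optional PNG renders).
* **`synthetic_data`** — a coupled synthetic vineyard: one virtual-canopy
  leaf-density profile drives rendered frames, simulated point-quadrat
  insertions and survey logs, so image-derived CI and PQA metrics are
  correlated mechanistically and every stage is testable end to end.

## CLI

```bash
vitisense simulate --vines 24 --dates 5 --seed 7 --outdir fixtures/
vitisense segment fixtures/vine_01.png --out mask.png          # CI + mask
vitisense profile --log fixtures/survey.csv --levels pqa
vitisense indices --log fixtures/survey.csv                    # COG/MOI/T_V
vitisense pqa --insertions fixtures/pqa.csv --by vine
vitisense calibrate --merged merged.csv --scope vine
vitisense map --log fixtures/survey.csv --param CI --out maps/
```

`vitisense segment` prints a JSON sidecar (pixel counts, CI, weights,
threshold) and optionally writes a 0/255 mask PNG.

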