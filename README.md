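# landcarbon

Land-cover change analysis and avoided-deforestation carbon accounting:

* **synthetic** — seeded generation of multi-epoch 6-class categorical
  landscapes with known ground-truth transition matrices, driver surfaces
  (elevation / slope / distance fields) and class-conditional multiband
  reflectance stacks;
* **features** — spectral–temporal metrics (median, sample SD, min, max,
  25th/50th/75th percentiles) over a seasonal image stack plus DVI/NDVI/EVI,
  a seeded random-forest classifier (default 500 trees) and accuracy
  assessment (overall accuracy, Cohen's kappa, per-class F1);
* **change** — cross-tabulation of map pairs, per-class areas (ha) and
  interval change rates;
* **transition** — Markov transition-matrix estimation (P_ij = n_ij / n_i),
  matrix-power projection, per-transition MLP change-potential models
  (stopping at RMS ≤ 0.01 or 1000 iterations) and deterministic ranked
  change allocation;
* **validation** — the quantity/location agreement decomposition and the
  Kno / Klocation / Kquantity statistics;
* **redd** — BioCF-style ledgers: annualised deforestation per project area
  and leakage belt, emissions via a configurable per-hectare factor
  (default 10 tCO2e/ha), the identity
  `C_REDD = C_Baseline − C_Actual − C_Leakage`, and 5-year period reporting
  over a 30-year horizon.

Rasters are exchanged as TIFF with a JSON sidecar (`<name>.tif.json`)
carrying class codes, nodata (255 for categorical, NaN for continuous) and
pixel size; tables as CSV; reports as JSON.

## CLI

```sh
landcarbon full-pipeline --seed 7 --out-dir outputs
landcarbon simulate      --config run.yaml --out-dir outputs
landcarbon classify      --config run.yaml --out-dir outputs
landcarbon detect-change --config run.yaml --out-dir outputs
landcarbon project       --config run.yaml --out-dir outputs
landcarbon validate      --config run.yaml --out-dir outputs
landcarbon redd-account  --config run.yaml --out-dir outputs
```

Configuration is YAML with a strict schema (unknown keys are errors); every
run appends a JSON-lines record of versions, seeds and settings to
`run_log.jsonl` in the output directory, and reruns with the same config and
seed reproduce byte-identical CSV/JSON outputs.

Example `run.yaml`:

```yaml
grid_rows: 120
grid_cols: 120
epochs: [1985, 2000, 2010, 2020]
projection_target_year: 2050
n_trees: 500
rms_target: 0.01
max_iterations: 1000
emission_factor: 10.0      # tCO2e per deforested hectare — replace for real biomes
effectiveness: 0.8
displacement: 0.1
horizon_years: 30
reporting_period_years: 5
```

`redd-account` can also be driven directly from scenario totals
(`c_baseline`, `c_actual`, `c_leakage` in the config), in which case it just
evaluates the accounting identity.

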