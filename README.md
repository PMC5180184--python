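# aridflux

Gridded analysis of the interannual variability (IAV) of land gross
primary production (GPP) and its coupling to the water cycle:

* **`aridflux.grid`** — regular lat–lon data model (fields, time-stacked
  cubes, fractional land cover) with NetCDF I/O, cosine-latitude area
  weighting, land-cover aggregation and monthly→annual aggregation.
* **`aridflux.synthetic`** — a seeded synthetic planet with known ground
  truth: Budyko-consistent ET driven by precipitation, water-limited
  GPP = WUE·ET below aridity index 1 and radiation-driven GPP above it,
  a per-biome SIF proxy, and a multi-model GPP ensemble with known
  quality ranking. Every downstream stage is testable against the
  parameters the generator wrote down.
* **`aridflux.ensemble`** — SIF-proxy model weighting: per-biome Pearson
  correlations of each model's GPP with SIF (spatial or temporal mode),
  biome-area-weighted scores, order-γ weights
  `W_i = max(score_i, 0)^γ / Σ max(score_k, 0)^γ`, weighted/unweighted
  ensemble cubes, leave-one-model-out stability comparison.
* **`aridflux.budyko`** — analytical water balance
  `ET = P·PET/(Pⁿ+PETⁿ)^(1/n)`, closed-form sensitivities, first-order
  σ_ET propagation from σ_P, aridity index and the FAO/UNEP classifier
  (boundaries 0.05 / 0.2 / 0.5 / 0.65), least-squares fitting of n.
* **`aridflux.variability`** — per-cell OLS detrending, IAV maps,
  additive per-aridity-class contributions to global detrended IAV
  (covariance projection) and to the trend (slope shares), binned curves.
* **`aridflux.attribution`** — partial correlations of GPP with P/T/SW
  (residual method, t-test significance), per-cell GPP–ET regression
  slope β across ET products, the σ_GPP = β·σ_ET decomposition, and
  coupling-vs-IAV curves.
* **`aridflux.pipeline` / `aridflux.cli`** — one-config orchestration of
  all stages with a hashed artifact manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion. One
sub-case is red by design: the hyper-arid limit of dET/dP evaluated at
aridity index 1e-6 deviates from 1 by (n+1)/n·AIⁿ ≈ 3e-3 for n = 0.5,
which cannot meet the stated 1e-4 tolerance (the limit itself is exact;
convergence is just slower than the tolerance assumes).

## CLI

```bash
aridflux template                     # print a config with all defaults
aridflux run --seed 1 --out out/      # synth -> ensemble -> classify -> analyze -> attribute
aridflux report out/manifest.json     # summary table from the manifest
aridflux synth --seed 2 --out world/  # just the synthetic world + truth tables
aridflux budyko --curve               # ET/P vs PET/P tables for an n envelope
```

Individual stages (`ensemble`, `analyze`, `attribute`, `budyko
--classify/--predict-iav`) accept NetCDF cubes produced by `synth` or by
`aridflux.grid.write_cube`.

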