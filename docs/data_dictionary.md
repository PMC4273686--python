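# Data dictionary

## `results.csv` — one row per delineated object (and per scoring target)

| column | type | meaning |
|---|---|---|
| `phantom` | str | phantom family: `nema`, `spheres`, `necrotic`, `irregular` |
| `lesion_id` | int | lesion index within the phantom (builder order) |
| `size_mm` | float | lesion size label: sphere diameter; necrotic-core diameter; volume-equivalent diameter for irregular lesions |
| `size_group` | str | `small` (≤ 13 mm) or `large` (> 13 mm) |
| `contrast` | float | lesion:background activity ratio |
| `protocol` | str | reconstruction preset (`OP`, `OP+TOF`, `PSF`, `PSF+TOF`) |
| `counts` | float | true-coincidence level of the emulated acquisition |
| `replicate` | int | replicate index (0-based) |
| `matrix` | int | in-plane matrix size (200 or 400) |
| `method` | str | delineation method key (`T40`, `T50`, `CT`, `AT40`, `AT50`, `FLAB`) |
| `eqpet` | bool | whether the harmonising filter was applied before delineation |
| `target` | str | `whole` for solid lesions; `shell`/`core` rows for necrotic lesions |
| `si` | float | similarity index (Dice), in [0, 1]; NaN if status ≠ `ok` |
| `pct_ve` | float | percentage volume error, ≥ −100; NaN if status ≠ `ok` |
| `vol_pet_ml` | float | delineated volume (ml); for `core` rows, the hole-estimate volume |
| `vol_true_ml` | float | true volume (ml): analytic for NEMA spheres, voxelized mask volume otherwise |
| `threshold` | float | threshold applied (image units) |
| `status` | str | `ok` or `unavailable` (external method not bundled) |
| `note` | str | surfaced warnings (e.g. no lesion contrast, threshold above SUVmax) |
| `seed` | int | derived per-condition simulation seed, for replay |

All spreads use the sample standard deviation (n−1 denominator).

## `summary.json`

* `by_method.<METHOD>[+EQ]` — `mean_si`, `mean_pct_ve`, `sd_pct_ve`, `n`,
  and `by_size_group.{small,large}` with per-group `mean_si`,
  `mean_pct_ve`, `n`. Core rows of necrotic phantoms are excluded.
* `mean_volume_cv.<METHOD>[+EQ].{small,large}` — mean (over lesions,
  contrasts and matrices) of the CV of delineated volumes pooled across
  protocols, count levels and replicates.

## `fits.json`

* `ct.<protocol>_<matrix>` — CT regression: `a`, `b`, `fit_rmse`, `n_samples`.
* `eqpet.<protocol>_<matrix>` — harmonising filter: `filter_fwhm` (mm),
  `rmse` at the optimum, `reference` protocol label.

## `results/acceptance.json` (from `scripts/acceptance.py`)

Map of target id → `{"value": number, "n": problem size}`; `t4` is the
ideal-case similarity index, `t5` the ideal-case %VE, both computed from a
freshly voxelized NEMA sphere mask.
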