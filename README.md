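# traitflux

Tools for decomposing changes in community functional-trait composition
along an environmental gradient (e.g. successional age) into **species
turnover** and **intraspecific trait variability (ITV)** components, at
both the community and the individual scale:

- **`core_data`** — study data model (traits / species / plots /
  individuals), CSV I/O, hierarchical-mean imputation of missing trait
  values, Sørensen similarity and tie-corrected Kendall tau.
- **`synthetic_community`** — generator of synthetic sapling communities
  with Gaussian-niche species turnover, within-species gradient shifts,
  ontogeny and light effects, plus a stored ground truth and an
  independent oracle (`truth_expected_decomposition`) for recovery tests.
- **`cwm_partition`** — specific vs. fixed community-weighted means and
  the sum-of-squares partition of community trait variation into
  turnover / ITV / covariation, overall and against the age gradient.
- **`ordination_hs`** — principal-axes ordination of mixed
  quantitative/categorical tables (reduces to weighted-correlation PCA
  for all-quantitative input).
- **`rlq_partial`** — RLQ three-table cross-covariance analysis with
  among-species and within-species partial variants.
- **`gradient_models`** — environment-vs-age checks, quasi-binomial
  logit GLMs with backward selection for categorical-trait proportions,
  and species-random-effect mixed models of log trait values vs.
  relative height (H/Hmax), forest type and crown illumination, with
  marginal/conditional R².
- **`pipeline_cli`** — one-config orchestration of the full analysis
  with a deterministic, machine-readable report
  (schema in `docs/report_schema.json`).

## Command line

```sh
# generate a synthetic study (four CSVs + truth.json)
traitflux simulate --seed 1 --out study/

# single-trait decomposition against the age gradient
traitflux decompose --study study/ --mode gradient --out decomposition.csv

# mixed-variable ordination of the trait table
traitflux ordinate --study study/ --out ordination.json

# partial RLQ for one forest type
traitflux rlq --study study/ --forest-type MIX --component within --out rlq.json

# regression models
traitflux models --study study/ --which lmm --trait SLA --out lmm.json

# full pipeline from one YAML config
traitflux run --config run.yaml
```

A minimal `run.yaml`:

```yaml
mode: synthetic
seed: 7
out_dir: out
synthetic:
  n_species: 40
  n_plots_per_type: 6
  itv_strength: 0.03
  turnover_strength: 0.03
stages: [data, impute, decompose, ordinate, rlq, models]
```

Rerunning the same config reproduces `out/report.json` bit-for-bit.

## Study file formats

Four UTF-8 comma-delimited tables with mandatory headers
(missing values as empty fields or `NA`):

- `traits.csv`: `name,kind,units,log_transform_for_lmm`
- `species.csv`: `species_id,hmax,legume,phenology,compoundness,pubescence`
- `plots.csv`: `plot_id,forest_type,successional_age,<environment columns>`
- `individuals.csv`: `individual_id,plot_id,species_id,height_class_midpoint,cii,<one column per quantitative trait>`

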