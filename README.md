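# siderotrait

Analysis toolkit for quantifying how metal stress reshapes siderophore
production in a bacterial community and a focal strain:

- **CAS quantification** (`siderotrait.cas`) — convert chrome azurol S plate
  reads (A630, reference A630, OD600) into scores via
  `(1 − A/A_ref)/OD`, with dataset-wide min-zero standardization.
- **Fitness statistics** (`siderotrait.fitness`) — Malthusian growth rates,
  relative fitness (ratio) and selection rate (difference), Cohen's *d* with
  pooled SD, Spearman rank correlation with midrank ties (exact permutation
  p for n ≤ 9), a 2×2 factorial OLS with sequential F-tests and marginal
  means, and a per-genus effect-size screen against baseline production.
- **Hierarchical Bayesian model** (`siderotrait.bayes`) — heteroscedastic
  Gaussian model with replicate-level random means
  (`y ~ N(λ[group, replicate], σ[group])`, `λ ~ N(α[type] + β[type]·copper, τ)`,
  half-normal/normal/exponential priors), fitted by an in-repo No-U-Turn
  sampler with analytic gradients, plus MAP estimation (bounded multi-restart
  L-BFGS), shortest-window 95% HPD intervals, derived posterior contrasts
  (combined copper effect, type differences with/without copper, SD
  contrasts), and PSIS-LOO comparison of residual-variance structures
  (per-group / by-type / by-copper / single σ) via arviz.
- **Synthetic data** (`siderotrait.synthetic`) — seeded generators with
  exactly the generative structure the model assumes (factorial design with
  Bernoulli dropout, replicate-level means, group SDs, invertible CAS reads,
  exponential-growth competitions), so every stage is testable offline.
- **Pipeline + CLI** (`siderotrait.pipeline`, `siderotrait.cli`) —
  end-to-end orchestration with schema validation, seeded determinism and a
  hashed output manifest.

## CLI

```sh
siderotrait simulate --seed 1 --out isolates.csv --assays-out assays.csv
siderotrait quantify --assays assays.csv --out scores.csv
siderotrait fit --isolates isolates.csv --chains 4 --iterations 1000 --seed 1 --out summary.csv
siderotrait contrasts --isolates isolates.csv --seed 1 --out contrasts.csv
siderotrait loo --isolates isolates.csv --seed 1 --out loo.csv
siderotrait effectsizes --isolates isolates.csv --out effects.csv
siderotrait means --isolates isolates.csv --out means.csv
siderotrait run --config pipeline.yaml --json
```

A pipeline config contains exactly one of `synthetic:` (generator fields) or
`inputs: {isolates: path, column_map: {...}}`, plus optional `model:`,
`loo:` and `effect_sizes:` sections; see `siderotrait.pipeline.PipelineConfig`.

### Canonical isolate table

```
isolate_id, microcosm_id, group, replicate, isolate_type, copper,
community_context, genus, siderophore
```

`isolate_type` is `community` or `SBW25`; `copper` is a 0/1 indicator;
group labels 1–4 follow the fixed order (community/no-Cu, community/Cu,
SBW25/no-Cu, SBW25/Cu). Loaders accept a `column_map` so externally
deposited tables with different headers can be ingested unchanged.

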