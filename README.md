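# metgp

Kernel-based whole-genome prediction for multi-environment trials (MET).
`metgp` builds additive, dominance and envirotype relationship kernels from
marker dosages and daily weather tables, assembles five MET model
structures of increasing complexity (main additive effects up to full
reaction-norm genotype-by-environment interaction), fits them with an
eigen-reparameterized Bayesian Gibbs sampler, and evaluates predictive
ability under three cross-validation schemes.  A synthetic-data module
generates genotypes (inbred parents crossed to F1 hybrids), weather series
and phenotypes with known variance components so the whole pipeline is
testable without external data.

## Components

| module              | what it does |
|---------------------|--------------|
| `metgp.simulate`    | synthetic parents/hybrids, daily weather, phenotypes drawn from the generative model with configurable variance components |
| `metgp.envirotyping`| interval x percentile summaries of daily weather, scaling + QC into the environment covariable matrix `W`, environmental kernel |
| `metgp.kernels`     | marker codings (additive, dominance-deviation), GB (trace-normalized linear), GK (Gaussian) and DK (recursive arc-cosine) kernels, marginal-likelihood selection of the GK bandwidth and DK depth |
| `metgp.models`      | the five model structures (`EA`, `EAD`, `EAD+GE`, `EADW`, `EADW+GW`) as fixed designs plus observation-level random-effect covariances |
| `metgp.solver`      | eigen-reparameterized Gibbs sampler with scaled-inverse-chi-square priors, held-out prediction, variance partition |
| `metgp.evaluation`  | CV1 (new hybrids) / CV2 (sparse trials) / CV0 (new environments) folds, predictive ability, corrected standard errors, per-hybrid resolution and typology, the full model x kernel x scheme grid |

## CLI

```bash
# synthetic data set (genotypes, phenotypes, weather, W, ground truth)
metgp simulate --parents 20 --hybrids 60 --markers 300 --environments 5 \
    -v A=1.0 -v D=0.5 -v residual=1.0 --seed 1 --out data/

# envirotype covariables from daily weather CSVs
metgp envirotype data/weather_E*.csv --out env/

# relationship kernel from a dosage CSV
metgp kernel data/genotypes.csv --method GK --h 1.0 --out K_A.csv

# fit one model/kernel combination
metgp fit data/ --model EADW+GW --method DK --layers 2 --out fit/

# cross-validation grid (YAML config optional)
metgp cv data/ --config grid.yaml --out cv/
```

A grid YAML may set `models`, `kernels`, `schemes`, `repetitions`,
`train_fraction`, `iterations`, `burn_in`, `thin`, `h`, `layers`,
`select_hyperparams` and `seed`.

## Input formats

* genotypes: CSV (hybrid IDs x markers, dosages 0/1/2) or diploid
  biallelic VCF (ALT-allele dosage; requires `cyvcf2`),
* phenotypes: CSV with `env,gid,value` columns,
* weather: one CSV per environment with a `day` column (1-based day of
  cycle) and one column per daily variable.
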