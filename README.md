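# herdlink

Multi-herd pedigree BLUP toolkit for repeated litter-size records (number
born alive, NBA), built around a repeatability animal model:

```
y = Xb + Zl·l + Zp·p + Za·a + e,
l ~ N(0, I·σ²l),  p ~ N(0, I·σ²p),  a ~ N(0, A·σ²a),  e ~ N(0, I·σ²e)
```

with fixed effects for parity, mating season (year-month), sow genotype,
litter sire, herd, weaning-to-conception class, and centered age/lactation
covariates (age nested within parity, linear + quadratic).

## What it does

- **pedigree** — validated, topologically ordered pedigrees; inbreeding by
  the Meuwissen–Luo recursion; dense tabular A (oracle); sparse A⁻¹ from
  per-animal rules with inbreeding-adjusted Mendelian-sampling variances;
  per-herd structure summaries.
- **design** — deterministic factor coding (reference level dropped for all
  factors *except* herd, which keeps every level with no intercept so herd
  contrasts are directly comparable), nested centered covariates, sparse
  X / Zl / Zp / Za with a column map; exactly collinear columns are pruned
  by a rank-revealing pass (the herd block is protected).
- **varcomp** — EM-REML for (σ²a, σ²p, σ²l, σ²e) with a monotone restricted
  log-likelihood trace, safeguarded log-space Aitken acceleration, boundary
  flooring, and derived ratios (h², p², l², e²).
- **blup** — sparse mixed-model equations, direct factorization, EBVs,
  prediction-error variance from the inverse coefficient matrix, and
  reliability r² = 1 − PEV/σ²a with per-herd summaries (N, mean, SD, min,
  max).
- **connectedness** — connectedness rating between herds: the correlation
  of estimated herd effects computed from the herd block of the inverse MME
  coefficient matrix, with threshold flagging and per-dataset reports.
- **geneflow** — A = T·W·T′ decomposition; per-animal herd-of-origin gene
  shares (rows of T restricted to base-animal columns) and group-averaged
  herd × origin-herd contribution matrices.
- **synthetic_data** — a seeded multi-herd population simulator: three
  herds of unequal size, herd B as an AI centre siring litters in A and C,
  limited gilt trade, L/LW breeds with optional reciprocal F1 crosses, and
  phenotypes generated under the exact model above (breeding values sampled
  down the pedigree with inbreeding-adjusted Mendelian-sampling variance).
- **cli / pipeline** — configuration-driven runs over the analysis grid
  (per-herd vs merged, purebred vs purebred+crossbred).

## CLI

```sh
herdlink simulate --preset ai_connected --seed 1 --out data/
herdlink summary  --pedigree data/pedigree.csv --phenotypes data/phenotypes.csv
herdlink reml     --pedigree data/pedigree.csv --phenotypes data/phenotypes.csv
herdlink blup     --pedigree ... --phenotypes ... --vc 0.825,1.171,0.189,10.324 --out out/
herdlink cr       --pedigree ... --phenotypes ... --vc 0.825,1.171,0.189,10.324
herdlink geneflow --pedigree ... --phenotypes ...
herdlink run      --config cfg.yaml            # full pipeline + manifest
herdlink run      --preset ai_connected --seed 3 --variant merged --out out/
```

Presets: `disconnected`, `ai_connected`, `ai_connected_with_crossbreds`.
`run` writes CSV reports (variance components, EBV/reliability, CR, gene
flow, pedigree summary) plus a `manifest.json` capturing config, seed and
convergence flags; identical config + seed reproduces every output
byte-for-byte.

## File formats

- Pedigree CSV: `animal,sire,dam,herd,birth_year,sex,breed`, `0` = unknown
  parent.
- Phenotype CSV: `sow,parity,year,month,genotype,litter_sire,herd,age_days,
  wci_days,prev_lact_days,birth_litter,nba` (`wci_days`/`prev_lact_days`
  empty on first parity).
- Run configs are YAML (see `herdlink run --help` for keys).

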