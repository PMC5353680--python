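# edafs

Wrapper feature selection that simultaneously discovers **relevant
features** and **pairwise dependencies** among them. The search evolves a
forest-factored probability model over binary relevance indicators
(an estimation-of-distribution algorithm with bivariate, spanning-forest
structure), guided by the 5-fold cross-validated accuracy of a
weighted-kernel soft-margin SVM. Because a weighted RBF/polynomial kernel
equals the plain kernel on `sqrt(w)`-scaled inputs, any standard SVM solver
serves as the weighted machine — candidates simply rescale the data.

Two search variants share one loop:

- `bmda` — re-estimates the pairwise dependency structure every iteration:
  edges from a chi-square / mutual-information / combined (SIM) criterion
  over the elite pool, a maximum-strength spanning forest (Kruskal), roots
  chosen by minimum marginal entropy, counts via frequentist updates with
  Laplace smoothing.
- `umda` — forces an empty edge set, evolving independent per-variable
  marginals only.

The package also ships:

- a synthetic pure-epistasis testbed: k SNPs in {0,1,2} under
  Hardy-Weinberg, class = parity of the genotype bits (provably zero
  lower-order marginal signal), plus uniform-noise pollution features;
- multi-repetition protocols: averaged relevance factors with cutoff
  selection, cross-run dependency count matrices, a Kruskal consensus tree
  on inverse counts, discovery scoring `(#relevant found, #noise excluded)`
  and bubble tallies;
- preprocessing for real tabular data: naive-Bayes (or mode/mean) missing
  value imputation, min-max normalization, stratified splits.

## Library quick start

```python
from edafs import (EpistasisSpec, SearchConfig, generate_epistasis_dataset,
                   normalize_minmax, split_train_test, run_search)

ds = normalize_minmax(generate_epistasis_dataset(
    EpistasisSpec(k=3, n_noise=5, m=600, seed=0)))
train, test = split_train_test(ds, 0.25, seed=0)
result = run_search(train, test, SearchConfig(seed=0), variant="bmda")
print(result.best.bits, result.test_accuracy)
```

## CLI

```sh
# generate a 3-way epistasis dataset + ground-truth sidecar
edafs simulate --k 3 --n-noise 5 --m 600 --seed 0 --out epi.csv

# one search run (writes result JSON + dependency-count TSV)
edafs run epi.csv --train-fraction 0.25 --seed 0 --out result.json

# 30-repetition protocol with averaged relevance and consensus tree
edafs aggregate epi.csv --reps 30 --cutoff 0.7 --seed 0 --out-prefix epi30

# score a selection against the ground truth
edafs score --selected 0,1,2 --truth epi.truth.json
```

## Layout

| Module | Contents |
|---|---|
| `edafs.dataset` | `Dataset`, CSV/TSV IO, imputation, normalization, splits |
| `edafs.simulate` | epistasis/testbed generators, toy fixtures |
| `edafs.dependency` | pair counts, chi2/MI/SIM statistics, spanning forest |
| `edafs.model` | forest-factored model: estimation, sampling, exact probability |
| `edafs.fitness` | weighted kernels, scaling identity, CV wrapper cost |
| `edafs.search` | the evolutionary loop (`bmda`/`umda`), convergence |
| `edafs.aggregate` | repetition protocols, consensus tree, discovery scores |
| `edafs.cli` | `edafs` command group (`simulate`/`run`/`aggregate`/`score`) |
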