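# sbsp

Bayesian nonparametric estimation of unseen feature counts with a
stable-Beta scaled process prior.

Given `N` binary genomes (per-sample presence/absence of variants), the
package estimates how many *new* variants — in total and broken down by
prevalence — will be discovered in `M` future samples. The posterior of the
unseen count is negative-Binomial in closed form and depends on the data
only through the sample size `N` and the number of distinct observed
features `K_N`; as `M` grows, the count grows like `M^sigma` with a
Gamma-distributed multiplier. Hyperparameters `(sigma, c, beta)` are fitted
by empirical Bayes, maximizing the exchangeable feature probability
function (the marginal allocation likelihood).

## Package layout

| module            | contents                                                              |
|-------------------|-----------------------------------------------------------------------|
| `sbsp.special`    | Beta-sum rate functions `gamma0`, `gamma_forward`, `rho_prevalence`    |
| `sbsp.io`         | TSV / coordinate / VCF loading, sufficient statistics, splits, truth   |
| `sbsp.posterior`  | negative-Binomial posteriors, point estimates, credible intervals, Gamma limit laws |
| `sbsp.efpf`       | log-EFPF, empirical-Bayes fitting, profile diagnostics                 |
| `sbsp.generative` | exact forward / posterior-predictive simulators, misspecified generators |
| `sbsp.evaluation` | accuracy metric, replicate subsampling experiments, coverage calibration |
| `sbsp.cli`        | `sbsp fit / predict / simulate / evaluate / coverage`                  |

## CLI

```sh
# simulate a dataset from the model
sbsp simulate --sigma 0.6 --c 2 --beta 1 --n 100 --seed 1 --output sim.tsv

# empirical-Bayes fit of (sigma, c, beta)
sbsp fit --input sim.tsv --output fit.json

# posterior estimates and a 90% credible interval for M future samples,
# plus the singleton (prevalence-1) breakdown
sbsp predict --input sim.tsv --m 50 --r 1 --level 0.9 \
             --fit-json fit.json --output pred.json

# replicate subsampling experiment and interval-coverage calibration
sbsp evaluate --input sim.tsv --n-train 20 --reps 100 --seed 1 --output eval.tsv
sbsp coverage --input sim.tsv --n-train 20 --reps 100 --levels 0.5,0.9 \
              --seed 1 --output cov.json
```

Input dialects: dense TSV (header of feature ids, first column sample id,
cells 0/1), coordinate pairs (`sample feature` header; optional
`<path>.samples` sidecar declaring empty samples), and VCF 4.x
(gzip-transparent; a sample carries a feature iff its genotype contains the
corresponding ALT allele; multi-allelic sites are split per ALT allele and
features are identified as `CHROM:POS:REF:ALT`).

Exit codes: 0 success, 2 usage, 3 data/validation, 4 numerical failure.

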