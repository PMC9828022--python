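# serialsfs

Demographic inference from serially sampled site frequency spectra, built
for the question a rebuilt fishery poses: did effective population size
(N_e) decline and recover along with census abundance?  The motivating
system is summer flounder (*Paralichthys dentatus*) on the U.S. East
coast, where archived larval cohorts from 1994, 1997 and 2008 bracket a
collapse and rebuilding of the stock, but the machinery is generic for any
single panmictic population sampled at a few time points.

## What it does

Given biallelic one-SNP-per-locus genotypes for temporally spaced cohorts
(or a ready-made folded multiSFS), `serialsfs`:

* filters genotypes with the standard RAD protocol (individual
  missingness > 50%, locus presence ≥ 95%, first SNP per contig,
  heterozygosity outliers, Hardy–Weinberg exact test at p < 0.001);
* builds the folded multidimensional SFS over the cohorts, pooled-minor-
  allele convention, fastsimcoal-style `.obs` serialization;
* estimates expected spectra for seven bottleneck/recovery model
  topologies by serial-sampling coalescent simulation (a fast numba
  kernel; every branch of every genealogy tallied by length, the
  low-mutation-limit estimator `p_e = E[L_e]/E[L_tot]`);
* fits each model by maximizing the composite likelihood
  `lnL = Σ_e O_e ln p_e` with a multi-start Nelder–Mead search on log
  parameters (common random numbers, screening draws, warm starts from
  simpler models) and selects among models with `AIC = 2k − 2 lnL`;
* quantifies uncertainty and power: nonparametric bootstrap CIs across
  loci, a pseudo-observed-data confusion matrix, and an equal-sample-size
  power variant;
* computes the diversity panel (H_obs, H_exp, F_IS, windowed π with
  bootstrap CIs) and the census-side quantities (peak-spawning abundance
  `N_ps,t = Σ_a N_a,t m_a e^{−pZ_a,t}`, fecundity-weighted generation
  length, N_e/N_c ratios).

A synthetic-data module generates cohort genotype matrices under any of
the seven models, planted filter test-sets, and age-structured tables with
closed-form answers, so the entire pipeline is testable offline.

See `docs/methods.md` for the model definitions, estimators, search
protocol and known identifiability limits.

## Worked example

Simulate three cohorts (26/103/150 diploids sampled 7.0/5.5/0 generations
before present) under the reference bottleneck-and-recovery history, refit
the constant-size and bottleneck models, and compare by AIC:

```python
import numpy as np
from serialsfs import (SimulationConfig, fit_model, flounder_sample_spec,
                       model6_reference, select_model)
from serialsfs.power import pseudo_observed_sfs

spec = flounder_sample_spec()          # 52/206/300 haploids at 7.0/5.5/0.0
truth = model6_reference()             # NBOT=1820, NPREBOT=64418 (haploid)
obs = pseudo_observed_sfs(truth, spec, L=1068, rng=1)

cfg = SimulationConfig(n_sims=5000)
fits = [fit_model(obs, m, n_restarts=3, max_cycles=8, cfg=cfg, seed=m,
                  pool_threshold=2, n_screen=2, rescore_pool_threshold=1,
                  rescore_cfg=SimulationConfig(50_000), rescore_seed=99)
        for m in (1, 2)]
table = select_model(fits)
print(table.to_frame().to_string(index=False))
```

```
 model  k          lnL          AIC     dAIC
     1  1 -6378.713701 12759.427402 53.34202
     2  5 -6348.042691 12706.085382  0.00000
```

The bottleneck model (model 2) is preferred over constant size by
ΔAIC ≈ 53: the serially sampled spectra carry a clear record of the
collapse and recovery.  The reference scenario itself summarizes to a
decline ratio NBOT/NPREBOT ≈ 0.028, a recovery ratio NPOP08/NBOT ≈ 11.2,
post-bottleneck exponential growth of 0.20 per generation, and a
bottleneck ending 12 generations (24 years) before the 2008 cohort.

The same analysis is scriptable end to end from a YAML config:

```
serialsfs simulate --model 6 -L 1068 --seed 1 --out-prefix data/sim
serialsfs build-sfs --vcf data/sim.vcf --cohorts data/sim.cohorts.tsv --out data/sim.obs
serialsfs fit --obs data/sim.obs --model 6 --restarts 10 --n-sims 20000 --out fit6.json
serialsfs census --age-table data/ages.tsv --years 1982-2008
```

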