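# Methods

`serialsfs` infers recent demographic history from the folded
multidimensional site frequency spectrum (multiSFS) of cohorts sampled from
one panmictic population at different times, and carries the companion
computations of a temporal population-genomic study of an exploited marine
fish: genotype filtering, diversity statistics, and census-side abundance
and generation-length calculations from stock-assessment tables.

## Demographic models

Seven single-population, backward-time histories are supported, spanning
the scenarios relevant to a harvested stock that declined and rebuilt:

| model | history (forward time) | free parameters |
|---|---|---|
| 1 | constant size | NANC |
| 2 | bottleneck, instantaneous recovery | NPREBOT, NBOT, NPOP08, TLEN, TBOT |
| 3 | bottleneck, exponential recovery | NPREBOT, NBOT, NPOP08, TLEN, TBOT |
| 4 | ancestral exponential growth, bottleneck, instantaneous recovery | + NANC, TCAR |
| 5 | two bottlenecks, instantaneous changes | NPREBOT, NBOT1, NINT, NBOT2, NPOP08, TLEN1, TBOT1, TLEN2, TBOT2 |
| 6 | ancestral exponential growth, bottleneck, exponential recovery | as model 4 |
| 7 | ancestral exponential growth to carrying capacity, no bottleneck | NANC, NPOP08, TCAR |

All sizes are haploid; all times are generations before the most recent
sampling event.  TBOT is the time since the bottleneck ended, TLEN its
duration, TCAR the (forward-time) end of the ancestral size change.  For
models 4, 6 and 7 the ancestral exponential segment is anchored at a fixed
deep horizon `T_LGM` = 10,000 generations (about 20,000 years at a 2-year
generation, i.e. post-glacial recolonization), beyond which the population
sits at NANC.  The exponential rate of any segment is implied by its
endpoint sizes, `r = ln(N_end/N_start)/duration`.

Model 5's intermediate size (NINT) is a free parameter, giving nine free
parameters; the AIC parameter counts are k = (1, 5, 5, 7, 9, 7, 3) for
models 1-7 and are configurable.

The package ships a reference model-6 scenario (`model6_reference()`): deep
size 2104 growing to 64,418 (haploid) before a 2-generation bottleneck at
1820 ending 12 generations before present, then exponential recovery at
0.20 per generation to 20,424.  TCAR, which recent cohorts constrain only
weakly, defaults to 500 generations; this implies an ancestral growth rate
of 3.6e-4 per generation and leaves the pre-bottleneck epoch with enough
coalescent exposure for NPREBOT to be estimable, which a much smaller TCAR
would not (see "Identifiability" below).

## Sampling design

The default design mirrors the study conditions: three larval cohorts of
26, 103 and 150 diploids (52/206/300 haploids) collected 14, 11 and 0 years
before the most recent cohort; at a 2-year generation these are sampling
times of 7.0, 5.5 and 0.0 generations.  Fractional sampling times are
supported directly by the simulator, so no integerization is needed.

## Coalescent engine

Genealogies are simulated backward in time with lineages entering at their
cohort sampling times and k lineages coalescing at rate C(k,2)/N(t).
Waiting times through piecewise-exponential epochs are inverted in closed
form (no time stepping).  The implementation is a numba kernel that packs
the three per-cohort descendant counts of each lineage into one integer, so
a coalescence is a single addition; one genealogy of the full 558-haploid
design costs about 60 microseconds.

The estimand is the low-mutation-limit SFS conditioned on polymorphism,

    p_e = E[L_e] / E[L_tot],

where L_e is the summed length of branches whose mutation would produce
entry e.  A mutation placed uniformly on a single genealogy is *not* an
unbiased draw from this distribution — genealogies must be weighted by
their total branch length.  `simulate_entry` therefore returns the entry
together with that importance weight, and `expected_sfs` tallies every
branch of every genealogy by its length (the Rao-Blackwellized form of the
same estimator), folds by the pooled minor allele, and normalizes.  With
n_sims genealogies each contributing ~2n branches, the marginal-bin
precision at n_sims = 5,000 is already better than one part in a hundred.
The engine was cross-checked against msprime's branch-mode allele frequency
spectrum on serial-sampling bottleneck histories (agreement within
Monte-Carlo error) and against the neutral 1/i law.

Folding convention: an entry moves to its complement when its pooled minor
allele count exceeds half the pooled total; entries at exactly half stay in
place with full weight.

## Composite likelihood

For L unlinked one-SNP loci the composite log-likelihood is
`lnL = Σ_e O_e ln p_e` over polymorphic entries (multinomial coefficient
omitted).  Three practical forms are provided:

* **Full (contract) form.**  Expected probabilities below a floor are
  raised to it; the default floor is `1/(10 n_sims)`, the scale of a single
  unobserved genealogy, applied without renormalization (the excess mass is
  at most ~1e-2).  This keeps unexplained observed entries finitely
  penalized and identical across models.
* **Pooled form** (`pool_threshold = C`).  Entries observed at least C
  times keep individual terms; all rarer and unobserved entries are pooled
  into one class with the remaining expected mass.  At Monte-Carlo
  fidelities where most of the ~3.3M-entry grid is unexplored, the full
  form rewards parameter vectors whose spectra happen to cover more of the
  observed support (a pure coverage artifact); the pooled form has no such
  term and its evaluation noise is under 1 log-unit at 3,000 genealogies.
* **Cohort-marginal surrogate.**  The composite likelihood of the three
  folded marginal spectra; cheap and nearly noise-free, at the cost of
  discarding cross-cohort structure.  Available as a search-phase
  objective.

## Maximum-likelihood search

Initial values follow the study's distributions: sizes log-uniform on
[100, 100,000] haploid, TLEN uniform on [1, 5], TBOT uniform on [1, 12],
TCAR log-uniform on [1, 5000]; a widened sensitivity mode (TBOT to 30,
TLEN to 15) and a fixed-TLEN mode are provided.  Lower bounds are hard;
upper bounds limit only initialization.  The optimizer is a multi-start
Nelder-Mead on log-transformed parameters (TCAR is parameterized as
TBOT + TLEN + exp(θ) so epoch ordering holds by construction), capped at a
configurable number of iterations.  Each restart can prepend cheap
screening draws and keeps a fixed simulation seed for all of its
evaluations (common random numbers), which makes the search surface
deterministic; when several models are fit to one dataset the same
per-restart seeds are reused across models.

Because the reported maximum is a maximum over noisy evaluations, every
fit ends with a single rescoring evaluation on a fresh set of genealogies
— shared across models and usually at higher fidelity — and that rescored
lnL feeds AIC (`AIC = 2k − 2 lnL`, ties to the smaller k).  Model
comparison uses the full composite for this rescore: the fine rare-entry
structure it retains is exactly what separates near-nested recovery
scenarios (instantaneous versus exponential growth after a bottleneck),
and the pooled form is measurably blind to it.

## Bootstrap and power analyses

Nonparametric CIs: bootstrap spectra are multinomial resamples of the L
observed loci; each is refit with restarts initialized at the observed-data
ML values jittered ±10% on the log scale, and 95% intervals are 2.5/97.5
percentiles with linear interpolation.

Pseudo-observed datasets for power analyses are L multinomial draws from a
generating model's expected spectrum.  The generating spectrum is always
estimated at high fidelity (≥100,000 genealogies) regardless of the search
budget — the data-generating conditions are not part of the search-cost
dial.  The confusion matrix tallies AIC-selected against generating models;
the equal-sampling variant redraws the design at 80 diploids per cohort.

## Problem sizes used in the shipped analyses

The package's bundled acceptance analyses run scaled-down versions of the
full protocol, sized for a single CPU:

* model-selection power: 5 pseudo-observed datasets, 7 candidate models,
  3 restarts each (one screening draw per restart, 5 search cycles, doubled
  for models with seven or more free parameters) at 5,000 genealogies per
  likelihood evaluation, simple-to-complex warm-start order, rescored on
  the full composite at 40,000 genealogies with a seed shared across
  models;
* ratio recovery: 10 replicate datasets, model-6 refits (2 restarts, 8
  screening draws each, 10 cycles) with the pooled search objective at
  3,000 genealogies, rescored at 40,000.

The full-fidelity protocol (50 restarts, 40 cycles, 100,000 genealogies
per evaluation, 100 bootstrap spectra) is exposed through the same
functions and the CLI.

## Identifiability

Two structural facts about this design surfaced repeatedly in calibration
and are worth recording.  First, with sampling spans of only ~7 generations
and N in the tens of thousands, absolute sizes are informed almost entirely
by the serial sampling (the equilibrium SFS shape is size-free), so
parameter precision degrades quickly for histories whose size changes sit
outside the sampled window.  Second, the deep-history parameters
(NPREBOT, TCAR, NANC) trade off along a likelihood ridge: shortening the
pre-bottleneck plateau while inflating its size changes the spectrum very
little (~2 log-units at L = 1068 even at high fidelity).  Refits of
simulated data therefore scatter widely in NPREBOT — and hence in the
decline ratio NBOT/NPREBOT — no matter how thorough the optimizer;
confidence intervals obtained by refitting from the ML values (the usual
bootstrap practice) are local and understate this global uncertainty.

## Genotype filters and diversity statistics

The filter chain applies, in order: individual missingness (> 50%
discarded, strictly), locus presence (≥ 95% typed), first SNP per contig,
one-pass heterozygosity-outlier removal (> mean + 3 SD of the per-individual
heterozygous-call proportion), and a Hardy-Weinberg exact test (full
enumeration, individuals pooled, p < 0.001 removed; monomorphic loci are
retained untested).  Upstream depth/quality/strand filters are assumed
already applied to the input VCF.

Diversity: per-locus observed heterozygosity; Nei gene diversity with
small-sample correction `H_exp = n/(n−1)(1 − p² − q² − H_obs/(2n))`;
`F_IS = 1 − H_obs/H_exp` (loci with zero gene diversity excluded from the
F_IS average); nucleotide diversity as the sum of per-site unbiased
heterozygosity over a contig's SNPs divided by the 140-bp window length,
with individual-bootstrap percentile CIs.

## Census demography

Peak-spawning abundance discounts mature abundance by total mortality to
the within-year spawning moment, `N_ps,t = Σ_a N_a,t m_a e^{−p Z_a,t}` with
p = 10/12 (a November spawning peak).  Female generation length is the
egg-production-weighted mean female age; male generation length assumes
equal contribution per mature fish; years are averaged with equal weight.
Fecundity-at-age is an input schedule (derived externally from age-length
and length-fecundity relations).

## Synthetic data

The generators exist so every stage can be exercised without the archived
genotypes.  Cohort genotype matrices draw per-locus folded SFS entries from
an engine-estimated expected spectrum (multinomially, matching the
one-SNP-per-locus independence assumption), place minor alleles uniformly
on haplotypes within cohorts, and pair haplotypes into diploids; missingness
is i.i.d. per call with an optional per-individual multiplier.  They do not
emulate genotyping error, allele dropout, linked SNPs, or structured
missingness, so passing tests demonstrate correctness of the statistical
machinery, not robustness to those artifacts.  The filter test-set plants
deterministic violations of each rule (including exact-boundary cases) with
the intended survivor sets recorded; the age-table generator stores its
closed-form generation length and peak abundance.

## Numerical details and limitations

* Expected spectra are dense float arrays (~3.3M entries, 26 MB at the
  full design); observed spectra are integer arrays of the same shape.
* Optimization treats times as continuous; reported estimates are not
  rounded.
* The pooled-likelihood threshold C = 2 is used by the desk-scale
  protocols; C is exposed everywhere it matters.
* Self-complementary folding behaviour (entries at exactly half the pooled
  total) is a convention; any consistent choice conserves mass.
* No migration, population structure, selection, recombination within
  loci, or multiple-merger coalescent behaviour is modelled.
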