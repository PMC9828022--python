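"""Synthetic datasets with known truth for every stage of the analysis.

Three generators, all pure functions of their parameters and a seed:

* cohort genotype matrices drawn under a known demography (per-locus SFS
  entries from the coalescent engine's expected spectrum, alleles assigned
  uniformly within cohorts, i.i.d. missingness);
* a pre-filter genotype matrix with planted violations of each filter rule
  and the intended survivor sets recorded;
* age-structured abundance tables whose generation length and peak-spawning
  abundance are known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .census import AgeStructuredTable
from .engine import SimulationConfig, expected_sfs
from .models import ParameterVector, SampleSpec
from .popgen import GenotypeMatrix
from .sfs import MultiSFS

__all__ = [
    "TruthRecord",
    "generate_cohort_genotypes",
    "generate_filter_testset",
    "generate_age_table",
    "write_cohort_table",
]


@dataclass
class TruthRecord:
    """Everything needed to verify a generated dataset."""

    seed: int
    params: ParameterVector | None = None
    samples: SampleSpec | None = None
    entries: np.ndarray | None = None  # (L, n_cohorts) folded entry per locus
    surviving_individuals: list[str] | None = None
    surviving_loci: list[str] | None = None
    stage_survivors: dict[str, list[str]] | None = None
    generation_length: tuple[float, float, float] | None = None
    peak_abundance: dict[int, float] | None = None
    extra: dict[str, Any] = field(default_factory=dict)


def generate_cohort_genotypes(
    params: ParameterVector,
    samples: SampleSpec,
    L: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    per_individual_missing_scale: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Biallelic one-SNP-per-contig genotypes for serially sampled cohorts.

    Each locus takes a folded SFS entry drawn from the demography's expected
    spectrum; the minor-allele copies are assigned to uniformly chosen
    haplotypes within each cohort and paired into diploids.  Missingness is
    i.i.d. per call at ``missing_rate``, optionally scaled per individual.
    """
    if L < 1:
        raise ValueError("need at least one locus")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if any(n % 2 for n in samples.n_haploid):
        raise ValueError("haploid sample sizes must be even (diploids)")
    rng = np.random.default_rng(seed)
    cfg = cfg or SimulationConfig(n_sims=20_000)
    exp = expected_sfs(params, samples, SimulationConfig(cfg.n_sims, int(rng.integers(2**31 - 1))))
    flat = np.asarray(exp.counts, dtype=float).ravel()
    locus_flat = rng.choice(flat.size, size=L, p=flat / flat.sum())
    entries = np.stack(np.unravel_index(locus_flat, exp.dims), axis=1)
    n_ind = samples.total // 2
    calls = np.zeros((n_ind, L), dtype=np.int8)
    cohort_starts = np.cumsum([0] + [n // 2 for n in samples.n_haploid])
    sample_names = []
    cohort_labels = []
    for c, lab in enumerate(samples.labels):
        n_dip = samples.n_haploid[c] // 2
        sample_names += [f"{lab}_ind{i:03d}" for i in range(n_dip)]
        cohort_labels += [lab] * n_dip
    for j in range(L):
        for c in range(samples.n_cohorts):
            n_hap = samples.n_haploid[c]
            alt = int(entries[j, c])
            hap = np.zeros(n_hap, dtype=np.int8)
            hap[rng.choice(n_hap, size=alt, replace=False)] = 1
            dip = hap[0::2] + hap[1::2]
            calls[cohort_starts[c] : cohort_starts[c + 1], j] = dip
    if missing_rate > 0:
        rate = np.full(n_ind, missing_rate)
        if per_individual_missing_scale is not None:
            rate = np.clip(rate * per_individual_missing_scale, 0.0, 0.95)
        miss = rng.random(calls.shape) < rate[:, None]
        calls[miss] = -1
    contigs = tuple(f"contig{j:05d}" for j in range(L))
    positions = tuple(1 + (j % 120) for j in range(L))
    g = GenotypeMatrix(
        calls,
        tuple(sample_names),
        contigs,
        positions,
        tuple(cohort_labels),
    )
    truth = TruthRecord(
        seed=seed, params=params, samples=samples, entries=entries
    )
    return g, truth


def write_cohort_table(g: GenotypeMatrix, path) -> None:
    pd.DataFrame({"sample": g.samples, "cohort": g.cohorts}).to_csv(
        path, sep="\t", index=False
    )


def generate_filter_testset(seed: int = 0) -> tuple[GenotypeMatrix, TruthRecord]:
    """Pre-filter matrix with planted violations of every filter rule.

    Plants: two individuals above and one exactly at the 50% missingness
    boundary; one locus just under and one exactly at 95% presence;
    multi-SNP contigs; one heterozygosity outlier; one locus far out of
    Hardy-Weinberg proportions.  The intended survivors of each stage are
    recorded in the truth record.
    """
    rng = np.random.default_rng(seed)
    n_base = 20  # well-behaved individuals
    loci = (
        [("ctgA", 10), ("ctgA", 90)]  # second SNP on ctgA must go
        + [(f"ctg{i:02d}", 5) for i in range(1, 12)]  # singleton contigs
        + [("ctgLOW", 5), ("ctgBOUND", 5), ("ctgHWE", 5)]
    )
    n_loci = len(loci)  # 16
    names = [f"ind{i:02d}" for i in range(n_base)]
    # deterministic background at allele frequency 0.5 and perfect HWP:
    # each column has 10 heterozygotes and 5/5 homozygotes, and each row is
    # heterozygous at half its loci, so the het-proportion distribution is
    # tight around 0.5 and the planted outlier is unambiguous
    ii = np.arange(n_base)[:, None]
    jj = np.arange(n_loci)[None, :]
    het = (ii + jj) % 2 == 0
    hom_alt = (ii // 2) % 2 == 1
    base = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
    # HWP-violating locus: 10/10 homozygotes, no heterozygotes
    hwe_col = loci.index(("ctgHWE", 5))
    base[:, hwe_col] = np.where(ii[:, 0] % 2 == 0, 0, 2)
    calls = base
    low_col = loci.index(("ctgLOW", 5))
    bound_col = loci.index(("ctgBOUND", 5))
    # individuals: 2 discards (>50% missing), 1 boundary (exactly 50%)
    extra_names = ["miss60a", "miss60b", "miss50", "hetout"]
    extras = np.zeros((4, n_loci), dtype=np.int8)
    n_missing_60 = n_loci // 2 + 1  # just past the strict > 50% boundary
    for row in (0, 1):
        extras[row] = rng.choice([0, 1, 2], size=n_loci).astype(np.int8)
        extras[row, :n_missing_60] = -1
    # exactly 50% missing: kept by the strict > rule (requires even n_loci)
    assert n_loci % 2 == 0
    extras[2] = np.where(jj[0] % 2 == 1, 1, 0).astype(np.int8)
    extras[2, : n_loci // 2] = -1
    # heterozygosity outlier: heterozygous everywhere
    extras[3] = np.ones(n_loci, dtype=np.int8)
    calls = np.vstack([calls, extras])
    names = names + extra_names
    # plant missingness driving the locus-presence filter: with 22 surviving
    # individuals, 2 missing -> 20/22 = 0.91 < 0.95 (drop) and 1 missing ->
    # 21/22 = 0.955 >= 0.95 (keep)
    calls[0, low_col] = -1
    calls[1, low_col] = -1
    calls[0, bound_col] = -1
    cohorts = tuple(
        ["c1994"] * 7 + ["c1997"] * 7 + ["c2008"] * (len(names) - 14)
    )
    g = GenotypeMatrix(
        calls,
        tuple(names),
        tuple(c for c, _ in loci),
        tuple(p_ for _, p_ in loci),
        cohorts,
    )
    after_missing = [n for n in names if n not in ("miss60a", "miss60b")]
    after_presence = [f"{c}:{p_}" for c, p_ in loci if c != "ctgLOW"]
    after_first = [s for s in after_presence if s != "ctgA:90"]
    after_het = [n for n in after_missing if n != "hetout"]
    after_hwp = [s for s in after_first if s != "ctgHWE:5"]
    truth = TruthRecord(
        seed=seed,
        surviving_individuals=after_het,
        surviving_loci=after_hwp,
        stage_survivors={
            "individual_missingness": after_missing,
            "locus_presence": after_presence,
            "first_snp_per_contig": after_first,
            "het_outliers": after_het,
            "hwp": after_hwp,
        },
    )
    return g, truth


def generate_age_table(
    A: int = 7,
    years: list[int] | None = None,
    seed: int = 0,
    peak_fraction: float = 10.0 / 12.0,
) -> tuple[AgeStructuredTable, TruthRecord]:
    """Random but reproducible age-structured table with closed-form truth.

    Schedules loosely emulate a moderately exploited flatfish stock:
    abundance declining with age, total mortality 0.2-1.0 per year, knife-
    edge-ish maturity and fecundity increasing with age.
    """
    if A < 1:
        raise ValueError("need at least one age class")
    years = years or [2000, 2001, 2002]
    rng = np.random.default_rng(seed)
    rows = []
    for y in years:
        n0 = rng.uniform(1e4, 1e6)
        surv = rng.uniform(0.4, 0.8)
        for a in range(A + 1):
            rows.append(
                {
                    "year": y,
                    "age": a,
                    "N": n0 * surv**a,
                    "Z": rng.uniform(0.2, 1.0),
                    "maturity": float(np.clip((a - 0.5) / 2.5, 0.0, 1.0)),
                    "fecundity": 0.0 if a == 0 else 1e3 * a**1.5,
                }
            )
    tbl = AgeStructuredTable(pd.DataFrame(rows), peak_fraction)
    # closed-form truth, computed entry by entry
    peak = {}
    fems, males = [], []
    for y in years:
        d = [r for r in rows if r["year"] == y]
        peak[y] = sum(
            r["N"] * r["maturity"] * np.exp(-peak_fraction * r["Z"]) for r in d
        )
        egg_w = [r["N"] * r["maturity"] * r["fecundity"] for r in d]
        mat_w = [r["N"] * r["maturity"] for r in d]
        ages = [r["age"] for r in d]
        fems.append(
            sum(a * w for a, w in zip(ages, egg_w)) / sum(egg_w)
        )
        males.append(
            sum(a * w for a, w in zip(ages, mat_w)) / sum(mat_w)
        )
    f = float(np.mean(fems))
    m = float(np.mean(males))
    truth = TruthRecord(
        seed=seed,
        generation_length=(f, m, (f + m) / 2.0),
        peak_abundance=peak,
    )
    return tbl, truth
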