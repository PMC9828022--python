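"""Genotype-matrix filtering and diversity statistics for RAD SNP panels.

The filter chain mirrors the standard post-variant-calling protocol for
ddRAD genotypes: drop individuals with more than half their calls missing,
keep loci typed in at least 95% of the remaining individuals, keep only the
first SNP of each contig (unlinked panel), drop individuals whose
heterozygosity lies more than three standard deviations above the mean
(library contamination), and drop loci out of Hardy-Weinberg proportions at
p < 0.001 (exact test, individuals pooled).

Diversity statistics: per-locus observed heterozygosity, Nei gene diversity
with small-sample correction, Wright's F_IS, and nucleotide diversity pi
summed over the SNPs of each contig window and divided by the window length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "DiversityReport",
    "filter_individuals_by_missingness",
    "filter_loci_by_presence",
    "first_snp_per_contig",
    "remove_het_outlier_individuals",
    "hwp_filter",
    "hwe_exact_pvalue",
    "heterozygosity_stats",
    "windowed_pi",
    "pi_bootstrap_ci",
    "apply_standard_filters",
    "read_vcf",
    "write_vcf",
    "read_cohort_table",
]

MISSING = -1


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x loci biallelic genotypes (0/1/2 alt copies, -1 missing)."""

    calls: np.ndarray  # int8 (n_individuals, n_loci)
    samples: tuple[str, ...]
    contigs: tuple[str, ...]
    positions: tuple[int, ...]
    cohorts: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n_ind, n_loc = self.calls.shape
        if len(self.samples) != n_ind:
            raise ValueError("sample names do not match matrix rows")
        if len(self.contigs) != n_loc or len(self.positions) != n_loc:
            raise ValueError("locus metadata does not match matrix columns")
        if self.cohorts is not None and len(self.cohorts) != n_ind:
            raise ValueError("cohort labels do not match matrix rows")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        seen = {}
        for c, p in zip(self.contigs, self.positions):
            if (c, p) in seen:
                raise ValueError(f"duplicate position {p} on contig {c}")
            seen[(c, p)] = True

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def take_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            calls=self.calls[mask],
            samples=tuple(np.array(self.samples)[mask]),
            cohorts=(
                tuple(np.array(self.cohorts)[mask]) if self.cohorts else None
            ),
        )

    def take_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            calls=self.calls[:, mask],
            contigs=tuple(np.array(self.contigs)[mask]),
            positions=tuple(int(p) for p in np.array(self.positions)[mask]),
        )


@dataclass
class DiversityReport:
    per_locus: pd.DataFrame  # columns: contig, pos, n, h_obs, h_exp, f_is
    cohort_means: pd.DataFrame  # columns: cohort, h_obs, h_exp, f_is, pi
    windows: pd.DataFrame  # columns: cohort, contig, pi
    pi_ci: dict[str, tuple[float, float]] | None = None


# ---------------------------------------------------------------------- #
# filters
# ---------------------------------------------------------------------- #


def filter_individuals_by_missingness(
    g: GenotypeMatrix, threshold: float = 0.5
) -> GenotypeMatrix:
    """Drop individuals whose missing fraction exceeds ``threshold`` (strict)."""
    frac = (g.calls == MISSING).mean(axis=1)
    keep = frac <= threshold
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    return g.take_individuals(keep)


def filter_loci_by_presence(
    g: GenotypeMatrix, presence: float = 0.95
) -> GenotypeMatrix:
    """Keep loci typed in at least ``presence`` of individuals."""
    frac = (g.calls != MISSING).mean(axis=0)
    # guard the boundary against float round-off (19/20 == 0.95 must pass)
    return g.take_loci(frac >= presence - 1e-12)


def first_snp_per_contig(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the smallest-position SNP of each contig."""
    best: dict[str, int] = {}
    for j, (c, p) in enumerate(zip(g.contigs, g.positions)):
        if c not in best or p < g.positions[best[c]]:
            best[c] = j
    mask = np.zeros(g.n_loci, dtype=bool)
    mask[list(best.values())] = True
    return g.take_loci(mask)


def remove_het_outlier_individuals(
    g: GenotypeMatrix, k_sd: float = 3.0
) -> GenotypeMatrix:
    """One-pass removal of individuals with outlying heterozygosity.

    The heterozygous-call proportion over non-missing loci is computed per
    individual; anyone above mean + k_sd x SD of that (pre-removal)
    distribution is dropped.
    """
    if g.n_individuals < 2:
        return g
    typed = (g.calls != MISSING).sum(axis=1)
    het = (g.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(typed > 0, het / typed, 0.0)
    thresh = prop.mean() + k_sd * prop.std(ddof=0)
    return g.take_individuals(prop <= thresh)


def hwe_exact_pvalue(n_het: int, n_hom_alt: int, n_hom_ref: int) -> float:
    """Exact Hardy-Weinberg test p-value by full enumeration.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    configuration's.
    """
    n = n_het + n_hom_alt + n_hom_ref
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0
    # log-probabilities of each possible het count (same parity as rare)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array(
        [
            math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma((n_alt - h) // 2 + 1)
            - math.lgamma((n_ref - h) // 2 + 1)
            + h * math.log(2.0)
            for h in hets
        ]
    )
    logp -= (
        math.lgamma(2 * n + 1)
        - math.lgamma(n_alt + 1)
        - math.lgamma(n_ref + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def hwp_filter(g: GenotypeMatrix, alpha: float = 0.001) -> GenotypeMatrix:
    """Drop loci out of Hardy-Weinberg proportions (pooled individuals).

    Monomorphic loci are retained untested.
    """
    keep = np.ones(g.n_loci, dtype=bool)
    for j in range(g.n_loci):
        col = g.calls[:, j]
        het = int((col == 1).sum())
        alt = int((col == 2).sum())
        ref = int((col == 0).sum())
        n_alt = 2 * alt + het
        n_ref = 2 * ref + het
        if n_alt == 0 or n_ref == 0:
            continue
        if hwe_exact_pvalue(het, alt, ref) < alpha:
            keep[j] = False
    return g.take_loci(keep)


def apply_standard_filters(
    g: GenotypeMatrix,
    missing_threshold: float = 0.5,
    presence: float = 0.95,
    het_k_sd: float = 3.0,
    hwp_alpha: float = 0.001,
) -> GenotypeMatrix:
    """The full chain, in protocol order.

    Upstream site-annotation filters (quality, depth, strand heuristics) are
    assumed already applied to the input VCF and are not re-implemented.
    """
    g = filter_individuals_by_missingness(g, missing_threshold)
    g = filter_loci_by_presence(g, presence)
    g = first_snp_per_contig(g)
    g = remove_het_outlier_individuals(g, het_k_sd)
    g = hwp_filter(g, hwp_alpha)
    return g


# ---------------------------------------------------------------------- #
# diversity statistics
# ---------------------------------------------------------------------- #


def _locus_stats(col: np.ndarray) -> tuple[int, float, float, float]:
    """(n typed, H_obs, H_exp, F_IS) for one locus; F_IS is nan if H_exp=0."""
    typed = col != MISSING
    n = int(typed.sum())
    if n < 2:
        raise ValueError("need at least two typed individuals per locus")
    calls = col[typed]
    h_obs = float((calls == 1).mean())
    p = float(calls.sum()) / (2 * n)
    q = 1.0 - p
    h_exp = n / (n - 1) * (1.0 - p * p - q * q - h_obs / (2 * n))
    f_is = 1.0 - h_obs / h_exp if h_exp > 0 else math.nan
    return n, h_obs, h_exp, f_is


def heterozygosity_stats(
    g: GenotypeMatrix, by_cohort: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus and cohort-mean H_obs, H_exp (Nei, corrected) and F_IS.

    Cohort means average across loci; loci with zero gene diversity are
    excluded from the F_IS average only.
    """
    groups: dict[str, np.ndarray]
    if by_cohort and g.cohorts is not None:
        labs = np.array(g.cohorts)
        groups = {lab: labs == lab for lab in dict.fromkeys(g.cohorts)}
    else:
        groups = {"all": np.ones(g.n_individuals, dtype=bool)}
    per_rows = []
    mean_rows = []
    for lab, rows in groups.items():
        sub = g.calls[rows]
        stats = []
        for j in range(g.n_loci):
            n, ho, he, fis = _locus_stats(sub[:, j])
            stats.append((lab, g.contigs[j], g.positions[j], n, ho, he, fis))
        df = pd.DataFrame(
            stats,
            columns=["cohort", "contig", "pos", "n", "h_obs", "h_exp", "f_is"],
        )
        per_rows.append(df)
        mean_rows.append(
            {
                "cohort": lab,
                "h_obs": df["h_obs"].mean(),
                "h_exp": df["h_exp"].mean(),
                "f_is": df["f_is"].dropna().mean(),
            }
        )
    return pd.concat(per_rows, ignore_index=True), pd.DataFrame(mean_rows)


def _window_pi(sub: np.ndarray, cols: Sequence[int], window: float) -> float:
    """Summed per-site heterozygosity of the window's SNPs over its length."""
    tot = 0.0
    for j in cols:
        col = sub[:, j]
        typed = col != MISSING
        c = 2 * int(typed.sum())
        if c < 2:
            continue
        a = int(col[typed].sum())
        tot += 2.0 * a * (c - a) / (c * (c - 1))
    return tot / window


def windowed_pi(
    g: GenotypeMatrix, window: float = 140.0, by_cohort: bool = True
) -> pd.DataFrame:
    """Nucleotide diversity per contig window (all SNPs on the contig)."""
    if window <= 0:
        raise ValueError("window length must be positive")
    if by_cohort and g.cohorts is not None:
        labs = np.array(g.cohorts)
        groups = {lab: labs == lab for lab in dict.fromkeys(g.cohorts)}
    else:
        groups = {"all": np.ones(g.n_individuals, dtype=bool)}
    contig_cols: dict[str, list[int]] = {}
    for j, c in enumerate(g.contigs):
        contig_cols.setdefault(c, []).append(j)
    rows = []
    for lab, sel in groups.items():
        sub = g.calls[sel]
        for contig, cols in contig_cols.items():
            rows.append(
                {
                    "cohort": lab,
                    "contig": contig,
                    "pi": _window_pi(sub, cols, window),
                }
            )
    return pd.DataFrame(rows)


def pi_bootstrap_ci(
    g: GenotypeMatrix,
    reps: int = 1000,
    seed: int | None = None,
    window: float = 140.0,
    by_cohort: bool = True,
) -> dict[str, tuple[float, float]]:
    """95% CI of mean windowed pi by bootstrapping individuals."""
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    rng = np.random.default_rng(seed)
    if by_cohort and g.cohorts is not None:
        labs = np.array(g.cohorts)
        groups = {
            lab: np.flatnonzero(labs == lab) for lab in dict.fromkeys(g.cohorts)
        }
    else:
        groups = {"all": np.arange(g.n_individuals)}
    contig_cols: dict[str, list[int]] = {}
    for j, c in enumerate(g.contigs):
        contig_cols.setdefault(c, []).append(j)
    out = {}
    for lab, rows in groups.items():
        means = np.empty(reps)
        for b in range(reps):
            pick = rng.choice(rows, size=rows.size, replace=True)
            sub = g.calls[pick]
            vals = [
                _window_pi(sub, cols, window) for cols in contig_cols.values()
            ]
            means[b] = float(np.mean(vals))
        lo, hi = np.percentile(means, [2.5, 97.5])
        out[lab] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #


def read_vcf(path, cohort_of: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load biallelic SNP genotypes (GT field) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    calls = []
    contigs = []
    positions = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        calls.append(col)
        contigs.append(rec.CHROM)
        positions.append(rec.POS)
    if not calls:
        raise ValueError(f"no biallelic SNPs found in {path}")
    cohorts = (
        tuple(cohort_of[s] for s in samples) if cohort_of is not None else None
    )
    return GenotypeMatrix(
        np.array(calls, dtype=np.int8).T,
        samples,
        tuple(contigs),
        tuple(positions),
        cohorts,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal uncompressed VCF (GT only)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j in range(g.n_loci):
            gts = "\t".join(code[int(v)] for v in g.calls[:, j])
            fh.write(
                f"{g.contigs[j]}\t{g.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_cohort_table(path) -> dict[str, str]:
    """sample -> cohort mapping from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if set(c.lower() for c in cols[:2]) != {"sample", "cohort"}:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df.columns = ["sample", "cohort"] + list(df.columns[2:])
    else:
        df.columns = [c.lower() for c in cols]
    return dict(zip(df["sample"], df["cohort"]))
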