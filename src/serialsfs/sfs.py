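"""Multidimensional site frequency spectra over serially sampled cohorts.

A :class:`MultiSFS` is a dense array over the index grid
``(i_1, ..., i_c)`` with ``i_k`` = copies of the alternate (or, once folded,
pooled-minor) allele in cohort ``k``.  Observed spectra hold locus counts;
expected spectra hold probabilities normalized over polymorphic entries.
Folding is by the allele that is minor in the pooled sample across all
cohorts; per-cohort folding is applied only when marginalizing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["CohortInfo", "MultiSFS", "read_obs", "write_obs", "sfs_from_genotypes"]


@dataclass(frozen=True)
class CohortInfo:
    label: str
    n_haploid: int
    time: float = 0.0


def _complement_view(a: np.ndarray) -> np.ndarray:
    """View of ``a`` with every axis index i replaced by n-i."""
    return a[tuple(slice(None, None, -1) for _ in range(a.ndim))]


def _pooled_grid(dims: Sequence[int]) -> np.ndarray:
    """Pooled alternate-allele count at every grid entry."""
    pool = np.zeros((), dtype=np.int64)
    for ax, d in enumerate(dims):
        shape = [1] * len(dims)
        shape[ax] = d
        pool = pool + np.arange(d, dtype=np.int64).reshape(shape)
    return pool


@dataclass(frozen=True)
class MultiSFS:
    """Folded or unfolded multidimensional SFS; counts or probabilities."""

    counts: np.ndarray
    cohorts: tuple[CohortInfo, ...]
    folded: bool = False
    kind: str = "counts"  # "counts" | "prob"
    n_sims: int | None = None  # Monte-Carlo fidelity of an expected spectrum

    def __post_init__(self) -> None:
        dims = tuple(c.n_haploid + 1 for c in self.cohorts)
        if self.counts.shape != dims:
            raise ValueError(
                f"array shape {self.counts.shape} does not match cohorts {dims}"
            )
        if self.kind not in ("counts", "prob"):
            raise ValueError("kind must be 'counts' or 'prob'")
        if np.any(self.counts < 0):
            raise ValueError("spectrum entries must be non-negative")

    # -- basic views ----------------------------------------------------

    @property
    def dims(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.cohorts)

    @property
    def pooled_total(self) -> int:
        return int(sum(c.n_haploid for c in self.cohorts))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def monomorphic_mask(self) -> np.ndarray:
        m = np.zeros(self.dims, dtype=bool)
        m[tuple(0 for _ in self.dims)] = True
        m[tuple(d - 1 for d in self.dims)] = True
        return m

    # -- operations ------------------------------------------------------

    def fold(self) -> "MultiSFS":
        """Fold by the pooled minor allele.

        Each entry is paired with its complement; mass lands on the member
        whose pooled count is at most half the pooled total.  Entries at
        exactly half stay in place with full weight.
        """
        if self.folded:
            raise ValueError("spectrum is already folded")
        pool = _pooled_grid(self.dims)
        tot = self.pooled_total
        comp = _complement_view(self.counts)
        out = np.where(
            2 * pool < tot,
            self.counts + comp,
            np.where(2 * pool == tot, self.counts, 0),
        ).astype(self.counts.dtype)
        return replace(self, counts=out, folded=True)

    def remove_monomorphic(self) -> "MultiSFS":
        """Zero the fixed entries; renormalize probability spectra."""
        out = self.counts.copy()
        out[tuple(0 for _ in self.dims)] = 0
        out[tuple(d - 1 for d in self.dims)] = 0
        s = out.sum()
        if s == 0:
            raise ValueError("all mass is monomorphic")
        if self.kind == "prob":
            out = out / s
        return replace(self, counts=out)

    def marginalize(self, cohort: str) -> np.ndarray:
        """Per-cohort folded one-dimensional SFS (sums over other cohorts)."""
        if cohort not in self.labels:
            raise KeyError(f"unknown cohort {cohort!r}")
        ax = self.labels.index(cohort)
        other = tuple(i for i in range(len(self.dims)) if i != ax)
        marg = self.counts.sum(axis=other)
        n = self.cohorts[ax].n_haploid
        out = np.zeros_like(marg)
        for i in range(n + 1):
            j = min(i, n - i)
            out[j] += marg[i]
        return out

    def bootstrap_resample(self, rng: np.random.Generator | int) -> "MultiSFS":
        """Multinomial resample of the observed loci (total preserved)."""
        if self.kind != "counts":
            raise ValueError("bootstrap resampling needs an observed spectrum")
        L = self.counts.sum()
        if L < 1:
            raise ValueError("empty spectrum")
        gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
        flat = np.asarray(self.counts, dtype=float).ravel()
        draw = gen.multinomial(int(round(L)), flat / flat.sum())
        return replace(self, counts=draw.reshape(self.dims).astype(self.counts.dtype))

    # -- invariant helpers (used by tests and sanity checks) -------------

    def check(self, atol: float = 1e-9) -> None:
        if self.kind == "prob":
            poly = ~self.monomorphic_mask()
            s = self.counts[poly].sum()
            if not math.isclose(s, 1.0, abs_tol=atol):
                raise AssertionError(f"polymorphic mass {s} != 1")
        if self.folded:
            pool = _pooled_grid(self.dims)
            bad = (2 * pool > self.pooled_total) & (self.counts > 0)
            if np.any(bad):
                raise AssertionError("folded spectrum has mass above half-total")


def sfs_from_genotypes(genotypes, cohort_of: dict[str, str] | None = None) -> MultiSFS:
    """Observed folded multiSFS from a genotype matrix, complete loci only.

    ``genotypes`` is a :class:`serialsfs.popgen.GenotypeMatrix`; loci with
    any missing call are excluded (the complete-data rule used before
    demographic fitting).  ``cohort_of`` optionally overrides the matrix's
    own sample-to-cohort labels.
    """
    g = genotypes
    labels = list(g.cohorts)
    if cohort_of is not None:
        labels = [cohort_of[s] for s in g.samples]
    if any(l is None for l in labels):
        raise ValueError("every individual needs a cohort label")
    order = list(dict.fromkeys(labels))
    complete = ~np.any(g.calls < 0, axis=0)
    if not complete.any():
        raise ValueError("no loci with complete data")
    calls = g.calls[:, complete]
    cohorts = []
    per_cohort_alt = []
    lab_arr = np.array(labels)
    for lab in order:
        rows = lab_arr == lab
        cohorts.append(CohortInfo(lab, int(2 * rows.sum())))
        per_cohort_alt.append(calls[rows].sum(axis=0))
    dims = tuple(c.n_haploid + 1 for c in cohorts)
    counts = np.zeros(dims, dtype=np.int64)
    np.add.at(counts, tuple(a for a in per_cohort_alt), 1)
    raw = MultiSFS(counts, tuple(cohorts), folded=False, kind="counts")
    return raw.fold()


# -- fastsimcoal-style .obs serialization --------------------------------


def write_obs(s: MultiSFS, path) -> None:
    """Write one canonical multiSFS ``.obs`` dialect.

    Line 1: ``1 observations``; line 2: number of demes followed by the
    haploid sample sizes; then the flattened entries with the last cohort's
    index varying fastest (C order).
    """
    flat = np.asarray(s.counts).ravel(order="C")
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        sizes = "\t".join(str(c.n_haploid) for c in s.cohorts)
        fh.write(f"{len(s.cohorts)}\t{sizes}\n")
        if s.kind == "counts" and np.allclose(flat, np.round(flat)):
            fh.write("\t".join(str(int(round(v))) for v in flat) + "\n")
        else:
            fh.write("\t".join(repr(float(v)) for v in flat) + "\n")


def read_obs(
    path,
    labels: Sequence[str] | None = None,
    times: Sequence[float] | None = None,
    folded: bool = True,
    kind: str = "counts",
) -> MultiSFS:
    """Read a multiSFS ``.obs`` file (whitespace-tolerant)."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not re.match(r"^\s*\d+\s+observation", lines[0]):
        raise ValueError("not a multiSFS .obs file")
    head = lines[1].split()
    ndem = int(head[0])
    sizes = [int(v) for v in head[1 : 1 + ndem]]
    vals = np.array(" ".join(lines[2:]).split(), dtype=float)
    dims = tuple(n + 1 for n in sizes)
    if vals.size != int(np.prod(dims)):
        raise ValueError(
            f"expected {int(np.prod(dims))} entries, found {vals.size}"
        )
    if labels is None:
        labels = [f"deme{i}" for i in range(ndem)]
    if times is None:
        times = [0.0] * ndem
    arr = vals.reshape(dims)
    if kind == "counts" and np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    cohorts = tuple(
        CohortInfo(str(l), n, float(t)) for l, n, t in zip(labels, sizes, times)
    )
    return MultiSFS(arr, cohorts, folded=folded, kind=kind)
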