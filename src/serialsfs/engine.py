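"""Serial-sampling coalescent simulation and Monte-Carlo expected spectra.

Genealogies are drawn under a piecewise-exponential backward-time size
function with lineages entering at their cohort sampling times; ``k``
lineages coalesce at rate ``C(k,2)/N(t)`` (haploid units), with waiting
times inverted in closed form through exponential epochs.  The estimand is
the low-mutation-limit SFS conditional on polymorphism,

    p_e = E[L_e] / E[L_tot],

where ``L_e`` is the total length of branches subtending entry ``e``.  A
single mutation placed uniformly on one genealogy must therefore be weighted
by that genealogy's total branch length; :func:`simulate_entry` returns the
weight alongside the entry, and :func:`expected_sfs` tallies every branch of
every genealogy by its length (the zero-variance-per-tree version of the
same estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import EpochTimeline, ParameterVector, SampleSpec, build_timeline
from .sfs import CohortInfo, MultiSFS

__all__ = ["SimulationConfig", "simulate_entry", "expected_sfs"]

_MASK = (1 << 20) - 1  # cohort counts packed 20 bits apiece (3 cohorts max)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings: genealogies per expected-SFS estimate, seed."""

    n_sims: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")


@njit(cache=True)
def _sim_kernel(
    n_loci,
    ep_end,
    ep_n0,
    ep_r,
    ep_exp_end,
    samp_t,
    samp_n,
    strides,
    out,
    draw_entries,
    draw_weights,
    weighted,
    seed,
):
    # Cohorts arrive sorted by sampling time ascending; counts are packed
    # into one int64 (20 bits per cohort) so that merging lineages is a
    # single integer addition.  Within an exponential epoch the factor
    # exp(-r*(t-start)) is carried forward between events instead of being
    # recomputed.
    np.random.seed(seed)
    ncoh = samp_n.shape[0]
    ntot = 0
    for c in range(ncoh):
        ntot += samp_n[c]
    cnt = np.zeros(ntot, np.int64)
    birth = np.zeros(ntot, np.float64)
    bl = np.zeros(2 * ntot, np.float64)
    bc = np.zeros(2 * ntot, np.int64)
    n_ep = ep_end.shape[0]
    ep_start = np.zeros(n_ep, np.float64)
    for i in range(1, n_ep):
        ep_start[i] = ep_end[i - 1]
    for loc in range(n_loci):
        k = 0
        nb = 0
        t = samp_t[0]
        nxt = 0
        while nxt < ncoh and samp_t[nxt] == t:
            unit = np.int64(1) << (20 * nxt)
            for _ in range(samp_n[nxt]):
                cnt[k] = unit
                birth[k] = t
                k += 1
            nxt += 1
        ei = 0
        a_cache = -1.0  # exp(-r*(t-start)) of the current epoch; <0 stale
        while k > 1 or nxt < ncoh:
            if k < 2:
                t = samp_t[nxt]
                a_cache = -1.0
                unit = np.int64(1) << (20 * nxt)
                for _ in range(samp_n[nxt]):
                    cnt[k] = unit
                    birth[k] = t
                    k += 1
                nxt += 1
                continue
            E = -np.log(np.random.random())
            pair = 0.5 * k * (k - 1)
            while True:
                while ei + 1 < n_ep and t >= ep_end[ei]:
                    ei += 1
                    a_cache = -1.0
                lim = ep_end[ei]
                sample_next = False
                if nxt < ncoh and samp_t[nxt] < lim:
                    lim = samp_t[nxt]
                    sample_next = True
                r = ep_r[ei]
                n0 = ep_n0[ei]
                if r == 0.0:
                    cap = pair * (lim - t) / n0 if lim < 1e300 else 1e308
                    if E <= cap:
                        tc = t + E * n0 / pair
                        break
                    a_end = -1.0
                else:
                    if a_cache < 0.0:
                        a_cache = np.exp(-r * (t - ep_start[ei]))
                    a = a_cache
                    if lim < 1e300:
                        if sample_next:
                            a_end = np.exp(-r * (lim - ep_start[ei]))
                        else:
                            a_end = ep_exp_end[ei]
                        cap = pair * (a - a_end) / (n0 * r)
                    else:
                        a_end = 0.0
                        cap = pair * a / (n0 * r) if r > 0 else 1e308
                    if E <= cap:
                        a_new = a - E * n0 * r / pair
                        tc = ep_start[ei] - np.log(a_new) / r
                        a_cache = a_new
                        break
                E -= cap
                t = lim
                if sample_next:
                    a_cache = a_end if r != 0.0 else -1.0
                    unit = np.int64(1) << (20 * nxt)
                    for _ in range(samp_n[nxt]):
                        cnt[k] = unit
                        birth[k] = t
                        k += 1
                    nxt += 1
                    E = -np.log(np.random.random())
                    pair = 0.5 * k * (k - 1)
                else:
                    ei += 1
                    a_cache = -1.0
            i1 = int(np.random.random() * k)
            i2 = int(np.random.random() * (k - 1))
            if i2 >= i1:
                i2 += 1
            t = tc
            bl[nb] = t - birth[i1]
            bl[nb + 1] = t - birth[i2]
            bc[nb] = cnt[i1]
            bc[nb + 1] = cnt[i2]
            cnt[i1] += cnt[i2]
            nb += 2
            birth[i1] = t
            k -= 1
            if i2 != k:
                cnt[i2] = cnt[k]
                birth[i2] = birth[k]
        tot = 0.0
        for b in range(nb):
            tot += bl[b]
        if weighted:
            # fold by pooled minor allele while tallying
            for b in range(nb):
                v = bc[b]
                idx = 0
                pool = 0
                for c in range(ncoh):
                    pool += (v >> (20 * c)) & _MASK
                flipped = 2 * pool > ntot
                for c in range(ncoh):
                    pc = (v >> (20 * c)) & _MASK
                    if flipped:
                        pc = samp_n[c] - pc
                    idx += strides[c] * pc
                out[idx] += bl[b]
        else:
            u = np.random.random() * tot
            acc = 0.0
            chosen = bc[nb - 1]
            for b in range(nb):
                acc += bl[b]
                if acc >= u:
                    chosen = bc[b]
                    break
            for c in range(ncoh):
                draw_entries[loc, c] = (chosen >> (20 * c)) & _MASK
            draw_weights[loc] = tot


def _prepare(timeline: EpochTimeline, samples: SampleSpec):
    if samples.n_cohorts > 3:
        raise ValueError("at most three cohorts are supported")
    if samples.total < 2:
        raise ValueError("need at least two haploid samples in total")
    if max(samples.n_haploid) >= _MASK:
        raise ValueError("cohort sample size too large for packed counts")
    end, n0, r = timeline.as_arrays()
    if np.any(n0 <= 0):
        raise ValueError("timeline has non-positive size")
    start = np.concatenate([[0.0], end[:-1]])
    exp_end = np.zeros_like(end)
    finite = np.isfinite(end)
    exp_end[finite] = np.exp(-r[finite] * (end[finite] - start[finite]))
    order = np.argsort(np.asarray(samples.times), kind="stable")
    samp_t = np.asarray([samples.times[i] for i in order], dtype=float)
    samp_n = np.asarray([samples.n_haploid[i] for i in order], dtype=np.int64)
    # stride of each (sorted) cohort in the C-ordered flat spectrum array
    dims = samples.dims
    c_strides = np.ones(len(dims), dtype=np.int64)
    for ax in range(len(dims) - 2, -1, -1):
        c_strides[ax] = c_strides[ax + 1] * dims[ax + 1]
    strides = np.asarray([c_strides[i] for i in order], dtype=np.int64)
    return end, n0, r, exp_end, samp_t, samp_n, strides, order


def simulate_entry(
    timeline: EpochTimeline,
    samples: SampleSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[tuple[int, ...], float]:
    """Draw one genealogy and one mutation; return (entry, importance weight).

    The entry is the unfolded per-cohort derived-allele count (cohorts in
    ``samples`` order); the weight is the genealogy's total branch length.
    Weighted averages of entry indicators estimate the polymorphic SFS.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = int(gen.integers(2**31 - 1))
    end, n0, r, exp_end, samp_t, samp_n, strides, order = _prepare(
        timeline, samples
    )
    entries = np.zeros((1, len(samp_n)), dtype=np.int64)
    weights = np.zeros(1)
    dummy = np.zeros(1)
    _sim_kernel(
        1, end, n0, r, exp_end, samp_t, samp_n, strides, dummy, entries,
        weights, False, seed,
    )
    # map sorted-cohort order back to the caller's cohort order
    unsorted = np.empty(len(samp_n), dtype=np.int64)
    unsorted[order] = entries[0]
    return tuple(int(v) for v in unsorted), float(weights[0])


def expected_sfs(
    params: ParameterVector | EpochTimeline,
    samples: SampleSpec,
    cfg: SimulationConfig | None = None,
) -> MultiSFS:
    """Monte-Carlo expected folded polymorphic spectrum (probabilities).

    Every branch of every simulated genealogy contributes its length to its
    folded entry; normalizing by the summed length gives
    ``E[L_e]/E[L_tot]``.  Reproducible under ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    timeline = build_timeline(params) if isinstance(params, ParameterVector) else params
    end, n0, r, exp_end, samp_t, samp_n, strides, _ = _prepare(
        timeline, samples
    )
    flat = np.zeros(int(np.prod(samples.dims)))
    seed = int(np.random.default_rng(cfg.seed).integers(2**31 - 1))
    dummy_e = np.zeros((1, len(samp_n)), dtype=np.int64)
    dummy_w = np.zeros(1)
    _sim_kernel(
        cfg.n_sims, end, n0, r, exp_end, samp_t, samp_n, strides, flat,
        dummy_e, dummy_w, True, seed,
    )
    total = flat.sum()
    if total <= 0:
        raise ValueError("simulation produced no branch length")
    arr = (flat / total).reshape(samples.dims)
    cohorts = tuple(
        CohortInfo(l, n, t)
        for l, n, t in zip(samples.labels, samples.n_haploid, samples.times)
    )
    return MultiSFS(arr, cohorts, folded=True, kind="prob", n_sims=cfg.n_sims)
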