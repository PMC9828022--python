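"""Composite-likelihood fitting of demographic models to an observed multiSFS.

The composite log-likelihood treats loci as independent draws from the
expected polymorphic spectrum: ``lnL = Σ_e O_e ln p_e`` (the multinomial
coefficient is constant across models and omitted).  Because the expected
spectrum is itself a Monte-Carlo estimate, each restart of the maximizer
uses common random numbers (one simulation seed for all of its likelihood
evaluations), turning the search surface deterministic, and the best
parameter vector of each model is rescored once with a fresh seed shared by
all models before AIC comparison so that max-over-noise bias does not favour
any model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .engine import SimulationConfig, expected_sfs
from .models import (
    MODEL_REGISTRY,
    T_LGM,
    ParameterVector,
    SampleSpec,
    free_param_count,
)
from .sfs import MultiSFS

__all__ = [
    "SearchRanges",
    "FitResult",
    "ModelSelectionTable",
    "composite_loglik",
    "composite_loglik_marginal",
    "ln_from_log10",
    "fit_model",
    "select_model",
]


@dataclass(frozen=True)
class SearchRanges:
    """Initialization ranges for the maximum-likelihood search.

    Sizes are drawn log-uniformly, bottleneck times uniformly, TCAR
    log-uniformly.  Lower bounds bound the search space; upper bounds limit
    only the initial draws.  ``widened`` switches to the sensitivity ranges
    (TBOT 1-30, TLEN 1-15); ``fix_tlen`` removes TLEN from the free set.
    """

    size_lo: float = 100.0
    size_hi: float = 100_000.0
    tlen_lo: float = 1.0
    tlen_hi: float = 5.0
    tbot_lo: float = 1.0
    tbot_hi: float = 12.0
    tcar_lo: float = 1.0
    tcar_hi: float = 5000.0
    widened: bool = False
    fix_tlen: float | None = None

    def __post_init__(self) -> None:
        if self.widened:
            object.__setattr__(self, "tbot_hi", 30.0)
            object.__setattr__(self, "tlen_hi", 15.0)
        for lo, hi in (
            (self.size_lo, self.size_hi),
            (self.tlen_lo, self.tlen_hi),
            (self.tbot_lo, self.tbot_hi),
            (self.tcar_lo, self.tcar_hi),
        ):
            if not (0 < lo <= hi):
                raise ValueError("ranges need 0 < lower <= upper")


@dataclass
class FitResult:
    model_id: int
    params: ParameterVector
    lnl: float
    k: int
    restart_lnls: list[float] = field(default_factory=list)
    trajectories: list[list[float]] = field(default_factory=list)
    seed: int | None = None
    n_evals: int = 0


@dataclass
class ModelSelectionTable:
    model_ids: list[int]
    k: list[int]
    lnl: list[float]
    aic: list[float]
    delta_aic: list[float]
    best_index: int = 0

    @property
    def best_model(self) -> int:
        return self.model_ids[self.best_index]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.model_ids,
                "k": self.k,
                "lnL": self.lnl,
                "AIC": self.aic,
                "dAIC": self.delta_aic,
            }
        )


def ln_from_log10(l10: float) -> float:
    """Convert a base-10 log-likelihood to natural log."""
    if not math.isfinite(l10):
        raise ValueError("input must be finite")
    return l10 * math.log(10.0)


def composite_loglik(
    obs: MultiSFS,
    exp: MultiSFS,
    floor: float | None = None,
    pool_threshold: int = 1,
) -> float:
    """``Σ_e O_e ln p_e`` over polymorphic entries.

    ``floor`` replaces expected probabilities below it (including zeros at
    observed entries) by the floor itself, without renormalization, keeping
    the penalty for unexplained observed entries finite and identical across
    models.  The default is one tenth of a single simulated genealogy's
    share, ``1/(10 n_sims)``, when the expected spectrum records its
    Monte-Carlo fidelity, else 1e-8.

    ``pool_threshold`` = C > 1 switches to the pooled form used by
    simulation-based SFS likelihoods: entries observed at least C times keep
    their own term, while every other entry (rare or unobserved) is
    aggregated into a single class whose expected probability is the
    remaining mass ``1 − Σ_kept p_e``.  Because the pooled tail mass is
    estimated accurately by even modest numbers of simulated genealogies,
    the pooled likelihood has no floor term and no bias from how much of
    the sparse entry grid a parameter vector happens to cover.
    """
    if obs.dims != exp.dims:
        raise ValueError("dimension mismatch between observed and expected")
    if obs.folded != exp.folded:
        raise ValueError("folding mismatch between observed and expected")
    o = np.asarray(obs.counts, dtype=float).ravel()
    p = np.asarray(exp.counts, dtype=float).ravel()
    mono = obs.monomorphic_mask().ravel()
    if pool_threshold > 1:
        keep = (o >= pool_threshold) & ~mono
        lnl = float(
            np.sum(o[keep] * np.log(np.maximum(p[keep], 1e-300)))
        )
        o_pool = float(o[~keep & ~mono].sum())
        if o_pool > 0:
            p_pool = max(1.0 - float(p[keep].sum()), 1e-12)
            lnl += o_pool * math.log(p_pool)
        return lnl
    if floor is None:
        floor = 1.0 / (10.0 * exp.n_sims) if exp.n_sims else 1e-8
    sel = (o > 0) & ~mono
    p_eff = np.maximum(p[sel], floor)
    if np.any(p_eff <= 0):
        raise ValueError("zero expected probability at an observed entry")
    return float(np.sum(o[sel] * np.log(p_eff)))


def composite_loglik_marginal(
    obs_marginals: dict[str, np.ndarray] | MultiSFS,
    exp: MultiSFS,
    floor: float = 1e-12,
) -> float:
    """Composite log-likelihood over the per-cohort folded marginal spectra.

    Marginal bins pool many joint entries, so their Monte-Carlo error is
    far smaller than any single joint entry's at the same number of
    simulated genealogies, and no entry of appreciable observed mass is ever
    unexplored.  Used as the search-phase surrogate objective; final model
    comparison always rescores on the full joint spectrum.
    """
    if isinstance(obs_marginals, MultiSFS):
        obs_marginals = {
            lab: obs_marginals.marginalize(lab).astype(float)
            for lab in obs_marginals.labels
        }
    tot = 0.0
    for lab, o in obs_marginals.items():
        p = exp.marginalize(lab).astype(float)
        s = p.sum()
        if s <= 0:
            raise ValueError("expected marginal has no mass")
        p = p / s
        sel = o > 0
        tot += float((o[sel] * np.log(np.maximum(p[sel], floor))).sum())
    return tot


# -- parameter transforms ------------------------------------------------
#
# Sizes and durations are optimized as theta = ln(x - lb) so the stated
# lower bounds are hard while the space is unbounded above.  TCAR is
# parameterized as TBOT + TLEN + exp(theta), keeping the epoch ordering
# valid by construction (capped just below the deep horizon).


def _free_names(model_id: int, ranges: SearchRanges) -> list[str]:
    names = list(MODEL_REGISTRY[model_id])
    if ranges.fix_tlen is not None:
        names = [n for n in names if not n.startswith("TLEN")]
    return names


def _lower_bound(name: str, ranges: SearchRanges) -> float:
    if name.startswith("TLEN"):
        return ranges.tlen_lo
    if name.startswith("TBOT"):
        return ranges.tbot_lo
    if name == "TCAR":
        return ranges.tcar_lo
    return ranges.size_lo


def _draw_initial(
    model_id: int, ranges: SearchRanges, rng: np.random.Generator
) -> dict[str, float]:
    vals: dict[str, float] = {}
    for name in MODEL_REGISTRY[model_id]:
        if name.startswith("TLEN"):
            v = (
                ranges.fix_tlen
                if ranges.fix_tlen is not None
                else rng.uniform(ranges.tlen_lo, ranges.tlen_hi)
            )
        elif name.startswith("TBOT"):
            v = rng.uniform(ranges.tbot_lo, ranges.tbot_hi)
        elif name == "TCAR":
            v = math.exp(
                rng.uniform(math.log(ranges.tcar_lo), math.log(ranges.tcar_hi))
            )
        else:
            v = math.exp(
                rng.uniform(math.log(ranges.size_lo), math.log(ranges.size_hi))
            )
        vals[name] = float(v)
    if "TCAR" in vals:
        lo = vals.get("TBOT", 0.0) + vals.get("TLEN", 0.0) + 0.5
        vals["TCAR"] = min(max(vals["TCAR"], lo), 0.98 * T_LGM)
    return vals


def _to_theta(
    vals: dict[str, float], names: list[str], ranges: SearchRanges
) -> np.ndarray:
    th = np.empty(len(names))
    for i, name in enumerate(names):
        if name == "TCAR":
            base = vals.get("TBOT", 0.0) + vals.get("TLEN", 0.0)
            th[i] = math.log(max(vals[name] - base, 1e-3))
        else:
            lb = _lower_bound(name, ranges)
            th[i] = math.log(max(vals[name] - lb, 1e-3 * max(lb, 1.0)))
    return th


def _from_theta(
    theta: np.ndarray,
    names: list[str],
    model_id: int,
    ranges: SearchRanges,
) -> ParameterVector:
    vals: dict[str, float] = {}
    for i, name in enumerate(names):
        if name == "TCAR":
            continue
        lb = _lower_bound(name, ranges)
        vals[name] = lb + math.exp(min(theta[i], 60.0))
    if ranges.fix_tlen is not None:
        for name in MODEL_REGISTRY[model_id]:
            if name.startswith("TLEN"):
                vals[name] = float(ranges.fix_tlen)
    if "TCAR" in names:
        i = names.index("TCAR")
        base = vals.get("TBOT", 0.0) + vals.get("TLEN", 0.0)
        tcar = base + math.exp(min(theta[i], 60.0))
        vals["TCAR"] = min(tcar, 0.99 * T_LGM)
    return ParameterVector(model_id, vals)


def fit_model(
    obs: MultiSFS,
    model_id: int,
    ranges: SearchRanges | None = None,
    n_restarts: int = 50,
    max_cycles: int = 40,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    samples: SampleSpec | None = None,
    rescore: bool = True,
    rescore_seed: int | None = None,
    rescore_cfg: SimulationConfig | None = None,
    init_at: ParameterVector | None = None,
    init_jitter: float = 0.0,
    objective: str = "joint",
    n_screen: int = 0,
    pool_threshold: int = 1,
    rescore_pool_threshold: int | None = None,
    sim_seeds: list[int] | None = None,
    extra_inits: list[ParameterVector] | None = None,
) -> FitResult:
    """Multi-start bounded local search for one model's ML parameters.

    Each restart draws initial values from the stated distributions (plus
    ``n_screen`` extra screening draws, keeping the best-scoring one as the
    start point) and runs a Nelder-Mead search on log-transformed
    parameters, capped at ``max_cycles`` iterations, re-estimating the
    expected spectrum with ``cfg.n_sims`` genealogies per evaluation under a
    restart-fixed simulation seed (common random numbers).  ``objective``
    selects the full-joint composite likelihood or its low-variance
    per-cohort marginal surrogate for the search phase.  The best restart's
    parameters are always rescored on the full joint spectrum with
    ``rescore_cfg``/``rescore_seed`` (callers fitting several models pass
    the same rescore seed so AIC compares like with like), and that
    rescored lnL is reported.
    """
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    if obs.total <= 0:
        raise ValueError("observed spectrum is empty")
    ranges = ranges or SearchRanges()
    cfg = cfg or SimulationConfig()
    if samples is None:
        samples = SampleSpec(
            obs.labels,
            tuple(c.n_haploid for c in obs.cohorts),
            tuple(c.time for c in obs.cohorts),
        )
    if objective not in ("joint", "marginal"):
        raise ValueError("objective must be 'joint' or 'marginal'")
    master = np.random.default_rng(seed)
    names = _free_names(model_id, ranges)
    k = len(names)
    obs_marg = (
        {lab: obs.marginalize(lab).astype(float) for lab in obs.labels}
        if objective == "marginal"
        else None
    )
    finals: list[np.ndarray] = []
    restart_lnls: list[float] = []
    trajectories: list[list[float]] = []
    n_evals = 0

    def score(theta: np.ndarray, sim_seed: int) -> float:
        nonlocal n_evals
        try:
            pv = _from_theta(theta, names, model_id, ranges)
        except ValueError:
            return -1e12
        exp = expected_sfs(pv, samples, replace(cfg, seed=sim_seed))
        n_evals += 1
        if obs_marg is not None:
            return composite_loglik_marginal(obs_marg, exp)
        return composite_loglik(obs, exp, pool_threshold=pool_threshold)

    def draw_init() -> dict[str, float]:
        if init_at is not None:
            init = dict(init_at.values)
            if init_jitter > 0:
                for name in init:
                    init[name] *= math.exp(
                        master.uniform(-init_jitter, init_jitter)
                    )
                if "TCAR" in init:
                    lo = init.get("TBOT", 0.0) + init.get("TLEN", 0.0) + 0.5
                    init["TCAR"] = min(max(init["TCAR"], lo), 0.98 * T_LGM)
            return init
        return _draw_initial(model_id, ranges, master)

    for i_restart in range(n_restarts):
        # callers fitting several models to one dataset may pass shared
        # per-restart simulation seeds (common random numbers across models)
        sim_seed = (
            sim_seeds[i_restart % len(sim_seeds)]
            if sim_seeds
            else int(master.integers(2**31 - 1))
        )
        theta0 = _to_theta(draw_init(), names, ranges)
        pool: list[np.ndarray] = []
        if i_restart == 0 and extra_inits:
            # warm starts transferred from simpler already-fitted models
            pool += [_to_theta(dict(pv.values), names, ranges) for pv in extra_inits]
        if n_screen > 0:
            pool += [_to_theta(draw_init(), names, ranges) for _ in range(n_screen)]
        if pool:
            best_s = score(theta0, sim_seed)
            for th in pool:
                v = score(th, sim_seed)
                if v > best_s:
                    best_s, theta0 = v, th
        traj: list[float] = []

        def negloglik(theta: np.ndarray) -> float:
            v = score(theta, sim_seed)
            traj.append(v)
            return -v

        res = minimize(
            negloglik,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": max_cycles,
                "maxfev": len(theta0) + 1 + 2 * max_cycles,
                "xatol": 1e-3,
                "fatol": 1e-3,
            },
        )
        trajectories.append(traj)
        restart_lnls.append(-res.fun)
        finals.append(res.x)
    i_best = int(np.argmax(restart_lnls))
    params = _from_theta(finals[i_best], names, model_id, ranges)
    lnl = restart_lnls[i_best]
    if rescore:
        # report lnL from one fresh joint evaluation: callers comparing
        # models pass a shared rescore seed (and usually higher fidelity)
        # so AIC differences are not the maximum of per-model search noise
        rs = (
            rescore_seed
            if rescore_seed is not None
            else int(master.integers(2**31 - 1))
        )
        rcfg = rescore_cfg if rescore_cfg is not None else cfg
        rpool = (
            rescore_pool_threshold
            if rescore_pool_threshold is not None
            else pool_threshold
        )
        exp = expected_sfs(params, samples, replace(rcfg, seed=rs))
        lnl = composite_loglik(obs, exp, pool_threshold=rpool)
        n_evals += 1
    return FitResult(
        model_id=model_id,
        params=params,
        lnl=lnl,
        k=k,
        restart_lnls=restart_lnls,
        trajectories=trajectories,
        seed=seed,
        n_evals=n_evals,
    )


def select_model(fits: list[FitResult]) -> ModelSelectionTable:
    """AIC model selection: ``AIC = 2k − 2 lnL``; ties go to the smaller k."""
    if not fits:
        raise ValueError("no fits to select among")
    ids = [f.model_id for f in fits]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    k = [f.k if f.k else free_param_count(f.model_id) for f in fits]
    lnl = [f.lnl for f in fits]
    aic = [2 * ki - 2 * li for ki, li in zip(k, lnl)]
    order = sorted(range(len(aic)), key=lambda i: (aic[i], k[i]))
    best = aic[order[0]]
    delta = [a - best for a in aic]
    return ModelSelectionTable(ids, k, lnl, aic, delta, best_index=order[0])
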