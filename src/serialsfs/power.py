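"""Bootstrap confidence intervals and pseudo-observed-data power analyses.

Nonparametric CIs come from refitting bootstrap resamples of the observed
loci, each restart initialized at the observed-data ML values with a ±10%
log-scale jitter.  Power is measured by simulating pseudo-observed spectra
(L multinomial loci from a generating model's expected spectrum), fitting
all candidate models, selecting by AIC, and tallying selections against the
generating model — either as a full confusion matrix or as the selection
fraction for one generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import SimulationConfig, expected_sfs
from .inference import FitResult, SearchRanges, fit_model, select_model
from .models import ParameterVector, SampleSpec, free_param_count
from .sfs import MultiSFS

__all__ = [
    "BootstrapResult",
    "ConfusionMatrix",
    "bootstrap_ci",
    "equal_sampling_power",
    "expected_marginals_at_ml",
    "power_confusion",
    "pseudo_observed_sfs",
]


@dataclass
class BootstrapResult:
    estimates: dict[str, np.ndarray]  # parameter -> B ML estimates
    intervals: dict[str, tuple[float, float]]  # 95% percentile CIs
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "parameter": k,
                "lower95": self.intervals[k][0],
                "upper95": self.intervals[k][1],
            }
            for k in self.intervals
        ]
        return pd.DataFrame(rows)


@dataclass
class ConfusionMatrix:
    model_ids: list[int]
    counts: np.ndarray  # rows = generating model, cols = selected model
    selections: dict[int, list[int]] = field(default_factory=dict)

    @property
    def fractions(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, self.counts / row, np.nan)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=[f"true_M{m}" for m in self.model_ids],
            columns=[f"sel_M{m}" for m in self.model_ids],
        )


def percentile_interval(
    values: np.ndarray, level: float = 95.0
) -> tuple[float, float]:
    lo = (100.0 - level) / 2.0
    a, b = np.percentile(np.asarray(values, dtype=float), [lo, 100.0 - lo])
    return float(a), float(b)


def bootstrap_ci(
    obs: MultiSFS,
    best: FitResult,
    B: int = 100,
    reps_per_sfs: int = 30,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    ranges: SearchRanges | None = None,
    max_cycles: int = 40,
    jitter: float = 0.1,
    pool_threshold: int = 2,
) -> BootstrapResult:
    """Percentile CIs from ML refits of ``B`` bootstrap spectra.

    Each bootstrap spectrum is refit with ``reps_per_sfs`` restarts
    initialized at the observed-data ML values (log-jittered ±``jitter``);
    2.5/97.5 percentile intervals use linear interpolation.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    cfg = cfg or SimulationConfig()
    master = np.random.default_rng(seed)
    names = list(best.params.values)
    collected: dict[str, list[float]] = {n: [] for n in names}
    for _ in range(B):
        boot = obs.bootstrap_resample(master)
        fit = fit_model(
            boot,
            best.model_id,
            ranges=ranges,
            n_restarts=reps_per_sfs,
            max_cycles=max_cycles,
            cfg=cfg,
            seed=int(master.integers(2**31 - 1)),
            init_at=best.params,
            init_jitter=jitter,
            rescore=False,
            pool_threshold=pool_threshold,
        )
        for n in names:
            collected[n].append(fit.params[n])
    estimates = {n: np.array(v) for n, v in collected.items()}
    intervals = {n: percentile_interval(v) for n, v in estimates.items()}
    return BootstrapResult(estimates, intervals, seed=seed)


def pseudo_observed_sfs(
    params: ParameterVector,
    samples: SampleSpec,
    L: int,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
    gen_n_sims: int | None = None,
) -> MultiSFS:
    """Pseudo-observed spectrum: L multinomial loci from the expected SFS.

    The generating spectrum is estimated at high fidelity (at least
    100,000 genealogies by default) regardless of the search fidelity in
    ``cfg``: the pseudo-data are the study conditions, not part of the
    search budget.  ``gen_n_sims`` overrides that fidelity explicitly.
    """
    gen = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(rng)
    )
    n = gen_n_sims if gen_n_sims else max(cfg.n_sims if cfg else 0, 100_000)
    exp = expected_sfs(
        params, samples, SimulationConfig(n, seed=int(gen.integers(2**31 - 1)))
    )
    flat = np.asarray(exp.counts, dtype=float).ravel()
    draw = gen.multinomial(L, flat / flat.sum()).reshape(exp.dims)
    return MultiSFS(draw.astype(np.int64), exp.cohorts, folded=True, kind="counts")


def _warm_inits(mid: int, fitted: dict[int, "FitResult"]) -> list[ParameterVector]:
    """Parameter transfers from simpler fitted models to model ``mid``."""
    from .models import T_LGM

    out: list[ParameterVector] = []

    def grab(source: int):
        f = fitted.get(source)
        return dict(f.params.values) if f else None

    def clamp_tcar(v: dict) -> dict:
        base = v.get("TBOT", 0.0) + v.get("TLEN", 0.0)
        v["TCAR"] = min(max(v.get("TCAR", base + 50.0), base + 10.0), 0.9 * T_LGM)
        return v

    if mid == 2 and (m1 := grab(1)):
        n = m1["NANC"]
        out.append(
            ParameterVector(
                2,
                {"NPREBOT": n, "NBOT": max(n / 5, 110.0), "NPOP08": n,
                 "TLEN": 3.0, "TBOT": 6.0},
            )
        )
    if mid == 3 and (m2 := grab(2)):
        out.append(ParameterVector(3, m2))
    if mid == 7:
        if m1 := grab(1):
            out.append(
                ParameterVector(7, {"NANC": m1["NANC"], "NPOP08": m1["NANC"],
                                    "TCAR": 100.0})
            )
    if mid == 4 and (m2 := grab(2)):
        v = dict(m2)
        v["NANC"] = max(v["NPREBOT"] / 10, 110.0)
        out.append(ParameterVector(4, clamp_tcar(v)))
    if mid == 6:
        for src in (3, 4):
            if v := grab(src):
                v = dict(v)
                v.setdefault("NANC", max(v["NPREBOT"] / 10, 110.0))
                out.append(ParameterVector(6, clamp_tcar(v)))
    if mid == 5 and (m2 := grab(2)):
        out.append(
            ParameterVector(
                5,
                {"NPREBOT": m2["NPREBOT"], "NBOT1": m2["NBOT"],
                 "NINT": m2["NPREBOT"], "NBOT2": m2["NBOT"],
                 "NPOP08": m2["NPOP08"], "TLEN1": m2["TLEN"],
                 "TBOT1": m2["TBOT"], "TLEN2": m2["TLEN"],
                 "TBOT2": 10.0},
            )
        )
    return out


def _fit_and_select(
    pseudo: MultiSFS,
    samples: SampleSpec,
    candidate_models: list[int],
    reps: int,
    cfg: SimulationConfig,
    ranges: SearchRanges | None,
    max_cycles: int,
    rng: np.random.Generator,
    objective: str = "joint",
    n_screen: int = 4,
    pool_threshold: int = 2,
    complex_cycles: int | None = None,
) -> int:
    # all candidates are rescored on one common, fresh set of genealogies at
    # higher fidelity, so the AIC comparison is not driven by the winner's
    # curse of maximizing over noisy likelihood evaluations; the rescore uses
    # the full (unpooled) composite, whose fine rare-entry structure is what
    # separates near-nested recovery scenarios
    rescore_seed = int(rng.integers(2**31 - 1))
    rescore_cfg = replace(cfg, n_sims=min(max(8 * cfg.n_sims, cfg.n_sims), 100_000))
    sim_seeds = [int(rng.integers(2**31 - 1)) for _ in range(reps)]
    # fit simple models first and hand their fitted parameters to the more
    # complex ones as warm starts; every model still maximizes its own
    # likelihood, but the high-dimensional searches no longer start cold
    order = [m for m in (1, 2, 3, 7, 4, 6, 5) if m in candidate_models]
    order += [m for m in candidate_models if m not in order]
    fitted: dict[int, FitResult] = {}
    for mid in order:
        # the high-dimensional topologies need deeper refinement; the low-
        # dimensional ones converge within a handful of simplex cycles
        deep = complex_cycles if complex_cycles else 2 * max_cycles
        cycles = deep if free_param_count(mid) >= 7 else max_cycles
        fitted[mid] = fit_model(
            pseudo,
            mid,
            ranges=ranges,
            n_restarts=reps,
            max_cycles=cycles,
            cfg=cfg,
            seed=int(rng.integers(2**31 - 1)),
            samples=samples,
            rescore=True,
            rescore_seed=rescore_seed,
            rescore_cfg=rescore_cfg,
            objective=objective,
            n_screen=n_screen,
            pool_threshold=pool_threshold,
            rescore_pool_threshold=1,
            sim_seeds=sim_seeds,
            extra_inits=_warm_inits(mid, fitted),
        )
    fits = [fitted[mid] for mid in candidate_models]
    return select_model(fits).best_model


def power_confusion(
    generating_params: dict[int, ParameterVector],
    samples: SampleSpec,
    n_datasets: int = 10,
    reps: int = 10,
    L: int = 1068,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    candidate_models: list[int] | None = None,
    ranges: SearchRanges | None = None,
    max_cycles: int = 40,
    objective: str = "joint",
    n_screen: int = 4,
    pool_threshold: int = 2,
    gen_n_sims: int | None = None,
    complex_cycles: int | None = None,
) -> ConfusionMatrix:
    """Model-selection confusion matrix over pseudo-observed datasets.

    For each generating model, ``n_datasets`` pseudo-observed spectra are
    simulated at its parameters, every candidate model is fit with ``reps``
    restarts, and the AIC-best model is tallied.
    """
    if not generating_params:
        raise ValueError("no generating parameters supplied")
    cfg = cfg or SimulationConfig()
    cand = candidate_models or sorted(generating_params)
    gen_ids = sorted(generating_params)
    missing = [m for m in gen_ids if m not in generating_params]
    if missing:
        raise ValueError(f"missing generating parameters for models {missing}")
    all_ids = sorted(set(cand) | set(gen_ids))
    idx = {m: i for i, m in enumerate(all_ids)}
    counts = np.zeros((len(all_ids), len(all_ids)), dtype=np.int64)
    master = np.random.default_rng(seed)
    selections: dict[int, list[int]] = {}
    for true_mid in gen_ids:
        picks: list[int] = []
        for _ in range(n_datasets):
            pseudo = pseudo_observed_sfs(
                generating_params[true_mid], samples, L, cfg, master,
                gen_n_sims=gen_n_sims,
            )
            best = _fit_and_select(
                pseudo, samples, cand, reps, cfg, ranges, max_cycles, master,
                objective, n_screen, pool_threshold, complex_cycles,
            )
            picks.append(best)
            counts[idx[true_mid], idx[best]] += 1
        selections[true_mid] = picks
    return ConfusionMatrix(all_ids, counts, selections)


def equal_sampling_power(
    params: ParameterVector,
    model_id: int = 6,
    n_datasets: int = 50,
    diploids_per_cohort: int = 80,
    L: int = 1068,
    reps: int = 10,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    candidate_models: list[int] | None = None,
    ranges: SearchRanges | None = None,
    max_cycles: int = 40,
    times: tuple[float, ...] = (7.0, 5.5, 0.0),
    labels: tuple[str, ...] = ("1994", "1997", "2008"),
    objective: str = "joint",
    n_screen: int = 4,
    pool_threshold: int = 2,
    gen_n_sims: int | None = None,
) -> float:
    """Fraction of equal-sample-size pseudo-datasets selecting ``model_id``."""
    n = 2 * diploids_per_cohort
    samples = SampleSpec(labels, (n, n, n), times)
    cm = power_confusion(
        {model_id: params},
        samples,
        n_datasets=n_datasets,
        reps=reps,
        L=L,
        cfg=cfg,
        seed=seed,
        candidate_models=candidate_models,
        ranges=ranges,
        max_cycles=max_cycles,
        objective=objective,
        n_screen=n_screen,
        pool_threshold=pool_threshold,
        gen_n_sims=gen_n_sims,
    )
    picks = cm.selections[model_id]
    return sum(1 for p in picks if p == model_id) / len(picks)


def expected_marginals_at_ml(
    best: FitResult,
    samples: SampleSpec,
    n_spectra: int = 100,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-cohort expected marginal SFS averaged over ``n_spectra`` spectra."""
    cfg = cfg or SimulationConfig()
    master = np.random.default_rng(seed)
    acc: dict[str, np.ndarray] | None = None
    for _ in range(n_spectra):
        s = expected_sfs(
            best.params, samples, replace(cfg, seed=int(master.integers(2**31 - 1)))
        )
        margs = {lab: s.marginalize(lab) for lab in s.labels}
        if acc is None:
            acc = {lab: m.astype(float) for lab, m in margs.items()}
        else:
            for lab, m in margs.items():
                acc[lab] += m
    assert acc is not None
    return {lab: m / n_spectra for lab, m in acc.items()}


def plot_marginal_comparison(
    observed: MultiSFS,
    expected_marginals: dict[str, np.ndarray],
    path,
    max_count: int = 15,
) -> None:
    """Save an observed-vs-expected marginal SFS comparison figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = observed.labels
    fig, axes = plt.subplots(1, len(labels), figsize=(4 * len(labels), 3))
    if len(labels) == 1:
        axes = [axes]
    L = observed.total
    for ax, lab in zip(axes, labels):
        obs_m = observed.marginalize(lab) / L
        exp_m = expected_marginals[lab]
        hi = min(max_count, len(obs_m) - 1)
        x = np.arange(1, hi + 1)
        ax.bar(x - 0.2, obs_m[1 : hi + 1], width=0.4, label="observed")
        ax.bar(x + 0.2, exp_m[1 : hi + 1], width=0.4, label="expected")
        ax.set_title(f"cohort {lab}")
        ax.set_xlabel("minor allele count")
    axes[0].set_ylabel("proportion of loci")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
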