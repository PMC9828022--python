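"""Bundled desk-scale analysis protocols.

Scaled-down versions of the full study protocol, sized for a single CPU:
the model-selection power analysis and the decline-ratio recovery
experiment at the reference bottleneck-and-recovery scenario.  Problem
sizes are documented in the methods note; the full-fidelity protocol is
available through the same underlying functions.
"""

from __future__ import annotations

import numpy as np

from .engine import SimulationConfig
from .inference import fit_model
from .models import ParameterVector, flounder_sample_spec, model6_reference
from .power import power_confusion, pseudo_observed_sfs

__all__ = [
    "desk_power_analysis",
    "desk_ratio_recovery",
    "reference_arithmetic",
]

#: decline and recovery ratios implied by the reference scenario, plus the
#: bottleneck-end year at a 2-year generation (quantities the fitted model
#: is summarized by)
def reference_arithmetic() -> dict[str, float]:
    from .models import growth_rate_between

    pv = model6_reference()
    gen_time = 2.0
    return {
        "decline_ratio": pv["NBOT"] / pv["NPREBOT"],
        "recovery_ratio": pv["NPOP08"] / pv["NBOT"],
        "net_ratio": pv["NPOP08"] / pv["NPREBOT"],
        "recovery_growth_rate": growth_rate_between(
            pv["NBOT"], pv["NPOP08"], pv["TBOT"]
        ),
        "bottleneck_end_year": 2008 - pv["TBOT"] * gen_time,
    }


def desk_power_analysis(
    seed: int,
    n_datasets: int = 5,
    reps: int = 3,
    n_sims: int = 5000,
    L: int = 1068,
    max_cycles: int = 5,
    n_screen: int = 1,
    complex_cycles: int = 12,
) -> tuple[float, list[int]]:
    """Model-6 selection rate among all seven models at desk scale.

    Returns (fraction of datasets selecting model 6, the per-dataset
    selections).
    """
    cm = power_confusion(
        {6: model6_reference()},
        flounder_sample_spec(),
        n_datasets=n_datasets,
        reps=reps,
        L=L,
        cfg=SimulationConfig(n_sims=n_sims),
        seed=seed,
        candidate_models=[1, 2, 3, 4, 5, 6, 7],
        max_cycles=max_cycles,
        n_screen=n_screen,
        pool_threshold=2,
        complex_cycles=complex_cycles,
    )
    picks = cm.selections[6]
    return sum(1 for p in picks if p == 6) / len(picks), picks


def desk_ratio_recovery(
    seed: int,
    n_replicates: int = 10,
    n_sims: int = 3000,
    L: int = 1068,
    n_restarts: int = 2,
    n_screen: int = 6,
    max_cycles: int = 8,
) -> tuple[list[float], list[ParameterVector]]:
    """Refit model 6 to data simulated at the reference values.

    Each replicate simulates a pseudo-observed spectrum at the reference
    parameters and refits model 6 from random starts with the desk search
    protocol; returns the recovered NBOT/NPREBOT ratios and parameter
    vectors.
    """
    spec = flounder_sample_spec()
    pv = model6_reference()
    rng = np.random.default_rng(seed)
    ratios: list[float] = []
    fits: list[ParameterVector] = []
    for _ in range(n_replicates):
        pseudo = pseudo_observed_sfs(pv, spec, L, None, rng)
        fit = fit_model(
            pseudo,
            6,
            n_restarts=n_restarts,
            max_cycles=max_cycles,
            cfg=SimulationConfig(n_sims=n_sims),
            seed=int(rng.integers(2**31 - 1)),
            objective="joint",
            pool_threshold=2,
            rescore_pool_threshold=1,
            rescore_cfg=SimulationConfig(n_sims=30_000),
            n_screen=n_screen,
        )
        ratios.append(fit.params["NBOT"] / fit.params["NPREBOT"])
        fits.append(fit.params)
    return ratios, fits
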