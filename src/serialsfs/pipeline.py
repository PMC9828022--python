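"""End-to-end orchestration: filter -> SFS -> fit -> select -> bootstrap ->
power -> diversity -> census, driven by one declarative configuration.

Every stage's seed is derived from the master seed and recorded in the run
manifest, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .census import AgeStructuredTable, generation_length, peak_spawning_abundance
from .engine import SimulationConfig
from .inference import SearchRanges, fit_model, select_model
from .models import SampleSpec, free_param_count
from .popgen import (
    apply_standard_filters,
    heterozygosity_stats,
    pi_bootstrap_ci,
    read_cohort_table,
    read_vcf,
    windowed_pi,
)
from .power import bootstrap_ci, power_confusion
from .sfs import read_obs, sfs_from_genotypes, write_obs

log = logging.getLogger("serialsfs")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    out_dir: str
    seed: int = 1
    # inputs: either a VCF + cohort table, or a ready-made .obs spectrum
    vcf: str | None = None
    cohort_table: str | None = None
    obs_sfs: str | None = None
    age_table: str | None = None
    # sampling design (cohort labels, haploid sizes, backward times)
    labels: tuple[str, ...] = ("1994", "1997", "2008")
    times: tuple[float, ...] = (7.0, 5.5, 0.0)
    # search protocol
    models: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    n_restarts: int = 50
    max_cycles: int = 40
    n_sims: int = 100_000
    fix_tlen: float | None = None
    widened_ranges: bool = False
    pool_threshold: int = 2
    n_screen: int = 2
    # optional stages
    bootstrap_B: int = 0
    bootstrap_reps: int = 30
    power_datasets: int = 0
    power_reps: int = 10
    pi_bootstrap_reps: int = 0

    def validate(self) -> None:
        if self.vcf is None and self.obs_sfs is None:
            raise ValueError("need either a VCF or an .obs spectrum as input")
        for name in ("vcf", "cohort_table", "obs_sfs", "age_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.n_restarts < 1 or self.max_cycles < 1 or self.n_sims < 1:
            raise ValueError("counts must be at least 1")


def _stage(manifest: dict, name: str, seed_master: np.random.Generator):
    seed = int(seed_master.integers(2**31 - 1))
    manifest["stages"][name] = {"seed": seed, "t_start": time.time()}
    log.info("stage %s (seed %d)", name, seed)
    return seed


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }
    ranges = SearchRanges(widened=cfg.widened_ranges, fix_tlen=cfg.fix_tlen)

    # --- genotypes -> filters -> observed spectrum ----------------------
    genotypes = None
    if cfg.vcf is not None:
        _stage(manifest, "filter", master)
        try:
            cohort_of = (
                read_cohort_table(cfg.cohort_table) if cfg.cohort_table else None
            )
            raw = read_vcf(cfg.vcf, cohort_of)
            genotypes = apply_standard_filters(raw)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'filter' failed: {e}") from e
        manifest["stages"]["filter"].update(
            n_individuals_in=raw.n_individuals,
            n_loci_in=raw.n_loci,
            n_individuals_out=genotypes.n_individuals,
            n_loci_out=genotypes.n_loci,
        )

    _stage(manifest, "build_sfs", master)
    try:
        if genotypes is not None:
            obs = sfs_from_genotypes(genotypes)
            # attach the configured sampling times to the cohorts
            from .sfs import CohortInfo, MultiSFS

            tmap = dict(zip(cfg.labels, cfg.times))
            cohorts = tuple(
                CohortInfo(c.label, c.n_haploid, tmap.get(c.label, 0.0))
                for c in obs.cohorts
            )
            obs = MultiSFS(obs.counts, cohorts, folded=True, kind="counts")
            write_obs(obs, out / "observed.obs")
        else:
            obs = read_obs(cfg.obs_sfs, labels=cfg.labels, times=cfg.times)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'build_sfs' failed: {e}") from e
    manifest["stages"]["build_sfs"]["n_loci"] = obs.total

    samples = SampleSpec(
        obs.labels,
        tuple(c.n_haploid for c in obs.cohorts),
        tuple(c.time for c in obs.cohorts),
    )

    # --- fit all models, select by AIC ----------------------------------
    sim = SimulationConfig(n_sims=cfg.n_sims)
    rescore_sim = SimulationConfig(
        n_sims=min(max(6 * cfg.n_sims, cfg.n_sims), 100_000)
    )
    fits = []
    rescore_seed = int(master.integers(2**31 - 1))
    sim_seeds = [int(master.integers(2**31 - 1)) for _ in range(cfg.n_restarts)]
    for mid in cfg.models:
        sd = _stage(manifest, f"fit_model_{mid}", master)
        try:
            fit = fit_model(
                obs,
                mid,
                ranges=ranges,
                n_restarts=cfg.n_restarts,
                max_cycles=cfg.max_cycles,
                cfg=sim,
                seed=sd,
                samples=samples,
                rescore_seed=rescore_seed,
                rescore_cfg=rescore_sim,
                pool_threshold=cfg.pool_threshold,
                n_screen=cfg.n_screen,
                sim_seeds=sim_seeds,
            )
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'fit_model_{mid}' failed: {e}") from e
        fits.append(fit)
        (out / f"fit_model_{mid}.json").write_text(
            json.dumps(
                {
                    "model": mid,
                    "lnl": fit.lnl,
                    "k": fit.k,
                    "params": fit.params.values,
                    "restart_lnls": fit.restart_lnls,
                },
                indent=2,
            )
        )
    table = select_model(fits)
    table.to_frame().to_csv(out / "model_selection.tsv", sep="\t", index=False)
    best = fits[table.best_index]
    manifest["best_model"] = best.model_id
    manifest["best_params"] = best.params.values

    # --- optional bootstrap CIs -----------------------------------------
    if cfg.bootstrap_B > 0:
        sd = _stage(manifest, "bootstrap", master)
        br = bootstrap_ci(
            obs,
            best,
            B=cfg.bootstrap_B,
            reps_per_sfs=cfg.bootstrap_reps,
            cfg=sim,
            seed=sd,
            ranges=ranges,
            max_cycles=cfg.max_cycles,
        )
        br.to_frame().to_csv(out / "bootstrap_ci.tsv", sep="\t", index=False)
        manifest["bootstrap_ci"] = {
            k: list(v) for k, v in br.intervals.items()
        }

    # --- optional confusion-matrix power analysis -----------------------
    if cfg.power_datasets > 0:
        sd = _stage(manifest, "power", master)
        cm = power_confusion(
            {best.model_id: best.params},
            samples,
            n_datasets=cfg.power_datasets,
            reps=cfg.power_reps,
            L=int(obs.total),
            cfg=sim,
            seed=sd,
            candidate_models=list(cfg.models),
            ranges=ranges,
            max_cycles=cfg.max_cycles,
        )
        cm.to_frame().to_csv(out / "confusion.tsv", sep="\t")
        row = cm.model_ids.index(best.model_id)
        manifest["power_selection_fraction"] = float(
            cm.fractions[row, row]
        )

    # --- diversity -------------------------------------------------------
    if genotypes is not None:
        sd = _stage(manifest, "diversity", master)
        per_locus, means = heterozygosity_stats(genotypes)
        pis = windowed_pi(genotypes)
        means = means.merge(
            pis.groupby("cohort", sort=False)["pi"].mean().reset_index(),
            on="cohort",
        )
        per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t", index=False)
        means.to_csv(out / "diversity_cohorts.tsv", sep="\t", index=False)
        if cfg.pi_bootstrap_reps > 0:
            cis = pi_bootstrap_ci(genotypes, reps=cfg.pi_bootstrap_reps, seed=sd)
            manifest["pi_ci"] = {k: list(v) for k, v in cis.items()}

    # --- census ----------------------------------------------------------
    if cfg.age_table is not None:
        _stage(manifest, "census", master)
        tbl = AgeStructuredTable.read(cfg.age_table)
        f, m, avg = generation_length(tbl)
        peaks = {int(y): peak_spawning_abundance(tbl, y) for y in tbl.years}
        manifest["census"] = {
            "generation_length_female": f,
            "generation_length_male": m,
            "generation_length_avg": avg,
            "peak_spawning_abundance": peaks,
        }

    for st in manifest["stages"].values():
        st["t_elapsed"] = time.time() - st.pop("t_start")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
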