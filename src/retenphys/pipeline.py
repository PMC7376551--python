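"""Pipeline orchestration: runs the analysis stages in dependency order.

Stages
------
generate   synthetic chemostat + retentostat datasets (with truth.json)
chemostat  steady-state rates/yields and (mu, q_S) pairs from chemostat.csv
pirt       substrate-partition fit on the chemostat pairs -> pirt.json
simulate   forward retentostat trajectory from the fitted/ configured model
infer      interval rates and windowed m_S from samples.csv
report     summary table and figures

All randomness flows from the single top-level seed, expanded per stage with
numpy's SeedSequence so adding a stage never shifts another stage's stream.
Every artifact carries a provenance header (package version, config hash,
seed) sufficient to reproduce it.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import io
from .chemostat import summarize_steady_state
from .config import ExperimentConfig, config_hash
from .errors import DependencyError
from .inference import interval_rates, moving_window_ms
from .pirt import RatePair, fit_pirt
from .retentostat import simulate
from .synthetic import ScenarioPreset, generate_chemostat_dataset, generate_retentostat_dataset, preset

__all__ = ["STAGES", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "chemostat", "pirt", "simulate", "infer", "report")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the top-level seed."""
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


def _scenario(config: ExperimentConfig) -> ScenarioPreset:
    base = preset(config.preset)
    # the configuration file can override geometry/maintenance of the preset
    return ScenarioPreset(
        name=base.name,
        maintenance=config.maintenance.build()
        if config.maintenance != type(config.maintenance)()
        else base.maintenance,
        y_xs_max=config.y_xs_max,
        config=config.retentostat.build(),
        mu_max=base.mu_max,
    )


def run_pipeline(
    config: ExperimentConfig,
    stages: Optional[Iterable[str]] = None,
    outdir: Optional[str] = None,
) -> dict[str, Path]:
    """Execute the requested stages; returns {artifact name: path}.

    Stage order follows dependency order regardless of the order given.
    Stages read their inputs from earlier artifacts in ``outdir`` (or the
    explicit paths in the config) and raise :class:`DependencyError` when an
    upstream artifact is missing.
    """
    requested = set(stages) if stages is not None else set(STAGES)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    prov = {"config_hash": chash, "seed": config.seed}
    artifacts: dict[str, Path] = {}
    scenario = _scenario(config)

    def chemostat_path() -> Path:
        p = Path(config.chemostat_csv) if config.chemostat_csv else out / "chemostat.csv"
        if not p.exists():
            raise DependencyError(
                f"chemostat records not found at {p}; run the generate stage "
                "or point chemostat_csv at measured data"
            )
        return p

    def samples_path() -> Path:
        p = Path(config.samples_csv) if config.samples_csv else out / "samples.csv"
        if not p.exists():
            raise DependencyError(
                f"biomass samples not found at {p}; run the generate stage "
                "or point samples_csv at measured data"
            )
        return p

    if "generate" in requested:
        logger.info("generate: synthetic datasets for preset %s", scenario.name)
        noise = config.noise.build(stage_seed(config.seed, "generate"))
        chem = generate_chemostat_dataset(
            scenario,
            dilution_rates=config.chemostat_dilution_rates,
            feed_glucose_g_L=config.chemostat_feed_g_L,
            replicates=config.replicates,
            noise=noise,
        )
        samples, truth = generate_retentostat_dataset(
            scenario, noise=noise, replicates=config.replicates
        )
        artifacts["chemostat.csv"] = io.write_chemostat_csv(
            chem, out / "chemostat.csv", **prov
        )
        artifacts["samples.csv"] = io.write_samples_csv(
            samples, out / "samples.csv", **prov
        )
        artifacts["truth.json"] = io.write_json(truth, out / "truth.json")

    if "chemostat" in requested:
        records = io.read_chemostat_csv(chemostat_path())
        logger.info("chemostat: %d steady-state records", len(records))
        rates = [summarize_steady_state(r, constants=config.molar_constants.build())
                 for r in records]
        pairs = [
            RatePair(
                mu_h=r.mu_h,
                q_s_g_g_h=r.q_s_g_g_h,
                source="chemostat",
                time_h=0.0,
                strain=r.strain,
                replicate=r.replicate,
            )
            for r in rates
        ]
        artifacts["rates.csv"] = io.write_rates_csv(rates, out / "rates.csv", **prov)
        artifacts["chemostat_pairs.csv"] = io.write_rate_pairs_csv(
            pairs, out / "chemostat_pairs.csv", **prov
        )

    if "pirt" in requested:
        p = out / "chemostat_pairs.csv"
        if not p.exists():
            raise DependencyError(f"{p} missing; run the chemostat stage first")
        pairs = io.read_rate_pairs_csv(p)
        fit = fit_pirt(pairs)
        logger.info("pirt: m_S=%.4g g/(g h), Yxs_max=%.4g g/g", fit.m_s, fit.y_xs_max)
        artifacts["pirt.json"] = io.write_pirt_json(
            fit, out / "pirt.json", config_hash=chash, seed=config.seed
        )

    if "simulate" in requested:
        traj = simulate(
            scenario.config,
            scenario.maintenance,
            scenario.y_xs_max,
            t_grid=_fine_grid(scenario.config.sampling_hours),
        )
        artifacts["trajectory.csv"] = io.write_trajectory_csv(
            traj, out / "trajectory.csv", **prov
        )

    if "infer" in requested:
        samples = io.read_samples_csv(samples_path())
        by_rep = defaultdict(list)
        for s in samples:
            by_rep[(s.strain, s.replicate)].append(s)
        chem_pairs: list[RatePair] = []
        if config.prepend_chemostat_pairs and (out / "chemostat_pairs.csv").exists():
            chem_pairs = io.read_rate_pairs_csv(out / "chemostat_pairs.csv")
        all_pairs: list[RatePair] = []
        all_ms = []
        for (strain, rep), group in sorted(by_rep.items()):
            group.sort(key=lambda s: s.time_h)
            pairs = interval_rates(group, scenario.config)
            all_pairs.extend(pairs)
            windowed = moving_window_ms(chem_pairs + pairs, window=config.window)
            all_ms.extend(windowed)
        artifacts["rate_pairs.csv"] = io.write_rate_pairs_csv(
            all_pairs, out / "rate_pairs.csv", **prov
        )
        artifacts["ms_estimates.csv"] = io.write_ms_csv(
            all_ms, out / "ms_estimates.csv", **prov
        )

    if "report" in requested:
        artifacts.update(_report(out, prov))

    return artifacts


def _fine_grid(sampling_hours: Sequence[float]) -> np.ndarray:
    """Hourly grid spanning the sampling schedule (for smooth trajectories)."""
    end = max(sampling_hours)
    grid = np.unique(np.concatenate([np.arange(0.0, end + 1.0, 1.0), sampling_hours]))
    return grid


def _report(out: Path, prov: dict) -> dict[str, Path]:
    """Summary table plus trajectory/q_S/m_S figures from existing artifacts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    artifacts: dict[str, Path] = {}
    rates_p = out / "rates.csv"
    if rates_p.exists():
        rates = io.read_csv(rates_p)
        summary = (
            rates.groupby(["strain", "mu_h-1"])
            .agg(["mean", "sem"])
            .reset_index()
        )
        summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
        artifacts["summary.csv"] = io.write_csv(summary, out / "summary.csv", **prov)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    drew = False
    traj_p = out / "trajectory.csv"
    if traj_p.exists():
        traj = io.read_csv(traj_p)
        axes[0].plot(traj["time_h"] / 24, traj["cx_g_L"], label="predicted")
        drew = True
    samples_p = out / "samples.csv"
    if samples_p.exists():
        samples = io.read_csv(samples_p)
        for rep, grp in samples.groupby("replicate"):
            axes[0].plot(
                grp["time_h"] / 24, grp["cx_g_L"], "o", ms=4,
                label=f"measured rep {rep}",
            )
        drew = True
    axes[0].set_xlabel("time (d)")
    axes[0].set_ylabel("biomass (g/L)")
    axes[0].legend(fontsize=8)

    pairs_p = out / "rate_pairs.csv"
    if pairs_p.exists():
        pairs = io.read_csv(pairs_p)
        for rep, grp in pairs.groupby("replicate"):
            axes[1].plot(grp["time_h"] / 24, grp["qs_g_g_h"], "o-", ms=4)
        axes[1].set_xlabel("time (d)")
        axes[1].set_ylabel("q_S (g/(g h))")
        drew = True

    ms_p = out / "ms_estimates.csv"
    if ms_p.exists():
        ms = io.read_csv(ms_p)
        for rep, grp in ms.groupby("replicate"):
            axes[2].errorbar(
                grp["time_h"] / 24, grp["ms_g_g_h"], yerr=grp["se_ms_g_g_h"],
                fmt="o-", ms=4,
            )
        axes[2].set_xlabel("time (d)")
        axes[2].set_ylabel("m_S (g/(g h))")
        drew = True

    if drew:
        fig.tight_layout()
        fig_path = out / "report.png"
        fig.savefig(fig_path, dpi=150)
        artifacts["report.png"] = fig_path
    plt.close(fig)
    return artifacts
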