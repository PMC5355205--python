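"""End-to-end orchestration: synthesize → forage → simulate → fit → analyze.

Every stage draws from a named substream of the single run-level seed, so a
rerun with the same config is bit-identical except for manifest timestamps.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import coefficient_correlation, lme_year_effect, tukey_years
from .config import RunConfig
from .forage import (
    fit_disk_calibration,
    project_rasters,
    train_forage_model,
    validate_model,
)
from .landscape import (
    generate_burn_history,
    generate_shrub_mask,
    generate_terrain,
    generate_weather,
    sample_plots,
    WeatherParams,
)
from .movement import MovementParams, Trajectory, simulate_trajectory
from .rasters import COVARIATE_NAMES, RasterStack
from .rng import substream
from .ssf import (
    PARAM_NAMES,
    build_steps,
    classify_strategy,
    fit_step_selection,
    prepare_step_data,
)

log = logging.getLogger("tallgrass")


@dataclass
class RunArtifacts:
    run_dir: Path
    stacks: dict[int, RasterStack]
    trajectories: list[Trajectory]
    fits: list
    coefficient_table: pd.DataFrame
    analysis: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def synthesize_landscape(config: RunConfig):
    lc = config.landscape
    terrain = generate_terrain(
        lc.rows, lc.cols, lc.cell_size, lc.relief_amplitude, lc.base_elevation,
        lc.correlation_length, seed=config.seed,
    )
    burns = generate_burn_history(terrain.shape, lc.burn_intervals, config.weather.years, seed=config.seed)
    wc = config.weather
    weather = generate_weather(
        wc.years,
        WeatherParams(
            mean_annual_precip_mm=wc.mean_annual_precip_mm,
            growing_season_fraction=wc.growing_season_fraction,
            mean_temp_c=wc.mean_temp_c,
            drought_precip_factor=wc.drought_precip_factor,
            drought_temp_offset_c=wc.drought_temp_offset_c,
        ),
        drought_years=wc.drought_years,
        seed=config.seed,
    )
    shrubs = generate_shrub_mask(terrain.shape, lc.shrub_fraction, seed=config.seed)
    return terrain, burns, weather, shrubs


def run_pipeline(config: RunConfig, run_dir: str | Path) -> RunArtifacts:
    """Run every stage and write all artifacts under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "synthesize"
    try:
        terrain, burns, weather, shrubs = synthesize_landscape(config)
        (run_dir / "rasters").mkdir(exist_ok=True)
        terrain.elevation.write_ascii(run_dir / "rasters" / "elevation.asc")
        weather.daily.to_csv(run_dir / "weather_daily.csv", index=False, date_format="%Y-%m-%d")

        stage = "forage"
        fc = config.forage
        prot_df, bio_df = sample_plots(
            terrain, burns, weather, config.weather.years,
            fc.n_protein_plots, fc.n_biomass_plots,
            protein_noise_sd=fc.protein_noise_sd, height_noise_cm=fc.height_noise_cm,
            calibrations=fc.calibrations, seed=config.seed,
        )
        prot_df.to_csv(run_dir / "plots_protein.csv", index=False, date_format="%Y-%m-%d")
        bio_df.to_csv(run_dir / "plots_biomass.csv", index=False, date_format="%Y-%m-%d")
        calibs = {}
        for year in sorted(bio_df["year"].unique()):
            sub = bio_df[bio_df["year"] == year]
            calibs[int(year)] = fit_disk_calibration(sub["height_cm"], sub["biomass"], str(year))
        bio_df = bio_df.copy()
        bio_df["biomass_est"] = np.nan
        for year, cal in calibs.items():
            sel = bio_df["year"] == year
            bio_df.loc[sel, "biomass_est"] = cal.predict(bio_df.loc[sel, "height_cm"])
        seed_rf = int(substream(config.seed, "forest").integers(2**31))
        protein_model = train_forage_model(prot_df, "protein", fc.trees, fc.node_size, seed=seed_rf)
        biomass_model = train_forage_model(
            bio_df.assign(biomass=bio_df["biomass_est"]), "biomass", fc.trees, fc.node_size, seed=seed_rf
        )
        reports = {
            "protein": validate_model(
                prot_df, "protein", fc.train_frac, fc.validation_repeats,
                trees=fc.trees, node_size=fc.node_size, seed=seed_rf,
            ).to_dict(),
        }
        with open(run_dir / "validation.json", "w") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
        stacks: dict[int, RasterStack] = {}
        years_needed = sorted({iy.year for iy in config.movement.individuals})
        for year in years_needed:
            stacks[year] = project_rasters(
                protein_model, biomass_model, terrain, weather, burns, year, shrub_mask=shrubs
            )
            stacks[year].write_dir(run_dir / "rasters")

        stage = "simulate"
        mc = config.movement
        beta = np.array([mc.beta[n] for n in COVARIATE_NAMES])
        params = MovementParams(theta=mc.theta_m, beta=beta)
        rows, cols = terrain.shape
        cx = terrain.elevation.origin[0] + cols * terrain.cell_size / 2
        cy = terrain.elevation.origin[1] + rows * terrain.cell_size / 2
        trajectories = []
        truth = {}
        (run_dir / "fixes").mkdir(exist_ok=True)
        for iy in mc.individuals:
            label = f"{iy.id}_{iy.year}"
            sseed = int(substream(config.seed, f"trajectory:{label}").integers(2**31))
            traj = simulate_trajectory(
                (cx, cy), params, stacks[iy.year], iy.n_steps, seed=sseed, individual_id=iy.id
            )
            traj.to_csv(run_dir / "fixes" / f"{label}.csv")
            trajectories.append(traj)
            truth[label] = {"theta": mc.theta_m, "beta": {n: float(v) for n, v in zip(COVARIATE_NAMES, beta)}}
        with open(run_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

        stage = "fit"
        fits = []
        rows_out = []
        (run_dir / "fits").mkdir(exist_ok=True)
        for iy, traj in zip(mc.individuals, trajectories):
            label = f"{iy.id}_{iy.year}"
            steps = build_steps(traj)
            fseed = int(substream(config.seed, f"fit:{label}").integers(2**31))
            data = prepare_step_data(
                steps, stacks[iy.year], n_controls=config.fitting.n_controls,
                radius_rule=config.fitting.radius_rule, seed=fseed,
            )
            fit = fit_step_selection(data, label=label)
            fit.to_json(run_dir / "fits" / f"{label}.json")
            fits.append(fit)
            row = {
                "eartag": iy.id,
                "year": iy.year,
                "lactating": int(iy.lactating),
                "theta_hat": fit.theta_hat,
                "converged": fit.converged,
                "n_steps": fit.n_steps,
                "strategy": classify_strategy(fit) if fit.converged else "unclassified",
            }
            for j, name in enumerate(COVARIATE_NAMES):
                row[f"beta_{name}"] = fit.beta_hat[j]
                row[f"se_{name}"] = fit.se[j + 1]
            rows_out.append(row)
        coef_table = pd.DataFrame(rows_out)
        coef_table.to_csv(run_dir / "coefficients.csv", index=False)

        stage = "analyze"
        analysis: dict = {}
        if config.analyze and coef_table["year"].nunique() >= 2:
            summ = lme_year_effect(coef_table, "beta_protein")
            analysis["year_effect_protein"] = {
                "F": summ.f_statistic,
                "df": [summ.df_num, summ.df_den],
                "p": summ.p_value,
                "random_intercept_var": summ.random_intercept_var,
            }
            tuk = tukey_years(summ)
            tuk.to_csv(run_dir / "tukey_protein.csv", index=False)
            corr = coefficient_correlation(coef_table)
            analysis["protein_vs_biomass_selection"] = {
                "slope": corr.slope, "se": corr.se, "p": corr.p_value,
            }
            with open(run_dir / "analysis.json", "w") as fh:
                json.dump(analysis, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "created": dt.datetime.now().isoformat(timespec="seconds"),
        "fits": [f.label for f in fits],
        "n_fits": len(fits),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(run_dir / "config.yaml")
    return RunArtifacts(
        run_dir=run_dir,
        stacks=stacks,
        trajectories=trajectories,
        fits=fits,
        coefficient_table=coef_table,
        analysis=analysis,
        manifest=manifest,
    )


def recovery_report(fits: list, truth: dict) -> pd.DataFrame:
    """Per-parameter recovery table across individual-years.

    For each of (θ, β₁…β₆): mean bias, mean |error|/SE, and the fraction of
    95% CIs covering the true value. ``truth`` maps fit labels to
    ``{"theta": ..., "beta": {covariate: value}}``.
    """
    if not truth:
        raise ValueError("ground-truth parameter sidecar is missing")
    missing = [f.label for f in fits if f.label not in truth]
    if missing:
        raise ValueError(f"truth entries missing for fit(s): {missing}")
    rows = []
    for i, name in enumerate(PARAM_NAMES):
        errs, scaled, covered = [], [], []
        for f in fits:
            t = truth[f.label]
            true_val = t["theta"] if name == "theta" else t["beta"][name]
            est = f.estimates[i]
            errs.append(est - true_val)
            if np.isfinite(f.se[i]) and f.se[i] > 0:
                scaled.append(abs(est - true_val) / f.se[i])
                covered.append(f.ci_low[i] <= true_val <= f.ci_high[i])
        rows.append(
            {
                "parameter": name,
                "bias": float(np.mean(errs)),
                "mean_abs_err_per_se": float(np.mean(scaled)) if scaled else np.nan,
                "coverage": float(np.mean(covered)) if covered else np.nan,
                "n": len(fits),
            }
        )
    return pd.DataFrame(rows)
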