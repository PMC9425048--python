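"""End-to-end orchestration: simulate -> derive traits -> fit -> report.

Each stage is a plain function over data frames so the numbered analysis
drivers, the command-line interface and the test suite all share the same
code path. Outputs are desk-scale CSV/YAML artifacts plus a JSON manifest
(config hash, seed, package versions) sufficient to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ct import SegmentationConfig, process_stack
from .gas import process_pac_table
from .intake import (
    FeedSpec,
    daily_intake,
    energy_intake,
    feeding_behavior,
    fit_rfi,
    interpolate_growth,
    regression_growth,
)
from .models import ModelSpec, default_model_specs, fit_bivariate_model, fit_univariate_model, report_tables
from .pedigree import PedigreeRecord, read_pedigree
from .simulate import FEED_BY_YEAR, SimulationConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulation`` (keyword arguments for
    :class:`rumigen.simulate.SimulationConfig`) or ``inputs`` (paths to the
    raw CSV tables) must be present.
    """

    seed: int = 0
    outdir: str = "results/run"
    simulation: dict | None = None
    inputs: dict | None = None
    model_specs: list[dict] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclasses.dataclass
class DataBundle:
    """Raw study tables, from simulation or disk."""

    pedigree: list[PedigreeRecord]
    animals: pd.DataFrame
    feeder_events: pd.DataFrame
    liveweights: pd.DataFrame
    pac: pd.DataFrame
    pac_body_weight: pd.DataFrame
    ct_stacks: pd.DataFrame | None
    ultrasound: pd.DataFrame | None
    truth: pd.DataFrame | None = None
    trait_table: pd.DataFrame | None = None

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort) -> "DataBundle":
        return cls(
            pedigree=cohort.pedigree,
            animals=cohort.animals,
            feeder_events=cohort.feeder_events,
            liveweights=cohort.liveweights,
            pac=cohort.pac,
            pac_body_weight=cohort.pac_body_weight,
            ct_stacks=cohort.ct_stacks,
            ultrasound=cohort.ultrasound,
            truth=cohort.truth,
            trait_table=cohort.trait_table,
        )

    @classmethod
    def from_paths(cls, paths: dict) -> "DataBundle":
        def need(key):
            if key not in paths:
                raise FileNotFoundError(f"input stage: missing required path {key!r}")
            p = Path(paths[key])
            if not p.exists():
                raise FileNotFoundError(f"input stage: {key} file not found at {p}")
            return p

        def optional(key):
            if key in paths and Path(paths[key]).exists():
                return pd.read_csv(paths[key])
            return None

        return cls(
            pedigree=read_pedigree(need("pedigree")),
            animals=pd.read_csv(need("animals")),
            feeder_events=pd.read_csv(need("feeder_events")),
            liveweights=pd.read_csv(need("liveweights")),
            pac=pd.read_csv(need("pac")),
            pac_body_weight=pd.read_csv(need("pac_body_weight")),
            ct_stacks=optional("ct_stacks"),
            ultrasound=optional("ultrasound"),
        )


def derive_traits(data: DataBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All derived traits per animal, plus the long gas table per round.

    Returns ``(traits, gas_long)``: one row per animal with intake, growth,
    RFI, behavior, round-mean gas and body-composition traits merged onto
    the covariates; and one row per animal-round with the lot-scaled gas
    traits for repeated-measures models.
    """
    animals = data.animals.copy()
    animals["animal"] = animals["animal"].astype(str)
    out = animals.set_index("animal")

    # intake and energy
    di = daily_intake(data.feeder_events)
    mean_g = di.mean(axis=1).rename("mean_intake_g_day")
    out = out.join(mean_g)
    year = out["birth_year"].astype(int)
    specs = {y: FeedSpec(*FEED_BY_YEAR[y], year=y) for y in year.unique()}
    out["energy_intake"] = [
        energy_intake(g, specs[y]) for g, y in zip(out["mean_intake_g_day"], year)
    ]

    # growth: interpolation is the headline method, regression kept alongside
    growth_rows = {}
    for animal, grp in data.liveweights.groupby(data.liveweights["animal"].astype(str)):
        interp = interpolate_growth(grp[["day", "kg"]])
        regr = regression_growth(grp[["day", "kg"]])
        growth_rows[animal] = {
            "mmwt": interp.mmwt,
            "adg": interp.adg,
            "day21_weight": interp.day21_weight,
            "mmwt_regression": regr.mmwt,
            "adg_regression": regr.adg,
        }
    out = out.join(pd.DataFrame.from_dict(growth_rows, orient="index"))
    out["aod2"] = out["aod"].astype(float) ** 2

    # feeding behavior
    out = out.join(feeding_behavior(data.feeder_events))

    # RFI residual
    rfi_input = out.reset_index()[
        ["animal", "energy_intake", "mmwt", "adg", "flock", "cohort", "pen"]
    ].dropna()
    fit = fit_rfi(rfi_input)
    out = out.join(fit.residuals.rename("rfi"))
    out.attrs["rfi_r2"] = fit.r2
    out.attrs["rfi_r2_by_cohort"] = fit.r2_by_cohort

    # gas traits
    gas = process_pac_table(data.pac, body_weight=data.pac_body_weight)
    gas["animal"] = gas["animal"].astype(str)
    gas = gas.rename(  # keep the unscaled versions under *_raw names
        columns={"ch4_co2_mol_day": "ch4_co2_mol_day_raw", "ch4_ratio": "ch4_ratio_raw"}
    )
    gas_long = gas.merge(animals, on="animal", how="left")
    gas_long = gas_long.rename(
        columns={
            "ch4_g_day_scaled": "ch4",
            "co2_g_day_scaled": "co2",
            "ch4_co2_mol_day_scaled": "ch4_co2_mol",
            "ch4_ratio_scaled": "ch4_ratio",
        }
    )
    round_means = (
        gas_long.groupby("animal")[["ch4", "co2", "ch4_co2_mol", "ch4_ratio"]]
        .mean()
        .rename(columns=lambda c: f"{c}_mean")
    )
    out = out.join(round_means)

    # body composition from CT
    if data.ct_stacks is not None and len(data.ct_stacks):
        seg = SegmentationConfig()
        comp_rows = {}
        for animal, grp in data.ct_stacks.groupby(data.ct_stacks["animal"].astype(str)):
            _, rec = process_stack(grp, seg, spacing_mm=30.0)
            comp_rows[animal] = rec.as_dict()
        comp = pd.DataFrame.from_dict(comp_rows, orient="index")
        comp["ctwt"] = comp["ct_weight"]
        out = out.join(comp)

    if data.ultrasound is not None and len(data.ultrasound):
        us = data.ultrasound.copy()
        us["animal"] = us["animal"].astype(str)
        us = us.set_index("animal")
        us["c_change_mm"] = us["c_final_mm"] - us["c_start_mm"]
        out = out.join(us)

    result = out.reset_index()
    result.attrs["rfi_r2"] = fit.r2
    result.attrs["rfi_r2_by_cohort"] = fit.r2_by_cohort
    return result, gas_long


def fit_models(
    traits: pd.DataFrame,
    gas_long: pd.DataFrame,
    pedigree: list[PedigreeRecord],
    specs: list[ModelSpec] | None = None,
) -> tuple[dict, dict]:
    """Fit every applicable univariate spec plus headline bivariate pairs."""
    specs = specs if specs is not None else default_model_specs()
    results: dict = {}
    for spec in specs:
        frame = gas_long if spec.repeated else traits
        if spec.trait not in frame.columns:
            logger.info("skipping %s: trait not present", spec.trait)
            continue
        missing = [c for c in spec.fixed if c not in frame.columns]
        if missing:
            logger.warning("skipping %s: missing fixed effects %s", spec.trait, missing)
            continue
        try:
            results[spec.trait] = fit_univariate_model(frame, spec, pedigree)
        except Exception as err:  # noqa: BLE001 - surface per-trait failures
            logger.warning("fit failed for %s: %s", spec.trait, err)

    correlations: dict = {}
    pairs = [("rfi", "ch4_ratio_mean"), ("rfi", "visceral_fat"), ("rfi", "nonfat_visceral")]
    for a, b in pairs:
        if a in traits.columns and b in traits.columns:
            try:
                correlations[(a, b)] = fit_bivariate_model(traits, a, b, pedigree)
            except Exception as err:  # noqa: BLE001
                logger.warning("bivariate fit failed for %s x %s: %s", a, b, err)
    return results, correlations


def recovery_report(results: dict, trait_table: pd.DataFrame | None) -> pd.DataFrame:
    """Truth-vs-estimate table when the run was simulated."""
    if trait_table is None:
        return pd.DataFrame()
    rows = []
    for trait, vc in results.items():
        if trait not in trait_table.index:
            continue
        rows.append(
            {
                "trait": trait,
                "true_h2": float(trait_table.loc[trait, "h2"]),
                "est_h2": vc.h2_direct,
                "est_h2_se": vc.h2_direct_se,
                "true_maternal_h2": float(trait_table.loc[trait, "mat_h2"]),
                "est_maternal_h2": vc.h2_maternal,
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest. Partial outputs are kept
    with a FAILED marker when a stage raises."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "rumigen_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages": [],
    }
    try:
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            sim_kwargs["seed"] = config.seed
            cohort = simulate_cohort(SimulationConfig(**sim_kwargs))
            cohort.write(out / "data")
            data = DataBundle.from_cohort(cohort)
            manifest["stages"].append("simulate")
        elif config.inputs is not None:
            data = DataBundle.from_paths(config.inputs)
            manifest["stages"].append("load")
        else:
            raise ValueError("config needs either a simulation block or input paths")

        traits, gas_long = derive_traits(data)
        traits.to_csv(out / "traits.csv", index=False)
        gas_long.to_csv(out / "gas_rounds.csv", index=False)
        manifest["rfi_r2"] = traits.attrs.get("rfi_r2")
        manifest["stages"].append("traits")

        specs = (
            [ModelSpec.from_dict(d) for d in config.model_specs]
            if config.model_specs
            else None
        )
        results, correlations = fit_models(traits, gas_long, data.pedigree, specs)
        report = report_tables(results, traits)
        report.to_csv(out / "genetic_parameters.csv", index=False)
        corr_rows = [
            {
                "trait_a": a, "trait_b": b, "r_g": ce.r_g, "r_g_se": ce.r_g_se,
                "r_p": ce.r_p, "r_p_se": ce.r_p_se,
                "r_g_significant": ce.significant_g,
            }
            for (a, b), ce in correlations.items()
        ]
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
        manifest["stages"].append("fit")

        rec = recovery_report(results, data.trait_table)
        if len(rec):
            rec.to_csv(out / "recovery.csv", index=False)
        manifest["stages"].append("report")
    except Exception as err:
        (out / "FAILED").write_text(f"{type(err).__name__}: {err}\n")
        raise
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
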