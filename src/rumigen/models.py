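"""Model specifications tying trait tables to the REML engine.

A :class:`ModelSpec` names the response trait, its fixed effects
(categorical factors such as contemporary group and cohort-pen, and
mean-centred covariates), and the random structure (direct additive always;
maternal dam effect; permanent environment for repeated chamber rounds).
The fitting wrappers assemble design matrices, map animals and dams into
the relationship matrix, and return fitted variance components or trait
pair correlations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import yaml

from .intake import _drop_aliased
from .pedigree import PedigreeRecord, build_A
from .reml import (
    CorrelationEstimate,
    VarianceComponents,
    reml_bivariate,
    reml_univariate,
    significance_flag,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One univariate animal-model specification."""

    trait: str
    fixed: tuple[str, ...] = ("cg",)
    covariates: tuple[str, ...] = ()
    maternal: str | None = "genetic"  #: "genetic", "iid" or None
    repeated: bool = False  #: two chamber rounds, adds permanent environment

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(
            trait=d["trait"],
            fixed=tuple(d.get("fixed", ("cg",))),
            covariates=tuple(d.get("covariates", ())),
            maternal=d.get("maternal", "genetic"),
            repeated=bool(d.get("repeated", False)),
        )


def model_specs_from_yaml(path) -> list[ModelSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ModelSpec.from_dict(d) for d in raw]


def default_model_specs() -> list[ModelSpec]:
    """Fixed-effect structures for the shipped traits.

    These encode the final (significant) effect sets of the study design:
    contemporary group everywhere, cohort-pen and birth-rearing rank for
    management-sensitive traits, age-of-dam terms for weight, and repeated
    rounds with permanent environment for the chamber gas traits.
    """
    return [
        ModelSpec("rfi", fixed=("cg",)),
        ModelSpec("energy_intake", fixed=("cg", "cohort_pen", "brr")),
        ModelSpec("mmwt", fixed=("cg", "brr"), covariates=("aod", "aod2", "bdev")),
        ModelSpec("adg", fixed=("cg", "cohort_pen", "brr")),
        ModelSpec("events_per_day", fixed=("cg", "cohort_pen")),
        ModelSpec("feeding_rate", fixed=("cg", "cohort_pen", "brr")),
        ModelSpec("ch4", fixed=("cg", "brr"), covariates=("aod2",), repeated=True),
        ModelSpec("co2", fixed=("cohort", "brr"), repeated=True),
        ModelSpec("ch4_ratio", fixed=("cg", "cohort"), covariates=("aod2",), repeated=True),
        ModelSpec("c_start_mm", fixed=("cg", "cohort_pen"), covariates=("mmwt",)),
        ModelSpec("c_final_mm", fixed=("cg", "cohort_pen"), covariates=("mmwt",)),
        ModelSpec("visceral_fat", fixed=("cg",), covariates=("ctwt",)),
        ModelSpec("carcass_lean", fixed=("cg", "brr")),
        ModelSpec("carcass_fat", fixed=("cg",), covariates=("ctwt",)),
    ]


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + centred covariates + dummy-coded factors, de-aliased."""
    parts = [np.ones((len(df), 1))]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov == "aod2" and "aod2" not in df:
            x = df["aod"].to_numpy(dtype=float) ** 2
        else:
            x = df[cov].to_numpy(dtype=float)
        parts.append((x - x.mean())[:, None])
        names.append(cov)
    for factor in spec.fixed:
        dummies = pd.get_dummies(df[factor].astype(str), prefix=factor, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    X = np.hstack(parts)
    X, names, _ = _drop_aliased(X, names)
    return X, names


def _pedigree_maps(pedigree: list[PedigreeRecord]):
    A = build_A(pedigree)
    pos = {a: i for i, a in enumerate(A.ids)}
    dam_of = {r.animal_id: r.dam_id for r in pedigree}
    return A, pos, dam_of


def fit_univariate_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    pedigree: list[PedigreeRecord],
) -> VarianceComponents:
    """Fit one trait's animal model by REML.

    ``data`` holds one row per record with an ``animal`` column, the trait
    column, every fixed-effect column of the spec, and (for repeated
    traits) a ``round`` column. Maternal terms need every record's dam in
    the pedigree; otherwise the term is dropped with a warning.
    """
    A, pos, dam_of = _pedigree_maps(pedigree)
    df = data.dropna(subset=[spec.trait]).copy()
    df["animal"] = df["animal"].astype(str)
    y = df[spec.trait].to_numpy(dtype=float)
    X, _ = design_matrix(df, spec)
    animal_idx = df["animal"].map(pos).to_numpy()
    if np.any(pd.isna(animal_idx)):
        raise ValueError("records for animals missing from the pedigree")
    animal_idx = animal_idx.astype(int)

    maternal = spec.maternal
    dam_idx = None
    if maternal is not None:
        dams = df["animal"].map(dam_of)
        if dams.isna().any() or any(d not in pos for d in dams.dropna()):
            logger.warning(
                "maternal term for %s dropped: not every record has a pedigreed dam",
                spec.trait,
            )
            maternal = None
        else:
            dam_idx = dams.map(pos).to_numpy().astype(int)
            if dams.nunique() == len(df):
                logger.warning(
                    "maternal effect for %s may be unestimable: every dam is a "
                    "singleton", spec.trait,
                )
    return reml_univariate(
        y,
        X,
        A.values,
        animal_idx,
        dam_idx=dam_idx,
        maternal=maternal,
        permanent_env=spec.repeated,
    )


def fit_bivariate_model(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    pedigree: list[PedigreeRecord],
    fixed: tuple[str, ...] = ("cg",),
    covariates: tuple[str, ...] = (),
) -> CorrelationEstimate:
    """Genetic/phenotypic correlation between two traits (one record each).

    Records missing either trait are dropped (the correlation uses the
    overlapping animals). Repeated gas traits should be averaged over
    rounds before calling.
    """
    df = data.dropna(subset=[trait1, trait2]).copy()
    df["animal"] = df["animal"].astype(str)
    A, pos, _ = _pedigree_maps(pedigree)
    spec = ModelSpec(trait1, fixed=fixed, covariates=covariates, maternal=None)
    X, _ = design_matrix(df, spec)
    animal_idx = df["animal"].map(pos).to_numpy().astype(int)
    return reml_bivariate(
        df[trait1].to_numpy(dtype=float),
        df[trait2].to_numpy(dtype=float),
        X,
        A.values,
        animal_idx,
        traits=(trait1, trait2),
    )


def report_tables(
    results: dict[str, VarianceComponents],
    data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summary table of fitted parameters, one row per trait.

    Mirrors the usual layout of genetic-parameter reports: trait mean and
    SD (when the data are supplied), direct and maternal heritability with
    SEs, repeatability for repeated traits, and the two-standard-error
    significance call for the direct heritability.
    """
    columns = [
        "trait", "mean", "sd", "h2", "h2_se", "maternal_h2", "maternal_h2_se",
        "repeatability", "repeatability_se", "h2_significant", "converged",
    ]
    rows = []
    for trait, vc in results.items():
        mean = sd = np.nan
        if data is not None and trait in data:
            mean = float(data[trait].mean())
            sd = float(data[trait].std())
        rows.append(
            {
                "trait": trait,
                "mean": mean,
                "sd": sd,
                "h2": vc.h2_direct,
                "h2_se": vc.h2_direct_se,
                "maternal_h2": vc.h2_maternal,
                "maternal_h2_se": vc.h2_maternal_se,
                "repeatability": vc.repeatability,
                "repeatability_se": vc.repeatability_se,
                "h2_significant": significance_flag(vc.h2_direct, vc.h2_direct_se)
                if vc.h2_direct_se > 0
                else False,
                "converged": vc.converged,
            }
        )
    return pd.DataFrame(rows, columns=columns)
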