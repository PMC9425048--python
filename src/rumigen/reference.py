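"""Published reference estimates for NZ maternal-sheep feed-efficiency traits.

These point estimates (trait means, phenotypic SDs, direct and maternal
heritabilities, repeatabilities and genetic/phenotypic correlations with
their standard errors) are packaged for two purposes: they seed the
synthetic cohort generator's default true parameters, and they exercise the
two-standard-error significance rule used to declare estimates different
from zero.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with importlib.resources.files("rumigen.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_reference_traits() -> pd.DataFrame:
    """Trait-level reference estimates.

    Columns: table (trait family), trait, mean, sd, h2, h2_se, maternal_h2,
    maternal_h2_se, repeatability, repeatability_se. Missing maternal /
    repeatability cells mean the term was not reported for that trait.
    """
    return _read("reference_traits.csv")


def load_reference_correlations() -> pd.DataFrame:
    """Pairwise genetic (rg) and phenotypic (rp) correlation estimates.

    Columns: trait_a, trait_b, type ('rg' or 'rp'), value, se.
    """
    return _read("reference_correlations.csv")
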