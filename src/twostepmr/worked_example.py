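"""Loaders for the published worked-example tables of the SGLT2-inhibition study.

Three small transcribed tables ship with the package: the ten genetic
instruments for genetically proxied SGLT2 inhibition (HbA1c effects of
SLC5A2 variants), the 53-metabolite step-1 screen results, and the 28
mediation pathways with their printed effect decompositions. They serve as
frozen regression fixtures for the estimators and the mediation identities.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_instruments", "load_metabolite_screen", "load_mediation_pathways"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("twostepmr.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_instruments() -> pd.DataFrame:
    """Ten SLC5A2 instruments: alleles, betas, SEs, p-values, F-statistics."""
    return _read("sglt2_instruments.tsv")


def load_metabolite_screen() -> pd.DataFrame:
    """Step-1 screen: metabolite, odds ratio with 95% CI, p-value."""
    return _read("metabolite_screen.tsv")


def load_mediation_pathways() -> pd.DataFrame:
    """28 mediation pathways: total/step-1/step-2 effects, products, proportions."""
    return _read("mediation_pathways.tsv")
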