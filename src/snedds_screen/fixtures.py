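"""Bundled example campaign data.

Two complete screening campaigns ship with the package: a celecoxib SNEDDS
campaign (11 mixtures, parallelogram refinement, three of the hexagon
mixtures never emulsified) and a fenofibrate SNEDDS campaign (14 mixtures,
trapezoid refinement).  Their measured responses and final formulation
compositions are packaged as CSV; the saturation-solubility and
miscibility tables are *synthetic* stand-ins (no numeric source tables
exist for them) chosen so the drug-load equation reproduces the
campaigns' stated loads of 9.09% and 5.21%.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .formulation import BlendComponent, SolubilityRecord
from .io import read_miscibility, read_responses, read_solubility
from .specs import EmulsionObservation

__all__ = [
    "DRUGS",
    "reference_responses",
    "reference_formulation",
    "surfactant_blend",
    "drug_factor",
    "synthetic_solubility",
    "synthetic_miscibility",
]

DRUGS = ("celecoxib", "fenofibrate")

#: Tween 80 : d-TPGS surfactant blend ratio (w/w) per campaign.
_BLEND_RATIOS = {"celecoxib": (8.0, 1.0), "fenofibrate": (5.0, 1.0)}
#: Drug-specific factor f in the drug-load equation.
_F_FACTORS = {"celecoxib": 0.7, "fenofibrate": 0.5}


def _data(name: str):
    return resources.files("snedds_screen.data").joinpath(name)


def _check_drug(drug: str) -> None:
    if drug not in DRUGS:
        raise ValueError(f"unknown campaign {drug!r}; expected one of {DRUGS}")


def reference_responses(drug: str) -> list[EmulsionObservation]:
    """Measured responses of the bundled campaign for ``drug``."""
    _check_drug(drug)
    with resources.as_file(_data(f"{drug}_responses.csv")) as path:
        return read_responses(path)


def reference_formulation(drug: str) -> pd.DataFrame:
    """Final formulation (component, kind, mass_pct) for ``drug``."""
    _check_drug(drug)
    with resources.as_file(_data("reference_formulations.csv")) as path:
        df = pd.read_csv(path)
    return df[df["drug"] == drug].reset_index(drop=True)


def surfactant_blend(drug: str) -> BlendComponent:
    _check_drug(drug)
    return BlendComponent(("Tween 80", "d-TPGS"), _BLEND_RATIOS[drug])


def drug_factor(drug: str) -> float:
    _check_drug(drug)
    return _F_FACTORS[drug]


def synthetic_solubility(drug: str | None = None) -> list[SolubilityRecord]:
    """Synthetic saturation-solubility table (mg/g)."""
    with resources.as_file(_data("synthetic_solubility.csv")) as path:
        records = read_solubility(path)
    if drug is not None:
        _check_drug(drug)
        records = [r for r in records if r.drug == drug]
    return records


def synthetic_miscibility() -> pd.DataFrame:
    """Synthetic pairwise miscibility matrix for the bundled excipients."""
    with resources.as_file(_data("synthetic_miscibility.csv")) as path:
        return read_miscibility(path)
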