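"""Excipient bookkeeping: solubility ranking, compatibility, drug load.

The drug load of a SNEDDS preconcentrate is set once per campaign from the
saturation solubilities c_s (mg drug / g excipient) of the drug in the
individual components:

    drug load [%] = f * mean(c_s) * 0.1

where f is a drug-specific safety factor (< 1) guarding against
precipitation as the excipient ratio varies across the design.  A ternary
design axis may be a single excipient or a fixed-ratio blend (e.g. a
Tween 80 : d-TPGS 5:1 surfactant mixture); :func:`expand_blend` turns a
simplex point plus the drug load into the full mass-percent formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .geometry import TernaryPoint

__all__ = [
    "Excipient",
    "SolubilityRecord",
    "BlendComponent",
    "Formulation",
    "drug_load",
    "expand_blend",
    "compatibility_filter",
    "rank_by_solubility",
    "encapsulation_efficiency",
]

ROLES = ("oil_lipid", "surfactant", "cosolvent")


@dataclass(frozen=True)
class Excipient:
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown excipient role {self.role!r}")


@dataclass(frozen=True)
class SolubilityRecord:
    """Saturation solubility of one drug in one excipient (mg/g)."""

    drug: str
    excipient: str
    c_s: float
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.c_s < 0:
            raise ValueError(f"negative saturation solubility {self.c_s}")


@dataclass(frozen=True)
class BlendComponent:
    """A design axis that is itself a fixed-ratio (w/w) excipient mixture."""

    constituents: tuple[str, ...]
    ratio: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.constituents) < 2:
            raise ValueError("a blend needs at least two constituents")
        if len(self.ratio) != len(self.constituents):
            raise ValueError("blend ratio length must match constituents")
        if any(w <= 0 for w in self.ratio):
            raise ValueError("blend ratio weights must be positive")

    def split(self, mass_percent: float) -> dict[str, float]:
        total = sum(self.ratio)
        return {
            name: mass_percent * w / total
            for name, w in zip(self.constituents, self.ratio)
        }


Axis = Union[str, BlendComponent]


@dataclass(frozen=True)
class Formulation:
    """Full mass-percent breakdown of a drug-loaded preconcentrate."""

    drug: str
    drug_load: float
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValueError("negative component percentage")
        total = self.drug_load + sum(self.components.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"formulation totals {total:.4f}%, expected 100")

    def as_series(self) -> pd.Series:
        data = dict(self.components)
        data[self.drug] = self.drug_load
        return pd.Series(data)


def drug_load(f: float, solubilities: Sequence[float]) -> float:
    """Drug load in percent from f and per-component c_s values (mg/g)."""
    if f <= 0:
        raise ValueError(f"drug-specific factor must be positive, got {f}")
    if len(solubilities) == 0:
        raise ValueError("need at least one saturation solubility")
    if any(c < 0 for c in solubilities):
        raise ValueError("saturation solubilities must be nonnegative")
    return f * (sum(solubilities) / len(solubilities)) * 0.1


def expand_blend(
    point: TernaryPoint,
    axes: Sequence[Axis],
    drug: str,
    load_percent: float,
) -> Formulation:
    """Expand a simplex point into the full drug-loaded formulation.

    Each excipient receives ``fraction * (100 - drug_load)`` mass percent;
    blend axes are split among their constituents by the blend ratio.
    Arithmetic is full precision — rounding to two decimals happens only at
    serialization.
    """
    if len(axes) != 3:
        raise ValueError("exactly three design axes are required")
    if not 0.0 <= load_percent < 100.0:
        raise ValueError(f"drug load must be in [0, 100), got {load_percent}")
    excipient_total = 100.0 - load_percent
    components: dict[str, float] = {}
    for fraction, axis in zip(point.as_array(), axes):
        mass = float(fraction) * excipient_total
        parts = axis.split(mass) if isinstance(axis, BlendComponent) else {axis: mass}
        for name, value in parts.items():
            if name in components:
                raise ValueError(f"excipient {name!r} appears on two axes")
            components[name] = value
    return Formulation(drug=drug, drug_load=load_percent, components=components)


def _as_matrix(miscibility) -> pd.DataFrame:
    m = pd.DataFrame(miscibility).astype(bool)
    if list(m.index) != list(m.columns):
        raise ValueError("miscibility matrix must have identical row/column labels")
    if not m.equals(m.T):
        raise ValueError("miscibility matrix must be symmetric")
    if not all(m.loc[n, n] for n in m.index):
        raise ValueError("miscibility matrix diagonal must be true")
    return m


def compatibility_filter(
    candidates: Iterable[Sequence[str]],
    miscibility,
) -> list[tuple[str, ...]]:
    """Keep only candidate excipient sets whose every pair is miscible.

    ``miscibility`` is a square boolean matrix labeled by excipient name
    (DataFrame or nested mapping).
    """
    m = _as_matrix(miscibility)
    known = set(m.index)
    kept = []
    for cand in candidates:
        names = tuple(cand)
        unknown = [n for n in names if n not in known]
        if unknown:
            raise ValueError(f"unknown excipients in candidate set: {unknown}")
        if all(
            m.loc[names[i], names[j]]
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ):
            kept.append(names)
    return kept


def rank_by_solubility(
    records: Sequence[SolubilityRecord], role: Optional[str] = None
) -> list[str]:
    """Excipients in descending c_s order; ties broken alphabetically."""
    if not records:
        raise ValueError("no solubility records to rank")
    if role is not None:
        records = [r for r in records if r.role == role]
    return [r.excipient for r in sorted(records, key=lambda r: (-r.c_s, r.excipient))]


def encapsulation_efficiency(measured_load: float, theoretical_load: float) -> float:
    """Measured vs theoretical drug load, in percent."""
    if theoretical_load <= 0:
        raise ValueError("theoretical drug load must be positive")
    return 100.0 * measured_load / theoretical_load
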