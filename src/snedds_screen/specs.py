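"""Specification evaluation and winner selection for emulsion responses.

A SNEDDS preconcentrate is judged after dispersion in water by three
quantitative responses — mean droplet size (dynamic light scattering),
polydispersity index (PDI) and transmittance at 650 nm relative to water —
plus an ordinal visual emulsification grade (I = rapid clear nanoemulsion
... V = no emulsion).  The screening targets are strict: size < 50 nm,
PDI < 0.15, transmittance > 99%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "GRADE_ROMAN",
    "SpecificationSet",
    "EmulsionObservation",
    "SpecEvaluation",
    "evaluate_specs",
    "select_best",
    "discard_unstable",
    "grade_to_roman",
    "roman_to_grade",
]

GRADE_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
_ROMAN_GRADE = {v: k for k, v in GRADE_ROMAN.items()}


def grade_to_roman(grade: int) -> str:
    try:
        return GRADE_ROMAN[int(grade)]
    except (KeyError, ValueError):
        raise ValueError(f"emulsification grade must be 1-5, got {grade!r}")


def roman_to_grade(text: str) -> int:
    try:
        return _ROMAN_GRADE[text.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown emulsification grade {text!r} (expected I-V)")


@dataclass(frozen=True)
class SpecificationSet:
    """Pass/fail thresholds for a promising SNEDDS formulation.

    All comparisons are strict, as the targets are stated: a droplet size
    of exactly 50.0 nm fails, a transmittance of exactly 99.0% fails.
    """

    max_size: float = 50.0        # nm
    max_pdi: float = 0.15         # dimensionless
    min_transmittance: float = 99.0  # percent vs purified water
    required_grade: int = 1       # ordinal I; used in ranking, not pass/fail

    def __post_init__(self) -> None:
        if self.max_size <= 0 or self.max_pdi <= 0 or self.min_transmittance <= 0:
            raise ValueError("specification thresholds must be positive")
        if self.min_transmittance > 100:
            raise ValueError("transmittance threshold cannot exceed 100%")
        if self.required_grade not in GRADE_ROMAN:
            raise ValueError("required grade must be 1-5")


@dataclass(frozen=True)
class EmulsionObservation:
    """Measured responses for one prepared mixture.

    ``formed_emulsion=False`` records a mixture that failed to emulsify;
    its quantitative metrics are absent (``None``, written as ``NA`` on
    disk) and its grade is V.  Standard deviations of the triplicate
    measurements are carried as metadata only.
    """

    sample_id: int
    size_nm: Optional[float] = None
    pdi: Optional[float] = None
    transmittance_pct: Optional[float] = None
    grade: int = 5
    formed_emulsion: bool = True
    size_sd: Optional[float] = None
    pdi_sd: Optional[float] = None
    transmittance_sd: Optional[float] = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.grade not in GRADE_ROMAN:
            raise ValueError(f"grade must be 1-5, got {self.grade}")
        if self.transmittance_pct is not None and self.transmittance_pct > 100.0 + 1e-9:
            raise ValueError(
                f"transmittance {self.transmittance_pct} exceeds 100%"
            )
        if self.size_nm is not None and self.size_nm < 0:
            raise ValueError(f"negative droplet size {self.size_nm}")

    @property
    def is_complete(self) -> bool:
        return (
            self.size_nm is not None
            and self.pdi is not None
            and self.transmittance_pct is not None
        )


@dataclass(frozen=True)
class SpecEvaluation:
    sample_id: int
    size_ok: bool
    pdi_ok: bool
    transmittance_ok: bool

    @property
    def overall(self) -> bool:
        return self.size_ok and self.pdi_ok and self.transmittance_ok


def evaluate_specs(
    obs: EmulsionObservation, specs: SpecificationSet = SpecificationSet()
) -> SpecEvaluation:
    """Strict per-criterion evaluation; absent metrics fail everything."""
    if not obs.formed_emulsion or not obs.is_complete:
        return SpecEvaluation(obs.sample_id, False, False, False)
    return SpecEvaluation(
        obs.sample_id,
        size_ok=obs.size_nm < specs.max_size,
        pdi_ok=obs.pdi < specs.max_pdi,
        transmittance_ok=obs.transmittance_pct > specs.min_transmittance,
    )


def _rank_key(obs: EmulsionObservation):
    # grade asc, PDI asc, size asc, transmittance desc; sample_id for
    # determinism on exact ties.
    return (obs.grade, obs.pdi, obs.size_nm, -obs.transmittance_pct, obs.sample_id)


def select_best(
    observations: Sequence[EmulsionObservation],
    specs: SpecificationSet = SpecificationSet(),
) -> tuple[Optional[int], list[EmulsionObservation]]:
    """Winner among spec-passing samples, plus the full passing ranking.

    Ordering is lexicographic: emulsification grade, then PDI, then droplet
    size, then (descending) transmittance.  Returns ``(None, [])`` when no
    sample passes.
    """
    if not observations:
        raise ValueError("select_best requires at least one observation")
    ids = [o.sample_id for o in observations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in observations")
    passing = [o for o in observations if evaluate_specs(o, specs).overall]
    ranking = sorted(passing, key=_rank_key)
    return (ranking[0].sample_id if ranking else None), ranking


def discard_unstable(
    observations: Iterable[EmulsionObservation],
) -> list[EmulsionObservation]:
    """Drop mixtures that never formed a nanoemulsion.

    The dropped records stay in the audit trail and in the statistical
    model (via worst-case imputation); they are merely removed from
    candidacy.
    """
    return [o for o in observations if o.formed_emulsion]
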