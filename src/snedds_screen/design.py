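"""The adaptive screening engine.

Stage 1 prepares the center point of the ternary diagram (sample 1) and
the six vertices of a hexagon mapped around it (samples 2–7).  The stage-1
responses locate the designated area of interest (DAOI): here, the
desirability-weighted centroid of the top-scoring samples, together with
the direction of steepest desirability increase from the center.  A
refinement figure — a parallelogram (4 mixtures, samples 8–11) or a
trapezoid with up to three extra points along its parallel sides (5–7
mixtures, samples 8–14) — is then placed into the DAOI and sampled until
a mixture meeting every specification is found.

The payoff is efficiency: the classical alternative varies each component
in 10% increments (66 grid compositions); the adaptive loop typically
needs 11–14 preparations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .geometry import (
    CENTROID,
    DesignFigure,
    PlanarPoint,
    SimplexError,
    TernaryPoint,
    from_cartesian,
    hexagon_vertices,
    to_cartesian,
)
from .specs import EmulsionObservation, SpecificationSet, evaluate_specs, select_best

__all__ = [
    "SampleRequest",
    "DAOI",
    "ScreeningRecord",
    "ScreeningResult",
    "ScreeningConfig",
    "NoDAOIError",
    "initial_design",
    "desirability",
    "identify_daoi",
    "refine",
    "run_screening",
]


class NoDAOIError(RuntimeError):
    """No area of interest can be identified; widen the search."""


@dataclass(frozen=True)
class SampleRequest:
    """One mixture to prepare: id 1 = center, 2–7 hexagon, ≥8 refinement."""

    sample_id: int
    point: TernaryPoint
    stage: str  # "initial" or "refinement_k"

    def __post_init__(self) -> None:
        if self.sample_id < 1:
            raise ValueError("sample ids start at 1")


@dataclass(frozen=True)
class DAOI:
    """Designated area of interest identified from observed responses."""

    centroid: TernaryPoint
    direction: tuple[float, float]  # unit vector in the Cartesian embedding
    support_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"DAOI direction must be a unit vector, norm {norm:.3g}")


@dataclass(frozen=True)
class ScreeningRecord:
    request: SampleRequest
    observation: EmulsionObservation
    desirability: float


@dataclass(frozen=True)
class ScreeningResult:
    records: tuple[ScreeningRecord, ...]
    daois: tuple[DAOI, ...]
    winner: Optional[int]
    n_experiments: int
    stop_reason: str  # spec_met | max_stages | exhausted

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "n_experiments": self.n_experiments,
            "stop_reason": self.stop_reason,
            "samples": [
                {
                    "sample_id": r.request.sample_id,
                    "stage": r.request.stage,
                    "composition_pct": [
                        round(v, 2) for v in r.request.point.as_percent()
                    ],
                    "formed_emulsion": r.observation.formed_emulsion,
                    "size_nm": r.observation.size_nm,
                    "pdi": r.observation.pdi,
                    "transmittance_pct": r.observation.transmittance_pct,
                    "grade": r.observation.grade,
                    "desirability": round(r.desirability, 4),
                }
                for r in self.records
            ],
            "daois": [
                {
                    "centroid_pct": [round(v, 2) for v in d.centroid.as_percent()],
                    "direction": [round(v, 4) for v in d.direction],
                    "support_ids": list(d.support_ids),
                }
                for d in self.daois
            ],
        }


@dataclass(frozen=True)
class ScreeningConfig:
    """Tunable knobs of the screening strategy.

    ``hex_radius`` and ``edge_length`` are Cartesian lengths in the
    unit-edge triangle; the refinement figure edge defaults to the hexagon
    radius so both stages probe the same length scale.
    """

    center: TernaryPoint = CENTROID
    hex_radius: float = 0.15
    hex_rotation: float = 0.0
    figure_kind: str = "parallelogram"
    extras: tuple[int, int] = (2, 1)
    edge_length: Optional[float] = None  # defaults to hex_radius
    top_k: int = 3
    max_stages: int = 3  # refinement stages after stage 1
    shrink_to_fit: bool = True
    specs: SpecificationSet = field(default_factory=SpecificationSet)

    def __post_init__(self) -> None:
        if self.hex_radius <= 0:
            raise ValueError("hex_radius must be positive")
        if self.figure_kind not in ("parallelogram", "trapezoid"):
            raise ValueError(f"unknown refinement figure {self.figure_kind!r}")
        if self.top_k < 1 or self.max_stages < 1:
            raise ValueError("top_k and max_stages must be at least 1")

    @property
    def refinement_edge(self) -> float:
        return self.edge_length if self.edge_length is not None else self.hex_radius


def initial_design(config: ScreeningConfig = ScreeningConfig()) -> list[SampleRequest]:
    """Sample 1 at the center, samples 2–7 on the surrounding hexagon."""
    vertices = hexagon_vertices(config.center, config.hex_radius, config.hex_rotation)
    requests = [SampleRequest(1, config.center, "initial")]
    requests += [
        SampleRequest(i + 2, v, "initial") for i, v in enumerate(vertices)
    ]
    return requests


# Desirability ramp floors: the score for each response decays linearly
# from 1 at its specification threshold to 0 at these values.
SIZE_ZERO = 200.0   # nm
PDI_ZERO = 0.35
TRANS_ZERO = 85.0   # percent


def desirability(
    obs: EmulsionObservation, specs: SpecificationSet = SpecificationSet()
) -> float:
    """Scalar [0, 1] score: geometric mean of three per-response ramps.

    Each response scores 1 inside its specification and decays linearly to
    0 at a hopeless value (size 200 nm, PDI 0.35, transmittance 85%).
    Mixtures that formed no emulsion (or lack any metric) score 0.
    """
    if not obs.formed_emulsion or not obs.is_complete:
        return 0.0
    d_size = 1.0 if obs.size_nm < specs.max_size else max(
        0.0, (SIZE_ZERO - obs.size_nm) / (SIZE_ZERO - specs.max_size)
    )
    d_pdi = 1.0 if obs.pdi < specs.max_pdi else max(
        0.0, (PDI_ZERO - obs.pdi) / (PDI_ZERO - specs.max_pdi)
    )
    d_trans = 1.0 if obs.transmittance_pct > specs.min_transmittance else max(
        0.0,
        (obs.transmittance_pct - TRANS_ZERO)
        / (specs.min_transmittance - TRANS_ZERO),
    )
    return float((d_size * d_pdi * d_trans) ** (1.0 / 3.0))


def identify_daoi(
    records: Sequence[tuple[SampleRequest, EmulsionObservation]],
    specs: SpecificationSet = SpecificationSet(),
    top_k: int = 3,
    center: TernaryPoint = CENTROID,
) -> DAOI:
    """Locate the area of interest from observed desirabilities.

    The DAOI centroid is the desirability-weighted Cartesian mean of the
    ``top_k`` best-scoring samples; the direction points from the stage-1
    center toward it (falling back to angle 0 when the two coincide).
    """
    scored = [
        (req, obs, desirability(obs, specs)) for req, obs in records
    ]
    nonzero = [t for t in scored if t[2] > 0.0]
    if not nonzero:
        raise NoDAOIError("all desirabilities are zero; no DAOI — widen search")
    if len(nonzero) < 3:
        raise NoDAOIError(
            f"only {len(nonzero)} samples with nonzero desirability; "
            "need at least 3 to locate a DAOI"
        )
    ordered = sorted(nonzero, key=lambda t: (-t[2], t[0].sample_id))
    # tie-inclusive top-k: samples tied with the k-th score all contribute,
    # so a perfectly uniform stage recovers its own center.
    cutoff = ordered[min(top_k, len(ordered)) - 1][2]
    top = [t for t in ordered if t[2] >= cutoff - 1e-12]
    weights = np.array([t[2] for t in top])
    coords = np.array([to_cartesian(t[0].point).as_array() for t in top])
    mean = weights @ coords / weights.sum()
    centroid = from_cartesian(PlanarPoint(*mean))
    delta = mean - to_cartesian(center).as_array()
    norm = float(np.linalg.norm(delta))
    direction = (1.0, 0.0) if norm < 1e-12 else (delta[0] / norm, delta[1] / norm)
    return DAOI(
        centroid=centroid,
        direction=direction,
        support_ids=tuple(t[0].sample_id for t in top),
    )


def refine(
    daoi: DAOI,
    figure_kind: str,
    config: ScreeningConfig = ScreeningConfig(),
    start_id: int = 8,
    stage: int = 1,
) -> list[SampleRequest]:
    """Place a refinement figure into the DAOI and request its points.

    The figure is anchored at the DAOI centroid, oriented along its
    direction, and sized by the configured edge length.  Sample ids
    continue the running numbering (8, 9, ...).
    """
    rotation = math.atan2(daoi.direction[1], daoi.direction[0])
    figure = DesignFigure(
        kind=figure_kind,
        anchor=daoi.centroid,
        size=config.refinement_edge,
        rotation=rotation,
        extras=config.extras if figure_kind == "trapezoid" else (0, 0),
    )
    points = figure.points(shrink_to_fit=config.shrink_to_fit)
    return [
        SampleRequest(start_id + i, p, f"refinement_{stage}")
        for i, p in enumerate(points)
    ]


Oracle = Callable[[TernaryPoint], EmulsionObservation]


def run_screening(
    oracle: Oracle, config: ScreeningConfig = ScreeningConfig()
) -> ScreeningResult:
    """Closed-loop screening: stage 1, then refinement until a winner.

    Stopping rule: the run ends at the first refinement stage containing a
    specification-passing sample (stage-1 near-misses never end the run);
    otherwise after ``max_stages`` refinements, or immediately if no DAOI
    can be identified.  ``n_experiments`` counts oracle calls.
    """
    records: list[ScreeningRecord] = []
    daois: list[DAOI] = []

    def measure(req: SampleRequest) -> ScreeningRecord:
        obs = oracle(req.point)
        obs = replace(obs, sample_id=req.sample_id)
        rec = ScreeningRecord(req, obs, desirability(obs, config.specs))
        records.append(rec)
        return rec

    for req in initial_design(config):
        measure(req)

    stop_reason = "max_stages"
    winner: Optional[int] = None
    next_id = len(records) + 1
    for stage in range(1, config.max_stages + 1):
        try:
            daoi = identify_daoi(
                [(r.request, r.observation) for r in records],
                config.specs,
                config.top_k,
                config.center,
            )
        except NoDAOIError:
            stop_reason = "exhausted"
            break
        daois.append(daoi)
        try:
            requests = refine(daoi, config.figure_kind, config, next_id, stage)
        except SimplexError:
            stop_reason = "exhausted"
            break
        stage_records = [measure(req) for req in requests]
        next_id += len(requests)
        if any(
            evaluate_specs(r.observation, config.specs).overall
            for r in stage_records
        ):
            winner, _ = select_best(
                [r.observation for r in records], config.specs
            )
            stop_reason = "spec_met"
            break

    return ScreeningResult(
        records=tuple(records),
        daois=tuple(daois),
        winner=winner,
        n_experiments=len(records),
        stop_reason=stop_reason,
    )
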