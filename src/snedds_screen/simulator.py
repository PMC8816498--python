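"""Synthetic composition→response surfaces for closed-loop testing.

No laboratory data accompany the screening engine, so this module supplies
a ground-truth simulator: a smooth response surface over the ternary
simplex with a single best composition, Gaussian measurement noise and a
failure region where no emulsion forms (recorded as N/D).

Functional forms (package choices, made to reproduce the qualitative
pattern of real campaigns — small droplets go with high transmittance and
good visual grade, and a high-oil corner fails to emulsify):

* droplet size: ``base + curvature * d²`` with d the Cartesian distance to
  the optimum composition (a paraboloid bowl, minimum = ``base`` nm);
* PDI: ``clamp(pdi_base + pdi_slope * (size - base), 0.01, 1)``;
* transmittance: ``100 * logistic((midpoint - size) / steepness)``;
* grade: I if size < 50 and transmittance > 99; II if transmittance > 98;
  III if > 90; IV otherwise; V (no emulsion) inside the failure region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import CENTROID, PlanarPoint, TernaryPoint, from_cartesian, to_cartesian
from .specs import EmulsionObservation, grade_to_roman

__all__ = [
    "ResponseSurfaceModel",
    "Scenario",
    "make_surface",
    "observe",
    "observe_triplicate",
    "scenario_preset",
    "generate_dataset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class ResponseSurfaceModel:
    """Deterministic ground-truth surface; noise is added by :func:`observe`."""

    optimum: TernaryPoint
    size_base: float = 20.0          # nm at the optimum
    size_curvature: float = 3000.0   # nm per squared Cartesian distance
    pdi_base: float = 0.08
    pdi_slope: float = 0.002         # PDI per nm above base size
    trans_midpoint: float = 100.0    # nm where transmittance crosses 50%
    trans_steepness: float = 11.0    # nm scale of the logistic
    #: composition fails to emulsify when component-1 fraction exceeds this.
    failure_max_component1: Optional[float] = None
    noise_sd: tuple[float, float, float] = (0.5, 0.01, 0.2)  # size, PDI, trans

    def forms_emulsion(self, point: TernaryPoint) -> bool:
        cut = self.failure_max_component1
        return cut is None or point.a <= cut

    def size(self, point: TernaryPoint) -> float:
        d = to_cartesian(point).as_array() - to_cartesian(self.optimum).as_array()
        return self.size_base + self.size_curvature * float(d @ d)

    def pdi(self, point: TernaryPoint) -> float:
        raw = self.pdi_base + self.pdi_slope * (self.size(point) - self.size_base)
        return float(np.clip(raw, 0.01, 1.0))

    def transmittance(self, point: TernaryPoint) -> float:
        return 100.0 * float(
            expit((self.trans_midpoint - self.size(point)) / self.trans_steepness)
        )

    def grade(self, point: TernaryPoint) -> int:
        if not self.forms_emulsion(point):
            return 5
        return self._grade_from(self.size(point), self.transmittance(point))

    @staticmethod
    def _grade_from(size: float, trans: float) -> int:
        if size < 50.0 and trans > 99.0:
            return 1
        if trans > 98.0:
            return 2
        if trans > 90.0:
            return 3
        return 4


def make_surface(
    optimum: TernaryPoint,
    size_base: float = 20.0,
    size_curvature: float = 3000.0,
    **kwargs,
) -> ResponseSurfaceModel:
    if size_base <= 0:
        raise ValueError(f"base droplet size must be positive, got {size_base}")
    if size_curvature < 0:
        raise ValueError("size curvature must be nonnegative")
    return ResponseSurfaceModel(
        optimum=optimum, size_base=size_base, size_curvature=size_curvature, **kwargs
    )


def _point_rng(seed: int, point: TernaryPoint, rep: int = 0) -> np.random.Generator:
    # Per-point stream derived from (seed, composition): design-order
    # changes never shift the noise.  Coordinates are keyed at 1e-12
    # resolution; Python's builtin hash is avoided (not stable across runs).
    key = (
        int(seed),
        int(round(point.a * 1e12)),
        int(round(point.b * 1e12)),
        int(rep),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def observe(
    surface: ResponseSurfaceModel,
    point: TernaryPoint,
    seed: int,
    sample_id: int = 0,
) -> EmulsionObservation:
    """One noisy measurement of the surface at ``point``; repeatable."""
    if not surface.forms_emulsion(point):
        return EmulsionObservation(sample_id=sample_id, formed_emulsion=False, grade=5)
    rng = _point_rng(seed, point)
    s_sd, p_sd, t_sd = surface.noise_sd
    size = max(1.0, surface.size(point) + s_sd * rng.standard_normal())
    pdi = float(np.clip(surface.pdi(point) + p_sd * rng.standard_normal(), 0.01, 1.0))
    trans = float(
        min(100.0, surface.transmittance(point) + t_sd * rng.standard_normal())
    )
    return EmulsionObservation(
        sample_id=sample_id,
        size_nm=size,
        pdi=pdi,
        transmittance_pct=trans,
        grade=surface._grade_from(size, trans),
        formed_emulsion=True,
    )


def observe_triplicate(
    surface: ResponseSurfaceModel,
    point: TernaryPoint,
    seed: int,
    sample_id: int = 0,
    n: int = 3,
) -> EmulsionObservation:
    """Mean ± SD of ``n`` independent measurements at one composition."""
    if not surface.forms_emulsion(point):
        return EmulsionObservation(sample_id=sample_id, formed_emulsion=False, grade=5)
    rng = _point_rng(seed, point)
    s_sd, p_sd, t_sd = surface.noise_sd
    sizes = np.maximum(1.0, surface.size(point) + s_sd * rng.standard_normal(n))
    pdis = np.clip(surface.pdi(point) + p_sd * rng.standard_normal(n), 0.01, 1.0)
    trans = np.minimum(
        100.0, surface.transmittance(point) + t_sd * rng.standard_normal(n)
    )
    return EmulsionObservation(
        sample_id=sample_id,
        size_nm=float(sizes.mean()),
        pdi=float(pdis.mean()),
        transmittance_pct=float(trans.mean()),
        grade=surface._grade_from(float(sizes.mean()), float(trans.mean())),
        formed_emulsion=True,
        size_sd=float(sizes.std(ddof=1)),
        pdi_sd=float(pdis.std(ddof=1)),
        transmittance_sd=float(trans.std(ddof=1)),
    )


@dataclass(frozen=True)
class Scenario:
    """A named simulator setup plus the refinement figure it pairs with."""

    name: str
    surface: ResponseSurfaceModel
    figure_kind: str = "parallelogram"
    extras: tuple[int, int] = (0, 0)


def _offset_point(distance1: float, angle1: float, distance2: float = 0.0,
                  angle2: float = 0.0) -> TernaryPoint:
    """Centroid displaced by polar offsets in the Cartesian embedding."""
    c = to_cartesian(CENTROID).as_array()
    c = c + distance1 * np.array([math.cos(angle1), math.sin(angle1)])
    c = c + distance2 * np.array([math.cos(angle2), math.sin(angle2)])
    return from_cartesian(PlanarPoint(*c))


PRESET_NAMES = ("celecoxib_like", "fenofibrate_like", "infeasible")


def scenario_preset(name: str) -> Scenario:
    """Fully specified, versioned-in-code simulation scenarios.

    ``celecoxib_like``: the optimum sits between the center point and one
    hexagon vertex, so stage 1 near-misses the targets and a single
    parallelogram refinement (4 points) contains a passing mixture —
    11 experiments in total.  ``fenofibrate_like``: same idea with the
    optimum toward a different vertex pair and a trapezoid refinement
    carrying 3 extra points on the parallel sides — 14 experiments.
    ``infeasible``: the droplet-size floor sits above the 50 nm target, so
    no composition can pass.
    """
    deg = math.pi / 180.0
    if name == "celecoxib_like":
        surface = make_surface(
            optimum=_offset_point(0.075, 240 * deg, 0.03, 150 * deg),
            size_base=24.0,
            size_curvature=4800.0,
            failure_max_component1=0.70,
        )
        return Scenario(name, surface, figure_kind="parallelogram")
    if name == "fenofibrate_like":
        surface = make_surface(
            optimum=_offset_point(0.075, 0 * deg, 0.03, 90 * deg),
            size_base=18.0,
            size_curvature=4800.0,
            failure_max_component1=0.70,
        )
        return Scenario(name, surface, figure_kind="trapezoid", extras=(2, 1))
    if name == "infeasible":
        # size floor above the 50 nm target: transmittance then tops out
        # below 99% too, so no composition can ever pass, yet the gentle
        # bowl keeps desirabilities nonzero and the loop refining.
        surface = make_surface(
            optimum=CENTROID, size_base=60.0, size_curvature=800.0
        )
        return Scenario(name, surface, figure_kind="parallelogram")
    raise ValueError(f"unknown scenario {name!r}; expected one of {PRESET_NAMES}")


def generate_dataset(
    scenario: Scenario,
    design_points: Sequence[TernaryPoint],
    seed: int,
    sample_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Triplicate response table for a list of design points.

    Returns the standard response-table schema (one row per sample, mean
    and SD per metric, Roman-numeral grade, ``NA`` for N/D rows).
    """
    if sample_ids is None:
        sample_ids = range(1, len(design_points) + 1)
    rows = []
    for sid, point in zip(sample_ids, design_points):
        obs = observe_triplicate(scenario.surface, point, seed, sample_id=sid)
        rows.append(
            {
                "sample_id": sid,
                "size_nm": obs.size_nm,
                "size_sd": obs.size_sd,
                "pdi": obs.pdi,
                "pdi_sd": obs.pdi_sd,
                "transmittance_pct": obs.transmittance_pct,
                "transmittance_sd": obs.transmittance_sd,
                "grade": grade_to_roman(obs.grade),
                "formed": obs.formed_emulsion,
            }
        )
    return pd.DataFrame(rows)
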