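"""CSV serialization for requests, responses, solubility and miscibility.

On-disk conventions: compositions in percent with two decimals (full
precision in memory), emulsification grades as Roman numerals I–V, ``NA``
for metrics of mixtures that never emulsified.  All writes use stable row
ordering and fixed float formatting so reruns are byte-identical.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import pandas as pd

from .design import SampleRequest
from .formulation import SolubilityRecord
from .geometry import TernaryPoint, validate_point
from .mixture_model import ContourGrid
from .specs import EmulsionObservation, grade_to_roman, roman_to_grade

__all__ = [
    "write_requests",
    "read_requests",
    "write_responses",
    "read_responses",
    "read_solubility",
    "read_miscibility",
    "write_contour",
]

RESPONSE_COLUMNS = [
    "sample_id",
    "size_nm",
    "size_sd",
    "pdi",
    "pdi_sd",
    "transmittance_pct",
    "transmittance_sd",
    "grade",
    "formed",
]


def write_requests(requests: Sequence[SampleRequest], path) -> None:
    """Sample requests as a percent-scale point list keyed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in requests],
            "component_1": [f"{100 * r.point.a:.2f}" for r in requests],
            "component_2": [f"{100 * r.point.b:.2f}" for r in requests],
            "component_3": [f"{100 * r.point.c:.2f}" for r in requests],
            "label": [r.stage for r in requests],
        }
    )
    df.to_csv(path, index=False)


def read_requests(path) -> list[SampleRequest]:
    df = pd.read_csv(path)
    requests = []
    for _, row in df.iterrows():
        point = validate_point(
            (row["component_1"], row["component_2"], row["component_3"]),
            scale="percent",
        )
        requests.append(
            SampleRequest(int(row["sample_id"]), point, str(row["label"]))
        )
    return requests


def _fmt(value: Optional[float], digits: int) -> str:
    return "NA" if value is None else f"{value:.{digits}f}"


def write_responses(observations: Sequence[EmulsionObservation], path) -> None:
    rows = []
    for o in observations:
        rows.append(
            {
                "sample_id": o.sample_id,
                "size_nm": _fmt(o.size_nm, 1),
                "size_sd": _fmt(o.size_sd, 1),
                "pdi": _fmt(o.pdi, 2),
                "pdi_sd": _fmt(o.pdi_sd, 2),
                "transmittance_pct": _fmt(o.transmittance_pct, 1),
                "transmittance_sd": _fmt(o.transmittance_sd, 1),
                "grade": grade_to_roman(o.grade),
                "formed": "true" if o.formed_emulsion else "false",
            }
        )
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def _parse_float(value, field: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text.upper() in ("NA", "N/D", ""):
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"row {row}: cannot parse {field}={value!r}") from None


def read_responses(path) -> list[EmulsionObservation]:
    """Read a response table; malformed rows are reported by number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns {missing}")
    observations = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        size = _parse_float(row.size_nm, "size_nm", i)
        trans = _parse_float(row.transmittance_pct, "transmittance_pct", i)
        if size is not None and size < 0:
            raise ValueError(f"row {i}: negative droplet size {size}")
        if trans is not None and trans > 100:
            raise ValueError(f"row {i}: transmittance {trans} exceeds 100%")
        try:
            grade = roman_to_grade(row.grade)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        formed = str(row.formed).strip().lower() in ("true", "yes", "1")
        observations.append(
            EmulsionObservation(
                sample_id=int(row.sample_id),
                size_nm=size,
                pdi=_parse_float(row.pdi, "pdi", i),
                transmittance_pct=trans,
                grade=grade,
                formed_emulsion=formed,
                size_sd=_parse_float(row.size_sd, "size_sd", i),
                pdi_sd=_parse_float(row.pdi_sd, "pdi_sd", i),
                transmittance_sd=_parse_float(
                    row.transmittance_sd, "transmittance_sd", i
                ),
            )
        )
    return observations


def read_solubility(path) -> list[SolubilityRecord]:
    """Schema: drug,excipient,role,cs_mg_per_g."""
    df = pd.read_csv(path)
    return [
        SolubilityRecord(
            drug=row["drug"],
            excipient=row["excipient"],
            c_s=float(row["cs_mg_per_g"]),
            role=row.get("role"),
        )
        for _, row in df.iterrows()
    ]


def read_miscibility(path) -> pd.DataFrame:
    """Square labeled 0/1 matrix, first column = excipient names."""
    return pd.read_csv(path, index_col=0).astype(bool)


def write_contour(grid: ContourGrid, path) -> None:
    df = pd.DataFrame(
        {
            "component_1": [f"{100 * a:.2f}" for a in grid.points[:, 0]],
            "component_2": [f"{100 * b:.2f}" for b in grid.points[:, 1]],
            "component_3": [f"{100 * c:.2f}" for c in grid.points[:, 2]],
            "value": [f"{v:.4f}" for v in grid.values],
            "bin": grid.bins,
        }
    )
    df.to_csv(path, index=False)
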