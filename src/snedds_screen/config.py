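"""Campaign configuration: YAML loading with validation and defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import yaml

from .design import ScreeningConfig
from .formulation import Axis, BlendComponent
from .geometry import CENTROID, TernaryPoint
from .mixture_model import WorstCasePolicy
from .specs import SpecificationSet

__all__ = ["CampaignConfig", "load_config"]

_KNOWN_KEYS = {
    "drug",
    "axes",
    "f_factor",
    "hex_radius",
    "hex_rotation",
    "figure_kind",
    "extras",
    "edge_length",
    "top_k",
    "max_stages",
    "shrink_to_fit",
    "max_size",
    "max_pdi",
    "min_transmittance",
    "alpha",
    "imputation",
    "outlier_threshold",
    "seed",
}
_IMPUTATION_KEYS = {"size_nm", "pdi", "transmittance_pct", "grade"}


@dataclass(frozen=True)
class CampaignConfig:
    """Everything a screening campaign needs, with sensible defaults."""

    drug: str = "drug"
    axes: tuple[Axis, Axis, Axis] = ("component_1", "component_2", "component_3")
    f_factor: float = 0.5
    hex_radius: float = 0.15
    hex_rotation: float = 0.0
    figure_kind: str = "parallelogram"
    extras: tuple[int, int] = (2, 1)
    edge_length: Optional[float] = None
    top_k: int = 3
    max_stages: int = 3
    shrink_to_fit: bool = True
    specs: SpecificationSet = field(default_factory=SpecificationSet)
    alpha: float = 0.95
    imputation: WorstCasePolicy = field(default_factory=WorstCasePolicy)
    outlier_threshold: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.axes) != 3:
            raise ValueError("exactly three design axes are required")
        if self.f_factor <= 0:
            raise ValueError("drug-specific factor f must be positive")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier threshold must be positive")

    @property
    def axis_names(self) -> tuple[str, str, str]:
        return tuple(
            "+".join(a.constituents) if isinstance(a, BlendComponent) else a
            for a in self.axes
        )

    def screening(self) -> ScreeningConfig:
        return ScreeningConfig(
            center=CENTROID,
            hex_radius=self.hex_radius,
            hex_rotation=self.hex_rotation,
            figure_kind=self.figure_kind,
            extras=self.extras,
            edge_length=self.edge_length,
            top_k=self.top_k,
            max_stages=self.max_stages,
            shrink_to_fit=self.shrink_to_fit,
            specs=self.specs,
        )


def _parse_axis(raw) -> Axis:
    if isinstance(raw, str):
        return raw
    if isinstance(raw, dict) and set(raw) == {"blend"}:
        blend = raw["blend"]
        if not isinstance(blend, dict) or len(blend) < 2:
            raise ValueError(f"blend axis needs >=2 constituents, got {blend!r}")
        names = tuple(blend.keys())
        return BlendComponent(names, tuple(float(blend[n]) for n in names))
    raise ValueError(f"cannot parse axis definition {raw!r}")


def load_config(path) -> CampaignConfig:
    """Load and validate a YAML campaign config; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for key in (
        "drug",
        "f_factor",
        "hex_radius",
        "hex_rotation",
        "figure_kind",
        "edge_length",
        "top_k",
        "max_stages",
        "shrink_to_fit",
        "alpha",
        "outlier_threshold",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "axes" in raw:
        axes = raw["axes"]
        if not isinstance(axes, list) or len(axes) != 3:
            raise ValueError("config key 'axes' must list exactly 3 entries")
        kwargs["axes"] = tuple(_parse_axis(a) for a in axes)
    if "extras" in raw:
        kwargs["extras"] = tuple(int(v) for v in raw["extras"])

    spec_kwargs = {
        k: raw[k] for k in ("max_size", "max_pdi", "min_transmittance") if k in raw
    }
    if spec_kwargs:
        kwargs["specs"] = SpecificationSet(**spec_kwargs)
    if "imputation" in raw:
        imp = raw["imputation"]
        bad = set(imp) - _IMPUTATION_KEYS
        if bad:
            raise ValueError(f"unknown imputation keys: {sorted(bad)}")
        kwargs["imputation"] = WorstCasePolicy(**imp)
    try:
        return CampaignConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid campaign config: {exc}") from exc
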