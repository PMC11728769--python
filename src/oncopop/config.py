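"""Structured configuration documents (YAML).

A config document bundles a population specification, the network
coefficients and the residual models into one human-readable file; the
shipped default reproduces the published network verbatim.  Loading
validates every nested invariant (probability sums, network acyclicity,
bounds) and rejects unknown keys by name; load/save round trips are
lossless.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError
from .network import (
    CoefficientSet,
    EquationSpec,
    ResidualSpec,
    ResidualStage,
    default_coefficient_set,
    default_residual_spec,
)
from .primaries import PopulationSpec


class NetworkSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    htc_log_scale: bool = False
    equations: tuple[EquationSpec, ...]


class ConfigDocument(BaseModel):
    """Top-level configuration: population + network + residuals."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    population: PopulationSpec
    network: NetworkSection
    residuals: dict[str, ResidualStage]

    def coefficient_set(self) -> CoefficientSet:
        return CoefficientSet(equations=self.network.equations)

    def residual_spec(self) -> ResidualSpec:
        return ResidualSpec(stages=dict(self.residuals))

    def content_hash(self) -> str:
        """Short SHA-256 over the canonical serialized form (provenance)."""
        text = yaml.safe_dump(_plain(self.model_dump(mode="python")), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively strip tuples (YAML-unfriendly) to lists."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> ConfigDocument:
    """Load and validate a YAML config document."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: not a mapping document")
    try:
        return ConfigDocument.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(map(str, err['loc']))}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigurationError(
            f"{path}: invalid configuration:\n  " + "\n  ".join(lines)
        ) from exc


def save_config(doc: ConfigDocument, path: str | Path) -> None:
    """Serialize a config document to YAML (round-trips losslessly)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(doc.model_dump(mode="python")), fh, sort_keys=False)


def build_config(
    population: PopulationSpec,
    coefficients: CoefficientSet | None = None,
    residuals: ResidualSpec | None = None,
    htc_log_scale: bool = False,
) -> ConfigDocument:
    coefs = coefficients if coefficients is not None else default_coefficient_set(htc_log_scale)
    res = residuals if residuals is not None else default_residual_spec()
    return ConfigDocument(
        population=population,
        network=NetworkSection(htc_log_scale=htc_log_scale, equations=coefs.equations),
        residuals=dict(res.stages),
    )


def default_config() -> ConfigDocument:
    """The shipped default document (reference population, published network)."""
    with resources.files("oncopop").joinpath("data/default_config.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        raw = yaml.safe_load(fh)
    return ConfigDocument.model_validate(raw)
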