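"""Run configuration: JSON serialization, validation and versioning.

A :class:`RunConfig` captures everything needed to reproduce a run —
assessment settings, the ordered stage rules, PCR cycles and the seed —
and round-trips losslessly through JSON.  The JSON layout is versioned via
a top-level ``format_version``: unknown future versions are rejected,
unknown extra keys produce a warning and are ignored.  A machine-readable
JSON Schema of the format ships as package data (``dnasim/schema``).
"""

from __future__ import annotations

import json
import warnings
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .assessment import AssessmentSettings
from .rules import ErrorRule
from .storage import AwgnStorage, DepurinationStorage, ErasureStorage, KimuraStorage

FORMAT_VERSION = "1.0"
SUPPORTED_FORMAT_VERSIONS = frozenset({"1.0"})

STAGE_NAMES = ("synthesis", "pcr", "storage", "sequencing")

StorageModel = Annotated[
    Union[KimuraStorage, DepurinationStorage, ErasureStorage, AwgnStorage],
    Field(discriminator="model"),
]


class ConfigError(ValueError):
    """Configuration text failed validation; message lists every failing path."""


class StageConfig(BaseModel):
    """One pipeline stage: a named process with either a rule or a storage model.

    Synthesis, PCR and sequencing stages carry an :class:`ErrorRule`; the
    storage stage carries either a rule (e.g. a host-organism preset) or
    exactly one channel/decay model.
    """

    model_config = ConfigDict(extra="ignore")

    stage: Literal["synthesis", "pcr", "storage", "sequencing"]
    rule: Optional[ErrorRule] = None
    model: Optional[StorageModel] = None

    @model_validator(mode="after")
    def _check_exclusive(self):
        if self.stage == "storage":
            if (self.rule is None) == (self.model is None):
                raise ValueError(
                    "storage stage needs exactly one of 'rule' or 'model'"
                )
        else:
            if self.rule is None:
                raise ValueError(f"{self.stage} stage requires a 'rule'")
            if self.model is not None:
                raise ValueError(f"{self.stage} stage cannot carry a storage 'model'")
        return self


class RunConfig(BaseModel):
    """Complete, reproducible run description."""

    model_config = ConfigDict(extra="ignore")

    format_version: str = FORMAT_VERSION
    seed: int = Field(ge=0)
    pcr_cycles: int = Field(default=30, gt=0)
    storage_generations: int = Field(default=1, gt=0)
    assessment: AssessmentSettings = AssessmentSettings()
    stages: list[StageConfig] = []

    @field_validator("stages")
    @classmethod
    def _unique_stages(cls, stages):
        names = [s.stage for s in stages]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate stage names in {names}")
        return stages


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def serialize_config(config: RunConfig) -> str:
    return config.model_dump_json(indent=2)


def deserialize_config(text: str) -> RunConfig:
    """Parse and validate configuration JSON.

    Round-trip contract: ``deserialize_config(serialize_config(c)) == c``.
    Raises :class:`ConfigError` listing every failing path; warns about
    (and ignores) unknown top-level keys.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("configuration JSON must be an object")
    version = raw.get("format_version", FORMAT_VERSION)
    if version not in SUPPORTED_FORMAT_VERSIONS:
        raise ConfigError(
            f"unsupported format_version {version!r}; supported: "
            f"{sorted(SUPPORTED_FORMAT_VERSIONS)}"
        )
    unknown = set(raw) - set(RunConfig.model_fields)
    if unknown:
        warnings.warn(
            f"ignoring unknown configuration keys: {sorted(unknown)}",
            stacklevel=2,
        )
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {paths}") from exc


def config_json_schema() -> dict:
    """JSON Schema of the configuration format (also shipped as package data)."""
    return RunConfig.model_json_schema()
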