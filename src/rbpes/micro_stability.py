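"""Transcoding matrix: from QAS status and validations to a microbiological cap.

The maximum microbiological shelf-life a unit may assign to its preparations
(and opened vial leftovers) is read from a *transcoding matrix* keyed on:

* the environment classification (working-zone grade of the hood and the
  grade of the background cleanroom it sits in, per GMP Annex 1 / EN ISO
  14644-1 — e.g. a Grade A laminar-flow hood inside a Grade C room),
* the medical-device class in use (closed systems with or without gas
  exchange, or open systems), and
* the current validation state: latest media-fill outcome, environmental
  monitoring within limits, particle counts, and full QAS self-assessment
  adherence.

The default matrix exposes the two documented extremes: the fully validated
configuration (Grade A in Grade C, closed systems without gas exchange, all
validations passing, fully adherent QAS) earns 168 h (7 days); any failed
validation, non-adherent QAS or open-system device falls back to 0 h beyond
the SPC (i.e. SPC-only shelf-life). Sites holding evidence for intermediate
cells (24 h, 48 h, ...) add them in the YAML matrix config.
"""

from __future__ import annotations

import enum
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class Grade(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


_GRADE_ORDER = {Grade.A: 0, Grade.B: 1, Grade.C: 2, Grade.D: 3}


class EnvironmentConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    working_zone_grade: Grade
    background_grade: Grade
    iso_class: str = ""

    @model_validator(mode="after")
    def _cleaner_inside(self) -> "EnvironmentConfig":
        if _GRADE_ORDER[self.working_zone_grade] >= _GRADE_ORDER[self.background_grade]:
            raise ValueError(
                f"working zone ({self.working_zone_grade.value}) must be strictly cleaner "
                f"than the background ({self.background_grade.value})"
            )
        return self


class DeviceClass(BaseModel):
    model_config = ConfigDict(frozen=True)

    closed_system: bool
    gas_exchange: bool


class ValidationState(BaseModel):
    model_config = ConfigDict(frozen=True)

    media_fill_current_pass: bool
    env_monitoring_within_limits: bool
    particle_counts_pass: bool
    qas_fully_adherent: bool

    def all_pass(self) -> bool:
        return (
            self.media_fill_current_pass
            and self.env_monitoring_within_limits
            and self.particle_counts_pass
            and self.qas_fully_adherent
        )


class MatrixGapError(Exception):
    """The (environment, device, validation) tuple has no configured cell."""


#: Matrix cells keyed "<working>/<background>/<device>/<validations>" ->
#: max shelf-life in hours beyond SPC. Device keys: closed_no_gas | other.
#: Validation keys: all_pass | not_all_pass.
DEFAULT_MATRIX: dict[str, float] = {
    "A/C/closed_no_gas/all_pass": 168.0,
    "A/C/closed_no_gas/not_all_pass": 0.0,
    "A/C/other/all_pass": 0.0,
    "A/C/other/not_all_pass": 0.0,
}


def canonical_key(env: EnvironmentConfig, dev: DeviceClass, val: ValidationState) -> str:
    device = "closed_no_gas" if dev.closed_system and not dev.gas_exchange else "other"
    validations = "all_pass" if val.all_pass() else "not_all_pass"
    return f"{env.working_zone_grade.value}/{env.background_grade.value}/{device}/{validations}"


def predict_micro_stability(
    env: EnvironmentConfig,
    dev: DeviceClass,
    val: ValidationState,
    matrix: dict[str, float] | None = None,
) -> float:
    """Maximum microbiological shelf-life in hours for the site configuration.

    Raises :class:`MatrixGapError` naming the canonical tuple when the matrix
    has no cell for it, so configuration gaps can never pass silently.
    """
    if matrix is None:
        matrix = DEFAULT_MATRIX
    key = canonical_key(env, dev, val)
    try:
        return float(matrix[key])
    except KeyError:
        raise MatrixGapError(f"transcoding matrix has no cell for {key!r}") from None


def load_matrix(path: str | Path) -> dict[str, float]:
    """Load a transcoding matrix from a YAML mapping of cell key -> hours."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    matrix = {str(k): float(v) for k, v in raw.items()}
    for key, hours in matrix.items():
        if hours < 0:
            raise ValueError(f"matrix cell {key!r} has a negative duration")
    return matrix
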