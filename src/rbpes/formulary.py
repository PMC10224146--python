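"""Domain model and file I/O for the compounding-unit formulary.

A formulary bundles four record collections used across the engine:

* active ingredients (a.i.) with their handling attributes,
* formulations (brand products, reconstitution and dilution rules),
* preparation requests (one prescribed bag/syringe each), and
* stability-evidence records curated from SPCs and the literature.

Collections are stored as UTF-8 CSV files with a header row
(``active_ingredients.csv``, ``formulations.csv``, ``stability_evidence.csv``)
plus a JSON file for preparation batches — diff-friendly formats a pharmacist
can hand-edit. Durations are hours internally; mass is mg, volume mL.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class FormularyError(Exception):
    """Raised on schema violations, dangling references or duplicate ids."""


class AICategory(str, enum.Enum):
    """Drug classes handled by the unit; ``antiblastic`` covers cytotoxic
    chemotherapy and is accepted under the alias ``chemotherapeutic``."""

    antiblastic = "antiblastic"
    antiretroviral = "antiretroviral"
    antidote = "antidote"
    pain_reliever = "pain_reliever"


#: Synonyms accepted when parsing category columns / config keys.
CATEGORY_ALIASES = {
    "chemotherapeutic": AICategory.antiblastic,
    "cytotoxic": AICategory.antiblastic,
}


def parse_category(value: str | AICategory) -> AICategory:
    if isinstance(value, AICategory):
        return value
    value = str(value).strip()
    if value in CATEGORY_ALIASES:
        return CATEGORY_ALIASES[value]
    return AICategory(value)


class Route(str, enum.Enum):
    IV = "IV"
    IP = "IP"
    PED = "PED"  # pediatric-flagged parenteral use


class Solvent(str, enum.Enum):
    none = "none"
    water = "water"
    NaCl_09 = "NaCl_0.9"
    glucose_5 = "glucose_5"
    other = "other"


class Diluent(str, enum.Enum):
    NaCl_09 = "NaCl_0.9"
    glucose_5 = "glucose_5"


class EvidenceSource(str, enum.Enum):
    SPC = "SPC"
    literature = "literature"


class EvidenceState(str, enum.Enum):
    opened_vial = "opened_vial"
    reconstituted = "reconstituted"
    diluted = "diluted"


class TemperatureBand(str, enum.Enum):
    room_20_25C = "room_20_25C"
    cold_2_8C = "cold_2_8C"


class EvidenceLevel(str, enum.Enum):
    A_plus = "A+"
    A = "A"
    B = "B"
    C = "C"
    unrated = "unrated"


class ConsensusCompliance(str, enum.Enum):
    high = "high"
    medium = "medium"
    low = "low"
    unknown = "unknown"


class ActiveIngredient(BaseModel):
    model_config = ConfigDict(frozen=True)

    ai_id: str
    name: str
    category: AICategory
    pharmacopoeia_listed: bool
    photosensitive: bool
    filter_required: bool  # 0.2-0.22 um in-line filter


class Formulation(BaseModel):
    model_config = ConfigDict(frozen=True)

    ai_id: str
    brand_name: str
    reconstitution_solvent: Solvent = Solvent.none
    reconstitution_volume_mL: float = Field(0.0, ge=0)
    stock_concentration_mg_mL: Optional[float] = Field(None, gt=0)
    allowed_diluents: tuple[Diluent, ...] = ()
    container_types: tuple[str, ...] = ()
    infusion_time_range: str = ""

    @model_validator(mode="after")
    def _check(self) -> "Formulation":
        # A ready-to-dilute or reconstituted product must carry a usable
        # stock concentration; powders awaiting reconstitution may omit it.
        if self.reconstitution_solvent is not Solvent.none and self.stock_concentration_mg_mL is None:
            raise ValueError(f"{self.brand_name}: reconstituted product needs stock_concentration_mg_mL")
        return self


class PreparationSpec(BaseModel):
    """One prescribed preparation: either BSA-based or fixed dosing."""

    model_config = ConfigDict(frozen=True)

    ai_id: str
    dose_per_bsa_mg_m2: Optional[float] = Field(None, ge=0)
    fixed_dose_mg: Optional[float] = Field(None, ge=0)
    bsa_m2: Optional[float] = Field(None, ge=0)
    diluent: Diluent = Diluent.NaCl_09
    bag_nominal_volume_mL: float = Field(..., gt=0)
    route: Route = Route.IV
    is_solution: bool = True
    sterile_required: bool = True
    software_assisted_calculation: bool = False

    @model_validator(mode="after")
    def _exactly_one_dose_rule(self) -> "PreparationSpec":
        bsa_rule = self.dose_per_bsa_mg_m2 is not None and self.bsa_m2 is not None
        fixed_rule = self.fixed_dose_mg is not None
        if bsa_rule == fixed_rule:
            raise ValueError(
                "exactly one of (dose_per_bsa_mg_m2 with bsa_m2) or fixed_dose_mg must be set"
            )
        return self


class StabilityEvidence(BaseModel):
    """One stability claim for an a.i. under stated conditions.

    ``cold_instability`` is an explicit documented trigger recording that the
    cited study proved low stability at 2-8 degC; it is never inferred.
    """

    model_config = ConfigDict(frozen=True)

    ai_id: str
    source: EvidenceSource
    state: EvidenceState
    temperature_band: TemperatureBand
    duration_h: float = Field(..., gt=0)
    concentration_min_mg_mL: Optional[float] = Field(None, ge=0)
    concentration_max_mg_mL: Optional[float] = Field(None, ge=0)
    diluent: Optional[Diluent] = None
    container: Optional[str] = None
    evidence_level: EvidenceLevel = EvidenceLevel.unrated
    consensus_compliance: ConsensusCompliance = ConsensusCompliance.unknown
    cold_instability: bool = False
    citation: str = ""

    @model_validator(mode="after")
    def _range_order(self) -> "StabilityEvidence":
        lo, hi = self.concentration_min_mg_mL, self.concentration_max_mg_mL
        if (lo is None) != (hi is None):
            raise ValueError("concentration range requires both bounds")
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"concentration range inverted: {lo} > {hi}")
        return self

    def concentration_contains(self, c_mg_mL: float) -> bool:
        """Interval membership; an absent range matches any concentration."""
        if self.concentration_min_mg_mL is None:
            return True
        return self.concentration_min_mg_mL <= c_mg_mL <= self.concentration_max_mg_mL


@dataclass
class Formulary:
    active_ingredients: dict[str, ActiveIngredient] = field(default_factory=dict)
    formulations: list[Formulation] = field(default_factory=list)
    preparations: list[PreparationSpec] = field(default_factory=list)
    evidence: list[StabilityEvidence] = field(default_factory=list)

    def evidence_for(self, ai_id: str) -> list[StabilityEvidence]:
        return [e for e in self.evidence if e.ai_id == ai_id]


AI_FILE = "active_ingredients.csv"
FORMULATION_FILE = "formulations.csv"
EVIDENCE_FILE = "stability_evidence.csv"
PREPARATION_FILE = "preparations.json"

_SET_SEP = ";"


def _split_set(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return ()
    return tuple(s.strip() for s in str(raw).split(_SET_SEP) if s.strip())


def _opt_float(raw: object) -> Optional[float]:
    if raw is None or str(raw).strip() == "" or (isinstance(raw, float) and pd.isna(raw)):
        return None
    return float(raw)


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.is_file():
        raise FormularyError(f"missing formulary file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _row_error(path: Path, idx: int, exc: Exception) -> FormularyError:
    # +2: header line plus 1-based counting.
    return FormularyError(f"{path.name}, row {idx + 2}: {exc}")


def load_formulary(path: str | Path) -> Formulary:
    """Load and cross-validate all formulary collections from a directory.

    Raises :class:`FormularyError` with the offending file and row number on
    schema violations, duplicate ``ai_id`` values or dangling references.
    """
    root = Path(path)
    form = Formulary()

    ai_path = root / AI_FILE
    for idx, row in _read_csv(ai_path).iterrows():
        try:
            ai = ActiveIngredient(
                ai_id=row["ai_id"],
                name=row["name"],
                category=parse_category(row["category"]),
                pharmacopoeia_listed=_parse_bool(row["pharmacopoeia_listed"]),
                photosensitive=_parse_bool(row["photosensitive"]),
                filter_required=_parse_bool(row["filter_required"]),
            )
        except (KeyError, ValueError) as exc:
            raise _row_error(ai_path, idx, exc) from exc
        if ai.ai_id in form.active_ingredients:
            raise _row_error(ai_path, idx, ValueError(f"duplicate ai_id {ai.ai_id!r}"))
        form.active_ingredients[ai.ai_id] = ai

    f_path = root / FORMULATION_FILE
    for idx, row in _read_csv(f_path).iterrows():
        try:
            rec = Formulation(
                ai_id=row["ai_id"],
                brand_name=row["brand_name"],
                reconstitution_solvent=Solvent(row.get("reconstitution_solvent", "none") or "none"),
                reconstitution_volume_mL=float(row.get("reconstitution_volume_mL", 0) or 0),
                stock_concentration_mg_mL=_opt_float(row.get("stock_concentration_mg_mL")),
                allowed_diluents=tuple(Diluent(d) for d in _split_set(row.get("allowed_diluents"))),
                container_types=_split_set(row.get("container_types")),
                infusion_time_range=row.get("infusion_time_range", ""),
            )
        except (KeyError, ValueError) as exc:
            raise _row_error(f_path, idx, exc) from exc
        if rec.ai_id not in form.active_ingredients:
            raise _row_error(f_path, idx, ValueError(f"dangling reference to unknown ai_id {rec.ai_id!r}"))
        form.formulations.append(rec)

    e_path = root / EVIDENCE_FILE
    for idx, row in _read_csv(e_path).iterrows():
        try:
            ev = StabilityEvidence(
                ai_id=row["ai_id"],
                source=EvidenceSource(row["source"]),
                state=EvidenceState(row["state"]),
                temperature_band=TemperatureBand(row["temperature_band"]),
                duration_h=float(row["duration_h"]),
                concentration_min_mg_mL=_opt_float(row.get("concentration_min_mg_mL")),
                concentration_max_mg_mL=_opt_float(row.get("concentration_max_mg_mL")),
                diluent=Diluent(row["diluent"]) if row.get("diluent") else None,
                container=row.get("container") or None,
                evidence_level=EvidenceLevel(row.get("evidence_level") or "unrated"),
                consensus_compliance=ConsensusCompliance(row.get("consensus_compliance") or "unknown"),
                cold_instability=_parse_bool(row.get("cold_instability", "false")),
                citation=row.get("citation", ""),
            )
        except (KeyError, ValueError) as exc:
            raise _row_error(e_path, idx, exc) from exc
        if ev.ai_id not in form.active_ingredients:
            raise _row_error(e_path, idx, ValueError(f"dangling reference to unknown ai_id {ev.ai_id!r}"))
        form.evidence.append(ev)

    p_path = root / PREPARATION_FILE
    if p_path.is_file():
        batch = json.loads(p_path.read_text())
        for i, entry in enumerate(batch):
            try:
                spec = PreparationSpec(**entry)
            except ValueError as exc:
                raise FormularyError(f"{p_path.name}, entry {i}: {exc}") from exc
            if spec.ai_id not in form.active_ingredients:
                raise FormularyError(
                    f"{p_path.name}, entry {i}: dangling reference to unknown ai_id {spec.ai_id!r}"
                )
            form.preparations.append(spec)

    return form


def save_formulary(form: Formulary, path: str | Path) -> None:
    """Write all collections back to CSV/JSON; inverse of :func:`load_formulary`."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    ai_rows = [
        {
            "ai_id": a.ai_id,
            "name": a.name,
            "category": a.category.value,
            "pharmacopoeia_listed": a.pharmacopoeia_listed,
            "photosensitive": a.photosensitive,
            "filter_required": a.filter_required,
        }
        for a in form.active_ingredients.values()
    ]
    pd.DataFrame(
        ai_rows,
        columns=["ai_id", "name", "category", "pharmacopoeia_listed", "photosensitive", "filter_required"],
    ).to_csv(root / AI_FILE, index=False, lineterminator="\n")

    f_rows = [
        {
            "ai_id": f.ai_id,
            "brand_name": f.brand_name,
            "reconstitution_solvent": f.reconstitution_solvent.value,
            "reconstitution_volume_mL": f.reconstitution_volume_mL,
            "stock_concentration_mg_mL": "" if f.stock_concentration_mg_mL is None else f.stock_concentration_mg_mL,
            "allowed_diluents": _SET_SEP.join(d.value for d in f.allowed_diluents),
            "container_types": _SET_SEP.join(f.container_types),
            "infusion_time_range": f.infusion_time_range,
        }
        for f in form.formulations
    ]
    pd.DataFrame(
        f_rows,
        columns=[
            "ai_id", "brand_name", "reconstitution_solvent", "reconstitution_volume_mL",
            "stock_concentration_mg_mL", "allowed_diluents", "container_types", "infusion_time_range",
        ],
    ).to_csv(root / FORMULATION_FILE, index=False, lineterminator="\n")

    e_rows = [
        {
            "ai_id": e.ai_id,
            "source": e.source.value,
            "state": e.state.value,
            "temperature_band": e.temperature_band.value,
            "duration_h": e.duration_h,
            "concentration_min_mg_mL": "" if e.concentration_min_mg_mL is None else e.concentration_min_mg_mL,
            "concentration_max_mg_mL": "" if e.concentration_max_mg_mL is None else e.concentration_max_mg_mL,
            "diluent": e.diluent.value if e.diluent else "",
            "container": e.container or "",
            "evidence_level": e.evidence_level.value,
            "consensus_compliance": e.consensus_compliance.value,
            "cold_instability": e.cold_instability,
            "citation": e.citation,
        }
        for e in form.evidence
    ]
    pd.DataFrame(
        e_rows,
        columns=[
            "ai_id", "source", "state", "temperature_band", "duration_h",
            "concentration_min_mg_mL", "concentration_max_mg_mL", "diluent", "container",
            "evidence_level", "consensus_compliance", "cold_instability", "citation",
        ],
    ).to_csv(root / EVIDENCE_FILE, index=False, lineterminator="\n")

    batch = [json.loads(p.model_dump_json()) for p in form.preparations]
    (root / PREPARATION_FILE).write_text(json.dumps(batch, indent=1) + "\n")


def compute_dose(spec: PreparationSpec) -> float:
    """Prescribed dose in mg: ``dose_per_bsa * bsa`` or the fixed dose verbatim.

    With BSA dosing this is linear in body surface area, e.g. 80 mg/m2 on a
    1.6 m2 patient gives 128 mg.
    """
    if spec.fixed_dose_mg is not None:
        return spec.fixed_dose_mg
    return spec.dose_per_bsa_mg_m2 * spec.bsa_m2


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")
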