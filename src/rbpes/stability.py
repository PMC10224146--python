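"""Risk-based predictive extended stability (RBPES) assignment.

The final shelf-life assigned to a preparation (and to the opened vial
leftover) integrates two independent ceilings:

1. the **microbiological cap** the unit's validated QAS supports (from the
   transcoding matrix, at most 168 h / 7 days for a fully validated unit), and
2. the **physiochemical/biological evidence** curated from SPCs and the
   high-evidence literature (levels A+/A, medium-high compliance with the
   European consensus on practical stability studies).

Integration rules, per temperature band (room 20-25 degC, cold 2-8 degC):

* evidence is filtered to the preparation's diluent, state and final
  concentration range;
* concordant records (same conditions families) may extend the duration up to
  the cap; contradictory claims for identical conditions resolve to the most
  restrictive (minimum);
* the global 7-day threshold is never exceeded, except for a.i. explicitly
  listed in the policy's exceptions map with an evidence-backed override
  (blinatumomab/Blincyto is the named default entry, with no default value);
* documented low stability at refrigerator temperature triggers a fixed 24 h
  cold fallback;
* with no acceptable literature evidence the band falls back to
  min(SPC duration, microbiological cap).

"Increased volume" compounding (injecting the drug volume into the bag
without withdrawing diluent) is supported by a concentration check against
the evidence-validated range.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .formulary import (
    ConsensusCompliance,
    EvidenceLevel,
    EvidenceState,
    Formulary,
    PreparationSpec,
    StabilityEvidence,
    TemperatureBand,
)


class StabilityError(Exception):
    pass


class StabilityPolicy(BaseModel):
    model_config = ConfigDict(frozen=True)

    global_cap_h: float = Field(168.0, gt=0)
    #: a.i. allowed past the global cap; value None means "declared but the
    #: site has not yet supplied the evidence-backed duration".
    exceptions: dict[str, Optional[float]] = {"blinatumomab": None}
    cold_fallback_h: float = Field(24.0, gt=0)
    conflict_rule: str = "most_restrictive"
    accepted_evidence_levels: tuple[EvidenceLevel, ...] = (EvidenceLevel.A_plus, EvidenceLevel.A)
    accepted_consensus: tuple[ConsensusCompliance, ...] = (
        ConsensusCompliance.high,
        ConsensusCompliance.medium,
    )


DEFAULT_POLICY = StabilityPolicy()


def load_policy(path: str | Path) -> StabilityPolicy:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return StabilityPolicy(**raw)


class StabilityAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    ai_id: str
    state: EvidenceState
    room_temp_h: Optional[float] = None
    cold_2_8C_h: Optional[float] = None
    spc_reference_h: float
    provenance: tuple[str, ...] = ()
    notes: str = ""


class IncreasedVolumeResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_volume_mL: float
    final_concentration_mg_mL: float
    in_range: bool


def select_evidence(
    records: Iterable[StabilityEvidence],
    prep: PreparationSpec,
    final_concentration_mg_mL: float,
    state: EvidenceState = EvidenceState.diluted,
    policy: StabilityPolicy = DEFAULT_POLICY,
) -> list[StabilityEvidence]:
    """Filter evidence records applicable to one preparation.

    Keeps literature records with an accepted evidence level (default A+/A)
    and medium-high consensus compliance, matching the preparation's a.i.,
    state and diluent, whose concentration range (when stated) contains the
    final concentration. Conflicting survivors are all retained; resolution
    belongs to :func:`assign_rbpes`.
    """
    kept = []
    for rec in records:
        if rec.ai_id != prep.ai_id or rec.state is not state:
            continue
        if rec.evidence_level not in policy.accepted_evidence_levels:
            continue
        if rec.consensus_compliance not in policy.accepted_consensus:
            continue
        if rec.diluent is not None and rec.diluent is not prep.diluent:
            continue
        if not rec.concentration_contains(final_concentration_mg_mL):
            continue
        kept.append(rec)
    return kept


def _band_duration(records: Sequence[StabilityEvidence], cap_h: float) -> Optional[float]:
    """Combine a band's evidence: min within identical-condition groups
    (restrictive conflict resolution), max across condition groups, then cap."""
    if not records:
        return None
    groups: dict[tuple, list[float]] = {}
    for rec in records:
        groups.setdefault((rec.diluent, rec.container), []).append(rec.duration_h)
    supported = max(min(durations) for durations in groups.values())
    return min(supported, cap_h)


def assign_rbpes(
    prep: PreparationSpec,
    spc_h: float,
    evidence: Sequence[StabilityEvidence],
    micro_cap_h: float,
    policy: StabilityPolicy = DEFAULT_POLICY,
    state: EvidenceState = EvidenceState.diluted,
) -> StabilityAssignment:
    """Assign the final extended stability for one preparation.

    ``evidence`` must already be filtered (see :func:`select_evidence`);
    ``micro_cap_h`` comes from the transcoding matrix and ``spc_h`` from the
    SPC record. The same rules cover opened-vial leftovers via ``state``.
    """
    if spc_h <= 0:
        raise StabilityError("SPC duration must be positive")
    # A matrix cell of 0 h grants no extension beyond the SPC: the SPC
    # duration itself becomes the microbiological ceiling.
    micro_ceiling = micro_cap_h if micro_cap_h > 0 else spc_h
    override = policy.exceptions.get(prep.ai_id)
    cap = override if override is not None else min(micro_ceiling, policy.global_cap_h)

    notes = []
    if prep.ai_id in policy.exceptions and override is None:
        notes.append(
            f"{prep.ai_id} is listed as a cap exception but no evidence-backed "
            "override duration is configured; global cap applies"
        )

    spc_floor = min(spc_h, micro_ceiling, policy.global_cap_h)
    durations: dict[TemperatureBand, Optional[float]] = {}
    for band in TemperatureBand:
        band_recs = [e for e in evidence if e.temperature_band is band]
        value = _band_duration(band_recs, cap)
        durations[band] = spc_floor if value is None else value

    if any(e.cold_instability for e in evidence):
        durations[TemperatureBand.cold_2_8C] = min(policy.cold_fallback_h, cap)
        notes.append("documented cold instability: 24 h fallback applied at 2-8 degC")

    provenance = tuple(
        sorted({e.citation for e in evidence if e.citation})
    )
    return StabilityAssignment(
        ai_id=prep.ai_id,
        state=state,
        room_temp_h=durations[TemperatureBand.room_20_25C],
        cold_2_8C_h=durations[TemperatureBand.cold_2_8C],
        spc_reference_h=spc_h,
        provenance=provenance,
        notes="; ".join(notes),
    )


def check_increased_volume(
    dose_mg: float,
    stock_concentration_mg_mL: float,
    bag_nominal_volume_mL: float,
    concentration_range_mg_mL: Optional[tuple[float, float]] = None,
) -> IncreasedVolumeResult:
    """Concentration check for increased-volume compounding.

    The drug volume ``dose / stock_concentration`` is added to the nominal bag
    volume, giving final concentration ``dose / (bag + drug_volume)``, which
    must fall inside the evidence-validated range.
    """
    if stock_concentration_mg_mL <= 0:
        raise StabilityError("stock concentration must be positive")
    if dose_mg < 0 or bag_nominal_volume_mL <= 0:
        raise StabilityError("dose must be >= 0 and bag volume > 0")
    drug_volume = dose_mg / stock_concentration_mg_mL
    final_c = dose_mg / (bag_nominal_volume_mL + drug_volume)
    if concentration_range_mg_mL is None:
        in_range = True
    else:
        lo, hi = concentration_range_mg_mL
        in_range = lo <= final_c <= hi
    return IncreasedVolumeResult(
        drug_volume_mL=drug_volume,
        final_concentration_mg_mL=final_c,
        in_range=in_range,
    )


def _fmt_duration(hours: Optional[float]) -> str:
    """Hours rendered as days when a whole multiple of 24 h, else hours."""
    if hours is None:
        return ""
    if hours == 0:
        return "SPC only"
    if hours % 24 == 0:
        days = int(hours // 24)
        return f"{days} d"
    value = int(hours) if float(hours).is_integer() else hours
    return f"{value} h"


#: Fixed column order of the exported stability table.
TABLE_COLUMNS = [
    "active_ingredient",
    "brand_name",
    "reconstitution",
    "stock_concentration_mg_mL",
    "dilution_vehicles",
    "vial_leftover_stability",
    "filter_0.2_0.22_um",
    "photosensitive",
    "infusion_time_range",
    "revised_stability_room",
    "revised_stability_2_8C",
    "spc_stability",
    "notes",
]


def export_table(
    formulary: Formulary,
    assignments: Iterable[StabilityAssignment],
    path: str | Path,
) -> pd.DataFrame:
    """Write the formulation stability table as deterministic CSV.

    One row per formulation, sorted by a.i. name then brand; requires a
    ``diluted`` assignment for every formulary entry (``opened_vial``
    assignments fill the vial-leftover column when present). Raises listing
    every missing ai_id.
    """
    by_key: dict[tuple[str, EvidenceState], StabilityAssignment] = {}
    for a in assignments:
        by_key[(a.ai_id, a.state)] = a

    missing = sorted(
        {f.ai_id for f in formulary.formulations}
        - {ai for (ai, state) in by_key if state is EvidenceState.diluted}
    )
    if missing:
        raise StabilityError(f"no diluted-state assignment for ai_id(s): {missing}")

    rows = []
    for f in formulary.formulations:
        ai = formulary.active_ingredients[f.ai_id]
        diluted = by_key[(f.ai_id, EvidenceState.diluted)]
        leftover = by_key.get((f.ai_id, EvidenceState.opened_vial))
        if f.reconstitution_solvent.value == "none":
            reconstitution = "ready to use"
        else:
            reconstitution = f"{f.reconstitution_volume_mL:g} mL {f.reconstitution_solvent.value}"
        rows.append(
            {
                "active_ingredient": ai.name,
                "brand_name": f.brand_name,
                "reconstitution": reconstitution,
                "stock_concentration_mg_mL": (
                    "" if f.stock_concentration_mg_mL is None else f"{f.stock_concentration_mg_mL:g}"
                ),
                "dilution_vehicles": "; ".join(d.value for d in f.allowed_diluents),
                "vial_leftover_stability": (
                    _fmt_duration(leftover.room_temp_h) if leftover else ""
                ),
                "filter_0.2_0.22_um": "yes" if ai.filter_required else "no",
                "photosensitive": "yes" if ai.photosensitive else "no",
                "infusion_time_range": f.infusion_time_range,
                "revised_stability_room": _fmt_duration(diluted.room_temp_h),
                "revised_stability_2_8C": _fmt_duration(diluted.cold_2_8C_h),
                "spc_stability": _fmt_duration(diluted.spc_reference_h),
                "notes": diluted.notes,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df.sort_values(["active_ingredient", "brand_name"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return df
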