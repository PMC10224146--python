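"""Quality-assurance-system (QAS) self-assessment scoring.

Adherence to the unit's QAS is self-assessed over ten critical factors
(quality management, personnel, laboratory, equipment, general operations,
aseptic manipulation, physiochemical stability, final-product quality
control, labelling, transportation). Each requirement is scored on an
ordinal scale:

* N.A. — not applicable,
* 1 — total absence of adherence,
* 2 — <= 50% adherence (organizational settings or tests under way),
* 3 — > 50% adherence (established but not completely documented),
* 4 — complete (100%) adherence with full documentation.

Factor-level aggregation is weakest-link: the factor score is the minimum
non-N.A. item score, and the unit counts as fully adherent only when every
factor scores 4. Full adherence is what certifies the unit for the 30% RA
reduction and for the extended-stability transcoding matrix, so a single
critical gap must never be averaged away.
"""

from __future__ import annotations

import datetime
import enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

#: The ten critical factors of the self-assessment sheet.
FACTORS: dict[int, str] = {
    1: "Quality management",
    2: "Personnel",
    3: "Laboratory",
    4: "Equipment",
    5: "General activities and operations",
    6: "Manipulation process in asepsis",
    7: "Physiochemical stability of the prepared drug",
    8: "Quality control of the final product",
    9: "Labelling",
    10: "Transportation process",
}


class QASError(Exception):
    pass


class AdherenceState(str, enum.Enum):
    absent = "absent"
    le_50 = "<=50%"
    gt_50_incomplete_docs = ">50%_incomplete_docs"
    full_documented = "100%_documented"
    not_applicable = "not_applicable"


#: Ordinal score per adherence state; None encodes N.A.
ADHERENCE_SCORES: dict[AdherenceState, Optional[int]] = {
    AdherenceState.absent: 1,
    AdherenceState.le_50: 2,
    AdherenceState.gt_50_incomplete_docs: 3,
    AdherenceState.full_documented: 4,
    AdherenceState.not_applicable: None,
}


def score_from_adherence(adherence: AdherenceState | str) -> Optional[int]:
    """Map an adherence state to its 1..4 score, or None for N.A."""
    return ADHERENCE_SCORES[AdherenceState(adherence)]


class QASItemScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    factor_id: int = Field(..., ge=1, le=10)
    requirement_id: str
    score: Optional[int] = Field(None, ge=1, le=4)  # None = N.A.
    evidence_note: str = ""


class QASAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    items: tuple[QASItemScore, ...]
    assessed_on: datetime.date

    def model_post_init(self, __context) -> None:
        present = {i.factor_id for i in self.items}
        missing = sorted(set(FACTORS) - present)
        if missing:
            raise ValueError(f"factors without any scored item: {missing}")


class QASStatus(BaseModel):
    model_config = ConfigDict(frozen=True)

    per_factor_min: dict[int, Optional[int]]
    fully_adherent: bool
    certified_for_modifier: bool
    na_only_factors: tuple[int, ...] = ()
    flags: tuple[str, ...] = ()


def aggregate_assessment(
    assessment: QASAssessment,
    optional_factors: frozenset[int] = frozenset(),
) -> QASStatus:
    """Weakest-link aggregation of an assessment into the unit's QAS status.

    Per factor, the score is the minimum over non-N.A. items (order
    independent). A factor whose items are all N.A. scores None: if the
    factor is whitelisted in ``optional_factors`` it is excluded from the
    full-adherence requirement, otherwise a flag is raised and the unit is
    not fully adherent. ``certified_for_modifier`` (default policy: equal to
    ``fully_adherent``) feeds the 30% RA reduction.
    """
    per_factor: dict[int, Optional[int]] = {}
    na_only: list[int] = []
    flags: list[str] = []
    for fid in sorted(FACTORS):
        scores = [i.score for i in assessment.items if i.factor_id == fid and i.score is not None]
        if scores:
            per_factor[fid] = min(scores)
        else:
            per_factor[fid] = None
            na_only.append(fid)
            if fid not in optional_factors:
                flags.append(
                    f"factor {fid} ({FACTORS[fid]}) has only N.A. items and is not "
                    "configured as optional"
                )
    fully = all(
        score == 4
        for fid, score in per_factor.items()
        if not (score is None and fid in optional_factors)
    ) and not flags
    return QASStatus(
        per_factor_min=per_factor,
        fully_adherent=fully,
        certified_for_modifier=fully,
        na_only_factors=tuple(na_only),
        flags=tuple(flags),
    )


def read_score_sheet(
    path: str | Path, assessed_on: Optional[datetime.date] = None
) -> QASAssessment:
    """Read a score-sheet CSV: ``factor_id, requirement_id, adherence_state, note``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    items = []
    for idx, row in df.iterrows():
        try:
            items.append(
                QASItemScore(
                    factor_id=int(row["factor_id"]),
                    requirement_id=row["requirement_id"],
                    score=score_from_adherence(row["adherence_state"]),
                    evidence_note=row.get("note", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise QASError(f"{Path(path).name}, row {idx + 2}: {exc}") from exc
    return QASAssessment(
        items=tuple(items), assessed_on=assessed_on or datetime.date(2000, 1, 1)
    )


def write_report(status: QASStatus) -> str:
    """Human-readable per-factor table of the aggregated status."""
    lines = ["factor  score  name", "------  -----  ----"]
    for fid in sorted(FACTORS):
        score = status.per_factor_min.get(fid)
        lines.append(f"{fid:>6}  {('N.A.' if score is None else score):>5}  {FACTORS[fid]}")
    lines.append("")
    lines.append(f"fully adherent: {status.fully_adherent}")
    for flag in status.flags:
        lines.append(f"FLAG: {flag}")
    return "\n".join(lines)
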