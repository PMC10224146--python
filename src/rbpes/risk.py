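"""Risk assessment for compounded preparations: RA = X + (Y x Z).

The score combines three ingredients:

* **X** — pharmacological risk, a rubric lookup on the a.i. class and the
  route of administration (e.g. 125 for a cytotoxic drug given parenterally);
* **Y = A x B x C x D** — technological risk, four criteria each scored 1
  (least critical) to 5 (most critical): A number of components/calculations/
  manipulations, B pharmaceutical form (1 for a solution), C route (5 for
  sterile parenteral), D process sterility (5 when the whole process must be
  sterile). When dose calculations for anticancer or parenteral-nutrition
  preparations are carried out by dedicated management software, one unit may
  be subtracted from A down to a floor of 4;
* **Z** — an activity-volume multiplier stepping with the number of
  preparations made the previous year (1.2 above 500/year).

A unit certified under a recognized, maintained QAS may lower RA by 30%, and
by a further 2.5% when personnel have more than 5 years' experience; the two
reductions compose multiplicatively in that order. The final RA (rounded to
one decimal) is classified into tertile tiers that set the QAS level to adopt:
low (RA <= 50), medium (50 < RA <= 175), high (RA > 175).

Score tables are configuration: defaults encode the explicitly documented
values and clearly marked neutral placeholders elsewhere; sites may override
any table via YAML.
"""

from __future__ import annotations

import enum
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .formulary import AICategory, PreparationSpec, Route, parse_category


class RiskLookupError(Exception):
    """An (a.i. category, route) pair missing from the configured X table."""


class RiskTier(str, enum.Enum):
    low = "low"
    medium = "medium"
    high = "high"


class RAModifiers(BaseModel):
    model_config = ConfigDict(frozen=True)

    qas_certified: bool = False       # certified + maintained QAS: -30%
    experienced_personnel: bool = False  # >5 years' experience: -2.5%


class RAResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    X: int
    Y: int
    Z: float
    RA_raw: float
    RA_final: float
    tier: RiskTier
    qas_requirement: str
    software_reduction_applied: bool = False


class RiskTierConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    low_max: float = 50.0
    medium_max: float = 175.0
    requirements: dict[RiskTier, str] = {
        RiskTier.low: "NBP with minimal required procedures.",
        RiskTier.medium: "Complete NBP, with specific procedure and periodic quality "
        "control of the pharmaceutical form (validated procedure).",
        RiskTier.high: "Complete NBP, with specific procedure and quality controls "
        "scheduled with a predefined frequency according to the method and the preparation.",
    }


class RiskTables(BaseModel):
    """All rubric tables and constants; everything here is site-editable."""

    model_config = ConfigDict(frozen=True)

    # X per (category, route class). Only the antiblastic/parenteral cell is
    # documented; the remaining cells are neutral placeholders.
    x_table: dict[str, int] = {
        "antiblastic|parenteral": 125,
        "antiretroviral|parenteral": 50,   # placeholder
        "antidote|parenteral": 50,         # placeholder
        "pain_reliever|parenteral": 50,    # placeholder
    }
    b_solution: int = 1
    b_non_solution: int = 3               # placeholder (form rubric not published)
    c_sterile_parenteral: int = 5
    c_other: int = 2                      # placeholder
    d_whole_process_sterile: int = 5
    d_other: int = 2                      # placeholder
    software_reduction_floor: int = 4
    #: Z tiers as (minimum annual preparation count, multiplier), ascending.
    z_tiers: tuple[tuple[int, float], ...] = ((0, 1.0), (501, 1.2))
    qas_certified_reduction: float = 0.30
    experienced_personnel_reduction: float = 0.025
    tiers: RiskTierConfig = RiskTierConfig()


DEFAULT_TABLES = RiskTables()

#: Categories whose software-assisted dose calculation earns the A reduction.
SOFTWARE_REDUCTION_CATEGORIES = frozenset({AICategory.antiblastic})

_PARENTERAL_ROUTES = {Route.IV, Route.IP, Route.PED, "parenteral", "IV", "IP", "PED"}


def _route_class(route: Route | str) -> str:
    return "parenteral" if route in _PARENTERAL_ROUTES else str(route)


def load_tables(path: str | Path) -> RiskTables:
    """Read a YAML risk-table override file into a :class:`RiskTables`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "z_tiers" in raw:
        raw["z_tiers"] = tuple((int(a), float(b)) for a, b in raw["z_tiers"])
    return RiskTables(**raw)


def pharmacological_risk(
    ai_category: AICategory | str,
    route: Route | str,
    tables: RiskTables = DEFAULT_TABLES,
) -> int:
    """X score from the configured rubric; raises on an unmapped pair."""
    category = parse_category(ai_category)
    key = f"{category.value}|{_route_class(route)}"
    try:
        return tables.x_table[key]
    except KeyError:
        raise RiskLookupError(
            f"no X score configured for (category={category.value!r}, route={_route_class(route)!r})"
        ) from None


def technological_risk(
    spec: PreparationSpec,
    raw_A: int,
    ai_category: AICategory = AICategory.antiblastic,
    tables: RiskTables = DEFAULT_TABLES,
) -> tuple[int, int, int, int, int]:
    """Score the four technological criteria and return (A, B, C, D, Y).

    ``raw_A`` is the manually assessed complexity score in 1..5; the software
    reduction (one unit, floored at 4) applies only when the preparation's
    calculations are software-assisted and the category qualifies.
    """
    if not 1 <= raw_A <= 5:
        raise ValueError(f"raw_A must be in 1..5, got {raw_A}")
    A = raw_A
    if spec.software_assisted_calculation and ai_category in SOFTWARE_REDUCTION_CATEGORIES:
        A = max(tables.software_reduction_floor, raw_A - 1)
    B = tables.b_solution if spec.is_solution else tables.b_non_solution
    sterile_parenteral = spec.sterile_required and _route_class(spec.route) == "parenteral"
    C = tables.c_sterile_parenteral if sterile_parenteral else tables.c_other
    D = tables.d_whole_process_sterile if spec.sterile_required else tables.d_other
    return A, B, C, D, A * B * C * D


def activity_volume_score(
    n_preps_prev_year: int, tables: RiskTables = DEFAULT_TABLES
) -> float:
    """Z multiplier: step-function lookup on last year's preparation count."""
    if n_preps_prev_year < 0:
        raise ValueError("preparation count cannot be negative")
    z = tables.z_tiers[0][1]
    for threshold, value in tables.z_tiers:
        if n_preps_prev_year >= threshold:
            z = value
    return z


def _round1_half_up(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_ra(
    X: int,
    Y: int,
    Z: float,
    modifiers: RAModifiers = RAModifiers(),
    tables: RiskTables = DEFAULT_TABLES,
    software_reduction_applied: bool = False,
) -> RAResult:
    """RA_raw = X + Y*Z; reductions applied multiplicatively in sequence.

    Classification uses RA_final (after reduction and one-decimal rounding,
    half-up): e.g. 125 + 100*1.2 = 245, then *0.70 *0.975 -> 167.2, medium.
    """
    ra_raw = X + Y * Z
    ra = ra_raw
    if modifiers.qas_certified:
        ra *= 1.0 - tables.qas_certified_reduction
    if modifiers.experienced_personnel:
        ra *= 1.0 - tables.experienced_personnel_reduction
    ra_final = _round1_half_up(ra)
    tier, requirement = classify_risk(ra_final, tables.tiers)
    return RAResult(
        X=X, Y=Y, Z=Z,
        RA_raw=ra_raw,
        RA_final=ra_final,
        tier=tier,
        qas_requirement=requirement,
        software_reduction_applied=software_reduction_applied,
    )


def classify_risk(
    ra_final: float, cfg: Optional[RiskTierConfig] = None
) -> tuple[RiskTier, str]:
    """Tertile classification: the three tiers partition [0, inf)."""
    if cfg is None:
        cfg = DEFAULT_TABLES.tiers
    if ra_final < 0:
        raise ValueError("RA cannot be negative")
    if ra_final <= cfg.low_max:
        tier = RiskTier.low
    elif ra_final <= cfg.medium_max:
        tier = RiskTier.medium
    else:
        tier = RiskTier.high
    return tier, cfg.requirements[tier]


def assess_preparation(
    spec: PreparationSpec,
    ai_category: AICategory,
    raw_A: int,
    n_preps_prev_year: int,
    modifiers: RAModifiers = RAModifiers(),
    tables: RiskTables = DEFAULT_TABLES,
) -> RAResult:
    """End-to-end RA for one preparation: X lookup, A..D scoring, Z, RA."""
    X = pharmacological_risk(ai_category, spec.route, tables)
    A, B, C, D, Y = technological_risk(spec, raw_A, ai_category, tables)
    Z = activity_volume_score(n_preps_prev_year, tables)
    return compute_ra(
        X, Y, Z, modifiers, tables,
        software_reduction_applied=(A < raw_A),
    )
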