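"""Deterministic synthetic inputs: formularies, QAS sheets, monitoring logs.

Everything the engine consumes can be generated here from a single integer
seed, so the whole toolchain is exercisable with no external data. The
generated formulary always includes a paclitaxel entry mirroring the standard
worked scenario (80 mg/m2 BSA dosing, 6 mg/mL stock, 250 mL NaCl 0.9% bag,
A+/A evidence over 0.3-1.2 mg/mL), plus seed-dependent extra drugs. No
statistical realism is claimed for contamination dynamics: events are i.i.d.
Bernoulli per microbiological sample at the configured rate.
"""

from __future__ import annotations

import datetime
import random
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import monitoring
from .formulary import (
    ActiveIngredient,
    AICategory,
    ConsensusCompliance,
    Diluent,
    EvidenceLevel,
    EvidenceSource,
    EvidenceState,
    Formulary,
    Formulation,
    PreparationSpec,
    Solvent,
    StabilityEvidence,
    TemperatureBand,
    save_formulary,
)


class FixtureConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_ais: int = Field(5, ge=1)
    n_evidence_per_ai: int = Field(2, ge=0)
    contamination_rate: float = Field(0.0, ge=0.0, le=1.0)
    year: int = 2022


_AI_POOL = [
    ("gemcitabine", AICategory.antiblastic, 38.0),
    ("fluorouracil", AICategory.antiblastic, 50.0),
    ("oxaliplatin", AICategory.antiblastic, 5.0),
    ("cyclophosphamide", AICategory.antiblastic, 20.0),
    ("irinotecan", AICategory.antiblastic, 20.0),
    ("pembrolizumab", AICategory.antiblastic, 25.0),
    ("trastuzumab", AICategory.antiblastic, 21.0),
    ("zidovudine", AICategory.antiretroviral, 10.0),
    ("mesna", AICategory.antidote, 100.0),
    ("morphine", AICategory.pain_reliever, 10.0),
]


def paclitaxel_worked_example() -> PreparationSpec:
    """The reference scenario: 80 mg/m2 on a 1.6 m2 patient, 250 mL NaCl 0.9%
    bag, software-assisted calculation (dose 128 mg)."""
    return PreparationSpec(
        ai_id="paclitaxel",
        dose_per_bsa_mg_m2=80.0,
        bsa_m2=1.6,
        diluent=Diluent.NaCl_09,
        bag_nominal_volume_mL=250.0,
        route="IV",
        is_solution=True,
        sterile_required=True,
        software_assisted_calculation=True,
    )


def build_formulary(cfg: FixtureConfig) -> Formulary:
    """Construct an in-memory synthetic formulary (paclitaxel entry first)."""
    rng = random.Random(cfg.seed)
    form = Formulary()

    form.active_ingredients["paclitaxel"] = ActiveIngredient(
        ai_id="paclitaxel",
        name="paclitaxel",
        category=AICategory.antiblastic,
        pharmacopoeia_listed=True,
        photosensitive=False,
        filter_required=True,
    )
    form.formulations.append(
        Formulation(
            ai_id="paclitaxel",
            brand_name="Paclitaxel generic",
            reconstitution_solvent=Solvent.none,
            reconstitution_volume_mL=0.0,
            stock_concentration_mg_mL=6.0,
            allowed_diluents=(Diluent.NaCl_09, Diluent.glucose_5),
            container_types=("PVC-free bag",),
            infusion_time_range="3 h",
        )
    )
    form.evidence.append(
        StabilityEvidence(
            ai_id="paclitaxel",
            source=EvidenceSource.literature,
            state=EvidenceState.diluted,
            temperature_band=TemperatureBand.room_20_25C,
            duration_h=336.0,
            concentration_min_mg_mL=0.3,
            concentration_max_mg_mL=1.2,
            diluent=Diluent.NaCl_09,
            container="PVC-free bag",
            evidence_level=EvidenceLevel.A,
            consensus_compliance=ConsensusCompliance.high,
            citation="synthetic-paclitaxel-room",
        )
    )
    form.evidence.append(
        StabilityEvidence(
            ai_id="paclitaxel",
            source=EvidenceSource.SPC,
            state=EvidenceState.diluted,
            temperature_band=TemperatureBand.room_20_25C,
            duration_h=24.0,
            evidence_level=EvidenceLevel.unrated,
            citation="synthetic-paclitaxel-spc",
        )
    )
    form.preparations.append(paclitaxel_worked_example())

    pool = list(_AI_POOL)
    for i in range(cfg.n_ais - 1):
        name, category, stock = pool[i % len(pool)]
        ai_id = name if i < len(pool) else f"{name}_{i}"
        form.active_ingredients[ai_id] = ActiveIngredient(
            ai_id=ai_id,
            name=ai_id,
            category=category,
            pharmacopoeia_listed=True,
            photosensitive=rng.random() < 0.3,
            filter_required=rng.random() < 0.2,
        )
        form.formulations.append(
            Formulation(
                ai_id=ai_id,
                brand_name=f"{ai_id.capitalize()} brand",
                reconstitution_solvent=(solvent := rng.choice([Solvent.none, Solvent.water, Solvent.NaCl_09])),
                reconstitution_volume_mL=0.0 if solvent is Solvent.none else float(rng.choice([5, 10, 20])),
                stock_concentration_mg_mL=stock,
                allowed_diluents=(Diluent.NaCl_09,),
                container_types=("bag",),
                infusion_time_range=f"{rng.choice([0.5, 1, 2])} h",
            )
        )
        for j in range(cfg.n_evidence_per_ai):
            band = rng.choice(list(TemperatureBand))
            lo = round(rng.uniform(0.05, 1.0), 2)
            hi = round(lo + rng.uniform(0.5, 5.0), 2)
            form.evidence.append(
                StabilityEvidence(
                    ai_id=ai_id,
                    source=EvidenceSource.literature,
                    state=EvidenceState.diluted,
                    temperature_band=band,
                    duration_h=float(rng.choice([24, 48, 72, 168, 336])),
                    concentration_min_mg_mL=lo,
                    concentration_max_mg_mL=hi,
                    diluent=Diluent.NaCl_09,
                    container="bag",
                    evidence_level=rng.choice([EvidenceLevel.A_plus, EvidenceLevel.A, EvidenceLevel.B]),
                    consensus_compliance=rng.choice(
                        [ConsensusCompliance.high, ConsensusCompliance.medium, ConsensusCompliance.low]
                    ),
                    citation=f"synthetic-{ai_id}-{j}",
                )
            )
        form.preparations.append(
            PreparationSpec(
                ai_id=ai_id,
                fixed_dose_mg=float(rng.choice([50, 100, 200, 500])),
                diluent=Diluent.NaCl_09,
                bag_nominal_volume_mL=float(rng.choice([100, 250, 500])),
                route="IV",
                software_assisted_calculation=True,
            )
        )
    return form


def generate_formulary(cfg: FixtureConfig, out_dir: str | Path) -> Formulary:
    """Write a synthetic formulary to ``out_dir``; byte-identical per seed."""
    form = build_formulary(cfg)
    save_formulary(form, out_dir)
    return form


def build_monitoring_log(cfg: FixtureConfig) -> list[monitoring.MonitoringSample]:
    """Biweekly-session log: per session one hood settle plate, one room
    settle plate, one surface swab and three glove prints; contamination is
    Bernoulli(``contamination_rate``) per sample with a 1-3 CFU count."""
    rng = random.Random(cfg.seed + 1)
    schedule = monitoring.build_schedule(cfg.year)
    samples: list[monitoring.MonitoringSample] = []
    session_plan = [
        (monitoring.SampleKind.settle_plate_hood_1h, monitoring.Medium.TSA, monitoring.Grade.A),
        (monitoring.SampleKind.settle_plate_room_4h, monitoring.Medium.TSA, monitoring.Grade.C),
        (monitoring.SampleKind.surface_swab, monitoring.Medium.TSA, monitoring.Grade.A),
        (monitoring.SampleKind.glove_print_left, monitoring.Medium.TSA, monitoring.Grade.A),
        (monitoring.SampleKind.glove_print_right, monitoring.Medium.TSA, monitoring.Grade.A),
        (monitoring.SampleKind.glove_print_control, monitoring.Medium.TSA, monitoring.Grade.A),
    ]
    for entry in schedule.entries:
        if entry.kind != "environmental_control":
            continue
        for kind, medium, grade in session_plan:
            contaminated = rng.random() < cfg.contamination_rate
            value = float(rng.randint(1, 3)) if contaminated else 0.0
            samples.append(
                monitoring.MonitoringSample(
                    kind=kind, medium=medium, grade_context=grade, value=value, date=entry.date
                )
            )
    return samples


def generate_monitoring_log(cfg: FixtureConfig, out_path: str | Path) -> list[monitoring.MonitoringSample]:
    """Write the synthetic sample log as CSV and return the samples."""
    samples = build_monitoring_log(cfg)
    df = pd.DataFrame(
        [
            {
                "kind": s.kind.value,
                "medium": s.medium.value,
                "grade_context": s.grade_context.value,
                "value": s.value,
                "date": s.date.isoformat(),
            }
            for s in samples
        ],
        columns=["kind", "medium", "grade_context", "value", "date"],
    )
    df.to_csv(out_path, index=False, lineterminator="\n")
    return samples


def read_monitoring_log(path: str | Path) -> list[monitoring.MonitoringSample]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        monitoring.MonitoringSample(
            kind=monitoring.SampleKind(row["kind"]),
            medium=monitoring.Medium(row["medium"]),
            grade_context=monitoring.Grade(row["grade_context"]),
            value=float(row["value"]),
            date=datetime.date.fromisoformat(row["date"]),
        )
        for _, row in df.iterrows()
    ]


def generate_qas_sheet(cfg: FixtureConfig, out_path: str | Path, fully_adherent: bool = True) -> None:
    """Write a ten-factor score sheet; optionally inject sub-4 scores."""
    rng = random.Random(cfg.seed + 2)
    rows = ["factor_id,requirement_id,adherence_state,note"]
    from .qas import FACTORS

    for fid in sorted(FACTORS):
        for req in ("a", "b"):
            if fully_adherent:
                state = "100%_documented"
            else:
                state = rng.choice(["100%_documented", ">50%_incomplete_docs", "<=50%"])
            rows.append(f"{fid},{fid}{req},{state},")
    Path(out_path).write_text("\n".join(rows) + "\n")


def generate_site_config(cfg: FixtureConfig, out_path: str | Path) -> dict:
    """Write a YAML site configuration mirroring the reference unit: Grade A
    hood in a Grade C room, closed no-gas devices, ~200,000 preparations/year,
    certified QAS and experienced personnel."""
    site = {
        "environment": {"working_zone_grade": "A", "background_grade": "C", "iso_class": "ISO 4.8"},
        "device": {"closed_system": True, "gas_exchange": False},
        "validation": {
            "media_fill_current_pass": True,
            "env_monitoring_within_limits": True,
            "particle_counts_pass": True,
            "qas_fully_adherent": True,
        },
        "n_preps_prev_year": 200000,
        "modifiers": {"qas_certified": True, "experienced_personnel": True},
        "operators": [
            {"name": "op-senior", "status": "experienced"},
            {"name": "op-junior", "status": "new_hire"},
        ],
        "year": cfg.year,
    }
    Path(out_path).write_text(yaml.safe_dump(site, sort_keys=True))
    return site


def generate_all(cfg: FixtureConfig, out_dir: str | Path) -> None:
    """Emit every fixture family under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    generate_formulary(cfg, out)
    generate_monitoring_log(cfg, out / "monitoring_log.csv")
    generate_qas_sheet(cfg, out / "qas_scores.csv")
    generate_site_config(cfg, out / "site.yaml")
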