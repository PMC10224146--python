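"""RBPES integration rules: evidence filtering, caps, conflicts, export."""

import random

import pytest

from rbpes.fixtures import paclitaxel_worked_example
from rbpes.formulary import (
    ConsensusCompliance,
    Diluent,
    EvidenceLevel,
    EvidenceSource,
    EvidenceState,
    StabilityEvidence,
    TemperatureBand,
    compute_dose,
)
from rbpes.stability import (
    DEFAULT_POLICY,
    StabilityError,
    StabilityPolicy,
    assign_rbpes,
    check_increased_volume,
    export_table,
    select_evidence,
)


def evidence(
    duration_h=168.0,
    band=TemperatureBand.room_20_25C,
    level=EvidenceLevel.A,
    consensus=ConsensusCompliance.high,
    conc=(0.3, 1.2),
    diluent=Diluent.NaCl_09,
    container="bag",
    ai_id="paclitaxel",
    cold_instability=False,
    citation="c",
):
    lo, hi = conc if conc else (None, None)
    return StabilityEvidence(
        ai_id=ai_id,
        source=EvidenceSource.literature,
        state=EvidenceState.diluted,
        temperature_band=band,
        duration_h=duration_h,
        concentration_min_mg_mL=lo,
        concentration_max_mg_mL=hi,
        diluent=diluent,
        container=container,
        evidence_level=level,
        consensus_compliance=consensus,
        cold_instability=cold_instability,
        citation=citation,
    )


@pytest.fixture()
def prep():
    return paclitaxel_worked_example()


class TestSelectEvidence:
    def test_level_B_excluded(self, prep):
        records = [evidence(level=EvidenceLevel.A), evidence(level=EvidenceLevel.B)]
        kept = select_evidence(records, prep, 0.512)
        assert [r.evidence_level for r in kept] == [EvidenceLevel.A]

    def test_low_consensus_excluded(self, prep):
        records = [evidence(consensus=ConsensusCompliance.low)]
        assert select_evidence(records, prep, 0.512) == []

    def test_concentration_interval_membership(self, prep):
        # 128 mg in 250 mL -> 0.512 mg/mL sits inside 0.3-1.2
        final_c = compute_dose(prep) / prep.bag_nominal_volume_mL
        assert final_c == pytest.approx(0.512)
        assert select_evidence([evidence(conc=(0.3, 1.2))], prep, final_c)
        assert select_evidence([evidence(conc=(0.6, 1.2))], prep, final_c) == []

    def test_diluent_mismatch_excluded(self, prep):
        assert select_evidence([evidence(diluent=Diluent.glucose_5)], prep, 0.512) == []

    def test_conflicting_records_both_retained(self, prep):
        records = [evidence(duration_h=72.0), evidence(duration_h=168.0)]
        assert len(select_evidence(records, prep, 0.512)) == 2


class TestAssignRBPES:
    def test_evidence_capped_at_micro_cap(self, prep):
        a = assign_rbpes(prep, spc_h=24.0, evidence=[evidence(duration_h=336.0)], micro_cap_h=168.0)
        assert a.room_temp_h == 168.0

    def test_no_evidence_falls_back_to_spc_floor(self, prep):
        a = assign_rbpes(prep, spc_h=24.0, evidence=[], micro_cap_h=168.0)
        assert a.room_temp_h == 24.0 and a.cold_2_8C_h == 24.0

    def test_conflicting_claims_resolve_restrictively(self, prep):
        records = [evidence(duration_h=72.0), evidence(duration_h=168.0)]
        a = assign_rbpes(prep, spc_h=24.0, evidence=records, micro_cap_h=168.0)
        assert a.room_temp_h == 72.0

    def test_cold_instability_triggers_24h_fallback(self, prep):
        records = [
            evidence(duration_h=168.0),
            evidence(duration_h=168.0, band=TemperatureBand.cold_2_8C, cold_instability=True),
        ]
        a = assign_rbpes(prep, spc_h=24.0, evidence=records, micro_cap_h=168.0)
        assert a.cold_2_8C_h == 24.0
        assert "cold instability" in a.notes

    def test_zero_micro_cap_means_spc_only(self, prep):
        a = assign_rbpes(prep, spc_h=24.0, evidence=[evidence(duration_h=336.0)], micro_cap_h=0.0)
        assert a.room_temp_h == 24.0

    def test_exception_without_value_keeps_global_cap(self, prep):
        policy = StabilityPolicy(exceptions={"paclitaxel": None})
        a = assign_rbpes(
            prep, spc_h=24.0, evidence=[evidence(duration_h=336.0)], micro_cap_h=168.0, policy=policy
        )
        assert a.room_temp_h == 168.0
        assert "exception" in a.notes

    def test_evidence_backed_exception_overrides_cap(self, prep):
        policy = StabilityPolicy(exceptions={"paclitaxel": 240.0})
        a = assign_rbpes(
            prep, spc_h=24.0, evidence=[evidence(duration_h=336.0)], micro_cap_h=168.0, policy=policy
        )
        assert a.room_temp_h == 240.0

    def test_nonpositive_spc_rejected(self, prep):
        with pytest.raises(StabilityError):
            assign_rbpes(prep, spc_h=0.0, evidence=[], micro_cap_h=168.0)


class TestRandomizedInvariants:
    """Rule invariants over randomized synthetic evidence sets."""

    def random_records(self, rng, n):
        return [
            evidence(
                duration_h=float(rng.choice([6, 24, 48, 72, 168, 240, 336])),
                band=rng.choice(list(TemperatureBand)),
                container=rng.choice(["bag", "syringe"]),
                citation=f"r{i}",
            )
            for i in range(n)
        ]

    def test_cap_dominance(self, prep):
        rng = random.Random(11)
        for _ in range(50):
            records = self.random_records(rng, rng.randint(0, 6))
            micro_cap = float(rng.choice([24, 96, 168]))
            a = assign_rbpes(prep, spc_h=24.0, evidence=records, micro_cap_h=micro_cap)
            cap = min(micro_cap, DEFAULT_POLICY.global_cap_h)
            assert a.room_temp_h <= cap
            assert a.cold_2_8C_h <= cap

    def test_adding_conflicting_record_never_extends(self, prep):
        rng = random.Random(12)
        for _ in range(50):
            records = self.random_records(rng, rng.randint(1, 5))
            base = assign_rbpes(prep, spc_h=24.0, evidence=records, micro_cap_h=168.0)
            extra = evidence(
                duration_h=float(rng.choice([6, 24, 48])),
                band=rng.choice(list(TemperatureBand)),
                container=rng.choice(["bag", "syringe"]),
                citation="conflict",
            )
            conflicted = [r for r in records if (r.diluent, r.container) == (extra.diluent, extra.container)
                          and r.temperature_band is extra.temperature_band]
            if not conflicted:
                continue
            more = assign_rbpes(prep, spc_h=24.0, evidence=records + [extra], micro_cap_h=168.0)
            band_attr = (
                "room_temp_h" if extra.temperature_band is TemperatureBand.room_20_25C else "cold_2_8C_h"
            )
            assert getattr(more, band_attr) <= getattr(base, band_attr)

    def test_spc_floor_when_all_evidence_removed(self, prep):
        rng = random.Random(13)
        for _ in range(20):
            spc = float(rng.choice([8, 24, 48]))
            micro_cap = float(rng.choice([24, 168]))
            a = assign_rbpes(prep, spc_h=spc, evidence=[], micro_cap_h=micro_cap)
            assert a.room_temp_h == a.cold_2_8C_h == min(spc, micro_cap)


class TestIncreasedVolume:
    def test_worked_arithmetic(self):
        # 128 mg of a 6 mg/mL stock into a 250 mL bag
        result = check_increased_volume(128.0, 6.0, 250.0, (0.3, 1.2))
        assert result.drug_volume_mL == pytest.approx(128 / 6)
        assert result.final_concentration_mg_mL == pytest.approx(128 / (250 + 128 / 6))
        assert result.final_concentration_mg_mL == pytest.approx(0.472, abs=5e-4)
        assert result.in_range

    def test_zero_dose(self):
        result = check_increased_volume(0.0, 6.0, 250.0, (0.3, 1.2))
        assert result.final_concentration_mg_mL == 0.0
        assert not result.in_range  # below the 0.3 lower bound

    def test_zero_dose_without_lower_bound_is_in_range(self):
        assert check_increased_volume(0.0, 6.0, 250.0, (0.0, 1.2)).in_range

    def test_invalid_stock_concentration(self):
        with pytest.raises(StabilityError):
            check_increased_volume(128.0, 0.0, 250.0)


class TestExportTable:
    def make_assignments(self, formulary):
        return [
            assign_rbpes(prep, spc_h=24.0, evidence=[], micro_cap_h=168.0)
            for prep in formulary.preparations
        ]

    def test_shape_and_sort(self, formulary, tmp_path):
        out = tmp_path / "table.csv"
        df = export_table(formulary, self.make_assignments(formulary), out)
        assert len(df) == len(formulary.formulations) == 3
        assert len(df.columns) >= 12
        assert list(df["active_ingredient"]) == sorted(df["active_ingredient"])

    def test_reexport_byte_identical(self, formulary, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        assignments = self.make_assignments(formulary)
        export_table(formulary, assignments, a)
        export_table(formulary, assignments, b)
        assert a.read_bytes() == b.read_bytes()

    def test_missing_assignment_errors_listing_ai(self, formulary, tmp_path):
        assignments = self.make_assignments(formulary)[1:]
        with pytest.raises(StabilityError, match="no diluted-state assignment.*paclitaxel"):
            export_table(formulary, assignments, tmp_path / "t.csv")

    def test_durations_rendered_in_days_when_whole_days(self, formulary, tmp_path):
        df = export_table(formulary, self.make_assignments(formulary), tmp_path / "t.csv")
        assert set(df["revised_stability_room"]) == {"1 d"}  # 24 h SPC floor
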