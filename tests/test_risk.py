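"""Risk assessment: rubric lookups, RA formula, reductions, tier partition."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpes.formulary import PreparationSpec
from rbpes.risk import (
    DEFAULT_TABLES,
    RAModifiers,
    RiskLookupError,
    RiskTables,
    RiskTier,
    activity_volume_score,
    assess_preparation,
    classify_risk,
    compute_ra,
    pharmacological_risk,
    technological_risk,
)


def make_spec(**overrides) -> PreparationSpec:
    base = dict(
        ai_id="paclitaxel",
        dose_per_bsa_mg_m2=80.0,
        bsa_m2=1.6,
        bag_nominal_volume_mL=250.0,
        route="IV",
        is_solution=True,
        sterile_required=True,
        software_assisted_calculation=True,
    )
    base.update(overrides)
    return PreparationSpec(**base)


class TestPharmacologicalRisk:
    def test_chemotherapeutic_parenteral_scores_125(self):
        assert pharmacological_risk("chemotherapeutic", "parenteral") == 125
        assert pharmacological_risk("antiblastic", "IV") == 125

    def test_unmapped_pair_raises_naming_the_pair(self):
        with pytest.raises(RiskLookupError, match="antidote.*oral"):
            pharmacological_risk("antidote", "oral")

    def test_config_override_passthrough(self):
        tables = DEFAULT_TABLES.model_copy(
            update={"x_table": {"antiblastic|parenteral": 99}}
        )
        assert pharmacological_risk("chemotherapeutic", "IV", tables) == 99


class TestTechnologicalRisk:
    def test_worked_example_scores(self):
        """Software-assisted cytotoxic solution bag: A=4, B=1, C=5, D=5, Y=100."""
        A, B, C, D, Y = technological_risk(make_spec(), raw_A=5)
        assert (A, B, C, D, Y) == (4, 1, 5, 5, 100)

    def test_software_reduction_floors_at_4(self):
        A, *_ = technological_risk(make_spec(), raw_A=4)
        assert A == 4  # floored, not 3

    def test_no_software_no_reduction_and_product_identity(self):
        spec = make_spec(software_assisted_calculation=False)
        A, B, C, D, Y = technological_risk(spec, raw_A=3)
        assert A == 3 and Y == A * B * C * D

    @pytest.mark.parametrize("raw_A", [0, 6, -1])
    def test_raw_A_out_of_range_rejected(self, raw_A):
        with pytest.raises(ValueError, match="raw_A"):
            technological_risk(make_spec(), raw_A=raw_A)


class TestActivityVolume:
    @pytest.mark.parametrize("n, expected", [(200_000, 1.2), (501, 1.2), (0, 1.0), (500, 1.0)])
    def test_tier_lookup(self, n, expected):
        assert activity_volume_score(n) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            activity_volume_score(-1)


class TestComputeRA:
    def test_unmodified_worked_example(self):
        result = compute_ra(125, 100, 1.2)
        assert result.RA_raw == result.RA_final == 245.0

    def test_both_modifiers_give_167_2_medium(self):
        result = compute_ra(
            125, 100, 1.2, RAModifiers(qas_certified=True, experienced_personnel=True)
        )
        assert result.RA_final == 167.2
        assert result.tier is RiskTier.medium

    def test_low_tier_case(self):
        result = compute_ra(10, 1, 1.0)
        assert result.RA_final == 11.0 and result.tier is RiskTier.low

    def test_multiplicative_composition_against_brute_force(self):
        """Both reductions == RA_raw * 0.7 * 0.975, checked over a grid."""
        from decimal import ROUND_HALF_UP, Decimal

        for X, Y, Z in itertools.product([10, 125, 300], [1, 100, 625], [1.0, 1.2]):
            expected = float(
                Decimal(repr((X + Y * Z) * 0.7 * 0.975)).quantize(
                    Decimal("0.1"), rounding=ROUND_HALF_UP
                )
            )
            got = compute_ra(
                X, Y, Z, RAModifiers(qas_certified=True, experienced_personnel=True)
            ).RA_final
            assert got == expected

    @given(
        X=st.integers(1, 500),
        Y=st.integers(1, 625),
        Z=st.sampled_from([1.0, 1.1, 1.2]),
        qas=st.booleans(),
        exp=st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_reductions_never_increase_ra(self, X, Y, Z, qas, exp):
        base = compute_ra(X, Y, Z)
        modified = compute_ra(X, Y, Z, RAModifiers(qas_certified=qas, experienced_personnel=exp))
        assert modified.RA_final <= base.RA_final
        # one-decimal rounding may exceed RA_raw by at most half a tick
        assert modified.RA_final <= modified.RA_raw + 0.05

    @given(
        X=st.integers(1, 400),
        Y=st.integers(1, 624),
        Z=st.sampled_from([1.0, 1.2]),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_components(self, X, Y, Z):
        base = compute_ra(X, Y, Z).RA_final
        assert compute_ra(X + 1, Y, Z).RA_final >= base
        assert compute_ra(X, Y + 1, Z).RA_final >= base


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "ra, tier",
        [
            (0.0, RiskTier.low),
            (50.0, RiskTier.low),
            (50.1, RiskTier.medium),
            (175.0, RiskTier.medium),
            (175.1, RiskTier.high),
            (1e6, RiskTier.high),
        ],
    )
    def test_tier_boundaries(self, ra, tier):
        got, requirement = classify_risk(ra)
        assert got is tier
        assert requirement  # each tier carries its QAS requirement text

    @given(ra=st.floats(0, 1e4, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_tiers_partition_nonnegative_reals(self, ra):
        cfg = DEFAULT_TABLES.tiers
        tier, _ = classify_risk(ra)
        expected = (
            RiskTier.low if ra <= cfg.low_max
            else RiskTier.medium if ra <= cfg.medium_max
            else RiskTier.high
        )
        assert tier is expected

    def test_negative_ra_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(-0.1)


def test_assess_preparation_end_to_end():
    result = assess_preparation(
        make_spec(),
        ai_category="antiblastic",
        raw_A=5,
        n_preps_prev_year=200_000,
        modifiers=RAModifiers(qas_certified=True, experienced_personnel=True),
    )
    assert (result.X, result.Y, result.Z) == (125, 100, 1.2)
    assert result.RA_raw == 245.0
    assert result.RA_final == 167.2
    assert result.tier is RiskTier.medium
    assert result.software_reduction_applied


def test_z_tiers_configurable():
    tables = RiskTables(z_tiers=((0, 0.8), (100, 1.0), (501, 1.2)))
    assert activity_volume_score(0, tables) == 0.8
    assert activity_volume_score(100, tables) == 1.0
    assert activity_volume_score(5000, tables) == 1.2
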