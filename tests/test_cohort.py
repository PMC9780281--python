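"""Partitioned-survival cohort engine: traces, accrual, incremental CEA."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from psmcea import (
    CEAResult,
    ModelSettings,
    StrategyInputs,
    StrategyTotals,
    SurvivalDistribution,
    UtilityInputs,
    accrue,
    build_trace,
    compare,
)

SETTINGS = ModelSettings()


def _pembro_itt(**overrides) -> StrategyInputs:
    base = dict(
        name="pembrolizumab",
        os=SurvivalDistribution("lognormal", {"meanlog": 1.95, "sdlog": 1.04}),
        pfs=SurvivalDistribution("loglogistic", {"shape": 1.882, "scale": 2.742}),
        drug_cost_per_cycle=10323.2,
    )
    base.update(overrides)
    return StrategyInputs(**base)


def test_model_settings_derived_quantities():
    assert SETTINGS.n_cycles == 173
    assert SETTINGS.cycle_months == pytest.approx(21.0 / 30.4375)
    assert SETTINGS.cycle_years == pytest.approx(21.0 / 365.25)
    with pytest.raises(ValueError):
        ModelSettings(annual_discount=1.5)
    with pytest.raises(ValueError):
        ModelSettings(horizon_years=0.01, cycle_length_days=21.0)


def test_trace_starts_fully_progression_free(all_configs):
    for cfg in all_configs.values():
        for arm in ("pembrolizumab", "chemotherapy"):
            trace = build_trace(cfg.strategy_inputs(arm), cfg.settings)
            row0 = trace.frame.iloc[0]
            assert (row0["pfs"], row0["pd"], row0["dead"]) == (1.0, 0.0, 0.0)


def test_occupancy_conservation_and_monotonicity(all_configs):
    for cfg in all_configs.values():
        for arm in ("pembrolizumab", "chemotherapy"):
            frame = build_trace(cfg.strategy_inputs(arm), cfg.settings).frame
            occ = frame[["pfs", "pd", "dead"]].to_numpy()
            assert np.all((occ >= 0.0) & (occ <= 1.0))
            assert occ.sum(axis=1) == pytest.approx(np.ones(len(frame)), abs=1e-12)
            assert np.all(np.diff(frame["dead"]) >= -1e-12)
            assert np.all(np.diff(frame["pfs"]) <= 1e-12)


def test_occupancy_matches_direct_survival_evaluation():
    # independent oracle: scipy's survival functions evaluated directly
    strat = _pembro_itt()
    trace = build_trace(strat, SETTINGS)
    t10 = 10 * SETTINGS.cycle_months  # ~6.9 months
    s_os = stats.norm.sf((np.log(t10) - 1.95) / 1.04)
    s_pfs = 1.0 / (1.0 + (t10 / 2.742) ** 1.882)
    row = trace.frame.iloc[10]
    assert row["time_months"] == pytest.approx(t10)
    assert row["pfs"] == pytest.approx(min(s_pfs, s_os), abs=1e-12)
    assert row["pd"] == pytest.approx(s_os - min(s_pfs, s_os), abs=1e-12)
    assert row["dead"] == pytest.approx(1.0 - s_os, abs=1e-12)


def test_pfs_exceeding_os_is_clamped_with_warning():
    strat = _pembro_itt(
        os=SurvivalDistribution("exponential", {"rate": 0.3}),
        pfs=SurvivalDistribution("exponential", {"rate": 0.05}),
    )
    with pytest.warns(RuntimeWarning, match="clamping"):
        trace = build_trace(strat, SETTINGS)
    frame = trace.frame
    assert np.all(frame["pd"] >= 0.0)
    assert frame["pfs"].to_numpy() == pytest.approx(
        np.minimum(
            strat.pfs.survival(frame["time_months"]), strat.os.survival(frame["time_months"])
        )
    )


def test_life_years_match_trapezoid_integral_of_os_survival():
    strat = _pembro_itt()
    settings = ModelSettings(annual_discount=0.0)
    trace = build_trace(strat, settings)
    totals = accrue(trace, strat, UtilityInputs(), settings)
    horizon_months = settings.n_cycles * settings.cycle_months
    grid = np.linspace(0.0, horizon_months, 4001)
    oracle_ly = np.trapezoid(strat.os.survival(grid), grid) / 12.0
    assert abs(totals.ly - oracle_ly) < settings.cycle_years


def test_single_cycle_accrual_arithmetic():
    settings = ModelSettings(horizon_years=22.0 / 365.25)  # exactly one cycle
    assert settings.n_cycles == 1
    strat = _pembro_itt(ae_profile=[])
    trace = build_trace(strat, settings)
    totals = accrue(trace, strat, UtilityInputs(), settings)
    assert totals.cost == pytest.approx(10323.2 + 69.81 + 87.6 + 51.5)
    assert totals.qaly == pytest.approx(0.741 * settings.cycle_years)
    assert totals.ly == pytest.approx(settings.cycle_years)


def test_adverse_event_cost_enters_once():
    from psmcea import AdverseEvent

    settings = ModelSettings(horizon_years=22.0 / 365.25)
    aes = (AdverseEvent("anemia", 0.013, 508.2), AdverseEvent("fatigue", 0.006, 110.3))
    strat = _pembro_itt(ae_profile=aes)
    plain = _pembro_itt(ae_profile=[])
    expected_ae = 0.013 * 508.2 + 0.006 * 110.3
    cost_with = accrue(build_trace(strat, settings), strat, UtilityInputs(), settings).cost
    cost_without = accrue(build_trace(plain, settings), plain, UtilityInputs(), settings).cost
    assert cost_with - cost_without == pytest.approx(expected_ae)


def test_discounting_strictly_reduces_totals():
    strat = _pembro_itt()
    out = {}
    for r in (0.0, 0.03, 0.06):
        settings = ModelSettings(annual_discount=r)
        trace = build_trace(strat, settings)
        out[r] = accrue(trace, strat, UtilityInputs(), settings)
    assert out[0.0].cost > out[0.03].cost > out[0.06].cost
    assert out[0.0].qaly > out[0.03].qaly > out[0.06].qaly
    assert out[0.0].ly > out[0.03].ly > out[0.06].ly


def test_qaly_bounded_by_ly_and_equal_at_unit_utilities():
    strat = _pembro_itt()
    trace = build_trace(strat, SETTINGS)
    totals = accrue(trace, strat, UtilityInputs(), SETTINGS)
    assert totals.qaly <= totals.ly
    unit = accrue(trace, strat, UtilityInputs(pfs=1.0, pd=1.0), SETTINGS)
    assert unit.qaly == pytest.approx(unit.ly, rel=1e-14)


def test_half_cycle_correction_reduces_accrual():
    strat = _pembro_itt()
    plain = accrue(build_trace(strat, SETTINGS), strat, UtilityInputs(), SETTINGS)
    hc_settings = dataclasses.replace(SETTINGS, half_cycle_correction=True)
    hc = accrue(build_trace(strat, hc_settings), strat, UtilityInputs(), hc_settings)
    assert hc.ly < plain.ly
    assert hc.qaly < plain.qaly
    assert hc.cost < plain.cost


def test_accrue_rejects_mismatched_settings_or_strategy():
    strat = _pembro_itt()
    trace = build_trace(strat, SETTINGS)
    other_settings = dataclasses.replace(SETTINGS, annual_discount=0.05)
    with pytest.raises(ValueError):
        accrue(trace, strat, UtilityInputs(), other_settings)
    other = _pembro_itt(name="other")
    with pytest.raises(ValueError):
        accrue(trace, other, UtilityInputs(), SETTINGS)


def test_compare_identical_strategies_has_undefined_icer():
    a = StrategyTotals("a", 100.0, 1.0, 0.7)
    b = StrategyTotals("b", 100.0, 1.0, 0.7)
    res = compare(a, b, SETTINGS)
    assert res.delta_cost == 0.0
    assert np.isnan(res.icer_per_qaly) and np.isnan(res.icer_per_ly)
    assert not res.cost_effective


@given(
    dc=st.floats(-5e4, 5e4),
    qa=st.floats(0.01, 2.0),
    qb=st.floats(0.01, 2.0),
)
def test_icer_times_delta_effect_recovers_delta_cost(dc, qa, qb):
    a = StrategyTotals("a", 1000.0 + dc, qa + 0.1, qa)
    b = StrategyTotals("b", 1000.0, qb + 0.1, qb)
    res = compare(a, b, SETTINGS)
    if res.delta_qaly > 0:
        assert res.icer_per_qaly * res.delta_qaly == pytest.approx(res.delta_cost, rel=1e-9, abs=1e-6)
    if res.delta_ly > 0:
        assert res.icer_per_ly * res.delta_ly == pytest.approx(res.delta_cost, rel=1e-9, abs=1e-6)


def test_dominance_flags():
    cheaper_better = compare(
        StrategyTotals("a", 50.0, 1.2, 1.0), StrategyTotals("b", 100.0, 1.0, 0.8), SETTINGS
    )
    assert cheaper_better.dominant and cheaper_better.cost_effective
    worse = compare(
        StrategyTotals("a", 200.0, 0.8, 0.6), StrategyTotals("b", 100.0, 1.0, 0.8), SETTINGS
    )
    assert worse.dominated and not worse.cost_effective


def test_summary_table_shape():
    res = CEAResult(
        intervention=StrategyTotals("pembrolizumab", 200.0, 1.2, 0.9),
        comparator=StrategyTotals("chemotherapy", 100.0, 1.0, 0.7),
        wtp=150_000.0,
    )
    table = res.summary()
    assert list(table.columns) == [
        "strategy",
        "overall_cost",
        "overall_ly",
        "overall_qaly",
        "incremental_cost",
        "incremental_ly",
        "incremental_qaly",
        "icer_per_ly",
        "icer_per_qaly",
    ]
    assert list(table["strategy"]) == ["chemotherapy", "pembrolizumab"]
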