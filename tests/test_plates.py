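import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metalswitch import (
    KineticTrace,
    PlateSimSpec,
    RateResult,
    VariantSpec,
    WellDescriptor,
    aggregate_condition,
    aggregate_rates,
    classify_dose_response,
    read_plate_csvs,
    reversibility_recovery,
    reversibility_table,
    simulate_plate,
    sliding_window_max_slope,
    trace_max_slopes,
)


def _write_plate(tmp_path, wells=("A01", "A02", "A03", "A04"), drop_from_desc=()):
    times = np.arange(6) * 60.0
    raw = pd.DataFrame({"time_s": times})
    for k, w in enumerate(wells):
        raw[w] = 0.1 + 0.001 * (k + 1) * times
    desc = pd.DataFrame(
        [
            dict(well=w, variant=f"v{k}", metal="Ni", conc_uM=10.0 * k,
                 edta=0, replicate=1, blank=0)
            for k, w in enumerate(wells)
            if w not in drop_from_desc
        ]
    )
    raw_path, desc_path = tmp_path / "raw.csv", tmp_path / "desc.csv"
    raw.to_csv(raw_path, index=False)
    desc.to_csv(desc_path, index=False)
    return raw_path, desc_path


def test_read_plate_csvs_joins_metadata(tmp_path):
    traces = read_plate_csvs(*_write_plate(tmp_path))
    assert len(traces) == 4
    by_id = {t.well.well_id: t for t in traces}
    assert by_id["A03"].well.variant == "v2"
    assert by_id["A03"].well.metal_conc == 20.0
    assert np.allclose(np.diff(by_id["A01"].times), 60.0)


def test_undescribed_wells_skipped_with_warning(tmp_path, caplog):
    paths = _write_plate(tmp_path, drop_from_desc=("A04",))
    with caplog.at_level("WARNING"):
        traces = read_plate_csvs(*paths)
    assert len(traces) == 3
    assert any("A04" in r.message for r in caplog.records)


def test_descriptor_referencing_missing_well_is_error(tmp_path):
    raw_path, desc_path = _write_plate(tmp_path)
    desc = pd.read_csv(desc_path)
    desc.loc[0, "well"] = "Z99"
    desc.to_csv(desc_path, index=False)
    with pytest.raises(ValueError, match="Z99"):
        read_plate_csvs(raw_path, desc_path)


def test_duplicate_well_id_is_error(tmp_path):
    raw_path, desc_path = _write_plate(tmp_path)
    desc = pd.read_csv(desc_path)
    desc.loc[1, "well"] = "A01"
    desc.to_csv(desc_path, index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_plate_csvs(raw_path, desc_path)


def test_simulated_plate_roundtrips_through_csv(tmp_path):
    spec = PlateSimSpec(variants=[VariantSpec("v1", "inhibited")], noise_sd=0.01, seed=4)
    sim = simulate_plate(spec)
    raw_path, desc_path = sim.write(tmp_path)
    traces = read_plate_csvs(raw_path, desc_path)
    assert len(traces) == len(sim.descriptor)
    by_id = {t.well.well_id: t for t in traces}
    for well in sim.raw.columns[1:]:
        assert np.allclose(by_id[well].signal, sim.raw[well].to_numpy())


def _trace(times, signal, well_id="A01"):
    wd = WellDescriptor(well_id, "v", "Ni", 0.0, False, 1)
    return KineticTrace(wd, np.asarray(times, float), np.asarray(signal, float))


def test_max_slope_linear_trace():
    t = np.arange(20.0)
    slope, start = sliding_window_max_slope(_trace(t, 0.01 * t))
    assert slope == pytest.approx(0.01)


def test_max_slope_quadratic_closed_form():
    """For y = t^2 on equally spaced t, the OLS window slope is 2*mean(t):
    the last window {5..9} gives 14."""
    t = np.arange(10.0)
    slope, start = sliding_window_max_slope(_trace(t, t**2), saturation_ceiling=None)
    assert slope == pytest.approx(14.0)
    assert start == 5.0


def test_max_slope_default_window_is_five_points():
    t = np.arange(5.0)
    slope, _ = sliding_window_max_slope(_trace(t, 2.0 * t), saturation_ceiling=None)
    assert slope == pytest.approx(2.0)
    with pytest.raises(ValueError, match="window"):
        sliding_window_max_slope(_trace(t[:4], t[:4]))


def test_max_slope_earliest_window_on_concave_trace():
    t = np.arange(30.0)
    y = 1.0 - np.exp(-0.3 * t)  # monotone increasing, concave
    _, start = sliding_window_max_slope(_trace(t, y))
    assert start == 0.0


def test_saturated_points_and_nans_are_dropped():
    t = np.arange(12.0)
    y = 0.5 * t
    y[8:] = 3.9  # beyond the 3.5 AU ceiling
    y[2] = np.nan
    slope, _ = sliding_window_max_slope(_trace(t, y))
    assert slope == pytest.approx(0.5)


def test_aggregate_condition_examples():
    assert aggregate_condition([1.0, 1.0, 1.0]) == (1.0, 0.0, 3)
    mean, sd, n = aggregate_condition([1.0, 2.0, 3.0])
    assert (mean, n) == (2.0, 3)
    assert sd == pytest.approx(1.0)
    assert aggregate_condition([5.0])[1] == 0.0
    with pytest.raises(ValueError):
        aggregate_condition([])


def _rr(variant, conc, rate, metal="Ni", edta=False):
    return RateResult(variant, metal, conc, edta, rate, 0.0, 3, 0.0)


def test_classification_inhibited_with_fold_change():
    res = classify_dose_response(
        [_rr("v", 0.0, 1.0), _rr("v", 1.0, 0.8), _rr("v", 10.0, 0.4)]
    )
    assert res.classification == "inhibited"
    assert res.fold_change_low_high == pytest.approx(2.5)
    assert np.allclose(res.normalized_rates, [1.0, 0.8, 0.4])


def test_classification_activated():
    res = classify_dose_response(
        [_rr("v", 0.0, 1.0), _rr("v", 1.0, 1.2), _rr("v", 10.0, 1.6)]
    )
    assert res.classification == "activated"


def test_classification_unresponsive_flat():
    res = classify_dose_response(
        [_rr("v", 0.0, 1.0), _rr("v", 1.0, 1.0), _rr("v", 10.0, 1.0)]
    )
    assert res.classification == "unresponsive"
    assert res.fold_change_low_high == pytest.approx(1.0)


def test_classification_inactive_below_floor():
    res = classify_dose_response(
        [_rr("v", 0.0, 0.01), _rr("v", 10.0, 0.01)], activity_floor=0.05
    )
    assert res.classification == "inactive"


def test_classification_requires_apo():
    with pytest.raises(ValueError, match="apo"):
        classify_dose_response([_rr("v", 1.0, 1.0), _rr("v", 10.0, 0.4)])


@given(
    scale=st.floats(1e-3, 1e3),
    rates=st.lists(st.floats(0.05, 10.0), min_size=3, max_size=6),
)
def test_classification_invariant_to_uniform_rescaling(scale, rates):
    series = [_rr("v", float(c), r) for c, r in enumerate(rates)]
    scaled = [_rr("v", float(c), r * scale) for c, r in enumerate(rates)]
    assert (
        classify_dose_response(series).classification
        == classify_dose_response(scaled).classification
    )


@pytest.mark.parametrize(
    "metal,after,apo,expected",
    [(0.05, 1.0, 1.0, 1.0), (0.05, 0.05, 1.0, 0.0), (0.2, 0.6, 1.0, 0.5)],
)
def test_recovery_fraction_examples(metal, after, apo, expected):
    res = reversibility_recovery(metal, after, apo)
    assert res.defined
    assert res.recovery == pytest.approx(expected)


def test_recovery_undefined_for_non_responder():
    res = reversibility_recovery(1.0, 1.0, 1.02)
    assert not res.defined
    assert math.isnan(res.recovery)


def test_full_reversibility_pipeline_reversible_vs_iron_like(tmp_path):
    spec = PlateSimSpec(
        variants=[VariantSpec("rev", "inhibited", reversible=True),
                  VariantSpec("irrev", "inhibited", reversible=False)],
        noise_sd=0.0, include_edta=True, seed=9,
    )
    sim = simulate_plate(spec)
    traces = read_plate_csvs(*sim.write(tmp_path))
    table = reversibility_table(aggregate_rates(trace_max_slopes(traces)))
    rec = dict(zip(table.variant, table.recovery))
    assert rec["rev"] == pytest.approx(1.0, abs=1e-9)
    assert rec["irrev"] == pytest.approx(0.0, abs=1e-9)
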