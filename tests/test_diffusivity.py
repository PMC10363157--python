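"""Fickian slab diffusivity: regression oracle, unit conversion, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import uaod_kinetics as uk
from uaod_kinetics import reference
from uaod_kinetics.errors import InsufficientDataError, InvalidInputError


def _ols_slope(x, y):
    """Closed-form simple-regression slope: the independent oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sum(xc * xc))


def test_exact_exponential_slope(times):
    slope, r = uk.ln_mr_slope(times, np.exp(-0.003 * times))
    assert slope == pytest.approx(0.003, rel=1e-12)
    assert r == pytest.approx(1.0)


def test_constant_mr_has_zero_slope(times):
    slope, r = uk.ln_mr_slope(times, np.ones_like(times))
    assert slope == 0.0


def test_page_curve_slope_matches_closed_form_ols(times):
    mr = np.exp(-0.0130 * times**0.6127)
    slope, _ = uk.ln_mr_slope(times, mr)
    assert slope == pytest.approx(abs(_ols_slope(times, np.log(mr))), rel=1e-12)


@given(seed=st.integers(0, 500))
def test_slope_matches_oracle_on_random_curves(seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 80, 9))
    t[0] = 0.0
    mr = np.clip(np.exp(-rng.uniform(0.001, 0.01) * t)
                 + rng.normal(0, 0.01, 9), 1e-3, None)
    slope, r = uk.ln_mr_slope(t, mr)
    assert slope == pytest.approx(abs(_ols_slope(t, np.log(mr))), abs=1e-12)
    assert 0 <= r <= 1


def test_nonpositive_mr_dropped_with_warning(times):
    mr = np.exp(-0.01 * times)
    mr[-1] = 0.0
    with pytest.warns(UserWarning, match="MR <= 0"):
        slope, _ = uk.ln_mr_slope(times, mr)
    assert slope == pytest.approx(0.01, rel=1e-9)
    with pytest.raises(InsufficientDataError):
        uk.ln_mr_slope([0.0, 10.0, 20.0], [1.0, -0.5, 0.0])


def test_deff_reference_arithmetic():
    """Slope 0.0033 per min with L = 2.5 mm gives 1.39e-10 m^2/s at 3 s.f."""
    deff = uk.deff_from_slope(0.0033, 0.0025)
    assert f"{deff:.2E}" == "1.39E-10"
    assert uk.deff_from_slope(0.0, 0.0025) == 0.0


def test_deff_rejects_negative_slope_with_guidance():
    with pytest.raises(InvalidInputError, match="magnitude"):
        uk.deff_from_slope(-0.0033, 0.0025)
    with pytest.raises(InvalidInputError):
        uk.deff_from_slope(0.0033, 0.0)


@given(slope=st.floats(1e-4, 0.05), scale=st.floats(0.1, 5.0),
       half=st.floats(5e-4, 5e-3))
def test_deff_linear_in_slope_quadratic_in_half_thickness(slope, scale, half):
    base = uk.deff_from_slope(slope, half)
    assert uk.deff_from_slope(scale * slope, half) == pytest.approx(
        scale * base, rel=1e-12
    )
    assert uk.deff_from_slope(slope, 2 * half) == pytest.approx(4 * base, rel=1e-12)


def test_reference_rows_recompute_within_rounding():
    """Printed slopes (rounded to 2 s.f.) reproduce printed D_eff within 3%;
    the 0.0033 rows agree exactly at 3 significant figures."""
    for power, conc, slope, deff_printed, _ in reference.DIFFUSIVITY_ROWS:
        recomputed = uk.deff_from_slope(slope, reference.HALF_THICKNESS_M)
        assert recomputed == pytest.approx(deff_printed, rel=0.03)
        if slope == 0.0033:
            assert f"{recomputed:.2E}" == f"{deff_printed:.2E}"


def test_pure_exponential_pipeline_recovers_deff_exactly(times):
    """End-to-end: exponential MR with known k gives D_eff = (k/60) 4 L^2 / pi^2."""
    k = 0.004
    w0, a0 = 8.4, 10.0
    traj = uk.OsmoticTrajectory(
        condition=uk.TreatmentCondition(power_w=75, concentration_pct=30),
        times_min=times,
        water_mass_g=w0 * np.exp(-k * times),
        solids_mass_g=np.full_like(times, a0 - w0),
        total_mass_g=w0 * np.exp(-k * times) + (a0 - w0),
    )
    table = uk.diffusivity_table([traj], half_thickness_m=0.0025)
    expected = (k / 60.0) * 4.0 * 0.0025**2 / math.pi**2
    assert table.loc[0, "Deff_m2_per_s"] == pytest.approx(expected, rel=1e-12)


def test_diffusivity_table_on_synthetic_study(noisy_study):
    table = uk.diffusivity_table(noisy_study)
    assert len(table) == 9
    assert (table["Deff_m2_per_s"] >= 0).all()
    assert table["r"].between(0, 1).all()


def test_deff_increases_with_generator_drying_rate(times):
    """Faster generator kinetics -> larger estimated D_eff (monotone)."""
    deffs = []
    for k in (0.002, 0.005, 0.01):
        mr = np.exp(-k * times)
        slope, _ = uk.ln_mr_slope(times, mr)
        deffs.append(uk.deff_from_slope(slope, 0.0025))
    assert deffs == sorted(deffs)


def test_aggregate_deff_groups_and_single_row():
    table = reference.diffusivity_frame()
    by_conc = uk.aggregate_deff(table, "concentration")
    assert by_conc.loc[40] == pytest.approx(2.43e-10, rel=1e-3)
    single = uk.aggregate_deff(table[table["power_W"] == 0].iloc[:1], "power")
    assert single.loc[0] == pytest.approx(9.05e-11)
    with pytest.raises(InvalidInputError):
        uk.aggregate_deff(table, "temperature")
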