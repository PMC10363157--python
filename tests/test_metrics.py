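"""Mass-transfer indices: worked arithmetic, error contracts, conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import uaod_kinetics as uk
from uaod_kinetics.errors import InconsistentRecordError, InvalidInputError
from uaod_kinetics.metrics import metrics_summary
from uaod_kinetics.records import RehydrationPair

masses = st.floats(0.1, 100.0, allow_nan=False)


@pytest.mark.parametrize(
    "a0, at, expected",
    [(10.0, 10.0, 0.0), (10.0, 8.5, 15.0), (10.0, 11.0, -10.0)],
)
def test_mass_reduction_arithmetic(a0, at, expected):
    assert uk.mass_reduction(a0, at) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a0, s0, st_, expected",
    [(10.0, 1.6, 1.6, 0.0), (10.0, 1.6, 2.6, 10.0), (10.0, 1.6, 2.0, 4.0)],
)
def test_solids_gain_arithmetic(a0, s0, st_, expected):
    assert uk.solids_gain(a0, s0, st_) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a0, w0, at, st_, expected",
    [(10.0, 8.4, 10.0, 1.6, 0.0), (10.0, 8.4, 8.5, 2.0, 19.0)],
)
def test_water_loss_arithmetic(a0, w0, at, st_, expected):
    assert uk.water_loss(a0, w0, at, st_) == pytest.approx(expected)


@pytest.mark.parametrize(
    "dried, rehydrated, expected",
    [(5.0, 5.0, 100.0), (5.0, 10.205, 204.1), (5.0, 7.94, 158.8)],
)
def test_rehydration_ratio_spans_reported_range(dried, rehydrated, expected):
    """RR > 100 is normal; the definition reproduces the reported extremes."""
    pair = RehydrationPair(dried_mass_g=dried, rehydrated_mass_g=rehydrated)
    assert uk.rehydration_ratio(pair) == pytest.approx(expected)


@pytest.mark.parametrize(
    "mt, m0, expected", [(8.4, 8.4, 1.0), (4.2, 8.4, 0.5), (0.0, 8.4, 0.0)]
)
def test_moisture_ratio_arithmetic(mt, m0, expected):
    assert uk.moisture_ratio(mt, m0) == pytest.approx(expected)


def test_invalid_inputs_raise():
    with pytest.raises(InvalidInputError):
        uk.mass_reduction(0.0, 5.0)
    with pytest.raises(InvalidInputError):
        uk.solids_gain(-1.0, 1.0, 2.0)
    with pytest.raises(InconsistentRecordError):
        uk.water_loss(10.0, 8.4, 5.0, 6.0)  # solids exceed total
    with pytest.raises(InvalidInputError):
        uk.moisture_ratio(1.0, 0.0)
    with pytest.raises(InvalidInputError):
        RehydrationPair(dried_mass_g=0.0, rehydrated_mass_g=1.0)


def test_moisture_ratio_above_one_warns_not_clips():
    with pytest.warns(UserWarning, match="above 1"):
        assert uk.moisture_ratio(9.0, 8.4) == pytest.approx(9.0 / 8.4)


@given(w0=masses, s0=masses, st_=masses, wfrac=st.floats(0.01, 1.2))
def test_conservation_identity(w0, s0, st_, wfrac):
    """WL = MRe + SG whenever water = total - solids at both endpoints."""
    a0 = w0 + s0  # initial total mass = water + solids
    at = st_ + w0 * wfrac  # consistent treated record (Wt = At - St)
    wl = uk.water_loss(a0, w0, at, st_)
    mre = uk.mass_reduction(a0, at)
    sg = uk.solids_gain(a0, s0, st_)
    assert wl == pytest.approx(mre + sg, abs=1e-9)


@given(
    mt=st.floats(0.0, 50.0),
    m0=st.floats(0.1, 50.0),
    c=st.floats(0.01, 100.0),
)
def test_moisture_ratio_scale_invariant(mt, m0, c):
    assert uk.moisture_ratio(c * mt, c * m0) == pytest.approx(
        uk.moisture_ratio(mt, m0), rel=1e-12
    )


def test_trajectory_metrics_composes_hand_arithmetic():
    """The (10, 8.4, 8.5, 2.0) record yields row (MRe 15, SG 4, WL 19)."""
    traj = uk.OsmoticTrajectory(
        condition=uk.TreatmentCondition(power_w=75, concentration_pct=30),
        times_min=[0.0, 80.0],
        total_mass_g=[10.0, 8.5],
        solids_mass_g=[1.6, 2.0],
        water_mass_g=[8.4, 6.5],
        replicate_id=1,
    )
    table = uk.trajectory_metrics(traj)
    assert len(table) == 1  # t = 0 row excluded
    row = table.iloc[0]
    assert row["MRe_pct"] == pytest.approx(15.0)
    assert row["SG_pct"] == pytest.approx(4.0)
    assert row["WL_pct"] == pytest.approx(19.0)
    assert row["MR"] == pytest.approx(6.5 / 8.4)


def test_untreated_trajectory_has_null_indices():
    traj = uk.OsmoticTrajectory(
        condition=uk.TreatmentCondition(power_w=0, concentration_pct=20),
        times_min=np.arange(0.0, 31.0, 10.0),
        total_mass_g=np.full(4, 10.0),
        solids_mass_g=np.full(4, 1.6),
        water_mass_g=np.full(4, 8.4),
    )
    table = uk.trajectory_metrics(traj)
    assert np.allclose(table[["MRe_pct", "SG_pct", "WL_pct"]], 0.0)
    assert np.allclose(table["MR"], 1.0)


def test_dataset_metrics_and_summary_shape(noisy_study):
    table = uk.dataset_metrics(noisy_study)
    # 27 trajectories x 8 post-treatment times
    assert len(table) == 27 * 8
    assert (table["WL_pct"] - table["MRe_pct"] - table["SG_pct"]).abs().max() <= 1e-9
    summary = metrics_summary(table)
    assert len(summary) == 9 * 8
    assert {"WL_pct_mean", "WL_pct_std"} <= set(summary.columns)


def test_trajectory_invariants_enforced():
    cond = uk.TreatmentCondition(power_w=0, concentration_pct=20)
    with pytest.raises(InvalidInputError):
        uk.OsmoticTrajectory(cond, [10.0, 20.0], [10, 9], [1.6, 1.7], [8.4, 7.3])
    with pytest.raises(InconsistentRecordError):
        uk.OsmoticTrajectory(cond, [0.0, 10.0], [10, 9], [1.6, 1.7], [8.4, 6.0])
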