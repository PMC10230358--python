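"""Synthetic-data generator: determinism, distributions, event injection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vitalwatch import (
    ValidationError,
    generate_record,
    inject_artifacts,
    inject_deterioration,
    simulate,
    write_record,
)
from vitalwatch.dysfunction import SensorFaultDetector
from vitalwatch.preprocess import Stratum, ventilation_status
from vitalwatch.simulate import (
    HIGH_SAT_PROFILE,
    LOW_SAT_PROFILE,
    SIM_PARAMETERS,
    EventKind,
    InjectedEvent,
    apply_ventilation,
)


def test_same_seed_gives_byte_identical_output(tmp_path):
    a, _ = generate_record(LOW_SAT_PROFILE, 7200, seed=5)
    b, _ = generate_record(LOW_SAT_PROFILE, 7200, seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)
    write_record(a, tmp_path / "a.csv")
    write_record(b, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    c, _ = generate_record(LOW_SAT_PROFILE, 7200, seed=6)
    assert not a.data.equals(c.data)


def test_zero_dispersion_profile_is_constant_at_centers():
    profile = dataclasses.replace(
        LOW_SAT_PROFILE,
        sds={p: 0.0 for p in SIM_PARAMETERS},
        probe_sd=0.0,
    )
    record, _ = generate_record(profile, 7200, seed=1)
    for p in ("hr", "rr", "spo2", "ibp_mean"):
        assert np.all(record.data[p] == profile.centers[p])
    assert np.all(record.data["rso2_left"] == profile.centers["rso2"])


@pytest.mark.parametrize("profile", [LOW_SAT_PROFILE, HIGH_SAT_PROFILE])
def test_marginals_near_profile_targets(profile):
    record, _ = generate_record(profile, 21600, seed=3)
    series = {
        "hr": record.data["hr"], "rr": record.data["rr"], "spo2": record.data["spo2"],
        "rso2": (record.data["rso2_left"] + record.data["rso2_right"]) / 2,
        "ibp_mean": record.data["ibp_mean"],
    }
    for p, s in series.items():
        center, sd = profile.centers[p], profile.sds[p]
        assert abs(np.median(s) - center) < sd, p
        # IQR under heavy autocorrelation: generous Monte-Carlo band, and
        # clipping narrows saturation channels near the scale ceiling
        iqr = np.percentile(s, 75) - np.percentile(s, 25)
        assert 0.4 * sd * 1.349 < iqr < 1.7 * sd * 1.349, p


def test_duration_below_two_hours_rejected():
    with pytest.raises(ValidationError):
        generate_record(LOW_SAT_PROFILE, 7199, seed=1)


# ----------------------------------------------------------- deterioration
def test_deterioration_truth_interval_and_ramp():
    event = InjectedEvent(
        kind=EventKind.DETERIORATION, start=9000, end=10800,
        magnitude={"hr": 5.0, "ibp_mean": -5.0}, ramp=300,
    )
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=2)
    shifted, truth2 = inject_deterioration(record, truth, event, LOW_SAT_PROFILE)
    assert truth2.unstable[9000:10801].all()
    assert not truth2.unstable[:9000].any()
    mid = slice(9600, 10500)
    delta_hr = shifted.data["hr"][mid].mean() - record.data["hr"][mid].mean()
    assert delta_hr == pytest.approx(5.0 * LOW_SAT_PROFILE.sds["hr"], rel=0.05)
    # the ramp never triggers the jump artifact rule
    assert not SensorFaultDetector().detect(shifted).combined.any()


def test_zero_magnitude_deterioration_leaves_record_unchanged():
    event = InjectedEvent(
        kind=EventKind.DETERIORATION, start=8000, end=9000,
        magnitude={"hr": 0.0, "ibp_mean": 0.0},
    )
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=4)
    shifted, _ = inject_deterioration(record, truth, event, LOW_SAT_PROFILE)
    pd.testing.assert_frame_equal(record.data, shifted.data)


def test_overlapping_deteriorations_rejected():
    e1 = InjectedEvent(EventKind.DETERIORATION, 8000, 10000, {"hr": 2.0, "rr": 2.0})
    e2 = InjectedEvent(EventKind.DETERIORATION, 9000, 11000, {"hr": 2.0, "rr": 2.0})
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=5)
    record, truth = inject_deterioration(record, truth, e1, LOW_SAT_PROFILE)
    with pytest.raises(ValidationError):
        inject_deterioration(record, truth, e2, LOW_SAT_PROFILE)


def test_single_parameter_deterioration_rejected():
    e = InjectedEvent(EventKind.DETERIORATION, 8000, 9000, {"hr": 2.0})
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=5)
    with pytest.raises(ValidationError):
        inject_deterioration(record, truth, e, LOW_SAT_PROFILE)


def test_event_outside_record_rejected():
    e = InjectedEvent(EventKind.DETERIORATION, 20000, 30000, {"hr": 2.0, "rr": 2.0})
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=5)
    with pytest.raises(ValidationError):
        inject_deterioration(record, truth, e, LOW_SAT_PROFILE)


# -------------------------------------------------------------- artifacts
def test_artifact_jump_mask_is_exactly_the_expanded_window():
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=7)
    events = [InjectedEvent(EventKind.ARTIFACT_JUMP, 5000, 5005,
                            magnitude=30.0, params=("ibp_mean",))]
    rec2, truth2 = inject_artifacts(record, truth, events)
    flagged = np.flatnonzero(SensorFaultDetector().detect(rec2).combined)
    assert flagged.min() == 4940 and flagged.max() == 5060
    assert truth2.artifact[5000]


def test_rr_loss_mask_covers_loss_with_pad():
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=8)
    events = [InjectedEvent(EventKind.ARTIFACT_RR_LOSS, 12000, 12119)]
    rec2, truth2 = inject_artifacts(record, truth, events)
    mask = SensorFaultDetector().detect(rec2).per_parameter["rr"]
    assert mask[12000 - 60 : 12119 + 61].all()
    assert not mask[: 12000 - 61].any()


def test_every_injected_artifact_second_is_flagged():
    record, truth = simulate(
        Stratum.LOW_SAT, 21600, seed=9,
        events=[
            InjectedEvent(EventKind.ARTIFACT_JUMP, 5000, 5005, 30.0, params=("ibp_mean",)),
            InjectedEvent(EventKind.ARTIFACT_RSO2_RAIL, 8000, 8119),
            InjectedEvent(EventKind.ARTIFACT_RR_LOSS, 15000, 15119),
        ],
    )
    mask = SensorFaultDetector().detect(record)
    assert mask.combined[truth.artifact].all()


def test_no_events_means_empty_truth():
    _, truth = generate_record(LOW_SAT_PROFILE, 7200, seed=1)
    assert not truth.artifact.any() and not truth.unstable.any()


def test_dropout_creates_missing_not_artifact():
    record, truth = generate_record(LOW_SAT_PROFILE, 21600, seed=10)
    rec2, truth2 = inject_artifacts(
        record, truth, [InjectedEvent(EventKind.DROPOUT, 6000, 6300)]
    )
    assert rec2.data.loc[6000:6300, "hr"].isna().all()
    assert not truth2.artifact.any()


def test_ventilation_event_sets_etco2():
    record, _ = generate_record(LOW_SAT_PROFILE, 21600, seed=11)
    rec2 = apply_ventilation(record, InjectedEvent(EventKind.VENTILATION, 4000, 8000))
    vent = ventilation_status(rec2.data["etco2"].to_numpy())
    assert vent[4000:8001].all() and not vent[:4000].any()
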