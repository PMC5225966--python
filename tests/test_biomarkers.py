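"""QRS biomarkers on constructed traces and synthetic dipole fixtures."""

import numpy as np
import pytest

from qrsim.biomarkers import (
    FlatSignalError,
    UndefinedAxisError,
    classify_conduction,
    compute_biomarkers,
    detect_notch,
    frontal_axis,
    lead_metrics,
    qrs_window,
    synth_qrs,
    wave_pattern,
    LeadMetrics,
    QRSBiomarkers,
)
from qrsim.forward import ECG12, LEAD_NAMES, assemble_12lead


def _ecg_from_leads(time, leads, fs=1000.0):
    full = {k: leads.get(k, np.zeros_like(time)) for k in LEAD_NAMES}
    return ECG12(time=time, leads=full, fs=fs,
                 electrode_potentials={}, calibration=1.0)


def _gauss(time, t0, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((time - t0) / sigma) ** 2)


# ---------------------------------------------------------------------------
# window detection


def test_gaussian_width_matches_closed_form():
    time = np.arange(0.0, 200.0)
    sigma = 10.0
    ecg = _ecg_from_leads(time, {"II": _gauss(time, 100, sigma)})
    onset, offset = qrs_window(ecg)
    expected = 2.0 * sigma * np.sqrt(2.0 * np.log(20.0))  # 5% crossings
    assert (offset - onset) == pytest.approx(expected, abs=2.0)


def test_window_invariant_under_scaling():
    time = np.arange(0.0, 200.0)
    tr = _gauss(time, 90, 8.0)
    w1 = qrs_window(_ecg_from_leads(time, {"V3": tr}))
    w2 = qrs_window(_ecg_from_leads(time, {"V3": 3.0 * tr}))
    assert w1 == w2


def test_flat_signal_raises():
    time = np.arange(0.0, 100.0)
    with pytest.raises(FlatSignalError):
        qrs_window(_ecg_from_leads(time, {}))


# ---------------------------------------------------------------------------
# per-lead metrics and patterns


def test_metrics_of_constructed_gaussian():
    time = np.arange(0.0, 120.0)
    tr = _gauss(time, 40.0, 5.0)
    m = lead_metrics(tr, time, (20.0, 60.0))
    assert m.r_amplitude == pytest.approx(1.0, abs=1e-6)
    assert m.time_to_r_peak == pytest.approx(20.0, abs=1.0)
    assert m.s_amplitude == 0.0
    assert m.pattern == "R"


def test_negated_trace_swaps_roles():
    time = np.arange(0.0, 120.0)
    tr = -_gauss(time, 40.0, 5.0)
    m = lead_metrics(tr, time, (20.0, 60.0))
    assert m.r_amplitude == 0.0
    assert m.pattern == "QS"
    assert m.s_amplitude == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize(
    "amps,expected",
    [((-0.1, 1.0), "qR"), ((-0.2, 0.8), "qR"), ((0.9, -0.8), "RS")],
)
def test_biphasic_patterns(amps, expected):
    time = np.arange(0.0, 160.0)
    tr = _gauss(time, 60, 6, amps[0]) + _gauss(time, 90, 6, amps[1])
    assert wave_pattern(tr, time, (40.0, 120.0)) == expected


def test_intrinsicoid_uses_lead_local_onset():
    time = np.arange(0.0, 200.0)
    tr = _gauss(time, 100, 6)  # lead activity starts well after window onset
    m = lead_metrics(tr, time, (40.0, 140.0))
    assert m.time_to_r_peak == pytest.approx(60.0, abs=1.0)
    assert m.intrinsicoid < m.time_to_r_peak  # local onset is later


# ---------------------------------------------------------------------------
# axis


def test_axis_cardinal_cases():
    time = np.arange(0.0, 100.0)
    g = _gauss(time, 50, 8)
    ecg = _ecg_from_leads(time, {"I": g})
    assert frontal_axis(ecg, (0.0, 99.0)) == pytest.approx(0.0, abs=1e-9)
    ecg = _ecg_from_leads(time, {"I": g, "aVF": g})
    assert frontal_axis(ecg, (0.0, 99.0)) == pytest.approx(45.0, abs=1e-9)
    ecg = _ecg_from_leads(time, {"aVF": -g})
    assert frontal_axis(ecg, (0.0, 99.0)) == pytest.approx(-90.0, abs=1e-9)
    with pytest.raises(UndefinedAxisError):
        frontal_axis(_ecg_from_leads(time, {"V1": g}), (0.0, 99.0))
    with pytest.raises(ValueError):
        frontal_axis(_ecg_from_leads(time, {"I": g}), (0.0, 99.0), mode="early")


@pytest.mark.parametrize("axis", list(range(-30, 100, 10)))
def test_axis_recovery_on_synthetic_fixtures(axis):
    ecg = synth_qrs(width=80.0, axis=float(axis), seed=0)
    window = qrs_window(ecg)
    assert frontal_axis(ecg, window) == pytest.approx(axis, abs=1.0)


# ---------------------------------------------------------------------------
# notch


def test_notch_counting():
    time = np.arange(0.0, 300.0)
    single = _gauss(time, 150, 12)
    assert detect_notch(single, time, (100.0, 200.0)) == 0
    double = _gauss(time, 140, 8) + 0.8 * _gauss(time, 170, 8)
    # second-peak prominence (height above the inter-peak trough) ~ 0.47
    assert detect_notch(double, time, (100.0, 230.0), prominence=0.05) == 1
    assert detect_notch(double, time, (100.0, 230.0), prominence=0.6) == 0
    with pytest.raises(ValueError):
        detect_notch(double, time, (100.0, 230.0), prominence=-1.0)


def test_synth_notch_fixture_detected():
    ecg = synth_qrs(width=80.0, axis=60.0, notch=True, seed=0)
    bm = compute_biomarkers(ecg)
    assert bm.width == pytest.approx(80.0, abs=2.0)
    assert max(m.notch_count for m in bm.per_lead.values()) >= 1


# ---------------------------------------------------------------------------
# synthetic fixture contract


def test_synth_qrs_by_construction():
    ecg = synth_qrs(width=80.0, axis=60.0, seed=4)
    w = qrs_window(ecg)
    assert (w[1] - w[0]) == pytest.approx(80.0, abs=2.0)
    assert frontal_axis(ecg, w) == pytest.approx(60.0, abs=1.0)
    l = ecg.leads
    assert np.max(np.abs(l["I"] + l["III"] - l["II"])) < 1e-9
    assert np.max(np.abs(l["aVR"] + l["aVL"] + l["aVF"])) < 1e-9


def test_synth_qrs_deterministic():
    a = synth_qrs(width=70.0, axis=30.0, seed=7)
    b = synth_qrs(width=70.0, axis=30.0, seed=7)
    for k in LEAD_NAMES:
        assert np.array_equal(a.leads[k], b.leads[k])


# ---------------------------------------------------------------------------
# classification on constructed biomarker sets


def _mk_metrics(**kw):
    base = dict(r_amplitude=1.0, s_amplitude=0.0, time_to_r_peak=30.0,
                intrinsicoid=25.0, s_duration=0.0, notch_count=0, pattern="R")
    base.update(kw)
    return LeadMetrics(**base)


def _mk_bm(width, axis, late_axis, overrides):
    per_lead = {k: _mk_metrics() for k in LEAD_NAMES}
    for k, kw in overrides.items():
        per_lead[k] = _mk_metrics(**kw)
    return QRSBiomarkers(onset=10.0, offset=10.0 + width, axis=axis,
                         late_axis=late_axis, per_lead=per_lead)


def test_classify_normal():
    bm = _mk_bm(70.0, 60.0, 55.0, {})
    assert classify_conduction(bm) == {"NORMAL"}


def test_classify_lafb_constructed():
    rs = dict(pattern="RS", s_amplitude=0.5)
    bm = _mk_bm(90.0, -40.0, -50.0, {
        "aVL": dict(pattern="qR"),
        "II": dict(pattern="RS", r_amplitude=1.0, s_amplitude=0.4),
        "III": dict(pattern="RS", r_amplitude=0.6, s_amplitude=0.9),
        "aVF": rs,
    })
    assert "LAFB" in classify_conduction(bm)


def test_classify_lbbb_constructed():
    bm = _mk_bm(130.0, -10.0, -40.0, {
        "V1": dict(pattern="QS", r_amplitude=0.0, s_amplitude=1.5),
        "V6": dict(pattern="R", notch_count=1),
    })
    assert classify_conduction(bm) == {"LBBB"}


def test_classify_rbbb_constructed():
    bm = _mk_bm(130.0, 80.0, 140.0, {
        "V1": dict(pattern="rSR"),
        "I": dict(pattern="Rs", s_duration=50.0, s_amplitude=0.3),
        "V6": dict(pattern="Rs", s_duration=55.0, s_amplitude=0.4),
    })
    assert classify_conduction(bm) == {"RBBB"}


def test_classify_lpfb_constructed():
    bm = _mk_bm(100.0, 95.0, 110.0, {
        "I": dict(pattern="RS", s_amplitude=0.5),
        "aVL": dict(pattern="Rs", s_amplitude=0.4),
        "III": dict(pattern="qR"),
        "aVF": dict(pattern="qR"),
        **{f"V{i}": dict(pattern="RS", s_amplitude=0.5) for i in range(1, 7)},
    })
    assert classify_conduction(bm) == {"LPFB"}


def test_amplitude_scaling_leaves_shape_metrics_invariant(baseline_ecg):
    bm1 = compute_biomarkers(baseline_ecg)
    scaled = ECG12(
        time=baseline_ecg.time,
        leads={k: 3.0 * v for k, v in baseline_ecg.leads.items()},
        fs=baseline_ecg.fs,
        electrode_potentials=baseline_ecg.electrode_potentials,
        calibration=baseline_ecg.calibration,
    )
    bm2 = compute_biomarkers(scaled)
    assert bm2.width == bm1.width
    assert bm2.axis == pytest.approx(bm1.axis, abs=1e-9)
    for k in LEAD_NAMES:
        assert bm2.per_lead[k].pattern == bm1.per_lead[k].pattern
        assert bm2.per_lead[k].r_amplitude == pytest.approx(
            3.0 * bm1.per_lead[k].r_amplitude, rel=1e-9
        )
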