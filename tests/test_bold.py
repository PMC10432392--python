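"""Paradigm arithmetic, HRF shape, concentration response, nostril
scenarios and full-run simulation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spenfmri import bold_experiment as be
from spenfmri import activation_analysis as aa
from tests.conftest import small_params


def test_default_paradigm_arithmetic():
    p = be.build_paradigm()
    assert p.onsets_s[0] == 120.0
    assert int(p.onsets_s[0] / p.volume_interval_s) == 60  # first onset volume
    assert p.n_events * p.odor_s == 260.0                  # total odor-on time
    assert p.duration_s == 1400.0                          # 700 x 2 s
    assert abs(p.duration_s / 60.0 - 23.0) < 0.5           # ~23 min


def test_paradigm_validation():
    with pytest.raises(ValueError):
        be.build_paradigm(n_volumes=20)          # shorter than one event
    with pytest.raises(ValueError):
        be.build_paradigm(n_volumes=2000)        # extends past the paradigm
    with pytest.raises(ValueError):
        be.build_paradigm(odor_s=-1.0)


def test_single_immediate_block_boxcar_mass():
    p = be.build_paradigm(air_s=0.0, odor_s=26.0, n_events=1, n_volumes=20,
                          onset_ramp_s=1e-9)
    box = p.boxcar(p.volume_times_s)
    assert box.sum() == pytest.approx(26.0 / 2.0, abs=1.5)


def test_onsets_strictly_increasing_and_spaced():
    p = be.build_paradigm()
    assert np.all(np.diff(p.onsets_s) == 146.0)


# --- HRF ----------------------------------------------------------------


def test_hrf_zero_at_origin_and_single_sign_change():
    t = np.linspace(0, 40, 8001)
    h = be.hrf(t)
    assert be.hrf(0.0) == 0.0
    assert np.trapezoid(h, t) > 0
    signs = np.sign(h[np.abs(h) > 1e-12 * np.abs(h).max()])
    assert (np.diff(signs) != 0).sum() == 1  # peak then one undershoot


def test_hrf_peak_near_canonical_delay():
    t = np.linspace(0, 32, 3201)
    assert abs(t[np.argmax(be.hrf(t))] - 5.0) < 1.5  # mode of gamma(6,1)


def test_hrf_rejects_bad_shape():
    with pytest.raises(ValueError):
        be.hrf(1.0, be.HrfParams(peak_delay_s=-1.0))
    with pytest.raises(ValueError):
        be.hrf(-0.5)


def test_hrf_matches_independent_spm_kernel():
    """Dual-route check: the double-gamma kernel equals nilearn's SPM HRF
    (same delay/undershoot/ratio parameters) after accounting for
    nilearn's one-sample onset shift and sum-normalisation."""
    from nilearn.glm.first_level.hemodynamic_models import spm_hrf

    dt = 0.1
    t = np.linspace(0, 32, 320)  # nilearn's internal grid for t_r = dt
    ours = be.hrf(np.clip(t - dt, 0, None), be.HrfParams(ratio=0.167))
    theirs = spm_hrf(dt, oversampling=1, time_length=32)
    assert np.abs(ours / ours.sum() - theirs).max() < 1e-12 * np.abs(theirs).max()


def test_boxcar_convolution_peak_timing():
    """The convolved 26 s block peaks after onset but before the block end
    plus the undershoot span."""
    p = be.build_paradigm(air_s=120, odor_s=26, n_events=1, n_volumes=100)
    reg = be.task_regressor(p)
    t = p.volume_times_s
    t_peak = t[np.argmax(reg)]
    assert 120.0 < t_peak < 120.0 + 26.0 + 32.0


# --- concentration ------------------------------------------------------


def test_hill_midpoint_and_zero():
    m = be.ConcModel()
    assert be.concentration_amplitude(0.0, m) == 0.0
    assert be.concentration_amplitude(m.c50_ppm, m) == pytest.approx(m.max_scale / 2)
    with pytest.raises(ValueError):
        be.concentration_amplitude(-5.0, m)


def test_concentration_saturates_over_study_grid():
    m = be.ConcModel()
    scales = [be.concentration_amplitude(c, m) for c in (60, 300, 500, 700)]
    assert all(b > a for a, b in zip(scales, scales[1:]))  # monotone
    assert scales[3] / scales[1] < 1.25                    # saturation
    assert scales[0] > 0.4                                 # 60 ppm already strong


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    c1=st.floats(0.0, 1000.0),
    c2=st.floats(0.0, 1000.0),
    h=st.floats(0.5, 3.0),
)
def test_hill_monotone_and_bounded(c1, c2, h):
    m = be.ConcModel(hill=h)
    lo, hi = sorted((c1, c2))
    a, b = be.concentration_amplitude(lo, m), be.concentration_amplitude(hi, m)
    assert 0.0 <= a <= b <= m.max_scale


# --- nostril / lateralization ------------------------------------------


def test_nostril_scenarios(small_phantom):
    base = be.BoldModel()
    assert be.nostril_scenario(base, "none") == base
    left_plugged = be.nostril_scenario(base, "left")
    assert left_plugged.lateralization == "right_only"
    w = be.activation_weights(left_plugged, small_phantom)
    assert w[small_phantom.masks["ob_left"]].max() == 0.0
    assert w[small_phantom.masks["ob_right"]].max() > 0.0
    with pytest.raises(ValueError):
        be.nostril_scenario(left_plugged, "right")


def test_activation_weights_missing_mask(small_phantom):
    bad = be.BoldModel(active_masks={"no_such_region": 1.0})
    with pytest.raises(ValueError):
        be.activation_weights(bad, small_phantom)


# --- simulated runs -----------------------------------------------------


def _noiseless(kind, small_phantom):
    return small_params(kind, small_phantom, noise_sigma=0.0)


def test_null_activation_gives_no_epoch_response(small_phantom, short_paradigm, small_sigma):
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    ds = be.simulate_run(
        small_phantom, params, short_paradigm, be.BoldModel(delta_r2star_hz=0.0), seed=5
    )
    roi = be.activation_weights(be.BoldModel(), small_phantom) > 0
    resp = aa.percent_change(aa.roi_timecourse(ds, roi), short_paradigm)
    odor = (resp.t_s >= 6) & (resp.t_s <= 30)
    per_epoch = resp.per_epoch_pct[:, odor].mean(axis=1)
    t_stat = stats.ttest_1samp(per_epoch, 0.0).statistic
    assert abs(t_stat) < 3.0


def test_pr_response_exceeds_fr(small_phantom, short_paradigm):
    bold = be.BoldModel()
    roi = be.activation_weights(bold, small_phantom) > 0
    peaks = {}
    for kind in ("FR_SPEN", "PR_SPEN", "GE_EPI"):
        ds = be.simulate_run(
            small_phantom, _noiseless(kind, small_phantom), short_paradigm, bold,
            nuisance=be.Nuisance(drift_linear_pct=0, drift_cos_pct=0), seed=0,
            lam=1e-9 if kind.endswith("SPEN") else None,
        )
        peaks[kind] = aa.percent_change(aa.roi_timecourse(ds, roi), short_paradigm).peak_pct
    # contrast mechanism ordering at fixed dR2*
    assert peaks["GE_EPI"] >= peaks["PR_SPEN"] >= peaks["FR_SPEN"] > 0


def test_injected_five_percent_recovered_noiseless(small_phantom, short_paradigm):
    """Self-consistency against the closed-form signal model: choose dR2*
    so that exp(a*(f*TE + (1-f)*Delta)) - 1 = 5% and recover 5 +/- 0.2."""
    f, te, delta = 0.4, 0.026, 0.004
    conc = be.concentration_amplitude(450.0)
    a = np.log(1.05) / (f * te + (1 - f) * delta) / conc
    bold = be.BoldModel(delta_r2star_hz=a)
    params = _noiseless("PR_SPEN", small_phantom)
    ds = be.simulate_run(
        small_phantom, params, short_paradigm, bold,
        nuisance=be.Nuisance(drift_linear_pct=0, drift_cos_pct=0), seed=0, lam=1e-9,
    )
    roi = be.activation_weights(bold, small_phantom) > 0
    resp = aa.percent_change(aa.roi_timecourse(ds, roi), short_paradigm)
    assert resp.peak_pct == pytest.approx(5.0, abs=0.2)


def test_run_seed_determinism(small_phantom, short_paradigm, small_sigma):
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    a = be.simulate_run(small_phantom, params, short_paradigm, be.BoldModel(), seed=11)
    b = be.simulate_run(small_phantom, params, short_paradigm, be.BoldModel(), seed=11)
    assert np.array_equal(a.volumes, b.volumes)


def test_concentration_series_monotone_saturating(small_phantom, short_paradigm):
    """Measured ROI amplitude is nondecreasing over 60..700 ppm and the
    300->700 increment is smaller than the 0->60 one."""
    peaks = []
    roi = be.activation_weights(be.BoldModel(), small_phantom) > 0
    for c in (60.0, 300.0, 500.0, 700.0):
        bold = be.BoldModel(c_ppm=c)
        ds = be.simulate_run(
            small_phantom, _noiseless("PR_SPEN", small_phantom), short_paradigm, bold,
            nuisance=be.Nuisance(drift_linear_pct=0, drift_cos_pct=0), seed=0, lam=1e-9,
        )
        peaks.append(aa.percent_change(aa.roi_timecourse(ds, roi), short_paradigm).peak_pct)
    assert all(b >= a - 1e-6 for a, b in zip(peaks, peaks[1:]))
    assert (peaks[3] - peaks[1]) < peaks[0]  # 300->700 smaller than 0->60


def test_run_rejects_mismatched_volume_interval(small_phantom):
    par = be.build_paradigm(air_s=60, odor_s=26, n_events=2, volume_interval_s=1.0,
                            n_volumes=172)
    with pytest.raises(ValueError):
        be.simulate_run(small_phantom, _noiseless("PR_SPEN", small_phantom), par,
                        be.BoldModel())
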