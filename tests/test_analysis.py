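"""GLM calibration and recovery, second-level statistics, permutation
inference, QC screening."""

import numpy as np
import pytest
from scipy import stats

from spenfmri import activation_analysis as aa
from spenfmri import bold_experiment as be
from spenfmri import metrics as mt
from tests.conftest import small_params


def _noise_dataset(paradigm, shape=(50, 40), seed=0, baseline=100.0):
    rng = np.random.default_rng(seed)
    vols = baseline + rng.standard_normal(shape + (paradigm.n_volumes,))
    return be.TimeSeriesDataset(
        volumes=vols, volume_interval_s=paradigm.volume_interval_s, paradigm=paradigm
    )


# --- ROI time courses and percent change --------------------------------


def test_roi_timecourse_identities(short_run_pr, small_phantom):
    ds = short_run_pr
    left = small_phantom.masks["ob_left"]
    right = small_phantom.masks["ob_right"]
    both = left | right
    sl = aa.roi_timecourse(ds, left)
    sr = aa.roi_timecourse(ds, right)
    sb = aa.roi_timecourse(ds, both)
    nl, nr = left.sum(), right.sum()
    assert np.allclose(sb, (nl * sl + nr * sr) / (nl + nr))
    single = np.zeros_like(left)
    single[24, 18] = True
    assert np.allclose(aa.roi_timecourse(ds, single), ds.volumes[24, 18])
    with pytest.raises(ValueError):
        aa.roi_timecourse(ds, np.zeros_like(left))


def test_percent_change_constant_series_is_zero(short_paradigm):
    series = np.full(short_paradigm.n_volumes, 7.3)
    resp = aa.percent_change(series, short_paradigm)
    assert np.abs(resp.mean_pct).max() < 1e-10
    assert abs(resp.peak_pct) < 1e-10


def test_percent_change_recovers_injected_response():
    paradigm = be.build_paradigm()
    reg = be.task_regressor(paradigm)
    series = 100.0 * (1.0 + 0.05 * reg)
    resp = aa.percent_change(series, paradigm)
    assert 4.5 <= resp.peak_pct <= 5.5


def test_percent_change_cancels_pure_drift():
    """A 3%-per-run linear drift with no task structure leaves < 0.5%
    apparent response after epoch averaging over 10 epochs."""
    paradigm = be.build_paradigm()
    t = paradigm.volume_times_s
    series = 100.0 * (1.0 + 0.03 * t / t[-1])
    resp = aa.percent_change(series, paradigm)
    assert abs(resp.peak_pct) < 0.5


# --- smoothing ----------------------------------------------------------


def test_smoothing_identity_and_mass_conservation():
    rng = np.random.default_rng(0)
    img = np.zeros((64, 64))
    img[24:40, 24:40] = rng.uniform(1, 2, (16, 16))
    pix = (0.1, 0.1)
    assert np.array_equal(aa.smooth_gaussian(img, 0.0, pix), img)
    sm = aa.smooth_gaussian(img, 0.5, pix)
    assert abs(sm.sum() / img.sum() - 1) < 1e-3


def test_smoothing_delta_fwhm_matches():
    img = np.zeros((81, 81))
    img[40, 40] = 1.0
    pix = (0.1, 0.1)
    fwhm = 0.8
    sm = aa.smooth_gaussian(img, fwhm, pix)
    profile = sm[40]
    half = profile.max() / 2
    above = np.where(profile >= half)[0]
    measured = (above[-1] - above[0] + 1) * pix[1]
    assert abs(measured - fwhm) <= 0.05 + pix[1] / 2


def test_smoothing_warns_when_kernel_large():
    img = np.zeros((40, 30))
    with pytest.warns(RuntimeWarning):
        aa.smooth_gaussian(img, 2.5, (0.1, 0.1))
    with pytest.raises(ValueError):
        aa.smooth_gaussian(img, -1.0, (0.1, 0.1))


# --- design matrix and first level --------------------------------------


def test_design_matrix_columns_and_rank(short_paradigm):
    x = aa.build_design_matrix(short_paradigm)
    assert x.names[0] == "task"
    assert {"task_tmod1", "task_tmod2", "intercept"} <= set(x.names)
    assert any(n.startswith("drift_cos") for n in x.names)
    assert np.isclose(np.abs(x.matrix[:, 0]).max(), 1.0)  # max-normalised
    assert np.linalg.matrix_rank(x.matrix) == x.n_columns


def test_design_matrix_rank_deficiency_named():
    p = be.build_paradigm(air_s=10, odor_s=10, n_events=2, volume_interval_s=2.0,
                          n_volumes=20)
    with pytest.raises(ValueError, match="rank deficient"):
        aa.build_design_matrix(p, drift_cutoff_s=3.0)


def test_glm_type_one_error_calibrated(short_paradigm):
    """Null data: suprathreshold fraction at p = 0.001 inside the binomial
    99% interval over 20k pixel tests."""
    ds = _noise_dataset(short_paradigm, shape=(160, 125), seed=3)
    amap = aa.glm_first_level(ds, aa.build_design_matrix(short_paradigm))
    n = amap.stat.size
    k = int(amap.mask_supra.sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.001)
    assert lo <= k <= hi, f"{k} outside [{lo}, {hi}] of Binomial({n}, 0.001)"


def test_glm_recovers_injected_activation(short_run_pr, small_phantom):
    amap = aa.glm_first_level(short_run_pr, aa.build_design_matrix(short_run_pr.paradigm))
    roi = be.activation_weights(be.BoldModel(), small_phantom) > 0
    assert mt.dice(amap.mask_supra, roi) >= 0.6


def test_glm_degenerate_noiseless_pixel_sentinel(short_paradigm):
    reg = be.task_regressor(short_paradigm)
    vols = np.tile(100.0 + 5.0 * reg, (8, 6, 1))
    ds = be.TimeSeriesDataset(volumes=vols, volume_interval_s=2.0, paradigm=short_paradigm)
    amap = aa.glm_first_level(ds, aa.build_design_matrix(short_paradigm))
    assert np.all(np.isinf(amap.stat))
    assert np.all(amap.stat > 0)


def test_glm_rejects_mismatched_design(short_run_pr):
    bad = aa.build_design_matrix(be.build_paradigm(air_s=60, odor_s=26, n_events=2,
                                                   n_volumes=90))
    with pytest.raises(ValueError):
        aa.glm_first_level(short_run_pr, bad)


# --- second level -------------------------------------------------------


def _random_maps(n, shape=(20, 16), seed=0, mean=0.0):
    rng = np.random.default_rng(seed)
    return [mean + rng.standard_normal(shape) for _ in range(n)]


def test_identical_groups_give_zero_t():
    maps = _random_maps(3, seed=1)
    amap = aa.second_level_ttest(maps, [m.copy() for m in maps])
    assert np.abs(amap.stat).max() == 0.0


def test_second_level_null_calibration():
    a = _random_maps(8, shape=(40, 30), seed=2)
    b = _random_maps(8, shape=(40, 30), seed=3)
    amap = aa.second_level_ttest(a, b, p_threshold=0.05)
    frac = amap.mask_supra.mean()
    assert abs(frac - 0.05) < 0.02


def test_second_level_matches_closed_form_shift():
    """Group B = A + delta in a region with equal variances: the expected
    t equals delta / (s sqrt(1/nA + 1/nB))."""
    rng = np.random.default_rng(4)
    shape, na, nb, delta, s = (30, 24), 6, 6, 2.0, 1.0
    region = np.zeros(shape, bool)
    region[10:20, 8:16] = True
    a = [rng.normal(0, s, shape) for _ in range(na)]
    b = [m + delta * region for m in (rng.normal(0, s, shape) for _ in range(nb))]
    amap = aa.second_level_ttest(b, a)
    expected = delta / (s * np.sqrt(1 / na + 1 / nb))
    measured = amap.stat[region].mean()
    # mean of t over many pixels concentrates near the noncentrality
    assert abs(measured - expected) / expected < 0.25
    assert np.abs(amap.stat[~region].mean()) < 0.5


def test_t_squared_equals_f_for_two_groups():
    a = _random_maps(4, seed=5)
    b = _random_maps(5, seed=6, mean=0.3)
    t_map = aa.second_level_ttest(a, b)
    f_map = aa.second_level_anova([a, b])
    assert np.allclose(f_map.stat, t_map.stat**2, rtol=1e-10, atol=1e-10)
    assert f_map.df == (1, 7)


def test_anova_identical_groups_zero_f():
    maps = _random_maps(3, seed=7)
    amap = aa.second_level_anova([maps, [m.copy() for m in maps]])
    assert np.abs(amap.stat).max() < 1e-9


def test_second_level_invariant_to_common_rescaling():
    a = _random_maps(4, seed=8)
    b = _random_maps(4, seed=9, mean=0.5)
    t1 = aa.second_level_ttest(a, b).stat
    t2 = aa.second_level_ttest([3.0 * m for m in a], [3.0 * m for m in b]).stat
    assert np.allclose(t1, t2)


def test_anova_detects_shifted_group_with_power():
    """Three groups of 5, one shifted by 3 sigma in a region: empirical
    power at p = 0.01 matches the noncentral-F prediction (93.8%) and
    exceeds 80%."""
    rng = np.random.default_rng(10)
    shape = (30, 24)
    region = np.zeros(shape, bool)
    region[5:25, 6:18] = True
    delta, n = 3.0, 5
    g1 = [rng.standard_normal(shape) for _ in range(n)]
    g2 = [rng.standard_normal(shape) for _ in range(n)]
    g3 = [rng.standard_normal(shape) + delta * region for _ in range(n)]
    amap = aa.second_level_anova([g1, g2, g3])
    crit = stats.f.isf(0.01, *amap.df)
    power = (amap.stat[region] > crit).mean()
    lam = n * delta**2 * 2.0 / 3.0  # noncentrality of the shifted design
    predicted = stats.ncf.sf(crit, *amap.df, lam)
    assert power >= 0.8
    assert abs(power - predicted) < 0.1


# --- permutation inference ---------------------------------------------


def test_permutation_three_vs_three_exhaustive():
    a = _random_maps(3, seed=11)
    b = _random_maps(3, seed=12, mean=1.0)
    amap = aa.permutation_map([a, b], n_perm=1000, seed=0)
    assert amap.exhaustive and amap.n_permutations == 20
    multiples = amap.p_values * 20
    assert np.allclose(multiples, np.round(multiples))


def test_permutation_fwe_calibrated_under_null():
    """P(min corrected p <= 0.05) across replicate null experiments is
    close to 0.05."""
    rng = np.random.default_rng(13)
    hits = 0
    reps = 200
    for _ in range(reps):
        a = [rng.standard_normal((10, 8)) for _ in range(4)]
        b = [rng.standard_normal((10, 8)) for _ in range(4)]
        amap = aa.permutation_map([a, b], n_perm=200, seed=1)
        hits += amap.p_values.min() <= 0.05
    rate = hits / reps
    lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05) / reps
    assert lo <= rate <= hi, f"FWE rate {rate} outside [{lo}, {hi}]"


def test_permutation_concordant_with_parametric_on_strong_effect():
    rng = np.random.default_rng(14)
    shape = (24, 20)
    region = np.zeros(shape, bool)
    region[8:16, 6:14] = True
    a = [rng.standard_normal(shape) for _ in range(6)]
    b = [rng.standard_normal(shape) + 4.0 * region for _ in range(6)]
    par = aa.second_level_ttest(b, a, p_threshold=0.001)
    nonpar = aa.permutation_map([b, a], n_perm=924, seed=2, p_threshold=0.05)
    assert mt.dice(par.mask_supra, nonpar.mask_supra) >= 0.7


def test_permutation_input_validation():
    a = _random_maps(3, seed=15)
    with pytest.raises(ValueError):
        aa.permutation_map([a], n_perm=200)
    with pytest.raises(ValueError):
        aa.permutation_map([a, a], n_perm=10)


# --- QC -----------------------------------------------------------------


def test_qc_keeps_clean_run(short_run_pr):
    report = aa.qc_screen(short_run_pr)
    assert report.keep, report.reasons


def test_qc_discards_motion_spikes(small_phantom, short_paradigm, small_sigma):
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    nm = be.Nuisance(motion_spike_rate=10 / 180, motion_amp_px=2.0)
    ds = be.simulate_run(small_phantom, params, short_paradigm, be.BoldModel(),
                         nuisance=nm, seed=2)
    report = aa.qc_screen(ds)
    assert not report.keep and "motion" in report.reasons


def test_qc_discards_null_run_via_consistency(small_phantom, short_paradigm, small_sigma):
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    ds = be.simulate_run(small_phantom, params, short_paradigm,
                         be.BoldModel(delta_r2star_hz=0.0), seed=3)
    report = aa.qc_screen(ds)
    assert not report.keep and "consistency" in report.reasons
    without = aa.qc_screen(ds, require_consistency=False)
    assert "consistency" not in without.reasons


def test_qc_short_run_reports_missing_consistency(small_phantom, small_sigma):
    par = be.build_paradigm(air_s=60, odor_s=26, n_events=1, n_volumes=60)
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    ds = be.simulate_run(small_phantom, params, par, be.BoldModel(), seed=4)
    report = aa.qc_screen(ds)
    assert report.metrics["epoch_consistency_r"] is None
    assert "consistency_unavailable" in report.reasons


# --- lateralization recovery -------------------------------------------


def test_plugged_left_localises_to_right_hemisphere(small_phantom, short_paradigm, small_sigma):
    bold = be.nostril_scenario(be.BoldModel(), "left")
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    ds = be.simulate_run(small_phantom, params, short_paradigm, bold, seed=6)
    amap = aa.glm_first_level(ds, aa.build_design_matrix(short_paradigm))
    supra = amap.mask_supra
    assert supra.sum() > 10
    frac_right = (supra & small_phantom.masks["ob_right"]).sum() / supra.sum()
    assert frac_right >= 0.9
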