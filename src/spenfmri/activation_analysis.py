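"""Activation mapping and quality control.

The chain mirrors standard block-design fMRI practice: raw ROI time
courses inspected without statistics, Gaussian smoothing, a first-level
general linear model per pixel (canonical HRF regressor without
derivatives, second-order time modulation of the task regressor, cosine
drift basis), uncorrected p < 0.001 thresholding by default with FDR and
permutation-based family-wise-error control available, and second-level
two-sample t / one-way ANOVA tests across runs with a nonparametric
max-statistic permutation analogue.  A QC screen reproduces the
raw-image discard criteria: evident motion, excessive baseline drift, or
inconsistent activation across epochs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .bold_experiment import HrfParams, Paradigm, TimeSeriesDataset, task_regressor

__all__ = [
    "DesignMatrix",
    "ActivationMap",
    "EpochResponse",
    "QcThresholds",
    "QcReport",
    "roi_timecourse",
    "percent_change",
    "smooth_gaussian",
    "build_design_matrix",
    "glm_first_level",
    "contrast_effect_map",
    "second_level_ttest",
    "second_level_anova",
    "permutation_map",
    "qc_screen",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# raw time-course inspection


def roi_timecourse(ds: TimeSeriesDataset, mask: np.ndarray) -> np.ndarray:
    """Per-volume mean intensity over a binary mask."""
    mask = np.asarray(mask, bool)
    if mask.shape != ds.volumes.shape[:2]:
        raise ValueError("mask grid does not match the dataset")
    if not mask.any():
        raise ValueError("mask is empty")
    return ds.volumes[mask].mean(axis=0)


@dataclass
class EpochResponse:
    """Stimulus-locked epoch average of a ROI series, in percent change
    from the pre-odor baseline."""

    t_s: np.ndarray
    mean_pct: np.ndarray
    per_epoch_pct: np.ndarray
    peak_pct: float
    n_epochs: int


def percent_change(
    series: np.ndarray,
    paradigm: Paradigm,
    baseline_s: float = 30.0,
    window_s: tuple[float, float] = (-20.0, 60.0),
) -> EpochResponse:
    """Epoch-averaged percent signal change.

    For each odor event the baseline is the mean over the last
    ``baseline_s`` seconds of the preceding air block; epochs are aligned
    at odor onset, expressed in percent of their own baseline, averaged,
    and the peak percent change after onset is reported.
    """
    series = np.asarray(series, float)
    vi = paradigm.volume_interval_s
    t = np.arange(len(series)) * vi
    rel = np.arange(window_s[0], window_s[1] + vi / 2, vi)
    curves = []
    for onset in paradigm.onsets_s:
        epoch_t = onset + rel
        if epoch_t[-1] > t[-1] + vi / 2:
            continue  # incomplete or truncated trailing epoch
        base_sel = (t >= onset - baseline_s) & (t < onset)
        if not base_sel.any():
            raise ValueError("empty baseline window before an odor onset")
        base = series[base_sel].mean()
        vals = np.interp(epoch_t, t, series)
        curves.append((vals / base - 1.0) * 100.0)
    if not curves:
        raise ValueError("no complete epochs within the series")
    per_epoch = np.asarray(curves)
    mean_curve = per_epoch.mean(axis=0)
    post = rel >= 0
    peak = float(mean_curve[post].max())
    return EpochResponse(
        t_s=rel,
        mean_pct=mean_curve,
        per_epoch_pct=per_epoch,
        peak_pct=peak,
        n_epochs=len(curves),
    )


def smooth_gaussian(
    data: np.ndarray, fwhm_mm: float, pixel_mm: tuple[float, float]
) -> np.ndarray:
    """In-plane Gaussian smoothing with the kernel width given as FWHM in
    mm (the study used 2.5 mm).  Accepts an image (x, y) or a run
    (x, y, t); a warning is emitted when the kernel exceeds a quarter of
    the image extent, as 2.5 mm is large relative to an olfactory bulb."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    extent = min(data.shape[0] * pixel_mm[0], data.shape[1] * pixel_mm[1])
    if fwhm_mm > 0.25 * extent:
        warnings.warn(
            f"smoothing FWHM {fwhm_mm} mm exceeds 25% of the image extent "
            f"({extent:.1f} mm)",
            RuntimeWarning,
        )
    sigma = (
        fwhm_mm * FWHM_TO_SIGMA / pixel_mm[0],
        fwhm_mm * FWHM_TO_SIGMA / pixel_mm[1],
    )
    if data.ndim == 2:
        return ndimage.gaussian_filter(data, sigma)
    return ndimage.gaussian_filter(data, sigma + (0.0,))


# ---------------------------------------------------------------------------
# first level


@dataclass
class DesignMatrix:
    """Named-column design: task regressor (max-normalised), optional
    second-order time modulation (task x t, task x t^2 with mean-centred
    time), a cosine drift basis, and an intercept."""

    matrix: np.ndarray
    names: list
    volume_times_s: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def contrast(self, name: str = "task") -> np.ndarray:
        c = np.zeros(self.n_columns)
        c[self.names.index(name)] = 1.0
        return c


def build_design_matrix(
    paradigm: Paradigm,
    hrf_params: HrfParams = HrfParams(),
    time_modulation: bool = True,
    drift_cutoff_s: float = 256.0,
) -> DesignMatrix:
    """Design matrix for one run.

    Drift is handled by discrete-cosine nuisance regressors up to
    ``1/drift_cutoff_s`` Hz (equivalent to high-pass filtering under OLS);
    time modulation adds the task regressor multiplied by mean-centred
    linear and quadratic time covariates, accounting for slow
    non-stationarity of the response amplitude.
    """
    t = paradigm.volume_times_s
    n = len(t)
    task = task_regressor(paradigm, hrf_params)
    cols = [task]
    names = ["task"]
    if time_modulation:
        tc = (t - t.mean()) / (t.max() - t.min())
        for power, nm in ((1, "task_tmod1"), (2, "task_tmod2")):
            col = task * tc**power
            cols.append(col - col.mean())
            names.append(nm)
    n_drift = int(np.floor(2.0 * n * paradigm.volume_interval_s / drift_cutoff_s))
    for k in range(1, n_drift + 1):
        cols.append(np.cos(np.pi * k * (np.arange(n) + 0.5) / n))
        names.append(f"drift_cos{k}")
    cols.append(np.ones(n))
    names.append("intercept")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")
    return DesignMatrix(matrix=x, names=names, volume_times_s=t)


@dataclass
class ActivationMap:
    """Statistical map with its degrees of freedom and threshold state."""

    stat: np.ndarray
    df: tuple
    kind: str  # "t" or "F"
    p_threshold: float = 0.001
    correction: str = "none"
    mask_supra: np.ndarray = None
    p_values: np.ndarray = None

    def __post_init__(self) -> None:
        if self.p_values is None:
            self.p_values = self._p_map()
        if self.mask_supra is None:
            self.threshold(self.p_threshold, self.correction)

    def _p_map(self) -> np.ndarray:
        if self.kind == "t":
            return 2.0 * stats.t.sf(np.abs(self.stat), self.df[0])
        return stats.f.sf(self.stat, self.df[0], self.df[1])

    def threshold(self, p: float, correction: str = "none") -> np.ndarray:
        """Set and return the suprathreshold mask at level ``p`` under
        ``correction`` in {none, fdr}.  Permutation maps already carry
        FWE-corrected p-values; threshold those with 'none'."""
        pv = self.p_values
        is_perm = "permutation-FWE" in (correction, self.correction)
        if correction == "fdr":
            from statsmodels.stats.multitest import multipletests

            rej = multipletests(pv.ravel(), alpha=p, method="fdr_bh")[0]
            mask = rej.reshape(pv.shape)
            self.correction = "fdr"
        elif correction in ("none", "permutation-FWE"):
            if is_perm:
                # attainable permutation p-values are multiples of
                # 1/#splits, so significance at level p uses <=
                mask = pv <= p
            else:
                mask = pv < p
                self.correction = correction
        else:
            raise ValueError("correction must be 'none' or 'fdr'")
        self.p_threshold = p
        self.mask_supra = mask
        return mask


def glm_first_level(
    ds: TimeSeriesDataset,
    design: DesignMatrix,
    contrast: np.ndarray | None = None,
    p_threshold: float = 0.001,
) -> ActivationMap:
    """Ordinary-least-squares GLM per pixel with a t contrast.

    t = c'b / sqrt(sigma^2 c'(X'X)^-1 c), df = n_volumes - rank(X).
    Pixels with exactly zero residual variance (noiseless degenerate
    fits) are flagged with an infinite-t sentinel rather than raising.
    """
    x = design.matrix
    if x.shape[0] != ds.n_volumes:
        raise ValueError("design rows must equal the number of volumes")
    contrast = design.contrast("task") if contrast is None else np.asarray(contrast, float)
    if contrast.shape != (x.shape[1],):
        raise ValueError("contrast length must equal the number of columns")
    nx, ny, nt = ds.volumes.shape
    y = ds.volumes.reshape(nx * ny, nt).T  # (t, pixels)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = nt - np.linalg.matrix_rank(x)
    sigma2 = (resid**2).sum(axis=0) / df
    var_c = float(contrast @ xtx_inv @ contrast)
    eff = contrast @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = eff / np.sqrt(sigma2 * var_c)
    # zero residual variance up to roundoff relative to the data scale
    degenerate = sigma2 <= 1e-20 * (y**2).mean(axis=0)
    if degenerate.any():
        t_vals[degenerate] = np.sign(eff[degenerate]) * np.inf
        t_vals[degenerate & (eff == 0)] = 0.0
    return ActivationMap(
        stat=t_vals.reshape(nx, ny), df=(df,), kind="t", p_threshold=p_threshold
    )


def contrast_effect_map(
    ds: TimeSeriesDataset,
    design: DesignMatrix,
    contrast: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel contrast of parameter estimates (the first-level effect
    image passed to second-level analyses)."""
    x = design.matrix
    contrast = design.contrast("task") if contrast is None else np.asarray(contrast, float)
    nx, ny, nt = ds.volumes.shape
    y = ds.volumes.reshape(nx * ny, nt).T
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    return (contrast @ beta).reshape(nx, ny)


# ---------------------------------------------------------------------------
# second level


def _stack_maps(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, float) for m in maps], axis=0)
    if arr.ndim != 3:
        raise ValueError("maps must be 2D images")
    return arr


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise pooled-variance two-sample t (A minus B)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def second_level_ttest(maps_a, maps_b, p_threshold: float = 0.05) -> ActivationMap:
    """Pixelwise two-sample t-test between groups of first-level maps
    (signed: positive and negative t both meaningful)."""
    a, b = _stack_maps(maps_a), _stack_maps(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share one grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 maps")
    t = _two_sample_t(a, b)
    return ActivationMap(
        stat=t, df=(a.shape[0] + b.shape[0] - 2,), kind="t", p_threshold=p_threshold
    )


def second_level_anova(groups, p_threshold: float = 0.05) -> ActivationMap:
    """Pixelwise one-way ANOVA across k groups of maps; F with
    (k-1, N-k) degrees of freedom."""
    gs = [_stack_maps(g) for g in groups]
    if len(gs) < 2 or any(g.shape[0] < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 maps each")
    shape = gs[0].shape[1:]
    if any(g.shape[1:] != shape for g in gs):
        raise ValueError("groups must share one grid")
    k = len(gs)
    n_tot = sum(g.shape[0] for g in gs)
    grand = np.concatenate(gs, axis=0).mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in gs)
    df1, df2 = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[~np.isfinite(f)] = 0.0
    return ActivationMap(stat=f, df=(df1, df2), kind="F", p_threshold=p_threshold)


def permutation_map(
    groups,
    n_perm: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
) -> ActivationMap:
    """Nonparametric two-group inference with max-statistic family-wise
    error control (the SnPM-style analogue of the two-sample t-test).

    Group labels are permuted; when the number of distinct label splits
    is within ``n_perm`` the enumeration is exhaustive (and corrected
    p-values are multiples of 1/#splits), otherwise ``n_perm`` random
    permutations including the observed labelling are used.  The
    returned map carries FWE-corrected p-values.
    """
    if len(groups) != 2:
        raise ValueError("permutation_map expects exactly two groups")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, b = _stack_maps(groups[0]), _stack_maps(groups[1])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share one grid")
    pooled = np.concatenate([a, b], axis=0)
    n, na = pooled.shape[0], a.shape[0]
    t_obs = _two_sample_t(a, b)

    n_exhaustive = math.comb(n, na)
    exhaustive = n_exhaustive <= n_perm
    if exhaustive:
        splits = list(itertools.combinations(range(n), na))
    else:
        rng = np.random.default_rng(seed)
        splits = [tuple(range(na))]  # observed labelling included
        while len(splits) < n_perm:
            perm = rng.permutation(n)
            splits.append(tuple(sorted(perm[:na])))
    max_null = np.empty(len(splits))
    for i, idx_a in enumerate(splits):
        sel = np.zeros(n, bool)
        sel[list(idx_a)] = True
        max_null[i] = np.abs(_two_sample_t(pooled[sel], pooled[~sel])).max()
    p_fwe = (max_null[None, None, :] >= np.abs(t_obs)[:, :, None]).mean(axis=2)
    amap = ActivationMap(
        stat=t_obs,
        df=(n - 2,),
        kind="t",
        p_threshold=p_threshold,
        correction="permutation-FWE",
        p_values=p_fwe,
        mask_supra=p_fwe <= p_threshold,
    )
    amap.n_permutations = len(splits)
    amap.exhaustive = exhaustive
    amap.max_null = max_null
    return amap


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QcThresholds:
    """Discard rules: too many high-z frame-to-frame intensity jumps or
    center-of-mass jumps (motion), excessive linear drift, or poor
    split-half epoch consistency."""

    motion_z: float = 4.0
    motion_min_frac: float = 0.01  # spikes must also exceed 1% of the mean
    motion_max_volumes: int = 3
    motion_com_px: float = 1.0
    drift_pct: float = 3.0
    consistency_r: float = 0.3


@dataclass
class QcReport:
    keep: bool
    metrics: dict
    reasons: list


def qc_screen(
    ds: TimeSeriesDataset,
    mask: np.ndarray | None = None,
    thresholds: QcThresholds = QcThresholds(),
    require_consistency: bool = True,
) -> QcReport:
    """Raw-image screening mirroring by-eye run rejection.

    Computes (a) frame-to-frame global-intensity z-scores and
    center-of-mass translation estimates, (b) fitted linear drift in
    percent per run, (c) split-half (odd vs even epochs) correlation of
    the epoch-averaged ROI response.  The run is kept only if every
    criterion passes; all metrics are reported regardless.  Runs shorter
    than two complete epochs report the consistency metric as missing.
    """
    vols = ds.volumes
    if mask is None:
        mean_img = vols.mean(axis=2)
        mask = mean_img > 0.2 * np.percentile(mean_img, 95)
    g = vols[mask].mean(axis=0)
    # spike score: deviation from a running median, so smooth task-driven
    # intensity changes are tracked while single-volume jumps stand out
    resid = g - ndimage.median_filter(g, size=5, mode="nearest")
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    z = (resid - np.median(resid)) / max(mad, 1e-30)
    spike = (np.abs(z) > thresholds.motion_z) & (
        np.abs(resid) > thresholds.motion_min_frac * np.median(g)
    )
    n_motion = int(spike.sum())

    nx, ny, nt = vols.shape
    xi = np.arange(nx)
    yi = np.arange(ny)
    w = vols * mask[:, :, None]
    tot = w.sum(axis=(0, 1))
    com_x = (w.sum(axis=1) * xi[:, None]).sum(axis=0) / tot
    com_y = (w.sum(axis=0) * yi[:, None]).sum(axis=0) / tot
    com_dev = np.hypot(com_x - np.median(com_x), com_y - np.median(com_y))
    n_com = int((com_dev > thresholds.motion_com_px).sum())

    t = np.arange(nt) * ds.volume_interval_s
    slope = np.polyfit(t, g / g.mean(), 1)[0]
    drift_pct = float(slope * t[-1] * 100.0)

    consistency = None
    n_complete = int(np.sum(ds.paradigm.onsets_s + 60.0 <= t[-1] + ds.volume_interval_s / 2))
    if n_complete >= 2:
        resp = percent_change(g, ds.paradigm)
        odd = resp.per_epoch_pct[0::2].mean(axis=0)
        even = resp.per_epoch_pct[1::2].mean(axis=0)
        # remove per-curve linear trends so slow drift does not mimic a
        # reproducible response
        tt = resp.t_s
        odd = odd - np.polyval(np.polyfit(tt, odd, 1), tt)
        even = even - np.polyval(np.polyfit(tt, even, 1), tt)
        consistency = float(np.corrcoef(odd, even)[0, 1])

    reasons = []
    if n_motion > thresholds.motion_max_volumes or n_com > thresholds.motion_max_volumes:
        reasons.append("motion")
    if abs(drift_pct) > thresholds.drift_pct:
        reasons.append("drift")
    if require_consistency:
        if consistency is None:
            reasons.append("consistency_unavailable")
        elif consistency < thresholds.consistency_r:
            reasons.append("consistency")
    metrics = {
        "motion_n_highz": n_motion,
        "motion_n_com": n_com,
        "motion_max_z": float(np.abs(z).max()) if len(z) else 0.0,
        "motion_max_com_px": float(com_dev.max()),
        "drift_pct_per_run": drift_pct,
        "epoch_consistency_r": consistency,
    }
    return QcReport(keep=not reasons, metrics=metrics, reasons=reasons)
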