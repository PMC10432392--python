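"""Configuration, file formats and orchestration.

Formats: NIfTI for images/volumes (via nibabel), TSV for paradigm events,
CSV for metric tables, YAML for configuration and provenance.  All
randomness in a run derives from one integer seed expanded with
``numpy.random.SeedSequence`` (documented children: 0 phantom texture,
1 acquisition noise, 2 noise calibration).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import metrics as mt
from .bold_experiment import (
    BoldModel,
    ConcModel,
    HrfParams,
    Nuisance,
    Paradigm,
    TimeSeriesDataset,
    build_paradigm,
    nostril_scenario,
    simulate_run,
    activation_weights,
)
from .forward_sim import acquire, calibrate_noise
from .phantom import PhantomMap, air_interface_field, make_ob_phantom
from .recon import reconstruct
from .sequences import SequenceParams, default_params

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "split_seed",
    "build_phantom",
    "build_sequence",
    "build_bold",
    "save_phantom",
    "load_phantom",
    "save_run",
    "load_run",
    "save_map_nifti",
    "run_simulate",
    "run_analyze",
    "run_compare_sequences",
    "run_calibrate_noise",
]


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Full default run configuration (the study conditions)."""
    return {
        "seed": 0,
        "phantom": {"nx": 96, "ny": 70, "pixel_mm": [0.1083, 0.1071], "air_field": True},
        "sequence": {"kind": "PR_SPEN", "noise_sigma": None},  # None -> calibrate
        "target_snr": 30.0,
        "paradigm": {
            "air_s": 120.0,
            "odor_s": 26.0,
            "n_events": 10,
            "volume_interval_s": 2.0,
            "n_volumes": 700,
        },
        "bold": {
            "delta_r2star_hz": 5.0,
            "odor": "neutral",
            "c_ppm": 450.0,
            "plugged": "none",
        },
        "nuisance": {
            "drift_linear_pct": 1.0,
            "drift_cos_pct": 0.5,
            "motion_spike_rate": 0.0,
            "motion_amp_px": 0.0,
        },
        "analysis": {"p_threshold": 0.001, "smooth_fwhm_mm": 0.0, "correction": "none"},
    }


def merge_config(base: dict, override: dict) -> dict:
    """One-level-deep merge of an override onto a (default) config."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(default_config(), user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def split_seed(seed: int, n: int = 3) -> list[int]:
    """Expand one base seed into independent child seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# object construction from config blocks


def build_phantom(cfg: dict, seed: int) -> PhantomMap:
    pc = cfg["phantom"]
    p = make_ob_phantom(
        nx=pc.get("nx", 96),
        ny=pc.get("ny", 70),
        pixel_mm=tuple(pc.get("pixel_mm", (0.1083, 0.1071))),
        seed=seed,
    )
    if pc.get("air_field", True):
        p = air_interface_field(p, pc.get("perturbers"), pc.get("b0_scale", 1.0))
    return p


def build_sequence(cfg: dict, phantom: PhantomMap, seed: int) -> SequenceParams:
    sc = dict(cfg["sequence"])
    kind = sc.pop("kind", "PR_SPEN")
    sigma = sc.pop("noise_sigma", None)
    # acquisition geometry follows the phantom unless configured explicitly
    sc.setdefault("matrix", list(phantom.shape))
    sc.setdefault("fov_mm", [round(v, 6) for v in phantom.fov_mm])
    kw = {k: (tuple(v) if k in ("matrix", "fov_mm") else v)
          for k, v in sc.items() if v is not None}
    params = default_params(kind, **kw)
    if sigma is None:
        sigma = calibrate_noise(
            phantom, params, target_snr=cfg.get("target_snr", 30.0), seed=seed
        )
    return default_params(kind, noise_sigma=float(sigma), **kw)


def build_bold(cfg: dict) -> BoldModel:
    from .bold_experiment import ODOR_MASKS

    bc = cfg["bold"]
    masks = ODOR_MASKS.get(bc.get("odor", "neutral"), ODOR_MASKS["neutral"])
    bold = BoldModel(
        delta_r2star_hz=bc.get("delta_r2star_hz", 5.0),
        active_masks=masks,
        c_ppm=bc.get("c_ppm", 450.0),
        t2_fraction=bc.get("t2_fraction", 0.4),
        conc_model=ConcModel(**bc.get("conc_model", {})),
        hrf_params=HrfParams(**bc.get("hrf", {})),
    )
    return nostril_scenario(bold, bc.get("plugged", "none"))


def _build_paradigm(cfg: dict) -> Paradigm:
    return build_paradigm(**cfg["paradigm"])


def _build_nuisance(cfg: dict) -> Nuisance:
    return Nuisance(**cfg.get("nuisance", {}))


# ---------------------------------------------------------------------------
# NIfTI / TSV round trips


def _affine(pixel_mm: tuple[float, float], slice_mm: float = 0.8) -> np.ndarray:
    return np.diag([pixel_mm[0], pixel_mm[1], slice_mm, 1.0])


def save_phantom(phantom: PhantomMap, outdir) -> None:
    """One NIfTI volume per map plus a YAML sidecar with masks/geometry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.pixel_mm, phantom.slice_mm)
    for name in ("pd_map", "t2_map", "t2prime_map", "b0_map"):
        data = getattr(phantom, name)[:, :, None].astype(np.float64)
        nib.save(nib.Nifti1Image(data, aff), str(outdir / f"{name}.nii.gz"))
    sidecar = {
        "pixel_mm": list(phantom.pixel_mm),
        "slice_mm": phantom.slice_mm,
        "masks": {k: np.argwhere(v).tolist() for k, v in phantom.masks.items()},
        "shape": list(phantom.shape),
    }
    with open(outdir / "phantom.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_phantom(outdir) -> PhantomMap:
    outdir = Path(outdir)
    with open(outdir / "phantom.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    maps = {}
    for name in ("pd_map", "t2_map", "t2prime_map", "b0_map"):
        maps[name] = np.asarray(
            nib.load(str(outdir / f"{name}.nii.gz")).get_fdata()
        )[:, :, 0]
    shape = tuple(sidecar["shape"])
    masks = {}
    for k, idx in sidecar["masks"].items():
        m = np.zeros(shape, bool)
        if idx:
            arr = np.asarray(idx)
            m[arr[:, 0], arr[:, 1]] = True
        masks[k] = m
    return PhantomMap(
        pixel_mm=tuple(sidecar["pixel_mm"]),
        slice_mm=sidecar["slice_mm"],
        masks=masks,
        **maps,
    )


def save_run(ds: TimeSeriesDataset, outdir) -> None:
    """4D NIfTI + events TSV + provenance YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pix = ds.pixel_mm or (1.0, 1.0)
    img = nib.Nifti1Image(ds.volumes[:, :, None, :].astype(np.float32), _affine(pix))
    img.header.set_zooms((pix[0], pix[1], 0.8, ds.volume_interval_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(outdir / "run.nii.gz"))
    par = ds.paradigm
    events = pd.DataFrame(
        {
            "onset": par.onsets_s,
            "duration": np.full(par.n_events, par.odor_s),
            "trial_type": ["odor"] * par.n_events,
        }
    )
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    prov = {
        "paradigm": {f: getattr(par, f) for f in par.__dataclass_fields__},
        **_jsonable(ds.provenance),
    }
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=False)


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: float(o) if np.isscalar(o) else str(o)))


def load_run(outdir) -> TimeSeriesDataset:
    outdir = Path(outdir)
    img = nib.load(str(outdir / "run.nii.gz"))
    vols = np.asarray(img.get_fdata())[:, :, 0, :]
    with open(outdir / "provenance.yaml") as fh:
        prov = yaml.safe_load(fh)
    par = Paradigm(**prov["paradigm"])
    zooms = img.header.get_zooms()
    return TimeSeriesDataset(
        volumes=vols,
        volume_interval_s=float(zooms[3]) if len(zooms) > 3 else par.volume_interval_s,
        paradigm=par,
        pixel_mm=(float(zooms[0]), float(zooms[1])),
        provenance=prov,
    )


def save_map_nifti(map2d: np.ndarray, pixel_mm, path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(map2d, np.float64)[:, :, None], _affine(pixel_mm)),
        str(path),
    )


# ---------------------------------------------------------------------------
# orchestration (the CLI verbs as library functions)


def run_simulate(cfg: dict, outdir) -> TimeSeriesDataset:
    """Simulate a full run from a config and write its artifacts."""
    outdir = Path(outdir)
    s_phantom, s_noise, s_cal = split_seed(cfg["seed"])
    phantom = build_phantom(cfg, s_phantom)
    params = build_sequence(cfg, phantom, s_cal)
    paradigm = _build_paradigm(cfg)
    bold = build_bold(cfg)
    ds = simulate_run(
        phantom, params, paradigm, bold, nuisance=_build_nuisance(cfg), seed=s_noise
    )
    ds.provenance["config"] = _jsonable(cfg)
    ds.provenance["seeds"] = {"phantom": s_phantom, "noise": s_noise, "calibration": s_cal}
    save_run(ds, outdir)
    save_phantom(phantom, outdir / "phantom")
    save_config(cfg, outdir / "config.yaml")
    return ds


def run_analyze(run_dir, cfg: dict | None = None, outdir=None) -> dict:
    """First-level analysis + QC of a stored (or just-simulated) run."""
    from . import activation_analysis as aa

    run_dir = Path(run_dir)
    if not (run_dir / "events.tsv").exists():
        raise FileNotFoundError(f"missing paradigm file {run_dir/'events.tsv'}")
    ds = load_run(run_dir)
    cfg = cfg or (load_config(run_dir / "config.yaml") if (run_dir / "config.yaml").exists() else default_config())
    ac = cfg.get("analysis", {})
    phantom = load_phantom(run_dir / "phantom") if (run_dir / "phantom" / "phantom.yaml").exists() else None
    if phantom is not None:
        ds.masks = phantom.masks

    if ac.get("smooth_fwhm_mm", 0.0) > 0:
        ds.volumes = aa.smooth_gaussian(ds.volumes, ac["smooth_fwhm_mm"], ds.pixel_mm)
    design = aa.build_design_matrix(ds.paradigm)
    amap = aa.glm_first_level(ds, design, p_threshold=ac.get("p_threshold", 0.001))
    if ac.get("correction", "none") != "none":
        amap.threshold(ac.get("p_threshold", 0.001), ac["correction"])
    qc = aa.qc_screen(ds)

    report = {
        "n_suprathreshold": int(amap.mask_supra.sum()),
        "df": int(amap.df[0]),
        "p_threshold": amap.p_threshold,
        "correction": amap.correction,
        "qc_keep": bool(qc.keep),
        "qc_metrics": qc.metrics,
        "qc_reasons": qc.reasons,
    }
    if ds.masks is not None:
        ob = ds.masks["ob_left"] | ds.masks["ob_right"]
        resp = aa.percent_change(aa.roi_timecourse(ds, ob), ds.paradigm)
        report["ob_peak_percent_change"] = resp.peak_pct
        for side in ("ob_left", "ob_right"):
            report[f"n_suprathreshold_{side}"] = int(
                (amap.mask_supra & ds.masks[side]).sum()
            )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_map_nifti(amap.stat, ds.pixel_mm or (1, 1), outdir / "tmap.nii.gz")
        save_map_nifti(
            amap.mask_supra.astype(float), ds.pixel_mm or (1, 1), outdir / "supra.nii.gz"
        )
        pd.DataFrame([qc.metrics]).to_csv(outdir / "qc.csv", index=False)
        with open(outdir / "report.yaml", "w") as fh:
            yaml.safe_dump(_jsonable(report), fh, sort_keys=False)
    return report


def run_compare_sequences(cfg: dict | None = None, outdir=None) -> pd.DataFrame:
    """Metric table across GE/SE EPI and FR/PR SPEN on one phantom+field:
    image SNR, centroid shift vs the undistorted reference, support Dice
    vs ground truth, and peak percent change on a matched short BOLD run."""
    from . import activation_analysis as aa

    cfg = cfg or default_config()
    s_phantom, s_noise, s_cal = split_seed(cfg["seed"])
    phantom = build_phantom(cfg, s_phantom)
    phantom0 = build_phantom({**cfg, "phantom": {**cfg["phantom"], "air_field": False}}, s_phantom)
    ob = phantom.masks["ob_left"] | phantom.masks["ob_right"]
    truth_support = phantom.pd_map > 0.2 * np.percentile(phantom.pd_map[ob], 95)
    vi = cfg["paradigm"].get("volume_interval_s", 2.0)
    paradigm = build_paradigm(
        air_s=60.0, odor_s=26.0, n_events=4,
        volume_interval_s=vi, n_volumes=int(4 * 86 / vi),
    )
    bold = build_bold(cfg)
    roi = activation_weights(bold, phantom) > 0

    rows = []
    for kind in ("GE_EPI", "SE_EPI", "FR_SPEN", "PR_SPEN"):
        params = build_sequence({**cfg, "sequence": {**cfg["sequence"], "kind": kind}}, phantom, s_cal)
        img = reconstruct(acquire(phantom, params, seed=s_noise))
        img0 = reconstruct(acquire(phantom0, params, seed=s_noise))
        thr = img > 0.3 * np.percentile(img, 95)
        ds = simulate_run(phantom, params, paradigm, bold, seed=s_noise)
        resp = aa.percent_change(aa.roi_timecourse(ds, roi), paradigm)
        rows.append(
            {
                "sequence": kind,
                "snr": mt.snr(img, ob, phantom.masks["noise_roi"]),
                "centroid_shift_mm": mt.centroid_shift(img, img0, phantom.pixel_mm)[1],
                "dice": mt.dice(thr, truth_support),
                "peak_percent_change": resp.peak_pct,
            }
        )
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sequence_comparison.csv", index=False)
    return table


def run_calibrate_noise(cfg: dict | None = None) -> float:
    """Calibrate the raw-noise sigma for the configured sequence/target."""
    cfg = cfg or default_config()
    s_phantom, _, s_cal = split_seed(cfg["seed"])
    phantom = build_phantom(cfg, s_phantom)
    cfg = {**cfg, "sequence": {**cfg["sequence"], "noise_sigma": None}}
    return build_sequence(cfg, phantom, s_cal).noise_sigma
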