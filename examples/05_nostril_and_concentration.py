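"""Single-nostril lateralization and the saturating concentration curve.

Each OB hemisphere receives input from the ipsilateral nostril, so
plugging one nostril should silence one hemisphere; odor concentration
drives a saturating Hill response (physiological odors stay under
~100 ppm, so the tested 60-700 ppm grid saturates).
"""

import numpy as np

from spenfmri import activation_analysis as aa
from spenfmri import bold_experiment as be
from spenfmri import forward_sim as fs
from spenfmri import phantom as ph
from spenfmri import sequences as sq

p = ph.make_ob_phantom(nx=48, ny=36, seed=1)
fov = tuple(round(v, 6) for v in p.fov_mm)
base = sq.default_params("PR_SPEN", matrix=p.shape, fov_mm=fov)
sigma = fs.calibrate_noise(p, base, target_snr=30.0, seed=0)
par = sq.default_params("PR_SPEN", matrix=p.shape, fov_mm=fov, noise_sigma=sigma)
paradigm = be.build_paradigm(air_s=60, odor_s=26, n_events=4, n_volumes=180)

# plugged-left scenario
bold = be.nostril_scenario(be.BoldModel(), plugged="left")
ds = be.simulate_run(p, par, paradigm, bold, seed=6)
amap = aa.glm_first_level(ds, aa.build_design_matrix(paradigm))
supra = amap.mask_supra
right = (supra & p.masks["ob_right"]).sum()
print(f"plugged=left: {supra.sum()} suprathreshold pixels, "
      f"{100 * right / max(supra.sum(), 1):.0f}% in the right hemisphere")

# concentration series (noiseless for a clean curve)
quiet = be.Nuisance(drift_linear_pct=0, drift_cos_pct=0)
par0 = sq.default_params("PR_SPEN", matrix=p.shape, fov_mm=fov, noise_sigma=0.0)
roi = be.activation_weights(be.BoldModel(), p) > 0
print("c_ppm  peak%")
for c in (60, 300, 500, 700):
    dsc = be.simulate_run(p, par0, paradigm, be.BoldModel(c_ppm=c),
                          nuisance=quiet, seed=0, lam=1e-9)
    resp = aa.percent_change(aa.roi_timecourse(dsc, roi), paradigm)
    print(f"{c:5d}  {resp.peak_pct:.2f}")
print("-> activation lateralises to the open-nostril hemisphere, and the "
      "concentration response is strongly nonlinear: most of the "
      "amplitude is already present at 60 ppm.")
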