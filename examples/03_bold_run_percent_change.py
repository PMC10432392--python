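"""Simulate an odor-stimulation run and read out the raw response.

A partially refocused SPEN run with the default activation model
(neutral odor, 450 ppm, R2* decrease of 5 1/s at peak) and the block
paradigm; the epoch-averaged OB time course is the paper-style raw
readout that needs no statistics.  Reduced grid and 4 events keep this
example fast; the full protocol is 10 events / 700 volumes.
"""

from spenfmri import activation_analysis as aa
from spenfmri import bold_experiment as be
from spenfmri import forward_sim as fs
from spenfmri import phantom as ph
from spenfmri import sequences as sq

p = ph.make_ob_phantom(nx=48, ny=36, seed=1)
fov = tuple(round(v, 6) for v in p.fov_mm)
par = sq.default_params("PR_SPEN", matrix=p.shape, fov_mm=fov)
sigma = fs.calibrate_noise(p, par, target_snr=30.0, seed=0)
par = sq.default_params("PR_SPEN", matrix=p.shape, fov_mm=fov, noise_sigma=sigma)

paradigm = be.build_paradigm(air_s=60, odor_s=26, n_events=4, n_volumes=180)
bold = be.BoldModel()
ds = be.simulate_run(p, par, paradigm, bold, seed=1)

roi = be.activation_weights(bold, p) > 0
resp = aa.percent_change(aa.roi_timecourse(ds, roi), paradigm)
print(f"epochs averaged: {resp.n_epochs}")
print(f"peak percent signal change in the active ROI: {resp.peak_pct:.2f}%")
peak_t = resp.t_s[resp.mean_pct.argmax()]
print(f"peak occurs {peak_t:.0f} s after odor onset")
print("-> with Delta = 4 ms of residual T2* weighting the activation "
      "exceeds 5% of the baseline signal, visible without any "
      "statistical treatment.")
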