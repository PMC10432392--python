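"""Single-shot forward simulation.

Raw data are simulated sample-by-sample along the low-bandwidth (y) axis:

    s_m = sum_n rho(y_n) * exp(i[phi_e(y_n) + k(t_m) y_n])
                * exp(i 2 pi df(y_n) tau(y_n, t_m))
                * exp(-t_abs(m)/T2(y_n)) * exp(-|tau(y_n, t_m)|/T2'(y_n)) * dy

with tau(y, t) = tau_resid(y) + (t - t*(y)) for SPEN and the per-line
evolution time for EPI.  The readout (x) axis is an ideal, distortion-free
Fourier dimension: raw samples are stored as (kx index, y-sample index).
Integration always runs over the phantom's own grid, so a SPEN acquisition
whose FOV covers only part of the object ("zoom") receives out-of-window
signal naturally, while EPI at the same FOV aliases.

Complex Gaussian noise is added per raw sample and per average;
``n_averages`` acquisitions are summed coherently, so a zero-object
acquisition has per-component sample variance ``n_averages * sigma^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomMap
from .sequences import (
    SequenceParams,
    TimingTable,
    build_timing,
    k_of_t,
    quadratic_phase_coeffs,
)

__all__ = ["RawData", "Acquisition", "acquire", "calibrate_noise"]


@dataclass
class RawData:
    """Simulated single-shot samples: (readout kx index, y-sample index)."""

    samples: np.ndarray
    params: SequenceParams
    seed: int
    timing: TimingTable = field(repr=False, default=None)
    phantom_pixel_mm: tuple[float, float] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape


def _half_pixel_phase(n: int) -> np.ndarray:
    # pixel centers sit at ((i+0.5)-n/2)*dx, half a pixel off the FFT origin
    return np.exp(-1j * np.pi * (np.arange(n) - n / 2) / n)


def _cfft_x(v: np.ndarray) -> np.ndarray:
    """Forward DFT along axis 0 with true pixel-center coordinates:
    out[j] = sum_i v[i] exp(-i k_j x_i), k_j = 2 pi (j - n/2)/(n dx)."""
    out = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(v, axes=0), axis=0), axes=0)
    return out * _half_pixel_phase(v.shape[0])[:, None]


def _cifft_x(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_cfft_x`."""
    v = v * _half_pixel_phase(v.shape[0]).conj()[:, None]
    return np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(v, axes=0), axis=0), axes=0)


class Acquisition:
    """Precomputed encoding/off-resonance tensors for repeated acquisition
    of one phantom geometry under one sequence (the fMRI-run fast path).

    The per-sample encoding row, the evolution times tau(y, t_m) and the
    off-resonance phase tensor depend only on the sequence and the static
    b0 map and are built once; relaxation decay is recomputed per call so
    activation can modulate R2/R2' volume by volume.
    """

    def __init__(
        self,
        phantom: PhantomMap,
        params: SequenceParams,
        timing: TimingTable | None = None,
    ) -> None:
        self.phantom = phantom
        self.params = params
        self.timing = build_timing(params) if timing is None else timing
        if self.timing.kind is not params.kind:
            raise ValueError("timing was built for a different sequence kind")

        x_mm, y_mm = phantom.coords_mm()
        self.y_mm = y_mm
        self.dy = phantom.pixel_mm[1]
        t_m = self.timing.t_m
        nm = len(t_m)
        ny = len(y_mm)

        b0 = phantom.b0_map
        if params.kind.is_spen:
            ly = params.fov_mm[1]
            yc = params.zoom_center_mm
            t_star = ((y_mm - yc) / ly + 0.5) * params.tacq_s
            # tau[n, m] = delta + (t_m - t*(y_n))
            self.tau = params.delta_s + (t_m[None, :] - t_star[:, None])
            # Voxel-basis chirp encoding with the off-resonance phase
            # handled exactly: within pixel n the off-resonance phase
            # 2 pi df (delta + t_m - t*(y)) is linear in y (t* is linear),
            # so its slope joins the Fresnel integral's linear coefficient
            # and only the pixel-constant part stays outside.
            alpha, beta = quadratic_phase_coeffs(params)
            p_m = beta + np.asarray(k_of_t(params, t_m))  # (m,)
            kappa = 2.0 * np.pi * b0 * params.tacq_s / ly  # (x, n)
            p_eff = p_m[None, None, :] - kappa[:, :, None]  # (x, n, m)
            a = abs(alpha)
            q = p_eff / (2.0 * alpha)
            c = -(p_eff**2) / (4.0 * alpha)
            fscale = np.sqrt(np.pi / (2.0 * a))
            from scipy.special import fresnel

            lo = (y_mm - self.dy / 2.0)[None, :, None]
            hi = (y_mm + self.dy / 2.0)[None, :, None]
            sf_hi, cf_hi = fresnel((hi + q) / fscale)
            sf_lo, cf_lo = fresnel((lo + q) / fscale)
            prim = fscale * ((cf_hi - cf_lo) + 1j * (sf_hi - sf_lo))
            if alpha < 0:
                prim = prim.conj()
            phase0 = (
                2.0 * np.pi * b0[:, :, None] * (params.delta_s + t_m[None, None, :])
                - 2.0 * np.pi * b0[:, :, None] * params.tacq_s * (0.5 - yc / ly)
            )
            self.enc = np.exp(1j * (c + phase0)) * prim
            self.scale = phantom.slice_mm
        else:
            k_m = 2.0 * np.pi * (np.arange(nm) - nm / 2) / params.fov_mm[1]
            e = np.exp(-1j * k_m[:, None] * y_mm[None, :])  # (m, n)
            # whole PE line shares one evolution time
            self.tau = np.broadcast_to(self.timing.tau_resid[None, :], (ny, nm)).copy()
            self.enc = (
                np.exp(2j * np.pi * b0[:, :, None] * self.tau[None, :, :])
                * e.T[None, :, :]
            )
            self.scale = self.dy * phantom.slice_mm
        self.abs_tau = np.abs(self.tau)
        self.t_abs = self.timing.t_abs

    def signal(
        self,
        pd_map: np.ndarray | None = None,
        r2_hz: np.ndarray | None = None,
        r2prime_hz: np.ndarray | None = None,
    ) -> np.ndarray:
        """Noiseless samples for (possibly modulated) tissue maps.

        ``r2_hz``/``r2prime_hz`` are relaxation *rates* in 1/s; defaults are
        taken from the phantom (T2/T2' in ms).
        """
        ph = self.phantom
        pd = ph.pd_map if pd_map is None else pd_map
        r2 = 1000.0 / ph.t2_map if r2_hz is None else r2_hz
        with np.errstate(divide="ignore"):
            r2p = (1000.0 / ph.t2prime_map) if r2prime_hz is None else r2prime_hz
        decay = np.exp(
            -(
                self.t_abs[None, None, :] * r2[:, :, None]
                + self.abs_tau[None, :, :] * r2p[:, :, None]
            )
        )
        w = (pd[:, :, None] * self.scale) * decay
        v = np.einsum("xnm,xnm->xm", w, self.enc)
        return _cfft_x(v)

    def add_noise(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Coherent sum of ``n_averages`` noisy acquisitions."""
        p = self.params
        total = p.n_averages * signal
        if p.noise_sigma > 0:
            noise = rng.standard_normal((p.n_averages, *signal.shape, 2))
            total = total + p.noise_sigma * (
                noise[..., 0].sum(axis=0) + 1j * noise[..., 1].sum(axis=0)
            )
        return total


def acquire(
    phantom: PhantomMap,
    params: SequenceParams,
    timing: TimingTable | None = None,
    seed: int = 0,
) -> RawData:
    """Simulate one single-shot acquisition (with averaging and noise)."""
    acq = Acquisition(phantom, params, timing)
    rng = np.random.default_rng(seed)
    samples = acq.add_noise(acq.signal(), rng)
    return RawData(
        samples=samples,
        params=params,
        seed=seed,
        timing=acq.timing,
        phantom_pixel_mm=phantom.pixel_mm,
    )


def calibrate_noise(
    phantom: PhantomMap,
    params: SequenceParams,
    target_snr: float = 30.0,
    n_trials: int = 20,
    seed: int = 0,
    tol: float = 0.10,
    max_iter: int = 8,
) -> float:
    """Find the raw-sample noise sigma giving a reconstructed-image SNR
    (mean over the OB mask / SD over the noise ROI) of ``target_snr``.

    Image SNR is inversely proportional to sigma to good accuracy, so a
    probe acquisition followed by scaling converges in one or two secant
    steps; iteration continues until the measured SNR over ``n_trials``
    reconstructions is within ``tol`` (relative) of the target.
    """
    from . import recon as _recon

    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    if np.any(phantom.b0_map != 0):
        # noise calibration is a thermal-noise property: measure it on the
        # homogeneous-field phantom so distortion leakage into the noise
        # ROI cannot masquerade as noise
        phantom = phantom.copy()
        phantom.b0_map = np.zeros_like(phantom.b0_map)
    acq = Acquisition(phantom, params)
    clean = acq.signal()
    ob = phantom.masks["ob_left"] | phantom.masks["ob_right"]
    noise_roi = phantom.masks["noise_roi"]

    def measure(sigma: float) -> float:
        p = SequenceParams(**{**params.to_dict(), "noise_sigma": sigma})
        acq_n = Acquisition(phantom, p, acq.timing)
        rng = np.random.default_rng(seed)
        snrs = []
        for _ in range(n_trials):
            raw = RawData(
                samples=Acquisition.add_noise(acq_n, clean, rng),
                params=p,
                seed=seed,
                timing=acq.timing,
                phantom_pixel_mm=phantom.pixel_mm,
            )
            img = _recon.reconstruct(raw)
            snrs.append(img[ob].mean() / max(img[noise_roi].std(), 1e-30))
        return float(np.mean(snrs))

    # probe at a sigma scaled to the clean signal level
    sigma = np.abs(clean).mean() / (10.0 * params.n_averages)
    for _ in range(max_iter):
        snr = measure(sigma)
        if abs(snr - target_snr) <= tol * target_snr:
            return float(sigma)
        sigma = sigma * snr / target_snr
    raise RuntimeError(
        f"noise calibration did not converge: last SNR {snr:.2f} "
        f"for target {target_snr:.2f}"
    )
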