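"""Acquisition parameters and refocusing timings.

Four single-shot sequences are represented: gradient-echo and spin-echo EPI
(Fourier encoding along the low-bandwidth axis) and fully/partially
refocused SPEN, where a chirped 180° pulse applied with a gradient imparts a
quadratic phase ``phi_e(y) = alpha*y^2 + beta*y`` so each position y emits
its signal around its stationary moment t*(y) and is read out directly in
space.  Full refocusing (FR) unwinds each position's off-resonance/T2* phase
exactly at its stationary moment; partial refocusing (PR) leaves a uniform
residual T2* evolution time Delta, restoring BOLD sensitivity (the study
value is Delta = 4 ms).

The chirp is modelled by its net quadratic phase (instantaneous-inversion
approximation); its strength is set by the time-bandwidth product R via
``alpha = -pi * R / Ly^2``.  Sign conventions: the stationary point sweeps
low -> high y, k(t) increases linearly from 0 with
``k(tacq) - k(0) = 2|alpha|*Ly``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SequenceKind",
    "SequenceParams",
    "TimingTable",
    "quadratic_phase_coeffs",
    "build_timing",
    "default_params",
]


class SequenceKind(str, enum.Enum):
    GE_EPI = "GE_EPI"
    SE_EPI = "SE_EPI"
    FR_SPEN = "FR_SPEN"
    PR_SPEN = "PR_SPEN"

    @property
    def is_spen(self) -> bool:
        return self in (SequenceKind.FR_SPEN, SequenceKind.PR_SPEN)

    @property
    def is_epi(self) -> bool:
        return not self.is_spen


@dataclass
class SequenceParams:
    """Geometry and timing of one single-shot acquisition.

    ``tacq_s`` is the acquisition duration along the low-bandwidth (y) axis;
    ``chirp_r`` is the chirp time-bandwidth product R controlling the
    quadratic-phase strength (SPEN only); ``delta_s`` is the residual T2*
    weighting delay of PR SPEN.  The full-refocusing condition ties TE to
    the acquisition time (te_s == tacq_s for FR SPEN).
    """

    kind: SequenceKind
    fov_mm: tuple[float, float] = (10.4, 7.5)
    matrix: tuple[int, int] = (96, 70)
    tr_s: float = 1.0
    te_s: float = 0.026
    tacq_s: float = 0.026
    chirp_duration_s: float = 0.013
    chirp_r: float = 2000.0
    delta_s: float = 0.0
    n_averages: int = 2
    noise_sigma: float = 0.0
    zoom_center_mm: float = 0.0

    def __post_init__(self) -> None:
        self.kind = SequenceKind(self.kind)
        if min(self.tr_s, self.te_s, self.tacq_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.tr_s < self.tacq_s:
            raise ValueError("tr_s must be >= tacq_s")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kind is SequenceKind.FR_SPEN:
            if self.delta_s != 0:
                raise ValueError("FR_SPEN requires delta_s = 0")
            if not np.isclose(self.te_s, self.tacq_s):
                raise ValueError("FR_SPEN requires te_s = tacq_s (full refocusing)")
        if self.kind is SequenceKind.PR_SPEN and self.delta_s <= 0:
            raise ValueError("PR_SPEN requires delta_s > 0")
        if self.kind.is_spen:
            if self.te_s < self.chirp_duration_s:
                raise ValueError("infeasible timing: te_s < chirp_duration_s")
            if self.chirp_r <= 0:
                raise ValueError("chirp_r must be positive")

    @property
    def pixel_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def volume_interval_s(self) -> float:
        """Time per reconstructed volume: TR times the number of coherently
        summed averages (1 s x 2 averages -> one image every 2 s)."""
        return self.tr_s * self.n_averages

    def y_grid_mm(self) -> np.ndarray:
        """Nominal reconstruction grid along y (pixel centers within the
        acquisition FOV, offset by the zoom center)."""
        ny = self.matrix[1]
        dy = self.fov_mm[1] / ny
        return ((np.arange(ny) + 0.5) - ny / 2) * dy + self.zoom_center_mm

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind.value
        d["fov_mm"] = list(self.fov_mm)
        d["matrix"] = list(self.matrix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        d = dict(d)
        d["fov_mm"] = tuple(d["fov_mm"])
        d["matrix"] = tuple(d["matrix"])
        return cls(**d)


def default_params(kind: SequenceKind | str, **overrides) -> SequenceParams:
    """Study-condition defaults: TR 1 s, TE ~26 ms, 2 averages, 10.4 x 7.5 mm
    FOV on a 96 x 70 matrix; PR SPEN uses Delta = 4 ms."""
    kind = SequenceKind(kind)
    kw = dict(kind=kind)
    if kind is SequenceKind.PR_SPEN:
        kw["delta_s"] = 0.004
    kw.update(overrides)
    return SequenceParams(**kw)


def quadratic_phase_coeffs(params: SequenceParams) -> tuple[float, float]:
    """Coefficients (alpha, beta) of the post-chirp quadratic phase.

    With ``k(t) = 2|alpha|*Ly*t/tacq`` (rad/mm) the stationary point
    ``y*(t) = -(beta + k(t)) / (2*alpha)`` sweeps linearly from -Ly/2 at
    t = 0 to +Ly/2 at t = tacq (relative to the zoom center).
    """
    if not params.kind.is_spen:
        raise ValueError("quadratic phase is defined only for SPEN sequences")
    ly = params.fov_mm[1]
    alpha = -np.pi * params.chirp_r / ly**2
    # y* = (beta + k)/(2|alpha|) + offset handled via zoom_center shift of
    # the phase origin: beta chosen so y*(0) = zoom_center - Ly/2.
    beta = -abs(alpha) * ly - 2.0 * alpha * params.zoom_center_mm
    return float(alpha), float(beta)


def k_of_t(params: SequenceParams, t: np.ndarray | float) -> np.ndarray | float:
    """Accumulated readout moment along y at time t (rad/mm), linear in t."""
    alpha, _ = quadratic_phase_coeffs(params)
    return 2.0 * abs(alpha) * params.fov_mm[1] * np.asarray(t) / params.tacq_s


def ystar_of_t(params: SequenceParams, t: np.ndarray | float) -> np.ndarray | float:
    """Stationary point y*(t) = -(beta + k(t)) / (2 alpha)."""
    alpha, beta = quadratic_phase_coeffs(params)
    return -(beta + k_of_t(params, t)) / (2.0 * alpha)


def chirp_pixel_integrals(
    alpha: float, p: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Exact per-pixel integrals of ``exp(i [alpha y^2 + p_m y])``.

    ``p`` is one linear coefficient per sample (rad/mm), ``edges`` the
    pixel boundaries (len n+1, ascending).  Returns an (m, n) matrix via
    the Fresnel-integral closed form.
    """
    from scipy.special import fresnel

    a = abs(alpha)
    # alpha y^2 + p y = alpha (y + p/(2 alpha))^2 - p^2/(4 alpha)
    q = p / (2.0 * alpha)
    c = -(p**2) / (4.0 * alpha)
    scale = np.sqrt(np.pi / (2.0 * a))
    u = (edges[None, :] + q[:, None]) / scale  # (m, n+1)
    s_f, c_f = fresnel(u)
    prim = scale * (c_f + 1j * s_f)  # primitive of exp(i a u^2)
    if alpha < 0:
        prim = prim.conj()
    return np.exp(1j * c)[:, None] * np.diff(prim, axis=1)


def spen_encoding(
    params: SequenceParams, y_centers: np.ndarray, dy: float
) -> np.ndarray:
    """SPEN encoding matrix in a voxel (box) basis.

    Entry (m, n) is the exact integral of ``exp(i [phi_e(y) + k(t_m) y])``
    over the pixel ``[y_n - dy/2, y_n + dy/2]``, evaluated in closed form
    with Fresnel integrals.  For a slowly varying phase this reduces to the
    pointwise ``exp(i [phi_e(y_n) + k(t_m) y_n]) * dy``; at realistic chirp
    strengths (R of order 10^3) the within-pixel oscillation of the chirp is
    what keeps the operator well conditioned, so the box basis matters.
    """
    alpha, beta = quadratic_phase_coeffs(params)
    ny = params.matrix[1]
    t_m = (np.arange(ny) + 0.5) * params.tacq_s / ny
    p = beta + np.asarray(k_of_t(params, t_m))  # (m,)
    edges = np.concatenate([y_centers - dy / 2.0, [y_centers[-1] + dy / 2.0]])
    return chirp_pixel_integrals(alpha, p, edges)


@dataclass
class TimingTable:
    """Per-sample and per-position timing of one shot.

    ``t_m``: sample times within the acquisition window, in [0, tacq].
    ``t_abs``: elapsed time from excitation at each sample (T2 weighting).
    ``t_star``: stationary-point time t*(y_n) per nominal position (SPEN)
    or the per-line echo time (EPI, equals ``t_m``).
    ``tau_resid``: net off-resonance/T2* evolution time per position at its
    own acquisition moment (0 for FR, Delta for PR); for EPI this is per
    *sample* (the whole line shares one evolution time).
    """

    kind: SequenceKind
    t_m: np.ndarray
    t_abs: np.ndarray
    t_star: np.ndarray
    tau_resid: np.ndarray
    y_grid_mm: np.ndarray
    params: SequenceParams = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return len(self.t_m)


def build_timing(params: SequenceParams) -> TimingTable:
    """Solve the shot timing for the sequence kind.

    For SPEN the pre-acquisition delay is chosen so that the off-resonance
    phase each position accrues before its stationary moment is exactly
    unwound (FR) or leaves a uniform residual Delta (PR); the table stores
    only the net effect, ``tau_resid``.  EPI lines carry their full
    evolution time (GE: time from excitation; SE: time from the spin echo).
    """
    ny = params.matrix[1]
    t_m = (np.arange(ny) + 0.5) * params.tacq_s / ny
    # T2-weighting clock: acquisition window centered on TE
    t_abs = params.te_s - params.tacq_s / 2.0 + t_m
    y = params.y_grid_mm()
    if params.kind.is_spen:
        ly = params.fov_mm[1]
        yc = params.zoom_center_mm
        t_star = ((y - yc) / ly + 0.5) * params.tacq_s
        if np.any(np.diff(t_star) <= 0):
            raise ValueError("stationary-point map must be strictly monotonic")
        tau_resid = np.full(ny, params.delta_s)
    else:
        t_star = t_m.copy()
        if params.kind is SequenceKind.GE_EPI:
            tau_resid = t_abs.copy()
        else:  # SE_EPI: evolution measured from the spin echo at TE
            tau_resid = t_abs - params.te_s
    return TimingTable(
        kind=params.kind,
        t_m=t_m,
        t_abs=t_abs,
        t_star=t_star,
        tau_resid=tau_resid,
        y_grid_mm=y,
        params=params,
    )


def timing_to_frame(timing: TimingTable):
    """Export the timing table as a pandas DataFrame (CSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample": np.arange(timing.n_samples),
            "t_m_s": timing.t_m,
            "t_abs_s": timing.t_abs,
            "y_mm": timing.y_grid_mm,
            "t_star_s": timing.t_star,
            "tau_resid_s": timing.tau_resid,
        }
    )
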