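"""Digital olfactory-bulb phantoms.

A phantom is a 2D single-slice description of the mouse olfactory bulb (OB):
proton density, transverse relaxation (T2), reversible static-dephasing
relaxation (T2'), an off-resonance map (Hz) produced by nearby air
interfaces, and a set of named anatomical region masks.  The coordinate
convention, used consistently by the sequence/encoding modules, places pixel
centers at ``((i + 0.5) - N/2) * delta`` mm with x the readout axis (axis 0)
and y the low-bandwidth (phase / SPEN) axis (axis 1), 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomMap",
    "make_ob_phantom",
    "air_interface_field",
    "default_perturbers",
    "validate_masks",
]

#: Per-layer tissue defaults (ms).  Not measured values for OB at 15.2 T --
#: placeholders chosen to give visible T2* contrast and dropout near
#: perturbers; override via `make_ob_phantom` arguments.
DEFAULT_TISSUE = {
    # layer: (proton density, T2 ms, T2' ms)
    "glomerular": (0.85, 35.0, 22.0),
    "epl": (1.00, 45.0, 28.0),
    "core": (0.90, 40.0, 30.0),
}


@dataclass
class PhantomMap:
    """Spatial ground truth for one slice.

    All maps share one (nx, ny) grid.  ``t2_map``/``t2prime_map`` are in
    milliseconds; ``np.inf`` in ``t2prime_map`` means no reversible
    dephasing.  ``b0_map`` is off-resonance in Hz.
    """

    pd_map: np.ndarray
    t2_map: np.ndarray
    t2prime_map: np.ndarray
    b0_map: np.ndarray
    pixel_mm: tuple[float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    slice_mm: float = 0.8

    def __post_init__(self) -> None:
        shape = self.pd_map.shape
        for name in ("t2_map", "t2prime_map", "b0_map"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if np.any(self.pd_map < 0):
            raise ValueError("pd_map must be nonnegative")
        if self.pixel_mm[0] <= 0 or self.pixel_mm[1] <= 0:
            raise ValueError("pixel_mm must be positive")
        if np.any(self.t2_map <= 0) or np.any(self.t2prime_map <= 0):
            raise ValueError("relaxation times must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pd_map.shape

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_mm[0], self.shape[1] * self.pixel_mm[1])

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x_mm, y_mm) along each axis."""
        nx, ny = self.shape
        dx, dy = self.pixel_mm
        x = ((np.arange(nx) + 0.5) - nx / 2) * dx
        y = ((np.arange(ny) + 0.5) - ny / 2) * dy
        return x, y

    @property
    def t2star_map(self) -> np.ndarray:
        """Combined T2* (ms): 1/T2* = 1/T2 + 1/T2' by construction."""
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 / self.t2_map + 1.0 / self.t2prime_map)

    def copy(self) -> "PhantomMap":
        return PhantomMap(
            pd_map=self.pd_map.copy(),
            t2_map=self.t2_map.copy(),
            t2prime_map=self.t2prime_map.copy(),
            b0_map=self.b0_map.copy(),
            pixel_mm=self.pixel_mm,
            masks={k: v.copy() for k, v in self.masks.items()},
            slice_mm=self.slice_mm,
        )


def validate_masks(masks: dict[str, np.ndarray]) -> None:
    """Check the region-mask algebra: disjoint hemispheres, layers inside
    the bulb, background disjoint from tissue."""
    left, right = masks["ob_left"], masks["ob_right"]
    if np.any(left & right):
        raise ValueError("ob_left and ob_right overlap")
    ob = left | right
    layers = masks["epl"] | masks["glomerular_lateral"]
    if np.any(layers & ~ob):
        raise ValueError("layer masks extend outside the bulb")
    if np.any(masks["background"] & ob):
        raise ValueError("background overlaps the bulb")


def make_ob_phantom(
    nx: int = 96,
    ny: int = 70,
    pixel_mm: tuple[float, float] = (0.1083, 0.1071),
    seed: int = 0,
    tissue: dict | None = None,
    texture_pct: float = 2.0,
) -> PhantomMap:
    """Build a two-hemisphere OB phantom with concentric layers.

    Each hemisphere is an ellipse; from the rim inward: a glomerular rim, an
    external plexiform (EPL) ring, and a core.  A small seeded multiplicative
    texture (``texture_pct`` % SD, smoothed) breaks exact uniformity.  The
    default grid realises a 10.4 x 7.5 mm field of view at ~108 x 107 um.
    """
    if nx < 16 or ny < 16:
        raise ValueError("nx, ny must be >= 16")
    if pixel_mm[0] <= 0 or pixel_mm[1] <= 0:
        raise ValueError("pixel_mm must be positive")
    tissue = dict(DEFAULT_TISSUE if tissue is None else tissue)

    dx, dy = pixel_mm
    x = ((np.arange(nx) + 0.5) - nx / 2) * dx
    y = ((np.arange(ny) + 0.5) - ny / 2) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    fov_x = nx * dx

    # hemisphere geometry: centers mirrored about the midline (x = 0)
    cx = 0.22 * fov_x
    a, b = 0.19 * fov_x, 0.40 * ny * dy  # semi-axes, mm

    pd = np.zeros((nx, ny))
    t2 = np.full((nx, ny), 80.0)  # background values are irrelevant (pd = 0)
    t2p = np.full((nx, ny), np.inf)
    masks: dict[str, np.ndarray] = {}

    hemis = {"ob_left": -cx, "ob_right": +cx}
    glom_lat = np.zeros((nx, ny), bool)
    epl = np.zeros((nx, ny), bool)
    for name, cxi in hemis.items():
        r = np.sqrt(((X - cxi) / a) ** 2 + (Y / b) ** 2)
        inside = r <= 1.0
        masks[name] = inside
        glom = inside & (r > 0.85)
        ring = inside & (r > 0.60) & (r <= 0.85)
        core = r <= 0.60
        for layer_mask, layer in ((glom, "glomerular"), (ring, "epl"), (core, "core")):
            pdv, t2v, t2pv = tissue[layer]
            pd[layer_mask] = pdv
            t2[layer_mask] = t2v
            t2p[layer_mask] = t2pv
        epl |= ring
        # lateral glomerular sectors: the outward-facing (away-from-midline)
        # part of the rim
        outward = np.sign(cxi) * (X - cxi) / a
        glom_lat |= glom & (outward > 0.5 * np.maximum(r, 1e-9))

    ob = masks["ob_left"] | masks["ob_right"]
    masks["epl"] = epl
    masks["glomerular_lateral"] = glom_lat
    masks["background"] = ~ob
    # noise ROI: all background well clear of the object and the frame,
    # so its SD estimate is stable
    from scipy import ndimage

    near_ob = ndimage.binary_dilation(ob, iterations=3)
    noise_roi = ~near_ob
    noise_roi[:2, :] = noise_roi[-2:, :] = False
    noise_roi[:, :2] = noise_roi[:, -2:] = False
    masks["noise_roi"] = noise_roi

    if texture_pct > 0:
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        tex = ndimage.gaussian_filter(rng.standard_normal((nx, ny)), 1.5)
        tex /= max(tex.std(), 1e-12)
        pd *= 1.0 + (texture_pct / 100.0) * tex
        pd = np.clip(pd, 0.0, None)
    pd[~ob] = 0.0

    ph = PhantomMap(
        pd_map=pd,
        t2_map=t2,
        t2prime_map=t2p,
        b0_map=np.zeros((nx, ny)),
        pixel_mm=pixel_mm,
        masks=masks,
    )
    validate_masks(ph.masks)
    return ph


def _dipole_2d(X, Y, center, radius, peak):
    """2D dipole-like perturbation: peak*(a/r)^2*cos(2θ) outside the disk,
    clamped to peak inside it.  θ is the polar angle from the +x axis."""
    ddx = X - center[0]
    ddy = Y - center[1]
    r2 = ddx**2 + ddy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2t = (ddx**2 - ddy**2) / r2  # cos(2θ)
        f = peak * (radius**2 / r2) * cos2t
    inside = r2 < radius**2
    f[inside] = peak
    return f


def default_perturbers(phantom: PhantomMap) -> list[tuple[tuple[float, float], float, float]]:
    """Air pockets a scanner would see near the OB: nasal cavity anterior to
    the bulb and a sinus pocket posterior, scaled to the phantom FOV."""
    fx, fy = phantom.fov_mm
    return [
        ((-0.22 * fx, -0.70 * fy), 0.32 * fy, 750.0),
        ((+0.22 * fx, -0.70 * fy), 0.32 * fy, 750.0),
        ((0.0, +0.66 * fy), 0.27 * fy, -600.0),
    ]


def air_interface_field(
    phantom: PhantomMap,
    perturbers: list[tuple[tuple[float, float], float, float]] | None = None,
    b0_scale: float = 1.0,
) -> PhantomMap:
    """Return a copy of ``phantom`` with ``b0_map`` set to the superposition
    of 2D dipole-like fields, one per ``(center_mm, radius_mm, peak_hz)``
    perturber, scaled by ``b0_scale``.

    ``perturbers=None`` uses :func:`default_perturbers`; an empty list gives
    a homogeneous field.
    """
    if perturbers is None:
        perturbers = default_perturbers(phantom)
    x, y = phantom.coords_mm()
    X, Y = np.meshgrid(x, y, indexing="ij")
    fov = phantom.fov_mm
    b0 = np.zeros(phantom.shape)
    for center, radius, peak in perturbers:
        if radius <= 0:
            raise ValueError("perturber radius must be positive")
        if radius >= max(fov):
            raise ValueError("perturber covers the entire grid")
        b0 += _dipole_2d(X, Y, center, radius, peak)
    out = phantom.copy()
    out.b0_map = b0_scale * b0
    return out
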