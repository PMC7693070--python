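"""Digital phantoms and forward simulation of multi-echo GRE acquisitions.

Images are generated voxelwise from the signal model
S(TE_i) = S0 · exp(−R2*·TE_i) · F_zshim(TE_i): in-plane readout encoding is
not simulated because the model is purely through-slice.  Phase-encode
"shots" exist only as the unit of physiological field fluctuation: every
(phase-encode line, slice) shot carries one global field offset δB shared
by all its echoes and its navigator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import GAMMA, GAMMA_BAR, SequenceParams
from .excitation import (
    SliceProfile,
    sinc_hanning_pulse,
    simulate_profile,
    slice_select_gradient,
)
from .dephasing import dephasing_factors
from .patterns import ShimPattern


@dataclass
class DigitalPhantom:
    """Ground-truth maps on a 3D grid (slice axis last)."""

    s0: np.ndarray        # a.u.
    r2star: np.ndarray    # 1/s
    b0: np.ndarray        # T (offset from nominal field)
    voxel_size: tuple     # (dx, dy, dz) m
    b1: np.ndarray | None = None   # transmit scale ξ per voxel
    labels: np.ndarray | None = None
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if np.any(self.r2star < 0):
            raise ValueError("r2star must be non-negative")
        for name in ("r2star", "b0"):
            if getattr(self, name).shape != self.s0.shape:
                raise ValueError(f"{name} shape differs from s0")

    @property
    def shape(self):
        return self.s0.shape

    @property
    def n_slices(self) -> int:
        return self.shape[self.slice_axis]

    def gz_map(self) -> np.ndarray:
        """Discrete through-slice gradient of b0 (T/m), ground truth."""
        dz = self.voxel_size[self.slice_axis]
        order = 2 if self.shape[self.slice_axis] >= 3 else 1
        return np.gradient(self.b0, dz, axis=self.slice_axis, edge_order=order)


@dataclass
class EchoSeries:
    """Voxelwise multi-echo signals plus acquisition bookkeeping."""

    data: np.ndarray              # (nx, ny, nz, n_echoes), complex or float
    echo_times: np.ndarray        # s
    te_navigator: float | None = None
    navigator: np.ndarray | None = None  # complex, (ny shots, nz slices)
    patterns: list = field(default_factory=list)  # ShimPattern per slice
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.shape[-1] != self.echo_times.size:
            raise ValueError("last data axis must match the echo count")

    @property
    def is_magnitude(self) -> bool:
        return not np.iscomplexobj(self.data)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class FluctuationSpec:
    """Respiration-like global field fluctuation, sampled once per shot.

    δB(shot j) = amplitude · sin(2π·frequency·j·TR + phase0).  Sub-TR
    slice-timing offsets are neglected (δB varies on a ~3 s scale).
    """

    amplitude: float = 5e-9   # T
    frequency: float = 0.3    # Hz
    phase0: float = 0.0       # rad

    def series(self, n_shots: int, tr: float) -> np.ndarray:
        t = np.arange(n_shots) * tr
        return self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase0)


@dataclass
class PrescanSeries:
    """3-echo prescan output: magnitude and wrapped phase volumes."""

    magnitude: np.ndarray   # (nx, ny, nz, 3)
    phase: np.ndarray       # (nx, ny, nz, 3), wrapped to (−π, π]
    echo_times: np.ndarray
    voxel_size: tuple


def _base_profile(params: SequenceParams, b1_scale: float = 1.0,
                  tr_over_t1: float = np.inf) -> SliceProfile:
    from .excitation import apply_steady_state

    pulse = sinc_hanning_pulse(params.pulse_duration, params.time_bandwidth)
    prof = simulate_profile(
        pulse, params.flip_angle_deg, b1_scale,
        slice_select_gradient(params),
        slice_thickness=params.slice_thickness,
    )
    if np.isfinite(tr_over_t1):
        prof = apply_steady_state(prof, tr_over_t1)
    return prof


def simulate_mgre(
    phantom: DigitalPhantom,
    params: SequenceParams,
    patterns: list[ShimPattern],
    noise_sd: float = 0.0,
    fluctuation: FluctuationSpec | None = None,
    seed: int | None = None,
    profile: SliceProfile | None = None,
    tr_over_t1: float = np.inf,
) -> EchoSeries:
    """Forward-simulate the multi-echo series for one shim scheme.

    ``patterns`` holds one ShimPattern per slice.  F_zshim is evaluated
    directly (Bloch profile, λ-rescaling per voxel Gz) — no lookup table —
    so reconstruction-side tables are an independent code path.  Complex
    Gaussian noise (sd per channel) is drawn from ``seed``.
    """
    nx, ny, nz = phantom.shape
    if len(patterns) != nz:
        raise ValueError(f"need one pattern per slice ({nz}), got {len(patterns)}")
    gslice = slice_select_gradient(params)
    if profile is None:
        profile = _base_profile(params, 1.0, tr_over_t1)
    te = params.echo_times
    gz = phantom.gz_map()
    rng = np.random.default_rng(seed)

    data = np.zeros((nx, ny, nz, te.size), dtype=complex)
    for k in range(nz):
        gz_sl = gz[..., k].ravel()
        f = dephasing_factors(profile, gz_sl, patterns[k], gslice)
        decay = np.exp(-np.outer(phantom.r2star[..., k].ravel(), te))
        s = phantom.s0[..., k].ravel()[:, None] * decay * f
        data[..., k, :] = s.reshape(nx, ny, te.size)

    n_shots = ny
    if fluctuation is not None:
        db = fluctuation.series(n_shots, params.tr)
        phase = np.exp(1j * GAMMA * db[None, :, None, None] * te[None, None, None, :])
        data = data * phase
    else:
        db = np.zeros(n_shots)

    navigator = None
    if params.te_navigator is not None:
        amp = np.mean(
            phantom.s0 * np.exp(-phantom.r2star * params.te_navigator),
            axis=(0, 1),
        )  # per slice
        navigator = amp[None, :] * np.exp(
            1j * GAMMA * db[:, None] * params.te_navigator
        )
        if noise_sd > 0:
            nav_sd = noise_sd / np.sqrt(nx * ny)
            navigator = navigator + nav_sd * (
                rng.standard_normal(navigator.shape)
                + 1j * rng.standard_normal(navigator.shape)
            )

    if noise_sd > 0:
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return EchoSeries(
        data=data,
        echo_times=te,
        te_navigator=params.te_navigator,
        navigator=navigator,
        patterns=list(patterns),
        meta={
            "n_unshimmed_echoes": params.n_unshimmed_echoes,
            "tr": params.tr,
            "seed": seed,
            "noise_sd": noise_sd,
        },
    )


def simulate_prescan(
    phantom: DigitalPhantom,
    echo_times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PrescanSeries:
    """3-echo field-mapping prescan: magnitude and wrapped phase volumes."""
    echo_times = np.asarray(echo_times, dtype=float)
    if echo_times.size != 3:
        raise ValueError("prescan uses exactly 3 echoes")
    rng = np.random.default_rng(seed)
    shape = phantom.shape + (3,)
    c = (
        phantom.s0[..., None]
        * np.exp(-phantom.r2star[..., None] * echo_times)
        * np.exp(1j * 2 * np.pi * GAMMA_BAR * phantom.b0[..., None] * echo_times)
    )
    if noise_sd > 0:
        c = c + noise_sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    return PrescanSeries(
        magnitude=np.abs(c),
        phase=np.angle(c),
        echo_times=echo_times,
        voxel_size=phantom.voxel_size,
    )


def _smooth_random_field(shape, rng, sigma_vox=3.0):
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return f / (np.abs(f).max() + 1e-30)


def make_phantom(spec: str = "uniform-agar", seed: int | None = None,
                 shape: tuple | None = None) -> DigitalPhantom:
    """Built-in digital phantoms.

    ``uniform-agar``
        Homogeneous cylinder, R2* = 6.4 1/s, 4 mm slices; b0 quadratic in z
        so that the through-slice gradient ramps linearly from ≈ −200 to
        ≈ +150 µT/m across the slice stack (14 µT/m per slice, offset from
        the 10 µT/m quantization-bin edges).
    ``layered-r2star``
        Five in-plane layers with R2* from 5 to 40 1/s, no field offset;
        per-layer ground truth recorded in ``labels``.
    ``invivo-like``
        Elliptical "brain" with white-matter background (19 1/s), cortical
        rim (22 1/s) and two deep-nucleus blobs (31 and 38 1/s), plus two
        localized through-slice gradient pockets (≈ +120 and −150 µT/m)
        emulating sinus-induced fields; 3 mm slices.
    """
    rng = np.random.default_rng(seed)
    if spec == "uniform-agar":
        nx, ny, nz = shape or (16, 16, 26)
        voxel = (1e-3, 1e-3, 4e-3)
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
        r = np.hypot(xx - (nx - 1) / 2, yy - (ny - 1) / 2)
        inside = r <= 0.48 * min(nx, ny)
        s0 = np.where(inside[..., None], 1.0, 0.0) * np.ones((nx, ny, nz))
        r2 = np.full((nx, ny, nz), 6.4)
        z = np.arange(nz) * voxel[2]
        z_span = z[-1] - z[0]
        g0, g1 = -197e-6, 153e-6           # T/m at first/last slice
        a = (g1 - g0) / z_span
        b0_z = g0 * z + 0.5 * a * z**2     # dB/dz ramps g0 -> g1
        b0 = np.broadcast_to(b0_z, (nx, ny, nz)).copy()
        labels = inside[..., None] * np.ones((nx, ny, nz), dtype=int)
        s0 *= 1.0 + 0.02 * _smooth_random_field((nx, ny, nz), rng)
        s0[~inside] = 0.0
        return DigitalPhantom(s0, r2, b0, voxel, labels=labels)

    if spec == "layered-r2star":
        nx, ny, nz = shape or (20, 20, 8)
        voxel = (1e-3, 1e-3, 4e-3)
        r2_values = np.array([5.0, 10.0, 20.0, 30.0, 40.0])
        labels = np.zeros((nx, ny, nz), dtype=int)
        bounds = np.linspace(0, nx, r2_values.size + 1).astype(int)
        r2 = np.zeros((nx, ny, nz))
        for i, v in enumerate(r2_values):
            labels[bounds[i]:bounds[i + 1]] = i + 1
            r2[bounds[i]:bounds[i + 1]] = v
        s0 = np.ones((nx, ny, nz))
        b0 = np.zeros((nx, ny, nz))
        return DigitalPhantom(s0, r2, b0, voxel, labels=labels)

    if spec == "invivo-like":
        nx, ny, nz = shape or (24, 24, 12)
        voxel = (1e-3, 1e-3, 3e-3)
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
        cx, cy = (nx - 1) / 2, (ny - 1) / 2
        ellipse = ((xx - cx) / (0.46 * nx)) ** 2 + ((yy - cy) / (0.46 * ny)) ** 2 <= 1
        brain = np.repeat(ellipse[..., None], nz, axis=2)
        rim = ellipse & ~(
            ((xx - cx) / (0.36 * nx)) ** 2 + ((yy - cy) / (0.36 * ny)) ** 2 <= 1
        )
        labels = np.zeros((nx, ny, nz), dtype=int)
        labels[brain] = 1                      # white matter
        labels[np.repeat(rim[..., None], nz, axis=2)] = 2  # cortical rim
        blob1 = np.hypot(xx - cx + nx * 0.15, yy - cy) < 0.10 * nx
        blob2 = np.hypot(xx - cx - nx * 0.15, yy - cy) < 0.10 * nx
        for b, lab in ((blob1, 3), (blob2, 4)):
            labels[np.repeat(b[..., None], nz, axis=2) & brain] = lab
        r2_by_label = {0: 0.0, 1: 19.0, 2: 22.0, 3: 31.0, 4: 38.0}
        r2 = np.vectorize(r2_by_label.get)(labels).astype(float)
        s0 = np.where(brain, 1.0, 0.0)
        s0 *= 1.0 + 0.02 * _smooth_random_field((nx, ny, nz), rng)
        s0[~brain] = 0.0
        # Two smooth gradient pockets (sinus-like), Gz independent of z.
        z = (np.arange(nz) - (nz - 1) / 2) * voxel[2]
        w1 = np.exp(-((xx - cx * 0.5) ** 2 + (yy - cy * 0.55) ** 2) / (0.16 * nx) ** 2)
        w2 = np.exp(-((xx - cx * 1.5) ** 2 + (yy - cy * 1.45) ** 2) / (0.16 * nx) ** 2)
        gz_xy = 120e-6 * w1 - 150e-6 * w2
        b0 = gz_xy[..., None] * z[None, None, :]
        return DigitalPhantom(s0, r2, b0, voxel, labels=labels)

    raise ValueError(f"unknown phantom spec {spec!r}")


def strong_gradient_mask(phantom: DigitalPhantom,
                         threshold: float = 50e-6) -> np.ndarray:
    """Voxels with |Gz| above ``threshold`` (T/m) and nonzero signal."""
    return (np.abs(phantom.gz_map()) >= threshold) & (phantom.s0 > 0)
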