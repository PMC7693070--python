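"""Slice excitation profiles by numerical Bloch simulation.

The complex transverse magnetization M_xy(z) across the slice is obtained by
hard-pulse integration of the Bloch equations for a shaped RF pulse played
under the slice-select gradient, followed by the slice-refocusing lobe
(area −Gslice*T_pulse/2).  Transmit-field inhomogeneity enters as a
multiplicative scale ξ on the nominal flip angle; incomplete T1 relaxation
as the spoiled-GRE steady-state weighting; a through-slice background
gradient Gz superimposed on Gslice as the coordinate rescaling
z → z·λ with λ = Gslice/(Gz+Gslice).

T2 relaxation during the 2 ms pulse is neglected and spoiling is treated as
ideal (no transverse coherence across TRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import GAMMA, GAMMA_BAR, SequenceParams


@dataclass
class RFPulse:
    """Sampled RF amplitude envelope (arbitrary units, time-ordered)."""

    envelope: np.ndarray
    duration: float          # s
    time_bandwidth: float
    name: str = "custom"

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.envelope.size < 32:
            raise ValueError("envelope needs at least 32 samples")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def sinc_hanning_pulse(
    duration: float = 2e-3, time_bandwidth: float = 2.7, n_samples: int = 512
) -> RFPulse:
    """Hanning-windowed sinc pulse (the default excitation pulse).

    The sinc argument is scaled so the main lobe plus side lobes span the
    requested time-bandwidth product; the Hanning window apodizes the
    truncated side lobes.
    """
    t = np.linspace(-0.5, 0.5, n_samples)  # normalized time
    env = np.sinc(time_bandwidth * t) * (0.5 + 0.5 * np.cos(2 * np.pi * t))
    return RFPulse(env, duration, time_bandwidth, name="sinc-hanning")


@dataclass
class SliceProfile:
    """Complex transverse magnetization on a z-grid (unit M0)."""

    z_grid: np.ndarray   # m, symmetric about the slice centre
    mxy: np.ndarray      # complex, normalized to unit equilibrium magnetization
    mz: np.ndarray       # longitudinal component after excitation
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.mxy = np.asarray(self.mxy, dtype=complex)
        self.mz = np.asarray(self.mz, dtype=float)
        if not (self.z_grid.size == self.mxy.size == self.mz.size):
            raise ValueError("z_grid, mxy and mz must have equal length")
        if self.z_grid.size < 2:
            raise ValueError("degenerate z grid")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"z_m": self.z_grid, "re": self.mxy.real, "im": self.mxy.imag}
        ).to_csv(path, index=False)


def slice_select_gradient(params: SequenceParams) -> float:
    """Slice-select gradient amplitude Gslice (T/m).

    From the pulse bandwidth BW = TBW/T_pulse and the slice thickness:
    Gslice = BW / (γ̄ Δz).
    """
    if params.slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    bw = params.time_bandwidth / params.pulse_duration
    return bw / (GAMMA_BAR * params.slice_thickness)


def default_z_grid(slice_thickness: float, n_points: int = 2048, span: float = 3.0):
    """Symmetric z grid over ±span·Δz (captures out-of-slice ripple)."""
    half = span * slice_thickness
    return np.linspace(-half, half, n_points)


def simulate_profile(
    pulse: RFPulse,
    alpha_deg: float,
    b1_scale: float = 1.0,
    gslice: float = 0.0,
    z_grid: np.ndarray | None = None,
    slice_thickness: float | None = None,
    n_substeps: int = 512,
) -> SliceProfile:
    """Hard-pulse Bloch integration of the scaled RF envelope.

    The envelope is resampled to ``n_substeps`` hard sub-pulses; each step
    applies half the free precession under Gslice, the sub-pulse nutation,
    and the second half of the precession.  The envelope amplitude is
    calibrated so the on-resonance flip equals ``alpha_deg * b1_scale``.
    The slice-refocusing lobe is applied explicitly as a single free
    precession of area −Gslice*T_pulse/2.
    """
    if b1_scale <= 0:
        raise ValueError("b1_scale must be positive")
    if z_grid is None:
        if slice_thickness is None:
            raise ValueError("provide z_grid or slice_thickness")
        z_grid = default_z_grid(slice_thickness)
    z = np.asarray(z_grid, dtype=float)
    if z.size < 2:
        raise ValueError("degenerate z grid")

    dt = pulse.duration / n_substeps
    t_sub = (np.arange(n_substeps) + 0.5) / n_substeps - 0.5  # normalized
    t_env = np.linspace(-0.5, 0.5, pulse.envelope.size)
    env = np.interp(t_sub, t_env, pulse.envelope)
    alpha = np.deg2rad(alpha_deg) * b1_scale
    theta = env * (alpha / env.sum())  # per-step nutation, rad

    # Free precession under Gslice: mxy *= exp(-i*γ*Gslice*z*dt)
    half_prec = np.exp(-0.5j * GAMMA * gslice * z * dt)
    mxy = np.zeros(z.size, dtype=complex)
    mz = np.ones(z.size)
    for th in theta:
        mxy *= half_prec
        c, s = np.cos(th), np.sin(th)
        my = mxy.imag
        mxy = mxy.real + 1j * (my * c + mz * s)
        mz = mz * c - my * s
        mxy *= half_prec
    # Refocusing lobe, gradient area −Gslice*T_pulse/2.
    mxy *= np.exp(0.5j * GAMMA * gslice * z * pulse.duration)

    meta = {
        "alpha_deg": alpha_deg,
        "b1_scale": b1_scale,
        "gslice": gslice,
        "tr_over_t1": np.inf,
        "lambda": 1.0,
        "pulse": pulse.name,
    }
    return SliceProfile(z, mxy, mz, meta)


def apply_steady_state(profile: SliceProfile, tr_over_t1: float) -> SliceProfile:
    """Weight the profile with the spoiled-GRE steady state.

    Each position is scaled by (1−E1)/(1−E1·cosθ(z)) with E1 = exp(−TR/T1)
    and θ(z) the locally achieved flip angle (cosθ(z) = Mz(z) after the
    pulse, for unit equilibrium magnetization).
    """
    if tr_over_t1 <= 0:
        raise ValueError("tr_over_t1 must be positive")
    e1 = np.exp(-tr_over_t1)
    factor = (1.0 - e1) / (1.0 - e1 * np.clip(profile.mz, -1.0, 1.0))
    meta = dict(profile.meta, tr_over_t1=tr_over_t1)
    return SliceProfile(profile.z_grid, profile.mxy * factor, profile.mz, meta)


def slice_rescale_factor(gz: float, gslice: float) -> float:
    """λ = Gslice/(Gz+Gslice): effective slice-thickness scaling under Gz."""
    denom = gz + gslice
    if abs(denom) < 1e-12 * max(abs(gslice), 1e-30):
        raise ValueError("Gz = -Gslice: slice selection is singular")
    return gslice / denom


def lambda_rescale(profile: SliceProfile, gz: float, gslice: float) -> SliceProfile:
    """Rescale the z axis by λ for a superimposed through-slice gradient.

    During excitation Gz adds to Gslice, so the spatial encoding changes
    from z to z' = z·λ and the nominal thickness Δz becomes Δz·λ.  The
    cached Gslice-only profile is reused; only its coordinates change.
    """
    lam = slice_rescale_factor(gz, gslice)
    meta = dict(profile.meta, **{"lambda": lam, "gz": gz})
    return SliceProfile(profile.z_grid * lam, profile.mxy, profile.mz, meta)


def rectangular_profile(
    slice_thickness: float, n_points: int = 2048, span: float = 3.0,
    amplitude: float = 1.0,
) -> SliceProfile:
    """Ideal box-car slice profile (analytic reference model).

    With this profile the dephasing function reduces to the classical
    sinc(γ̄·G·Δz·TE) law.
    """
    z = default_z_grid(slice_thickness, n_points, span)
    mxy = np.where(np.abs(z) <= slice_thickness / 2, amplitude, 0.0).astype(complex)
    mz = np.sqrt(np.clip(1.0 - np.abs(mxy) ** 2, 0.0, 1.0))
    return SliceProfile(z, mxy, mz, {"pulse": "ideal-rect", "lambda": 1.0,
                                     "tr_over_t1": np.inf, "gslice": 0.0})
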