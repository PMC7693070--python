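"""Through-slice dephasing function F_zshim.

For a voxel with through-slice field gradient Gz and per-echo mean
compensation gradient Gbar_c,i, the echo-i signal attenuation is

    F_i = ∫ M_xy(z) exp(i γ (Gz + Gbar_c,i) z TE_i) dz / ∫ M_xy(z) dz

evaluated on the λ-rescaled slice profile.  The normalization by
∫M_xy dz fixes F(TE→0) = 1, so S0 absorbs the profile integral and stays
interpretable as the extrapolated TE = 0 signal.

Because λ-rescaling only scales the z coordinates of a cached Gslice-only
profile, F reduces to a function of the scalar phase-ramp slope
u = γ (Gz + Gbar_c,i) λ(Gz) TE_i on the unscaled grid, which makes bulk
voxelwise evaluation a chunked matrix product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .sequence import GAMMA
from .excitation import SliceProfile, slice_rescale_factor
from .patterns import ShimPattern


def _trapezoid_weights(z: np.ndarray) -> np.ndarray:
    w = np.empty_like(z)
    w[1:-1] = 0.5 * (z[2:] - z[:-2])
    w[0] = 0.5 * (z[1] - z[0])
    w[-1] = 0.5 * (z[-1] - z[-2])
    return w


def f_zshim(
    profile: SliceProfile, gz: float, pattern: ShimPattern, echo_index: int
) -> complex:
    """Dephasing factor for one echo (0-based ``echo_index``).

    ``profile`` must already be λ-rescaled for this Gz; the compensation
    gradients do not enter λ (they act between excitations, not during).
    """
    z = profile.z_grid
    if z.size < 2:
        raise ValueError("empty profile")
    w = _trapezoid_weights(z)
    norm = np.sum(w * profile.mxy)
    if abs(norm) < 1e-12 * np.sum(w * np.abs(profile.mxy)) or abs(norm) == 0:
        raise ValueError("profile integral is (numerically) zero")
    g_tot = gz + pattern.mean_gradients[echo_index]
    te = pattern.echo_times[echo_index]
    phase = np.exp(1j * GAMMA * g_tot * z * te)
    return complex(np.sum(w * profile.mxy * phase) / norm)


def dephasing_factors(
    profile: SliceProfile,
    gz_values: np.ndarray,
    pattern: ShimPattern,
    gslice: float,
    echo_times: np.ndarray | None = None,
    mean_gradients: np.ndarray | None = None,
    chunk: int = 4096,
) -> np.ndarray:
    """F for many voxels at once, λ-rescaling applied per Gz.

    ``profile`` is the cached Gslice-only profile (unscaled).  Returns a
    complex array of shape ``(len(gz_values), n_echoes)``.
    """
    gz_values = np.atleast_1d(np.asarray(gz_values, dtype=float))
    te = pattern.echo_times if echo_times is None else np.asarray(echo_times)
    gc = pattern.mean_gradients if mean_gradients is None else np.asarray(mean_gradients)
    z = profile.z_grid
    w = _trapezoid_weights(z)
    wm = w * profile.mxy
    norm = wm.sum()
    if abs(norm) == 0:
        raise ValueError("profile integral is zero")
    if gslice != 0.0:
        lam = np.array([slice_rescale_factor(g, gslice) for g in gz_values])
    else:
        lam = np.ones_like(gz_values)
    # phase-ramp slope per (voxel, echo)
    u = GAMMA * (gz_values[:, None] + gc[None, :]) * lam[:, None] * te[None, :]
    u_flat = u.reshape(-1)
    out = np.empty(u_flat.size, dtype=complex)
    for start in range(0, u_flat.size, chunk):
        sl = slice(start, start + chunk)
        out[sl] = wm @ np.exp(1j * np.outer(z, u_flat[sl]))
    return (out / norm).reshape(u.shape)


@dataclass
class DephasingTable:
    """F_zshim sampled on a uniform Gz grid for fast voxelwise lookup."""

    gz_grid: np.ndarray      # T/m, uniform spacing
    echo_times: np.ndarray   # s
    values: np.ndarray       # complex, shape (n_gz, n_echoes)
    pattern_id: str = ""

    def __post_init__(self) -> None:
        self.gz_grid = np.asarray(self.gz_grid, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.gz_grid.size, self.echo_times.size):
            raise ValueError("values must have shape (n_gz, n_echoes)")

    def in_range(self, gz) -> np.ndarray:
        gz = np.asarray(gz, dtype=float)
        return (gz >= self.gz_grid[0]) & (gz <= self.gz_grid[-1])

    def lookup(self, gz: float) -> np.ndarray:
        """Linearly interpolated complex F per echo at one Gz (T/m)."""
        if not self.in_range(gz):
            raise ValueError(
                f"Gz={gz:.3g} T/m outside table range "
                f"[{self.gz_grid[0]:.3g}, {self.gz_grid[-1]:.3g}]"
            )
        re = np.empty(self.echo_times.size)
        im = np.empty(self.echo_times.size)
        for i in range(self.echo_times.size):
            re[i] = np.interp(gz, self.gz_grid, self.values[:, i].real)
            im[i] = np.interp(gz, self.gz_grid, self.values[:, i].imag)
        return re + 1j * im

    def lookup_many(self, gz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated F for an array of Gz values.

        Returns ``(F, valid)``; rows of ``F`` for out-of-range Gz are NaN
        and flagged False in ``valid``.
        """
        gz = np.asarray(gz, dtype=float)
        valid = self.in_range(gz)
        out = np.full((gz.size, self.echo_times.size), np.nan, dtype=complex)
        gz_ok = np.clip(gz[valid], self.gz_grid[0], self.gz_grid[-1])
        for i in range(self.echo_times.size):
            re = np.interp(gz_ok, self.gz_grid, self.values[:, i].real)
            im = np.interp(gz_ok, self.gz_grid, self.values[:, i].imag)
            out[valid, i] = re + 1j * im
        return out, valid

    def to_npz(self, path, sidecar: str | None = None) -> None:
        np.savez(path, gz_grid=self.gz_grid, echo_times=self.echo_times,
                 values=self.values)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "pattern_id": self.pattern_id,
                        "gz_grid_uT_per_m": (self.gz_grid * 1e6).tolist(),
                        "echo_times_s": self.echo_times.tolist(),
                    },
                    fh, indent=2,
                )

    @classmethod
    def from_npz(cls, path, pattern_id: str = "") -> "DephasingTable":
        d = np.load(path)
        return cls(d["gz_grid"], d["echo_times"], d["values"], pattern_id)


def build_table(
    profile: SliceProfile,
    pattern: ShimPattern,
    gslice: float,
    gz_min: float = -300e-6,
    gz_max: float = 300e-6,
    step: float = 10e-6,
) -> DephasingTable:
    """Tabulate F over a uniform Gz grid (default ±300 µT/m at 10 µT/m).

    λ-rescaling is applied per grid point.  The grid must not cross the
    slice-selection singularity at Gz = −Gslice.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if gslice != 0.0 and gz_min < -gslice < gz_max:
        raise ValueError("gz range crosses the λ singularity at -Gslice")
    n = int(round((gz_max - gz_min) / step)) + 1
    grid = gz_min + step * np.arange(n)
    values = dephasing_factors(profile, grid, pattern, gslice)
    return DephasingTable(grid, pattern.echo_times.copy(), values,
                          pattern_id=pattern.scheme_label)
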