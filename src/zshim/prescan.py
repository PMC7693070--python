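"""Prescan processing: from a 3-echo phase series to per-slice shim gradients.

Pipeline: unwrap the phase volumes, form the field map from the phase
difference between the third and first echo, mask by magnitude threshold
plus slicewise disk erosion, differentiate along the slice axis, smooth
with a masked 3D Gaussian, quantize to 10 µT/m bin centres, and select the
per-slice compensation-gradient extrema.

Sign convention: the per-slice selection negates the field-gradient
extremum so that the compensation gradient *opposes* Gz — the positive
shim g_plus = −min(Gz<0) rephases the most negative field gradient in the
slice, and g_minus = −max(Gz>0) the most positive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import unwrap_phase as _unwrap3d

from .sequence import GAMMA_BAR, UT_PER_M
from .patterns import SliceShimSelection


@dataclass
class FieldGradientMap:
    """Per-voxel through-slice field gradient with validity mask."""

    gz: np.ndarray            # T/m
    mask: np.ndarray          # bool
    voxel_size: tuple         # (dx, dy, dz) in m
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.gz = np.asarray(self.gz, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.gz.shape != self.mask.shape:
            raise ValueError("gz and mask shapes differ")
        if not np.all(np.isfinite(self.gz[self.mask])):
            raise ValueError("non-finite gz inside mask")

    @property
    def n_slices(self) -> int:
        return self.gz.shape[self.slice_axis]

    def slice_values(self, n: int) -> np.ndarray:
        """Masked gz values of slice n (1D array, possibly empty)."""
        gz_sl = np.take(self.gz, n, axis=self.slice_axis)
        m_sl = np.take(self.mask, n, axis=self.slice_axis)
        return gz_sl[m_sl]


def unwrap_phase(phase: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Unwrap a wrapped phase volume (values in (−π, π]).

    Disconnected mask regions are unwrapped independently; their outputs may
    differ by region-constant 2π multiples, which cancel in any spatial
    gradient taken downstream.
    """
    phase = np.asarray(phase, dtype=float)
    if mask is not None:
        arr = np.ma.array(phase, mask=~np.asarray(mask, dtype=bool))
        out = _unwrap3d(arr)
        return np.ma.filled(out, fill_value=0.0)
    return np.asarray(_unwrap3d(phase))


def field_map(
    phase_te1: np.ndarray, phase_te3: np.ndarray, te1: float, te3: float
) -> np.ndarray:
    """Field map in Hz from two unwrapped phase volumes.

    f = (φ3 − φ1) / (2π (TE3 − TE1)).  Divide by γ̄ for tesla.
    """
    if te3 <= te1:
        raise ValueError("te3 must exceed te1")
    return (np.asarray(phase_te3) - np.asarray(phase_te1)) / (
        2.0 * np.pi * (te3 - te1)
    )


def make_mask(
    magnitude: np.ndarray,
    threshold: float | str = "otsu",
    erosion_radius_px: int = 5,
    slice_axis: int = 2,
) -> np.ndarray:
    """Magnitude-threshold mask, eroded slicewise with a disk element."""
    if erosion_radius_px < 0:
        raise ValueError("erosion_radius_px must be >= 0")
    magnitude = np.asarray(magnitude, dtype=float)
    if threshold == "otsu":
        threshold = threshold_otsu(magnitude)
    mask = magnitude > threshold
    if erosion_radius_px > 0:
        selem = disk(erosion_radius_px)
        mask = np.moveaxis(
            np.stack(
                [
                    ndimage.binary_erosion(np.take(mask, k, axis=slice_axis),
                                           structure=selem)
                    for k in range(mask.shape[slice_axis])
                ],
                axis=-1,
            ),
            -1,
            slice_axis,
        )
    if not mask.any():
        warnings.warn("mask is empty after thresholding/erosion", stacklevel=2)
    return mask


def _masked_axis_gradient(
    field: np.ndarray, mask: np.ndarray, spacing: float, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """Central differences inside the mask, one-sided at mask/volume edges.

    Voxels with no in-mask neighbour along the axis cannot be
    differentiated and are dropped from the returned mask.
    """
    f = np.moveaxis(field, axis, -1)
    m = np.moveaxis(mask, axis, -1)
    n = f.shape[-1]
    grad = np.zeros_like(f)
    ok = np.zeros_like(m)
    fm = np.where(m, f, 0.0)
    for k in range(n):
        prev_ok = m[..., k - 1] if k > 0 else np.zeros(m.shape[:-1], bool)
        next_ok = m[..., k + 1] if k < n - 1 else np.zeros(m.shape[:-1], bool)
        here = m[..., k]
        central = here & prev_ok & next_ok
        fwd = here & next_ok & ~prev_ok
        bwd = here & prev_ok & ~next_ok
        if central.any():
            grad[..., k][central] = (
                fm[..., (k + 1) % n][central] - fm[..., k - 1][central]
            ) / (2 * spacing)
        if fwd.any():
            grad[..., k][fwd] = (fm[..., k + 1][fwd] - fm[..., k][fwd]) / spacing
        if bwd.any():
            grad[..., k][bwd] = (fm[..., k][bwd] - fm[..., k - 1][bwd]) / spacing
        ok[..., k] = central | fwd | bwd
    return np.moveaxis(grad, -1, axis), np.moveaxis(ok, -1, axis)


def _masked_gaussian(field, mask, sigma):
    """Normalized masked Gaussian convolution (no bleed across the mask)."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(field * m, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    out = np.zeros_like(field)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    return out


def gradient_map(
    field_hz: np.ndarray,
    mask: np.ndarray,
    voxel_size: tuple,
    smoothing_kernel: float = 1.0,
    slice_axis: int = 2,
) -> FieldGradientMap:
    """Through-slice field-gradient map Gz (T/m) from a field map in Hz.

    Central differences along the slice axis (one-sided at volume and mask
    edges), conversion to T/m via 1/γ̄, then masked Gaussian smoothing with
    σ = ``smoothing_kernel`` voxels (3D).
    """
    field_hz = np.asarray(field_hz, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if field_hz.shape[slice_axis] < 2:
        raise ValueError("need at least 2 slices to differentiate")
    dz = voxel_size[slice_axis]
    field_t = field_hz / GAMMA_BAR
    gz, ok = _masked_axis_gradient(field_t, mask, dz, slice_axis)
    if smoothing_kernel > 0:
        gz = _masked_gaussian(gz, ok, smoothing_kernel)
    gz[~ok] = 0.0
    return FieldGradientMap(gz, ok, tuple(voxel_size), slice_axis)


def quantize_gz(fmap: FieldGradientMap, interval: float = 10e-6) -> FieldGradientMap:
    """Quantize Gz to bin centres: q = (floor(gz/Δ) + ½)·Δ.

    Bin centres are odd multiples of Δ/2, so a value is never mapped to
    exactly zero; idempotent.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    q = (np.floor(fmap.gz / interval) + 0.5) * interval
    q[~fmap.mask] = 0.0
    return FieldGradientMap(q, fmap.mask, fmap.voxel_size, fmap.slice_axis)


def select_slice_gradients(fmap: FieldGradientMap) -> list[SliceShimSelection]:
    """Per-slice compensation extrema from a quantized gradient map.

    g_plus = −min(Gz<0) (or 0 if the slice has no negative Gz) and
    g_minus = −max(Gz>0) (or 0 likewise); an empty slice mask yields
    (0, 0) with a warning.
    """
    selections = []
    for n in range(fmap.n_slices):
        vals = fmap.slice_values(n)
        if vals.size == 0:
            warnings.warn(f"slice {n}: empty mask, selecting zero shims",
                          stacklevel=2)
            selections.append(SliceShimSelection(n, 0.0, 0.0))
            continue
        neg = vals[vals < 0]
        pos = vals[vals > 0]
        g_plus = -neg.min() if neg.size else 0.0
        g_minus = -pos.max() if pos.size else 0.0
        selections.append(SliceShimSelection(n, float(g_plus), float(g_minus)))
    return selections


def selections_to_frame(selections) -> pd.DataFrame:
    """Tabulate selections with gradients in µT/m."""
    return pd.DataFrame(
        {
            "slice": [s.slice_index for s in selections],
            "g_plus_uT_per_m": [s.g_plus / UT_PER_M for s in selections],
            "g_minus_uT_per_m": [s.g_minus / UT_PER_M for s in selections],
        }
    )


def selections_from_frame(df: pd.DataFrame) -> list[SliceShimSelection]:
    return [
        SliceShimSelection(int(r["slice"]),
                           float(r["g_plus_uT_per_m"]) * UT_PER_M,
                           float(r["g_minus_uT_per_m"]) * UT_PER_M)
        for _, r in df.iterrows()
    ]


def process_prescan(
    magnitude: np.ndarray,
    phase: np.ndarray,
    echo_times: np.ndarray,
    voxel_size: tuple,
    threshold: float | str = "otsu",
    erosion_radius_px: int = 5,
    smoothing_kernel: float = 1.0,
    quantization_interval: float = 10e-6,
    slice_axis: int = 2,
    mask: np.ndarray | None = None,
) -> tuple[FieldGradientMap, list[SliceShimSelection]]:
    """Full prescan pipeline: phase series in, quantized Gz map and
    per-slice selections out.

    ``magnitude``/``phase`` are 4D arrays with echoes on the last axis;
    an externally supplied ``mask`` bypasses the threshold+erosion step.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if phase.shape[-1] < 3:
        raise ValueError("prescan needs 3 echoes")
    if mask is None:
        mask = make_mask(magnitude[..., 0], threshold, erosion_radius_px,
                         slice_axis)
    ph1 = unwrap_phase(phase[..., 0], mask)
    ph3 = unwrap_phase(phase[..., 2], mask)
    fmap_hz = field_map(ph1, ph3, echo_times[0], echo_times[2])
    gmap = gradient_map(fmap_hz, mask, voxel_size, smoothing_kernel, slice_axis)
    gmap_q = quantize_gz(gmap, quantization_interval)
    return gmap_q, select_slice_gradients(gmap_q)
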