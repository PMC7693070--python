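"""Model inversion: navigator correction and voxelwise R2* estimation.

The model-based fit minimizes, per voxel,

    sum_i ( |S_i| − S0 · exp(−R2*·TE_i) · |F_i(Gz)| )²

over S0 ≥ 0 and R2* ∈ [0, r2_max], with |F| interpolated from a
precomputed dephasing table at the voxel's through-slice gradient.  The
magnitude of F enters the objective (magnitude data are fitted; the phase
of F is discarded).  Initialization is a deterministic log-linear
regression on the leading unshimmed echoes, which are least contaminated
by F at small Gz.  The mono-exponential baseline fit is the same optimizer
with F ≡ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dephasing import DephasingTable
from .prescan import FieldGradientMap
from .simulate import EchoSeries

STATUS_CONVERGED = 0
STATUS_MAX_ITER = 1
STATUS_EXCLUDED = 2


@dataclass
class FitOptions:
    r2_max: float = 500.0        # 1/s, upper fit bound
    xtol: float = 1e-8           # relative step convergence
    max_iter: int = 200
    min_echoes: int = 3


@dataclass
class R2StarFit:
    """Voxelwise fit result; excluded voxels are flagged, never zeroed."""

    r2star: np.ndarray
    s0: np.ndarray
    residual_norm: np.ndarray
    status: np.ndarray           # STATUS_* codes
    method: str
    mask: np.ndarray = None

    def converged_mask(self) -> np.ndarray:
        return self.status == STATUS_CONVERGED


def navigator_correct(series: EchoSeries, reference_shot: int = 0) -> EchoSeries:
    """Remove per-shot physiological phase using the navigator echo.

    For shot s (one phase-encode line of one slice) the navigator phase
    offset Δφ(s) relative to the reference shot is scaled linearly in TE:
    echo i is multiplied by exp(−i·Δφ(s)·TE_i/TE_navi).  Magnitude-only
    input cannot be corrected and is returned unchanged with a warning.
    """
    if series.is_magnitude:
        warnings.warn("magnitude-only input: navigator correction skipped",
                      stacklevel=2)
        return series
    if series.navigator is None or series.te_navigator is None:
        raise ValueError("series has no navigator echo")
    nav = series.navigator  # (n_shots, n_slices)
    ref = nav[reference_shot][None, :]
    dphi = np.angle(nav * np.conj(ref))
    scale = series.echo_times / series.te_navigator
    corr = np.exp(-1j * dphi[None, :, :, None] * scale[None, None, None, :])
    return EchoSeries(
        data=series.data * corr,
        echo_times=series.echo_times,
        te_navigator=series.te_navigator,
        navigator=nav * np.exp(-1j * dphi),
        patterns=series.patterns,
        meta=dict(series.meta, navigator_corrected=True),
    )


def _loglinear_init(y: np.ndarray, te: np.ndarray, n_lead: int,
                    r2_max: float) -> tuple[float, float]:
    """Deterministic start point from the leading unshimmed echoes."""
    n_lead = max(2, min(n_lead, te.size))
    yy = np.maximum(y[:n_lead], 1e-12 * max(y.max(), 1e-30))
    slope, intercept = np.polyfit(te[:n_lead], np.log(yy), 1)
    r2_0 = float(np.clip(-slope, 0.0, r2_max))
    s0_0 = float(np.exp(intercept))
    return s0_0, r2_0


def _fit_voxel(y, te, fmag, opts: FitOptions):
    s0_0, r2_0 = _loglinear_init(y, te, opts.min_echoes, opts.r2_max)

    def resid(p):
        return p[0] * np.exp(-p[1] * te) * fmag - y

    def jac(p):
        e = np.exp(-p[1] * te) * fmag
        return np.column_stack([e, -p[0] * te * e])

    res = least_squares(
        resid, x0=[max(s0_0, 1e-12), r2_0], jac=jac,
        bounds=([0.0, 0.0], [np.inf, opts.r2_max]),
        xtol=opts.xtol, ftol=1e-12, gtol=1e-12,
        max_nfev=opts.max_iter,
    )
    status = STATUS_CONVERGED if res.status > 0 and res.nfev < opts.max_iter \
        else STATUS_MAX_ITER
    return res.x[0], res.x[1], float(np.linalg.norm(res.fun)), status


def _run_fit(mag, te, fmag_per_voxel, valid, n_lead, opts, method):
    shape = mag.shape[:-1]
    r2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    resn = np.full(shape, np.nan)
    status = np.full(shape, STATUS_EXCLUDED, dtype=np.int8)
    opts_local = FitOptions(opts.r2_max, opts.xtol, opts.max_iter, n_lead)
    for flat_idx, idx in enumerate(np.ndindex(shape)):
        y = mag[idx]
        if not valid.flat[flat_idx] or np.max(y) <= 0:
            continue  # excluded: out of table range, masked out, or all-zero
        s0[idx], r2[idx], resn[idx], status[idx] = _fit_voxel(
            y, te, fmag_per_voxel[flat_idx], opts_local
        )
    return R2StarFit(r2, s0, resn, status, method, mask=valid.reshape(shape))


def fit_r2star_model(
    series: EchoSeries,
    gz_map: FieldGradientMap | np.ndarray,
    tables: DephasingTable | list[DephasingTable],
    options: FitOptions | None = None,
) -> R2StarFit:
    """Model-based voxelwise (S0, R2*) fit using a dephasing table.

    ``tables`` is either a single table (same shim pattern for all slices)
    or one per slice.  Voxels whose Gz falls outside the table range, or
    outside the gradient-map mask, are excluded (status flag) rather than
    fitted.
    """
    opts = options or FitOptions()
    mag = series.magnitude()
    nx, ny, nz, ne = mag.shape
    if isinstance(gz_map, FieldGradientMap):
        gz = gz_map.gz
        mask = gz_map.mask
    else:
        gz = np.asarray(gz_map, dtype=float)
        mask = np.ones(gz.shape, dtype=bool)
    if gz.shape != (nx, ny, nz):
        raise ValueError("gz map not registered to the series grid")
    if isinstance(tables, DephasingTable):
        tables = [tables] * nz

    n_lead = int(series.meta.get("n_unshimmed_echoes", 3))
    te = series.echo_times
    fmag = np.empty((nx * ny * nz, ne))
    valid = np.zeros(nx * ny * nz, dtype=bool)
    # flatten in C order over (nx, ny, nz), matching np.ndindex in _run_fit
    flat_gz = gz.reshape(-1)
    flat_mask = mask.reshape(-1)
    slice_of = np.tile(np.arange(nz), nx * ny)
    for k in range(nz):
        rows = slice_of == k
        f, ok = tables[k].lookup_many(flat_gz[rows])
        fmag[rows] = np.abs(f)
        valid[rows] = ok & flat_mask[rows]
    return _run_fit(mag, te, fmag, valid, n_lead, opts, "model-based")


def fit_r2star_mono(
    series: EchoSeries, options: FitOptions | None = None
) -> R2StarFit:
    """Mono-exponential baseline fit (F ≡ 1), same optimizer and bounds."""
    opts = options or FitOptions()
    mag = series.magnitude()
    shape = mag.shape[:-1]
    n_vox = int(np.prod(shape))
    fmag = np.ones((n_vox, mag.shape[-1]))
    valid = (mag.max(axis=-1) > 0).reshape(-1)
    n_lead = int(series.meta.get("n_unshimmed_echoes", 3))
    return _run_fit(mag, series.echo_times, fmag, valid, n_lead, opts,
                    "mono-exponential")


def summarize_regions(fit: R2StarFit, labels: np.ndarray) -> pd.DataFrame:
    """Per-region median and interquartile range of fitted R2*.

    Percentiles use linear interpolation between order statistics.
    Excluded voxels are omitted; empty regions raise.
    """
    labels = np.asarray(labels)
    if labels.shape != fit.r2star.shape:
        raise ValueError("labels not aligned with fit maps")
    rows = []
    for lab in np.unique(labels[labels > 0]):
        sel = (labels == lab) & (fit.status != STATUS_EXCLUDED)
        vals = fit.r2star[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region {lab} has no fitted voxels")
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"region": int(lab), "n_voxels": int(vals.size),
             "median": q50, "iqr": q75 - q25}
        )
    return pd.DataFrame(rows)
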