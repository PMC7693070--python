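"""Compensation-gradient moment trains (z-shim patterns).

A z-shim pattern is a train of gradient moments m_c,k (T*s/m) inserted
between echo acquisitions along the slice axis.  For signal modelling only
the accumulated moment at each echo matters; it is expressed as an
equivalent *mean compensation gradient* acting over the whole echo time:

    M_c,i = sum_{k<=i} m_c,k = Gbar_c,i * TE_i

Three schemes are implemented:

``off``
    No compensation gradients.
``global``
    Alternating pairs with a linear increase along TE: one positive and one
    negative mean gradient (fixed for all slices), each pair rewound to zero
    net moment before the next echo.
``adaptive``
    Slice-specific: the per-slice extrema (g_plus, g_minus) from the prescan
    are each split into fractions 1/3, 2/3, 3/3 applied on consecutive
    echoes, followed by a moment-nulling echo; if one of the two is zero the
    other is split into five fractions 1/5 ... 5/5 instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence import SequenceParams, UT_PER_M


@dataclass
class SliceShimSelection:
    """Per-slice compensation-gradient extrema chosen from the prescan."""

    slice_index: int
    g_plus: float   # T/m, >= 0
    g_minus: float  # T/m, <= 0

    def __post_init__(self) -> None:
        if self.g_plus < 0:
            raise ValueError("g_plus must be >= 0")
        if self.g_minus > 0:
            raise ValueError("g_minus must be <= 0")


@dataclass
class ShimPattern:
    """Mean compensation gradients and inter-echo moments for one slice."""

    echo_times: np.ndarray      # s
    mean_gradients: np.ndarray  # T/m per echo, Gbar_c,i
    moments: np.ndarray         # T*s/m per echo, m_c,k applied before echo k
    scheme_label: str = "off"

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.mean_gradients = np.asarray(self.mean_gradients, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        n = self.echo_times.size
        if self.mean_gradients.size != n or self.moments.size != n:
            raise ValueError("echo_times, mean_gradients and moments must have equal length")

    @property
    def accumulated_moments(self) -> np.ndarray:
        """M_c,i = cumulative sum of the inter-echo moments (T*s/m)."""
        return np.cumsum(self.moments)

    def required_amplitudes(self, tc: float) -> np.ndarray:
        """Gradient amplitude |m_c,k|/tc (T/m) needed to play each lobe."""
        return np.abs(self.moments) / tc

    def check_amplitude(self, tc: float, limit: float) -> None:
        """Warn if any lobe exceeds a hardware amplitude limit (T/m)."""
        amp = self.required_amplitudes(tc)
        if np.any(amp > limit):
            warnings.warn(
                f"compensation lobe amplitude {amp.max():.4g} T/m exceeds "
                f"limit {limit:.4g} T/m",
                stacklevel=2,
            )

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the pattern with gradients in µT/m and moments in µT*s/m."""
        return pd.DataFrame(
            {
                "echo": np.arange(1, self.echo_times.size + 1),
                "te_s": self.echo_times,
                "mean_gradient_uT_per_m": self.mean_gradients / UT_PER_M,
                "moment_uT_s_per_m": self.moments / UT_PER_M,
                "accumulated_moment_uT_s_per_m": self.accumulated_moments / UT_PER_M,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme_label,
            "te_s": self.echo_times.tolist(),
            "mean_gradient_uT_per_m": (self.mean_gradients / UT_PER_M).tolist(),
            "moment_uT_s_per_m": (self.moments / UT_PER_M).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ShimPattern":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            echo_times=np.asarray(payload["te_s"]),
            mean_gradients=np.asarray(payload["mean_gradient_uT_per_m"]) * UT_PER_M,
            moments=np.asarray(payload["moment_uT_s_per_m"]) * UT_PER_M,
            scheme_label=payload.get("scheme", "off"),
        )


def mean_gradients_from_moments(moments, params: SequenceParams) -> np.ndarray:
    """Convert inter-echo moments to per-echo mean compensation gradients.

    Gbar_c,i = (sum_{k<=i} m_c,k) / TE_i.
    """
    moments = np.asarray(moments, dtype=float)
    te = params.echo_times
    if moments.size != te.size:
        raise ValueError(
            f"expected {te.size} moments, got {moments.size}"
        )
    return np.cumsum(moments) / te


def moments_from_mean_gradients(mean_gradients, params: SequenceParams) -> np.ndarray:
    """Convert per-echo mean gradients to inter-echo moments.

    m_c,i = Gbar_c,i*TE_i − Gbar_c,i−1*TE_i−1 (first difference of the
    accumulated moment); the exact inverse of
    :func:`mean_gradients_from_moments`.
    """
    g = np.asarray(mean_gradients, dtype=float)
    te = params.echo_times
    if g.size != te.size:
        raise ValueError(f"expected {te.size} mean gradients, got {g.size}")
    acc = g * te
    return np.diff(acc, prepend=0.0)


def _pattern_from_mean_gradients(g, params, label) -> ShimPattern:
    return ShimPattern(
        echo_times=params.echo_times,
        mean_gradients=np.asarray(g, dtype=float),
        moments=moments_from_mean_gradients(g, params),
        scheme_label=label,
    )


def build_off_pattern(params: SequenceParams) -> ShimPattern:
    """All-zero pattern of the plain spoiled mGRE sequence."""
    return _pattern_from_mean_gradients(
        np.zeros(params.n_echoes), params, "off"
    )


def build_global_pattern(
    params: SequenceParams, g_plus: float, g_minus: float
) -> ShimPattern:
    """Global alternating-pair pattern: (g_plus, 0, g_minus, 0, ...).

    Mean gradients repeat with period 4 over the shimmed echoes; every
    second shimmed echo has zero accumulated moment (a plain GRE image).
    """
    if not (g_plus >= 0 >= g_minus):
        raise ValueError("need g_plus >= 0 >= g_minus")
    n, n0 = params.n_echoes, params.n_unshimmed_echoes
    n_shimmed = n - n0
    if n_shimmed < 2:
        raise ValueError("global pattern needs at least 2 shimmed echoes")
    block = np.array([g_plus, 0.0, g_minus, 0.0])
    g = np.zeros(n)
    g[n0:] = np.resize(block, n_shimmed)
    return _pattern_from_mean_gradients(g, params, "global")


def adaptive_fraction_sequence(selection: SliceShimSelection) -> np.ndarray:
    """One period of adaptive mean gradients (before tiling over echoes).

    Both extrema nonzero: (1/3, 2/3, 1)*g_plus, 0, (1/3, 2/3, 1)*g_minus, 0.
    One zero: (1/5, ..., 5/5)*(the nonzero one), 0.  Both zero: (0,).
    """
    gp, gm = selection.g_plus, selection.g_minus
    if gp != 0 and gm != 0:
        thirds = np.array([1, 2, 3]) / 3.0
        return np.concatenate([thirds * gp, [0.0], thirds * gm, [0.0]])
    g = gp if gp != 0 else gm
    if g == 0:
        return np.zeros(1)
    fifths = np.array([1, 2, 3, 4, 5]) / 5.0
    return np.concatenate([fifths * g, [0.0]])


def build_adaptive_pattern(
    params: SequenceParams, selection: SliceShimSelection
) -> ShimPattern:
    """Slice-specific fractional pattern, truncated at the last echo."""
    n, n0 = params.n_echoes, params.n_unshimmed_echoes
    block = adaptive_fraction_sequence(selection)
    g = np.zeros(n)
    g[n0:] = np.resize(block, n - n0)
    return _pattern_from_mean_gradients(g, params, "adaptive")


def build_pattern(
    params: SequenceParams,
    scheme: str,
    selection: SliceShimSelection | None = None,
    g_plus: float = 0.0,
    g_minus: float = 0.0,
) -> ShimPattern:
    """Dispatch on scheme name: 'off', 'global' or 'adaptive'."""
    if scheme == "off":
        return build_off_pattern(params)
    if scheme == "global":
        return build_global_pattern(params, g_plus, g_minus)
    if scheme == "adaptive":
        if selection is None:
            raise ValueError("adaptive scheme requires a SliceShimSelection")
        return build_adaptive_pattern(params, selection)
    raise ValueError(f"unknown scheme {scheme!r}")
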