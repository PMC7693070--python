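"""Sequence parameters and scanner presets.

All internal quantities are SI (seconds, tesla, metres).  Gradients in
user-facing files (CSV/JSON) are µT/m; conversion happens only at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: Reduced gyromagnetic ratio of the proton, Hz/T.
GAMMA_BAR = 42.577e6
#: Gyromagnetic ratio of the proton, rad/(s*T).
GAMMA = 2.0 * np.pi * GAMMA_BAR

#: Gradient unit conversion.
UT_PER_M = 1e-6  # 1 µT/m in T/m


@dataclass
class SequenceParams:
    """Timing and excitation parameters of a 2D spoiled mGRE acquisition.

    Parameters
    ----------
    echo_times
        Echo times TE_i in seconds, strictly increasing.  TE lists are always
        taken verbatim from configuration and never regenerated from nominal
        spacings (printed TE endpoints are not exactly arithmetic).
    n_unshimmed_echoes
        Number of leading echoes acquired without compensation gradients
        (the z-shim train starts after these, avoiding signal crushing of
        the early echoes).
    delta_te_shimmed
        Nominal echo spacing in the shimmed part of the train (s).
    tc
        Duration of each compensation gradient lobe (s).
    tr
        Repetition time (s).
    flip_angle_deg
        Nominal excitation flip angle alpha (degrees).
    slice_thickness
        Nominal slice thickness Δz (m).
    pulse_duration
        RF pulse duration T_pulse (s).
    time_bandwidth
        Time-bandwidth product of the RF pulse (dimensionless).
    te_navigator
        Echo time of the navigator echo (s), or None if not acquired.
    """

    echo_times: np.ndarray
    n_unshimmed_echoes: int = 4
    delta_te_shimmed: float = 0.0
    tc: float = 2e-3
    tr: float = 3.0
    flip_angle_deg: float = 60.0
    slice_thickness: float = 4e-3
    pulse_duration: float = 2e-3
    time_bandwidth: float = 2.7
    te_navigator: float | None = None

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        te = self.echo_times
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times must be a non-empty 1D sequence")
        if np.any(te <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if not (1 <= self.n_unshimmed_echoes < te.size):
            raise ValueError(
                "n_unshimmed_echoes must be >= 1 and smaller than the echo count"
            )
        if self.tc <= 0:
            raise ValueError("tc must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if not (0 < self.flip_angle_deg <= 180):
            raise ValueError("flip_angle_deg must lie in (0, 180]")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["echo_times"] = self.echo_times.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        return cls(**d)


def phantom_params() -> SequenceParams:
    """20-echo phantom protocol (3 T, 4 mm slices, TR 3 s, alpha 60 deg).

    The first four echoes (2.8–12.9 ms) carry no shim gradients; echoes
    5–20 (18.2–98.8 ms) interleave with 2 ms compensation lobes; a navigator
    follows at 103.4 ms.  TE lists interpolate linearly between the printed
    endpoints.
    """
    te = np.concatenate([
        np.linspace(2.8e-3, 12.9e-3, 4),
        np.linspace(18.2e-3, 98.8e-3, 16),
    ])
    return SequenceParams(
        echo_times=te,
        n_unshimmed_echoes=4,
        delta_te_shimmed=float(te[5] - te[4]),
        tc=2e-3,
        tr=3.0,
        flip_angle_deg=60.0,
        slice_thickness=4e-3,
        pulse_duration=2e-3,
        time_bandwidth=2.7,
        te_navigator=103.4e-3,
    )


def invivo_params() -> SequenceParams:
    """16-echo head protocol (3 T, 3 mm slices, TR 2.5 s, alpha 60 deg)."""
    te = np.concatenate([
        np.linspace(3.0e-3, 9.7e-3, 4),
        np.linspace(13.9e-3, 60.6e-3, 12),
    ])
    return SequenceParams(
        echo_times=te,
        n_unshimmed_echoes=4,
        delta_te_shimmed=float(te[5] - te[4]),
        tc=2e-3,
        tr=2.5,
        flip_angle_deg=60.0,
        slice_thickness=3e-3,
        pulse_duration=2e-3,
        time_bandwidth=2.7,
        te_navigator=64.8e-3,
    )


def prescan_echo_times() -> np.ndarray:
    """Echo times of the 3-echo field-mapping prescan (s)."""
    return np.array([2.7e-3, 4.8e-3, 6.9e-3])
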