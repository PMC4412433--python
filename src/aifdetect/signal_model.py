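"""MRI signal <-> contrast-agent concentration conversion.

During bolus passage the T2*-weighted signal follows
``S(t) = S0 * exp(-kappa_vox * TE * C_t(t))``; inverting with the averaged
pre-contrast baseline gives ``C_t(t) = -ln(S/S_b) / (TE * kappa_vox)``.
``kappa_vox`` is unknown on clinical data; since the inversion is linear in
``1/(TE*kappa_vox)``, clustering and M-measure selection are invariant to it
and the default product of 1 simply reports concentrations in arbitrary
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalModelParams",
    "signal_from_concentration",
    "calibrate_kappa",
    "concentration_from_signal",
    "detect_bolus_arrival",
]


@dataclass(frozen=True)
class SignalModelParams:
    """Baseline signal ``s0``, susceptibility constant ``kappa_vox`` and echo
    time ``te`` (seconds)."""

    s0: float = 100.0
    kappa_vox: float = 1.0 / 0.03
    te: float = 0.03

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.kappa_vox <= 0 or self.te <= 0:
            raise ValueError("s0, kappa_vox and te must be positive")


def signal_from_concentration(conc: np.ndarray, params: SignalModelParams) -> np.ndarray:
    """Forward model ``S = s0 * exp(-kappa_vox * te * C)``; requires C >= 0."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    return params.s0 * np.exp(-params.kappa_vox * params.te * conc)


def calibrate_kappa(gm_nominal_peak_conc: float, te: float,
                    target_drop: float = 0.40) -> float:
    """Susceptibility constant producing a given fractional signal drop at the
    nominal grey-matter concentration peak.

    ``kappa_vox = -ln(1 - target_drop) / (te * gm_nominal_peak_conc)`` so the
    nominal GM signal minimum is ``(1 - target_drop) * s0``.
    """
    if gm_nominal_peak_conc <= 0:
        raise ValueError("gm_nominal_peak_conc must be positive")
    if not 0.0 < target_drop < 1.0:
        raise ValueError("target_drop must lie in (0, 1)")
    return -math.log(1.0 - target_drop) / (te * gm_nominal_peak_conc)


def concentration_from_signal(sig: np.ndarray, params: SignalModelParams,
                              grid=None,
                              baseline_window: np.ndarray | slice | None = None,
                              baseline_end_time: float = 26.0) -> np.ndarray:
    """Invert the signal model using an averaged pre-contrast baseline.

    ``S_b`` is the mean of ``sig`` over ``baseline_window``; when no window
    is given it defaults to all frames earlier than ``baseline_end_time``
    (which requires ``grid``).  Accepts a single curve or an
    ``(n_curves, n_frames)`` matrix (baseline averaged per curve).
    """
    sig = np.asarray(sig, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("signal values must be positive")
    if baseline_window is None:
        if grid is None:
            raise ValueError("need grid to derive the default baseline window")
        times = grid.times if hasattr(grid, "times") else np.asarray(grid, dtype=float)
        baseline_window = times < baseline_end_time
        if not np.any(baseline_window):
            raise ValueError("empty baseline window")
    base = sig[..., baseline_window]
    if base.shape[-1] == 0:
        raise ValueError("empty baseline window")
    s_b = base.mean(axis=-1, keepdims=True)
    return -np.log(sig / s_b) / (params.te * params.kappa_vox)


def detect_bolus_arrival(signals: np.ndarray, n_sd: float = 2.0,
                         min_baseline: int = 4) -> int:
    """Index of the first frame where the cohort-mean signal falls ``n_sd``
    standard deviations below its running pre-contrast baseline.

    Used on clinical data where the bolus arrival time is not known a
    priori; frames before the returned index form the baseline window.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    mean_curve = signals.mean(axis=0)
    for i in range(min_baseline, mean_curve.size):
        base = mean_curve[:i]
        sd = base.std()
        if sd == 0:
            continue
        if mean_curve[i] < base.mean() - n_sd * sd:
            return i
    raise ValueError("no bolus arrival detected")
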