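"""Closed-form MRI signal models for T1 mapping and their analytic consequences.

The steady-state RF-spoiled gradient-echo (SPGR) signal at flip angle
``alpha`` with repetition time TR is

    S = M0 * sin(k*alpha) * (1 - E1) / (1 - E1 * cos(k*alpha)),
    E1 = exp(-TR / T1),

where ``k`` is the transmit-field (B1+) ratio of actual to prescribed flip
angle.  Variable-flip-angle (VFA) T1 mapping acquires S at several flip
angles at fixed TR and inverts this relation; a wrong ``k`` therefore
propagates into a T1 bias, which :func:`predict_b1_bias` quantifies by
running the same linearized fit used on real data.

Inversion-recovery Look-Locker (MOLLI-type) acquisitions sample the
apparent recovery ``S(TI) = A - B * exp(-TI / T1*)``; the corrected
longitudinal relaxation time is ``T1 = T1* * (B/A - 1)``.

All angles at the public interfaces are in degrees, all times in
milliseconds; conversions to radians happen internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VfaAcquisition",
    "IrAcquisition",
    "Tissue",
    "spgr_signal",
    "e1",
    "ernst_angle",
    "ir_ll_signal",
    "look_locker_correction",
    "predict_b1_bias",
]


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


@dataclass(frozen=True)
class VfaAcquisition:
    """Variable-flip-angle SPGR acquisition parameters.

    Parameters
    ----------
    tr : float
        Repetition time in milliseconds, > 0.
    flip_angles : sequence of float
        Prescribed flip angles in degrees, strictly increasing, each in
        (0, 90].  At least two are required for a T1 fit.
    b1_ratio : float
        Ratio of actual to prescribed flip angle (transmit-field scale),
        > 0.  1.0 means a perfectly calibrated transmit field.
    """

    tr: float
    flip_angles: tuple = field(default=(2.0, 5.0, 8.0, 10.0, 12.0, 15.0))
    b1_ratio: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.tr) and self.tr > 0):
            raise ValueError(f"tr must be finite and > 0, got {self.tr}")
        fa = tuple(float(a) for a in self.flip_angles)
        if len(fa) < 2:
            raise ValueError("at least two flip angles are required")
        if any(not (0.0 < a <= 90.0) for a in fa):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if any(b <= a for a, b in zip(fa, fa[1:])):
            raise ValueError("flip angles must be strictly increasing")
        if not (math.isfinite(self.b1_ratio) and self.b1_ratio > 0):
            raise ValueError("b1_ratio must be finite and > 0")
        object.__setattr__(self, "flip_angles", fa)

    @property
    def effective_angles(self) -> np.ndarray:
        """Actual flip angles in degrees, ``b1_ratio * prescribed``."""
        return self.b1_ratio * np.asarray(self.flip_angles)


@dataclass(frozen=True)
class IrAcquisition:
    """Inversion-recovery (Look-Locker / MOLLI style) sampling scheme.

    ``inversion_times`` are in milliseconds and strictly increasing; the
    simulated ``heart_rate`` (beats/minute) spaces the readouts of a
    MOLLI-style scheme and is kept for provenance.
    """

    inversion_times: tuple
    heart_rate: float = 80.0

    def __post_init__(self):
        tis = tuple(float(t) for t in self.inversion_times)
        if len(tis) < 4:
            raise ValueError("at least four inversion times are required")
        if any(t <= 0 for t in tis):
            raise ValueError("inversion times must be > 0")
        if any(b <= a for a, b in zip(tis, tis[1:])):
            raise ValueError("inversion times must be strictly increasing")
        if not (math.isfinite(self.heart_rate) and self.heart_rate > 0):
            raise ValueError("heart_rate must be > 0")
        object.__setattr__(self, "inversion_times", tis)

    @classmethod
    def molli_scheme(cls, heart_rate: float = 80.0) -> "IrAcquisition":
        """A 5(3)3-style sampling: two inversions with base TIs of 100 and
        180 ms, readouts one RR interval apart (RR = 60000/heart_rate)."""
        rr = 60000.0 / heart_rate
        tis = sorted([100.0 + i * rr for i in range(5)] + [180.0 + i * rr for i in range(3)])
        return cls(inversion_times=tuple(tis), heart_rate=heart_rate)


@dataclass(frozen=True)
class Tissue:
    """Tissue relaxation parameters: T1 in milliseconds, M0 in arbitrary units."""

    t1: float
    m0: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.t1) and self.t1 > 0):
            raise ValueError(f"t1 must be finite and > 0, got {self.t1}")
        if not (math.isfinite(self.m0) and self.m0 >= 0):
            raise ValueError(f"m0 must be finite and >= 0, got {self.m0}")


def e1(t1, tr):
    """Longitudinal recovery factor ``exp(-TR/T1)``.

    Strictly increasing in ``t1`` and decreasing in ``tr``; both must be
    positive.  Accepts scalars or arrays.
    """
    t1 = _as_float_array(t1)
    tr = _as_float_array(tr)
    if np.any(t1 <= 0) or np.any(tr <= 0):
        raise ValueError("t1 and tr must be > 0")
    out = np.exp(-tr / t1)
    return out.item() if out.ndim == 0 else out


def ernst_angle(t1, tr):
    """Flip angle (degrees) maximizing the SPGR signal: ``arccos(E1)``."""
    out = np.degrees(np.arccos(e1(t1, tr)))
    return out.item() if np.ndim(out) == 0 else out


def spgr_signal(tissue: Tissue, acq: VfaAcquisition, flip_angle_deg):
    """Steady-state SPGR magnitude signal at the prescribed flip angle(s).

    The effective angle is ``acq.b1_ratio * flip_angle_deg``.  Returns a
    scalar for scalar input, an array for array input; the signal is
    nonnegative and vanishes exactly at zero flip angle.
    """
    alpha = np.radians(acq.b1_ratio * _as_float_array(flip_angle_deg))
    E1 = e1(tissue.t1, acq.tr)
    out = tissue.m0 * np.sin(alpha) * (1.0 - E1) / (1.0 - E1 * np.cos(alpha))
    return out.item() if np.ndim(out) == 0 else out


def ir_ll_signal(a, b, t1_star, ti):
    """Three-parameter Look-Locker recovery ``S(TI) = A - B*exp(-TI/T1*)``.

    ``S(0) = A - B`` and ``S(TI) -> A`` as TI grows.  Signed (not
    magnitude) signal; magnitude detection is handled at the fitting stage.
    """
    if not (math.isfinite(t1_star) and t1_star > 0):
        raise ValueError("t1_star must be finite and > 0")
    ti = _as_float_array(ti)
    if np.any(ti < 0):
        raise ValueError("inversion times must be >= 0")
    out = a - b * np.exp(-ti / t1_star)
    return out.item() if np.ndim(out) == 0 else out


def look_locker_correction(t1_star, a, b):
    """Corrected T1 from apparent Look-Locker parameters: ``T1* * (B/A - 1)``."""
    if a <= 0:
        raise ValueError("A must be > 0 for the Look-Locker correction")
    return t1_star * (b / a - 1.0)


def predict_b1_bias(k: float, tissue: Tissue, acq: VfaAcquisition) -> float:
    """Percent T1 bias of the linearized VFA fit under a transmit-field error.

    Simulates noiseless SPGR signals at effective angles ``k * alpha`` and
    fits them with the linearized VFA estimator assuming the nominal
    angles, returning ``100 * (T1_fit - T1_true) / T1_true``.  Exactly 0 at
    ``k = 1``; approaches ``100 * (k**2 - 1)`` in the small-angle limit.
    """
    if not (math.isfinite(k) and k > 0):
        raise ValueError("k must be finite and > 0")
    if len(acq.flip_angles) < 2:
        raise ValueError("at least two flip angles are required")
    # Lazy import: the bias must flow through the same fit used on data.
    from .t1_fitting import vfa_fit_linear

    actual = VfaAcquisition(tr=acq.tr, flip_angles=acq.flip_angles, b1_ratio=k)
    signals = spgr_signal(tissue, actual, np.asarray(acq.flip_angles))
    nominal = VfaAcquisition(tr=acq.tr, flip_angles=acq.flip_angles, b1_ratio=1.0)
    t1_fit, _, _ = vfa_fit_linear(signals, nominal)
    if not np.isfinite(t1_fit):
        raise ArithmeticError(f"VFA fit did not yield a physical T1 at k={k}")
    return 100.0 * (t1_fit - tissue.t1) / tissue.t1
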