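"""Voxelwise and bulk T1 estimation from VFA and inversion-recovery data.

VFA fitting uses the linearized steady-state SPGR relation: with
``y = S/sin(alpha)`` and ``x = S/tan(alpha)`` the model is a straight line
``y = E1 * x + M0*(1 - E1)``, so ordinary least squares gives
``T1 = -TR / ln(slope)`` and ``M0 = intercept / (1 - slope)``.  Slopes
outside (0, 1) have no physical T1 and are flagged invalid rather than
imputed.

Look-Locker / MOLLI fitting estimates the three-parameter recovery
``S(TI) = A - B*exp(-TI/T1*)`` by variable projection: for a trial T1*
the amplitudes (A, B) are a linear least-squares solve, so the fit
reduces to a one-dimensional search over T1* (coarse log-spaced grid
followed by golden-section refinement).  Magnitude data loses the sign of
the early inversion-recovery samples; polarity is restored by trying each
candidate number of sign-flipped leading points and keeping the lowest
residual (ties broken toward the later zero-crossing).  The corrected
T1 is ``T1* * (B/A - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_models import IrAcquisition, VfaAcquisition

__all__ = ["T1Map", "vfa_fit_linear", "molli_fit", "fit_map"]

# T1* search bounds for the variable-projection fit, as multiples of the
# shortest/longest inversion time.
_TAU_LO_FRAC = 0.05
_TAU_HI_FRAC = 20.0


@dataclass
class T1Map:
    """Per-voxel T1 fit results.

    All arrays share one shape.  ``t1`` is in milliseconds, ``m0`` in the
    data's arbitrary units (for MOLLI fits it stores the recovered
    amplitude A), ``fit_error`` is the root-mean-square residual in
    signal units.  ``valid_mask`` is False wherever the fit failed,
    produced a non-physical value, or the voxel was outside the requested
    mask; T1 values outside the mask are NaN and must not be used.
    """

    t1: np.ndarray
    m0: np.ndarray
    valid_mask: np.ndarray
    fit_error: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.t1, self.m0, self.valid_mask, self.fit_error)}
        if len(shapes) != 1:
            raise ValueError("all T1Map volumes must share one shape")
        bad = self.valid_mask & ~(np.isfinite(self.t1) & (self.t1 > 0))
        if np.any(bad):
            raise ValueError("valid_mask is true on non-physical T1 values")

    @property
    def shape(self):
        return self.t1.shape

    @property
    def invalid_fraction(self) -> float:
        """Fraction of voxels flagged invalid (over the whole volume)."""
        return 1.0 - self.valid_mask.mean()


def _vfa_fit_arrays(signals: np.ndarray, angles_deg: np.ndarray, tr: float):
    """Vectorized linearized VFA fit.

    signals: (..., n_angles) nonnegative magnitudes.
    Returns (t1, m0, rms, valid), each shaped like signals[..., 0].
    """
    alpha = np.radians(angles_deg)
    sin_a, tan_a = np.sin(alpha), np.tan(alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = signals / sin_a
        x = signals / tan_a
        xm = x.mean(axis=-1, keepdims=True)
        ym = y.mean(axis=-1, keepdims=True)
        sxx = ((x - xm) ** 2).sum(axis=-1)
        sxy = ((x - xm) * (y - ym)).sum(axis=-1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym[..., 0] - slope * xm[..., 0]
        ok = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
        t1 = np.where(ok, -tr / np.log(np.where(ok, slope, 0.5)), np.nan)
        m0 = np.where(ok, intercept / (1.0 - slope), np.nan)
        e1 = slope[..., None]
        pred = m0[..., None] * sin_a * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
        sq = np.where(ok[..., None], (signals - pred) ** 2, 0.0).sum(axis=-1)
        rms = np.where(ok, np.sqrt(sq / signals.shape[-1]), np.nan)
    ok &= np.isfinite(t1) & (t1 > 0) & np.isfinite(m0)
    t1 = np.where(ok, t1, np.nan)
    m0 = np.where(ok, m0, np.nan)
    rms = np.where(ok, rms, np.nan)
    return t1, m0, rms, ok


def vfa_fit_linear(signals, acq: VfaAcquisition):
    """Fit one voxel's VFA signals; returns ``(t1_ms, m0, rms_residual)``.

    ``acq.b1_ratio`` gives the flip-angle scale assumed by the fit (1.0
    fits at the prescribed angles).  A fit whose slope falls outside
    (0, 1) — including all-zero input — is invalid and returns NaNs.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 1 or signals.shape[0] != len(acq.flip_angles):
        raise ValueError(
            f"expected {len(acq.flip_angles)} signals, got shape {signals.shape}"
        )
    if np.any(signals < 0) or not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite and nonnegative")
    t1, m0, rms, _ = _vfa_fit_arrays(signals, acq.effective_angles, acq.tr)
    return float(t1), float(m0), float(rms)


def _varpro_rss(signals: np.ndarray, tis: np.ndarray, tau: np.ndarray):
    """Residual sum of squares of ``A - B*exp(-ti/tau)`` after solving the
    linear subproblem for (A, B) at each tau.

    signals: (..., n_ti); tau: (...,) broadcastable to signals[..., 0].
    Returns (rss, a, b) with the solved amplitudes.
    """
    n = signals.shape[-1]
    g = -np.exp(-tis / tau[..., None])  # design column for B
    s1g = g.sum(axis=-1)
    sgg = (g * g).sum(axis=-1)
    s1y = signals.sum(axis=-1)
    sgy = (g * signals).sum(axis=-1)
    det = n * sgg - s1g**2
    det = np.where(np.abs(det) > 1e-300, det, np.nan)
    a = (sgg * s1y - s1g * sgy) / det
    b = (n * sgy - s1g * s1y) / det
    resid = signals - (a[..., None] + b[..., None] * g)
    return (resid**2).sum(axis=-1), a, b


def _golden_tau(signals: np.ndarray, tis: np.ndarray, lo, hi, iters: int = 55):
    """Vectorized golden-section minimization of the varpro RSS over
    log(tau) within per-element brackets [lo, hi]."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.broadcast_to(np.log(lo), signals.shape[:-1]).copy()
    b = np.broadcast_to(np.log(hi), signals.shape[:-1]).copy()
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, _, _ = _varpro_rss(signals, tis, np.exp(c))
    fd, _, _ = _varpro_rss(signals, tis, np.exp(d))
    for _ in range(iters):
        take_c = fc < fd
        old_c, old_fc, old_fd = c, fc, fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = np.where(take_c, b - phi * (b - a), d)
        d = np.where(take_c, old_c, a + phi * (b - a))
        # one new function evaluation per iteration; the interior point
        # kept from the previous bracket reuses its known value
        pt = np.where(take_c, c, d)
        fpt, _, _ = _varpro_rss(signals, tis, np.exp(pt))
        fc = np.where(take_c, fpt, old_fd)
        fd = np.where(take_c, old_fc, fpt)
    tau = np.exp((a + b) / 2.0)
    rss, amp_a, amp_b = _varpro_rss(signals, tis, tau)
    return tau, rss, amp_a, amp_b


def _molli_fit_arrays(signals: np.ndarray, tis: np.ndarray, magnitude_data: bool,
                      n_grid: int = 40):
    """Vectorized Look-Locker fit.

    signals: (..., n_ti).  Returns (t1, t1_star, a, b, rms, valid), each
    shaped like signals[..., 0].  With ``magnitude_data`` the leading
    j = 0..n_ti points are sign-flipped in turn and the lowest-residual
    restoration wins; ties break toward larger j (later zero-crossing).
    """
    n_ti = tis.shape[0]
    flips = range(n_ti + 1) if magnitude_data else (0,)
    lo = _TAU_LO_FRAC * tis[0]
    hi = _TAU_HI_FRAC * tis[-1]
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))

    best = None
    for j in flips:
        sig = signals.copy()
        sig[..., :j] *= -1.0
        # coarse grid: localize the tau bracket per element
        rss_grid = np.stack(
            [_varpro_rss(sig, tis, np.full(sig.shape[:-1], t))[0] for t in grid]
        )
        idx = np.nanargmin(rss_grid, axis=0)
        lo_b = grid[np.maximum(idx - 1, 0)]
        hi_b = grid[np.minimum(idx + 1, n_grid - 1)]
        tau, rss, a, b = _golden_tau(sig, tis, lo_b, hi_b)
        phys = np.isfinite(a) & (a > 0)
        if best is None:
            best = [tau, rss, a, b, phys]
        else:
            # physical (A > 0) restorations beat unphysical ones; within a
            # class, lower residual wins and exact ties go to the later
            # zero-crossing (larger j).  Guards against the global
            # sign-flip degeneracy of magnitude data.
            with np.errstate(invalid="ignore"):
                better = (phys & ~best[4]) | ((phys == best[4]) & (rss <= best[1]))
            for i, new in enumerate((tau, rss, a, b, phys)):
                best[i] = np.where(better, new, best[i])
    tau, rss, a, b = best[:4]
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = tau * (b / a - 1.0)
    valid = (
        np.isfinite(rss)
        & np.isfinite(a)
        & (a > 0)
        & np.isfinite(t1)
        & (t1 > 0)
    )
    rms = np.sqrt(rss / n_ti)
    t1 = np.where(valid, t1, np.nan)
    return t1, tau, a, b, np.where(valid, rms, np.nan), valid


def molli_fit(signals, acq: IrAcquisition, magnitude_data: bool = True):
    """Fit one voxel's inversion-recovery samples.

    Returns ``(t1_ms, t1_star_ms, a, b, rms_residual)`` where ``t1`` is
    the Look-Locker-corrected estimate ``t1_star * (b/a - 1)``.  A fit
    with non-positive recovered A (or non-physical T1) is invalid and
    returns NaNs for all entries.
    """
    signals = np.asarray(signals, dtype=float)
    tis = np.asarray(acq.inversion_times, dtype=float)
    if signals.ndim != 1 or signals.shape[0] != tis.shape[0]:
        raise ValueError(f"expected {tis.shape[0]} signals, got shape {signals.shape}")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    t1, tau, a, b, rms, valid = _molli_fit_arrays(signals[None, :], tis, magnitude_data)
    if not valid[0]:
        return float("nan"), float("nan"), float("nan"), float("nan"), float("nan")
    return float(t1[0]), float(tau[0]), float(a[0]), float(b[0]), float(rms[0])


def fit_map(volumes, acq, method: str, mask=None) -> T1Map:
    """Voxelwise T1 fit over a stack of co-registered magnitude volumes.

    Parameters
    ----------
    volumes : ndarray, shape ``(*vol_shape, n)``
        One magnitude volume per acquisition coordinate (flip angle for
        ``method='vfa'``, inversion time for ``method='molli'``), stacked
        along the last axis in the order of ``acq``.
    acq : VfaAcquisition or IrAcquisition
    method : {'vfa', 'molli'}
    mask : boolean ndarray of ``vol_shape``, optional
        Voxels to fit; outside the mask ``valid_mask`` is False.
    """
    volumes = np.asarray(volumes, dtype=float)
    vol_shape = volumes.shape[:-1]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol_shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol_shape}")

    t1 = np.full(vol_shape, np.nan)
    m0 = np.full(vol_shape, np.nan)
    err = np.full(vol_shape, np.nan)
    valid = np.zeros(vol_shape, dtype=bool)
    sel = volumes[mask]  # (n_vox, n)

    if method == "vfa":
        if not isinstance(acq, VfaAcquisition):
            raise TypeError("method 'vfa' requires a VfaAcquisition")
        if volumes.shape[-1] != len(acq.flip_angles):
            raise ValueError("stack depth does not match the flip-angle set")
        if sel.size:
            t1_v, m0_v, rms_v, ok_v = _vfa_fit_arrays(sel, acq.effective_angles, acq.tr)
            t1[mask], m0[mask], err[mask], valid[mask] = t1_v, m0_v, rms_v, ok_v
    elif method == "molli":
        if not isinstance(acq, IrAcquisition):
            raise TypeError("method 'molli' requires an IrAcquisition")
        tis = np.asarray(acq.inversion_times, dtype=float)
        if volumes.shape[-1] != tis.shape[0]:
            raise ValueError("stack depth does not match the inversion-time set")
        if sel.size:
            t1_v, _, a_v, _, rms_v, ok_v = _molli_fit_arrays(sel, tis, magnitude_data=True)
            t1[mask], m0[mask], err[mask], valid[mask] = t1_v, a_v, rms_v, ok_v
    else:
        raise ValueError(f"unknown method {method!r}; expected 'vfa' or 'molli'")

    t1[~valid] = np.nan
    return T1Map(t1=t1, m0=m0, valid_mask=valid, fit_error=err)
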