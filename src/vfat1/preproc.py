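"""Free-breathing repeat handling: rigid in-plane registration and
magnitude averaging before T1 fitting.

Breathing motion between fast repeated acquisitions is modeled (and
corrected) as an integer in-plane translation.  Registration is an
exhaustive search over shifts within a window, scoring normalized
cross-correlation over the overlap region — deterministic and invariant
to the global intensity differences between flip angles.  This is a
deliberate rigid simplification of the deformable registration used on
real free-breathing liver data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegistrationResult", "register_translation", "magnitude_average"]


@dataclass(frozen=True)
class RegistrationResult:
    """Integer in-plane displacement (voxels) aligning moving to fixed,
    with the normalized cross-correlation achieved."""

    shift: tuple
    similarity: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_translation(moving: np.ndarray, fixed: np.ndarray, max_shift: int = 3
                         ) -> RegistrationResult:
    """Find the integer in-plane shift of ``moving`` that best matches
    ``fixed`` by exhaustive normalized-cross-correlation search.

    Shifts range over ``[-max_shift, max_shift]`` on each in-plane axis
    (the first two axes); similarity is computed on the overlap region
    only.  Ties break toward the smaller displacement.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a shape")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    nx, ny = moving.shape[:2]
    if max_shift > min(nx, ny) // 2:
        raise ValueError("max_shift exceeds half the in-plane grid")

    candidates = sorted(
        ((dx, dy) for dx in range(-max_shift, max_shift + 1)
         for dy in range(-max_shift, max_shift + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1]), s),
    )
    best_shift, best_sim = (0, 0), -np.inf
    for dx, dy in candidates:
        # overlap slices: moving shifted by (dx, dy) against fixed
        xs_f = slice(max(0, dx), min(nx, nx + dx))
        xs_m = slice(max(0, -dx), min(nx, nx - dx))
        ys_f = slice(max(0, dy), min(ny, ny + dy))
        ys_m = slice(max(0, -dy), min(ny, ny - dy))
        sim = _ncc(moving[xs_m, ys_m], fixed[xs_f, ys_f])
        if sim > best_sim:  # strict: earlier (smaller) shifts win ties
            best_shift, best_sim = (dx, dy), sim
    return RegistrationResult(shift=best_shift, similarity=best_sim)


def apply_shift(volume: np.ndarray, shift) -> np.ndarray:
    """Integer in-plane translation with zero fill (no wrap-around)."""
    dx, dy = int(shift[0]), int(shift[1])
    out = np.zeros_like(volume)
    nx, ny = volume.shape[:2]
    xs_src = slice(max(0, -dx), min(nx, nx - dx))
    xs_dst = slice(max(0, dx), min(nx, nx + dx))
    ys_src = slice(max(0, -dy), min(ny, ny - dy))
    ys_dst = slice(max(0, dy), min(ny, ny + dy))
    out[xs_dst, ys_dst] = volume[xs_src, ys_src]
    return out


def magnitude_average(repeats, shifts=None):
    """Align repeats by their registered shifts and average magnitudes.

    Voxels that some shifted repeat could not cover are averaged over the
    contributing repeats only.  Returns ``(average, full_overlap_mask)``
    where the mask is True at voxels covered by every repeat.
    """
    if len(repeats) == 0:
        raise ValueError("at least one repeat is required")
    if shifts is None:
        shifts = [RegistrationResult((0, 0), 1.0)] * len(repeats)
    if len(shifts) != len(repeats):
        raise ValueError("one shift per repeat is required")

    total = np.zeros_like(np.asarray(repeats[0], dtype=float))
    count = np.zeros(total.shape)
    for rep, reg in zip(repeats, shifts):
        rep = np.asarray(rep, dtype=float)
        shift = reg.shift if isinstance(reg, RegistrationResult) else tuple(reg)
        total += apply_shift(rep, shift)
        count += apply_shift(np.ones_like(rep), shift)
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.where(count > 0, count, 1.0), 0.0)
    return avg, count == len(repeats)


def average_fb_stack(volumes: np.ndarray, max_shift: int = 3) -> np.ndarray:
    """Register and average a free-breathing stack.

    ``volumes`` has shape ``(x, y, z, n_fa, n_rep)``; each repeat is
    registered to the first repeat of its flip angle, then magnitude
    averaged.  Returns a ``(x, y, z, n_fa)`` stack ready for VFA fitting.
    """
    if volumes.ndim != 5:
        raise ValueError("expected a (x, y, z, n_fa, n_rep) stack")
    out = np.zeros(volumes.shape[:4])
    for i in range(volumes.shape[3]):
        reps = [volumes[..., i, r] for r in range(volumes.shape[4])]
        regs = [RegistrationResult((0, 0), 1.0)]
        regs += [register_translation(rep, reps[0], max_shift) for rep in reps[1:]]
        out[..., i], _ = magnitude_average(reps, regs)
    return out
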