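"""Synthetic multi-subject, multi-scanner liver T1-mapping study.

The generator emulates a traveling-volunteer study: a cohort of subjects,
each scanned twice on every scanner of a six-scanner set (two field
strengths x three vendors), with three methods — breath-hold VFA
(``VFA_BH``), free-breathing VFA with repeated acquisitions and in-plane
motion (``VFA_FB``), and a MOLLI-style inversion-recovery reference
(``MOLLI``) available only on a subset of scanners.

Each scan simulates a small multi-slice liver slab: an elliptical liver
compartment at the subject's field-strength-specific T1, an embedded
tubular vessel with longer T1 and higher proton density, a smooth
scanner- and subject-dependent multiplicative B1+ (flip-angle-ratio)
field restricted to 0.4–1.3, and Rician magnitude noise.  The MOLLI
contrast is treated as insensitive to the B1+ field (ideal adiabatic
inversion), which is what makes it the low-bias reference arm.

All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawn keys indexed by (subject, scanner,
method, scan), so any single session can be regenerated independently of
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .signal_models import IrAcquisition, VfaAcquisition

__all__ = [
    "ScannerProfile",
    "SubjectProfile",
    "ScanSession",
    "LIVER_T1_LITERATURE",
    "default_scanners",
    "make_subjects",
    "make_anatomy",
    "make_b1_field",
    "add_rician_noise",
    "simulate_session",
    "simulate_study",
    "study_manifest",
]

#: Literature healthy-liver T1 (ms) by field strength, used as the bias
#: reference and as the center of the between-subject distribution.
LIVER_T1_LITERATURE = {1.5: 602.0, 3.0: 752.0}

METHODS = ("VFA_BH", "VFA_FB", "MOLLI")

_B1_MIN, _B1_MAX = 0.4, 1.3


@dataclass(frozen=True)
class ScannerProfile:
    """One scanner's acquisition and error characteristics.

    ``b1_field_params`` is ``(center, amplitude, smoothness)``: the mean
    flip-angle ratio of the transmit field, the spatial amplitude of its
    variation, and the correlation length as a fraction of the in-plane
    field of view.  Generated fields are clipped to [0.4, 1.3].
    """

    scanner_id: str
    vendor: str
    field_strength: float
    tr: float
    flip_angles: tuple = (2.0, 5.0, 8.0, 10.0, 12.0, 15.0)
    b1_field_params: tuple = (1.0, 0.1, 0.5)
    noise_sd: float = 1.0
    has_molli: bool = False

    def __post_init__(self):
        if self.field_strength not in (1.5, 3.0):
            raise ValueError("field_strength must be 1.5 or 3.0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        center, amp, smooth = self.b1_field_params
        if not (_B1_MIN <= center - amp and center + amp <= _B1_MAX):
            raise ValueError("b1 center +- amplitude must stay within [0.4, 1.3]")
        if smooth <= 0:
            raise ValueError("b1 smoothness length must be > 0")

    @property
    def vfa_acquisition(self) -> VfaAcquisition:
        return VfaAcquisition(tr=self.tr, flip_angles=self.flip_angles)

    @property
    def ir_acquisition(self) -> IrAcquisition:
        return IrAcquisition.molli_scheme(heart_rate=80.0)


@dataclass(frozen=True)
class SubjectProfile:
    """One volunteer: field-strength-specific liver T1 and body-size factor.

    ``size_factor`` (> 0) scales the spatial amplitude of the B1+ field,
    emulating the dependence of standing-wave effects on body size;
    ``vessel_t1_scale`` (> 1) sets blood T1 relative to liver.
    """

    subject_id: str
    liver_t1_15t: float
    liver_t1_30t: float
    vessel_t1_scale: float = 2.0
    size_factor: float = 1.0

    def __post_init__(self):
        if self.liver_t1_15t <= 0 or self.liver_t1_30t <= 0:
            raise ValueError("liver T1 values must be > 0")
        if self.liver_t1_30t <= self.liver_t1_15t:
            raise ValueError("T1 at 3.0 T must exceed T1 at 1.5 T")
        if self.vessel_t1_scale <= 1:
            raise ValueError("vessel_t1_scale must be > 1")
        if self.size_factor <= 0:
            raise ValueError("size_factor must be > 0")

    def liver_t1(self, field_strength: float) -> float:
        return {1.5: self.liver_t1_15t, 3.0: self.liver_t1_30t}[field_strength]


@dataclass
class ScanSession:
    """One simulated scan: the signal stack plus its ground truth."""

    subject_id: str
    scanner_id: str
    vendor: str
    field_strength: float
    method: str
    scan_index: int
    volumes: np.ndarray  # BH/MOLLI: (x, y, z, n); FB: (x, y, z, n_fa, n_rep)
    coords: np.ndarray  # flip angles (deg) or inversion times (ms)
    tr: float
    true_t1: np.ndarray
    true_b1: np.ndarray
    liver_mask: np.ndarray
    vessel_mask: np.ndarray
    seed: int

    @property
    def mean_b1(self) -> float:
        """Mean flip-angle ratio over the liver (vessel included)."""
        return float(self.true_b1[self.liver_mask].mean())

    @property
    def liver_t1(self) -> float:
        """Ground-truth parenchymal liver T1 (vessel excluded), ms."""
        return float(self.true_t1[self.liver_mask & ~self.vessel_mask].mean())


def default_scanners() -> list[ScannerProfile]:
    """The six-scanner set: two field strengths x vendors S, P, G.

    The MOLLI arm exists on the 3.0 T S scanner and both P scanners.
    B1+ centers put most scanners above ratio 1 (VFA overestimates T1)
    and give the 3.0 T S scanner a strong low-ratio offset with a large
    spatial amplitude, the dominant vendor effect; 1.5 T fields are close
    to uniform, with vendor S nearly unbiased at 1.5 T.
    """
    return [
        ScannerProfile("S1", "S", 3.0, tr=3.5, b1_field_params=(0.80, 0.22, 0.45),
                       noise_sd=1.0, has_molli=True),
        ScannerProfile("P1", "P", 3.0, tr=3.19, b1_field_params=(1.10, 0.12, 0.5),
                       noise_sd=1.0, has_molli=True),
        ScannerProfile("G1", "G", 3.0, tr=4.0, b1_field_params=(1.12, 0.10, 0.55),
                       noise_sd=1.0, has_molli=False),
        ScannerProfile("S2", "S", 1.5, tr=5.0, b1_field_params=(1.00, 0.05, 0.5),
                       noise_sd=1.0, has_molli=False),
        ScannerProfile("P2", "P", 1.5, tr=6.04, b1_field_params=(1.08, 0.06, 0.5),
                       noise_sd=1.0, has_molli=True),
        ScannerProfile("G2", "G", 1.5, tr=5.5, b1_field_params=(1.09, 0.06, 0.5),
                       noise_sd=1.0, has_molli=False),
    ]


def make_subjects(n_subjects: int = 8, seed=0, between_subject_cv: float = 0.075
                  ) -> list[SubjectProfile]:
    """Draw a cohort around the literature liver T1 means.

    A single subject factor multiplies both field strengths' T1 (liver T1
    at 1.5 T and 3.0 T are strongly correlated within subject), with
    coefficient of variation ``between_subject_cv``; the default 7.5%
    yields a ~15% between-subject variation (100 x 1.96 x CV) on an
    unbiased measurement.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        f = max(0.6, rng.normal(1.0, between_subject_cv))
        subjects.append(
            SubjectProfile(
                subject_id=f"sub{i + 1:02d}",
                liver_t1_15t=LIVER_T1_LITERATURE[1.5] * f,
                liver_t1_30t=LIVER_T1_LITERATURE[3.0] * f,
                vessel_t1_scale=2.0,
                size_factor=float(rng.uniform(0.8, 1.2)),
            )
        )
    return subjects


def make_anatomy(shape=(64, 64, 5), liver_t1: float = 752.0, liver_m0: float = 1000.0,
                 vessel_t1_scale: float = 2.0, vessel_m0_scale: float = 1.4,
                 liver_axes=(0.42, 0.34), vessel_center=(0.58, 0.42),
                 vessel_radius: float = 0.09):
    """Rasterize the two-compartment liver slab.

    The liver is an axis-aligned ellipse (semi-axes as fractions of the
    in-plane grid) constant across slices; the vessel is a tube whose
    circular cross-section is largest on the central slice and tapers
    toward the outer slices, emulating a portal vein.  ``vessel_radius``
    is the central-slice radius as a fraction of the first in-plane
    dimension; 0 disables the vessel.

    Returns ``(t1_map, m0_map, liver_mask, vessel_mask)`` with the vessel
    a subset of the liver and zero background.
    """
    nx, ny, nz = shape
    if nx < 32 or ny < 32:
        raise ValueError("in-plane grid must be at least 32 x 32")
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = liver_axes[0] * nx, liver_axes[1] * ny
    liver2d = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0

    liver_mask = np.repeat(liver2d[:, :, None], nz, axis=2)
    vessel_mask = np.zeros(shape, dtype=bool)
    if vessel_radius > 0:
        vx, vy = vessel_center[0] * (nx - 1), vessel_center[1] * (ny - 1)
        center_z = (nz - 1) / 2.0
        for z in range(nz):
            taper = 1.0 - 0.5 * abs(z - center_z) / max(center_z, 0.5)
            r = vessel_radius * nx * taper
            vessel_mask[:, :, z] = (x - vx) ** 2 + (y - vy) ** 2 <= r**2
        vessel_mask &= liver_mask
        if not vessel_mask.any():
            raise ValueError("vessel lies entirely outside the liver")

    t1_map = np.zeros(shape)
    m0_map = np.zeros(shape)
    t1_map[liver_mask] = liver_t1
    m0_map[liver_mask] = liver_m0
    t1_map[vessel_mask] = liver_t1 * vessel_t1_scale
    m0_map[vessel_mask] = liver_m0 * vessel_m0_scale
    return t1_map, m0_map, liver_mask, vessel_mask


def make_b1_field(shape, profile: ScannerProfile, subject: SubjectProfile, seed
                  ) -> np.ndarray:
    """Smooth multiplicative flip-angle-ratio field, clipped to [0.4, 1.3].

    The spatial pattern is a seeded sum of three broad Gaussian bumps
    (correlation length set by the profile's smoothness parameter),
    normalized to unit peak amplitude, then scaled by the scanner
    amplitude and the subject's size factor around the scanner's center
    ratio.  Amplitude 0 gives a uniform field.  Constant through-slice.
    """
    nx, ny, nz = shape
    center, amp, smooth = profile.b1_field_params
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny), indexing="ij")
    pattern = np.zeros((nx, ny))
    for _ in range(3):
        cx, cy = rng.uniform(0.1, 0.9, size=2)
        sx, sy = rng.uniform(0.6, 1.4, size=2) * smooth
        w = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        pattern += w * np.exp(-(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2) / 2.0)
    peak = np.abs(pattern).max()
    if peak > 0:
        pattern /= peak
    field2d = center + amp * subject.size_factor * pattern
    field2d = np.clip(field2d, _B1_MIN, _B1_MAX)
    return np.repeat(field2d[:, :, None], nz, axis=2)


def add_rician_noise(volume, noise_sd: float, seed=None) -> np.ndarray:
    """Magnitude-image noise: ``|v + n1 + i*n2|`` with i.i.d. Gaussian n1, n2.

    ``noise_sd`` is the per-channel Gaussian SD; 0 returns a copy of the
    input.  ``seed`` may be an int, SeedSequence, or Generator.
    """
    volume = np.asarray(volume, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return volume.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, noise_sd, size=volume.shape)
    n2 = rng.normal(0.0, noise_sd, size=volume.shape)
    return np.abs((volume + n1) + 1j * n2)


def _spgr_volume(t1_map, m0_map, b1_map, tr, flip_deg):
    """Noiseless SPGR volume at one prescribed flip angle with a per-voxel
    flip-angle-ratio field.  Background (t1 = 0) stays zero."""
    alpha = np.radians(b1_map * flip_deg)
    out = np.zeros_like(t1_map)
    tis = t1_map > 0
    e1 = np.exp(-tr / t1_map[tis])
    out[tis] = m0_map[tis] * np.sin(alpha[tis]) * (1 - e1) / (1 - e1 * np.cos(alpha[tis]))
    return out


def _shift_volume(volume, shift):
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


#: MOLLI apparent-rate factor: simulated recoveries use B/A = 2.1 and
#: T1* = T1 / (B/A - 1), so the Look-Locker correction is exact on
#: noiseless data.  Emulates the readout-driven shortening of the
#: apparent relaxation time.
MOLLI_B_OVER_A = 2.1
#: MOLLI readout amplitude relative to M0 (sets the MOLLI SNR scale).
MOLLI_AMP_SCALE = 0.05


def simulate_session(subject: SubjectProfile, scanner: ScannerProfile, method: str,
                     scan_index: int, seed, shape=(64, 64, 5), n_repeats: int = 10,
                     motion_amplitude: int = 3) -> ScanSession:
    """Simulate one scan of one subject on one scanner.

    ``seed`` may be an int or a ``SeedSequence``; noise, the B1+ field
    draw, and free-breathing motion each consume an independent child
    stream, so scans 1 and 2 share anatomy but differ in noise and in
    the (re-drawn) B1+ pattern around the same scanner center ratio.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method == "MOLLI" and not scanner.has_molli:
        raise ValueError(f"scanner {scanner.scanner_id} has no MOLLI sequence")
    if scan_index not in (1, 2):
        raise ValueError("scan_index must be 1 or 2")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_int = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    ss_b1, ss_noise, ss_motion = ss.spawn(3)

    t1_map, m0_map, liver_mask, vessel_mask = make_anatomy(
        shape,
        liver_t1=subject.liver_t1(scanner.field_strength),
        vessel_t1_scale=subject.vessel_t1_scale,
    )
    b1_map = make_b1_field(shape, scanner, subject, ss_b1)
    noise_rng = np.random.default_rng(ss_noise)

    if method == "MOLLI":
        tis = np.asarray(scanner.ir_acquisition.inversion_times)
        a_map = MOLLI_AMP_SCALE * m0_map
        tau = np.zeros_like(t1_map)
        liver_or_vessel = t1_map > 0
        tau[liver_or_vessel] = t1_map[liver_or_vessel] / (MOLLI_B_OVER_A - 1.0)
        signed = np.zeros(shape + (len(tis),))
        for i, ti in enumerate(tis):
            rec = np.zeros_like(t1_map)
            rec[liver_or_vessel] = a_map[liver_or_vessel] * (
                1.0 - MOLLI_B_OVER_A * np.exp(-ti / tau[liver_or_vessel])
            )
            signed[..., i] = rec
        # magnitude detection: noiseless data still loses the sign
        volumes = np.abs(add_rician_noise(signed, scanner.noise_sd, noise_rng))
        coords = tis
    elif method == "VFA_BH":
        fas = np.asarray(scanner.flip_angles)
        clean = np.stack(
            [_spgr_volume(t1_map, m0_map, b1_map, scanner.tr, fa) for fa in fas], axis=-1
        )
        volumes = add_rician_noise(clean, scanner.noise_sd, noise_rng)
        coords = fas
    else:  # VFA_FB
        fas = np.asarray(scanner.flip_angles)
        motion_rng = np.random.default_rng(ss_motion)
        volumes = np.zeros(shape + (len(fas), n_repeats))
        for i, fa in enumerate(fas):
            clean = _spgr_volume(t1_map, m0_map, b1_map, scanner.tr, fa)
            for r in range(n_repeats):
                if r == 0 or motion_amplitude == 0:
                    # acquisition starts at the reference breath position
                    shifted = clean
                else:
                    shift = motion_rng.integers(-motion_amplitude, motion_amplitude + 1,
                                                size=2)
                    shifted = _shift_volume(clean, shift)
                volumes[..., i, r] = add_rician_noise(shifted, scanner.noise_sd,
                                                      noise_rng)
        coords = fas

    return ScanSession(
        subject_id=subject.subject_id,
        scanner_id=scanner.scanner_id,
        vendor=scanner.vendor,
        field_strength=scanner.field_strength,
        method=method,
        scan_index=scan_index,
        volumes=volumes,
        coords=coords,
        tr=scanner.tr,
        true_t1=t1_map,
        true_b1=b1_map,
        liver_mask=liver_mask,
        vessel_mask=vessel_mask,
        seed=seed_int,
    )


def _session_keys(subjects, scanners, methods, dropout):
    """Deterministic (subject, scanner, method, scan) crossing.

    With ``dropout`` the last subject is limited to the first three
    scanners, mirroring a withdrawal partway through a traveling study.
    """
    for si, subject in enumerate(subjects):
        scanner_set = scanners
        if dropout and si == len(subjects) - 1:
            scanner_set = scanners[:3]
        for ci, scanner in enumerate(scanner_set):
            for mi, method in enumerate(methods):
                if method == "MOLLI" and not scanner.has_molli:
                    continue
                for scan_index in (1, 2):
                    yield (si, ci, mi, scan_index), subject, scanner, method


class Study:
    """Lazy handle on a full simulated study.

    Sessions are generated on demand (``sessions()`` iterates, ``session(i)``
    materializes one) so a full free-breathing study never has to fit in
    memory at once; the manifest records identity, seeds, and ground
    truth for every session up front.
    """

    def __init__(self, subjects, scanners, methods=METHODS, seed=0, dropout=False,
                 shape=(64, 64, 5), n_repeats: int = 10, motion_amplitude: int = 3):
        self.subjects = list(subjects)
        self.scanners = list(scanners)
        self.methods = tuple(methods)
        self.seed = int(seed)
        self.dropout = dropout
        self.shape = tuple(shape)
        self.n_repeats = n_repeats
        self.motion_amplitude = motion_amplitude
        self._keys = [k for k in _session_keys(self.subjects, self.scanners,
                                               self.methods, dropout)]

    def __len__(self):
        return len(self._keys)

    def _session_seed(self, key) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=key)

    def session(self, index: int) -> ScanSession:
        (key, subject, scanner, method) = self._keys[index]
        return simulate_session(
            subject, scanner, method, scan_index=key[3],
            seed=self._session_seed(key), shape=self.shape,
            n_repeats=self.n_repeats, motion_amplitude=self.motion_amplitude,
        )

    def sessions(self) -> Iterator[ScanSession]:
        for i in range(len(self._keys)):
            yield self.session(i)

    def manifest(self) -> pd.DataFrame:
        """Ground-truth manifest, one row per session (regenerates the B1
        field of each session to record its within-liver mean)."""
        rows = []
        for i, (key, subject, scanner, method) in enumerate(self._keys):
            ss = self._session_seed(key)
            seed_int = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            ss_b1 = ss.spawn(3)[0]
            _, _, liver_mask, _ = make_anatomy(
                self.shape, liver_t1=subject.liver_t1(scanner.field_strength),
                vessel_t1_scale=subject.vessel_t1_scale,
            )
            b1 = make_b1_field(self.shape, scanner, subject, ss_b1)
            rows.append(
                {
                    "session": i,
                    "subject_id": subject.subject_id,
                    "scanner_id": scanner.scanner_id,
                    "vendor": scanner.vendor,
                    "field_strength": scanner.field_strength,
                    "method": method,
                    "scan_index": key[3],
                    "seed": seed_int,
                    "true_t1": subject.liver_t1(scanner.field_strength),
                    "mean_b1": float(b1[liver_mask].mean()),
                }
            )
        return pd.DataFrame(rows)


def simulate_study(n_subjects: int = 8, scanners: Sequence[ScannerProfile] | None = None,
                   methods=METHODS, seed=0, dropout: bool = False,
                   between_subject_cv: float = 0.075, shape=(64, 64, 5),
                   n_repeats: int = 10, motion_amplitude: int = 3) -> Study:
    """Set up the full study crossing: subjects x scanners x {1, 2} x methods.

    MOLLI sessions exist only on scanners flagged ``has_molli``.  Returns
    a :class:`Study`; call ``.sessions()`` to generate the scans and
    ``.manifest()`` for the ground-truth table.
    """
    if scanners is None:
        scanners = default_scanners()
    subjects = make_subjects(
        n_subjects, seed=np.random.SeedSequence(entropy=seed, spawn_key=(0xC0,)),
        between_subject_cv=between_subject_cv,
    )
    return Study(subjects, scanners, methods=methods, seed=seed, dropout=dropout,
                 shape=shape, n_repeats=n_repeats, motion_amplitude=motion_amplitude)


def study_manifest(study: Study) -> pd.DataFrame:
    """Convenience alias for ``study.manifest()``."""
    return study.manifest()
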