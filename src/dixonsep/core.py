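"""Dual-echo chemical-shift signal model.

Two-point Dixon acquisitions sample the object at an in-phase echo time
(water and fat signals aligned) and an out-of-phase echo time.  Per pixel
the complex signals are

    S1 = (W + C1 F) e^{i phi1},   S2 = (W + C2 F) e^{i phi2},

where W, F >= 0 are water/fat amplitudes, Ck = exp(i 2 pi df TEk) is the
fat dephasing factor at echo time TEk for a fat-water chemical shift of
df Hz, and phi1/phi2 collect receive phase plus B0-induced phase.  The
magnitude pair (|S1|, |S2|) determines {W, F} only up to a swap; each of
the two amplitude candidates implies its own unit "phasor" candidate for
the inter-echo B0 phase.  Picking the right candidate per pixel is the
water-fat separation problem; this module provides the per-pixel algebra,
the spatial selection lives in :mod:`dixonsep.selector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

__all__ = [
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "AcquisitionParams",
    "DualEchoImage",
    "PhasorCandidates",
    "WaterFatResult",
    "dephasing_factor",
    "forward_simulate",
    "amplitude_candidates",
    "phasor_candidates",
    "amplitudes_from_phasor",
]

#: Proton gyromagnetic ratio gamma/2pi in MHz/T.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class AcquisitionParams:
    """Echo times and field parameters of a dual-echo acquisition.

    Echo times are in milliseconds everywhere in the public interface;
    conversion to seconds happens only inside formulas.  The fat
    chemical shift is signed and in ppm; fat resonates below water, so
    the default is negative.  The fat frequency offset in Hz is derived,
    never stored.
    """

    te1_ms: float
    te2_ms: float
    field_strength_t: float = 3.0
    fat_shift_ppm: float = -3.5
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("te1_ms", "te2_ms", "field_strength_t", "fat_shift_ppm"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"AcquisitionParams.{name} must be finite, got {v!r}")
        if self.te1_ms <= 0 or self.te2_ms <= 0:
            raise ValueError("echo times te1_ms/te2_ms must be positive")
        if self.te1_ms == self.te2_ms:
            raise ValueError("te1_ms and te2_ms must differ for a two-point acquisition")
        if self.field_strength_t <= 0:
            raise ValueError("field_strength_t must be positive")

    @property
    def delta_f_hz(self) -> float:
        """Fat-water frequency offset in Hz (signed), gamma/2pi * ppm * B0."""
        return self.fat_shift_ppm * GYROMAGNETIC_RATIO_MHZ_PER_T * self.field_strength_t

    @property
    def c1(self) -> complex:
        return dephasing_factor(self.te1_ms, self.delta_f_hz)

    @property
    def c2(self) -> complex:
        return dephasing_factor(self.te2_ms, self.delta_f_hz)


@dataclass
class DualEchoImage:
    """Paired complex in-phase/out-of-phase 2D images with acquisition metadata."""

    s1: np.ndarray
    s2: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=np.complex128)
        self.s2 = np.asarray(self.s2, dtype=np.complex128)
        if self.s1.shape != self.s2.shape:
            raise ValueError(
                f"echo shapes differ: s1 {self.s1.shape} vs s2 {self.s2.shape}"
            )
        if not (np.isfinite(self.s1).all() and np.isfinite(self.s2).all()):
            raise ValueError("dual-echo images must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s1.shape


@dataclass
class PhasorCandidates:
    """The two per-pixel (water, fat) amplitude candidates and their phasors.

    Candidate 2 is the amplitude swap of candidate 1 by construction
    (w2 = f1, f2 = w1); candidate 1 assigns the larger amplitude to
    water.  ``degenerate_mask`` marks pixels where the candidates
    coincide (w1 == f1, including background) or where negative
    discriminants/products were clamped to zero under noise.
    """

    w1: np.ndarray
    f1: np.ndarray
    w2: np.ndarray
    f2: np.ndarray
    p1: Optional[np.ndarray] = None
    p2: Optional[np.ndarray] = None
    degenerate_mask: Optional[np.ndarray] = None


@dataclass
class WaterFatResult:
    """Separated water/fat maps plus the selected phasor and labels."""

    water: np.ndarray
    fat: np.ndarray
    phasor: np.ndarray
    selection: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)


def dephasing_factor(te_ms: float, delta_f_hz: float) -> complex:
    """Unit complex fat dephasing factor C = exp(i 2 pi df TE).

    Parameters
    ----------
    te_ms:
        Echo time in milliseconds, >= 0.
    delta_f_hz:
        Fat-water frequency offset in Hz (signed).
    """
    if not np.isfinite(te_ms):
        raise ValueError(f"te_ms must be finite, got {te_ms!r}")
    if not np.isfinite(delta_f_hz):
        raise ValueError(f"delta_f_hz must be finite, got {delta_f_hz!r}")
    if te_ms < 0:
        raise ValueError(f"te_ms must be non-negative, got {te_ms!r}")
    return complex(np.exp(2j * np.pi * delta_f_hz * te_ms * 1e-3))


def forward_simulate(
    water: np.ndarray,
    fat: np.ndarray,
    b0_hz: np.ndarray,
    phi0: np.ndarray,
    params: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> DualEchoImage:
    """Simulate the dual-echo signals of a known water/fat/B0 configuration.

    Sk = (W + Ck F) exp(i (phi0 + 2 pi b0 TEk)) + n, with n i.i.d. complex
    Gaussian noise of standard deviation ``noise_sigma`` per real/imaginary
    component.  Fully seeded and reproducible.
    """
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    b0_hz = np.asarray(b0_hz, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    if not (water.shape == fat.shape == b0_hz.shape == phi0.shape):
        raise ValueError(
            "water, fat, b0_hz and phi0 must share a shape; got "
            f"{water.shape}, {fat.shape}, {b0_hz.shape}, {phi0.shape}"
        )
    if (water < 0).any() or (fat < 0).any():
        raise ValueError("water and fat amplitudes must be non-negative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    echoes = []
    for te in (params.te1_ms, params.te2_ms):
        c = dephasing_factor(te, params.delta_f_hz)
        s = (water + c * fat) * np.exp(1j * (phi0 + 2 * np.pi * b0_hz * te * 1e-3))
        if noise_sigma > 0:
            s = s + noise_sigma * (
                rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
            )
        echoes.append(s)
    return DualEchoImage(echoes[0], echoes[1], params)


def amplitude_candidates(
    s1_mag: np.ndarray,
    s2_mag: np.ndarray,
    c1: complex,
    c2: complex,
) -> PhasorCandidates:
    """Solve the per-pixel magnitude equations for the two (W, F) candidates.

    From |S1|^2 = W^2 + F^2 + 2 W F Re(C1) and likewise for S2:

        p = W*F     = (|S1|^2 - |S2|^2) / (2 (Re C1 - Re C2))
        q = W^2+F^2 = |S1|^2 - 2 p Re(C1)

    so W + F = sqrt(q + 2p) and |W - F| = sqrt(q - 2p).  Candidate 1
    assigns the larger root to water; candidate 2 is the swap.  Negative
    products or discriminants (noise) are clamped to zero and flagged in
    ``degenerate_mask``, as are pixels whose candidates coincide.
    """
    s1_mag = np.asarray(s1_mag, dtype=float)
    s2_mag = np.asarray(s2_mag, dtype=float)
    if s1_mag.shape != s2_mag.shape:
        raise ValueError("s1_mag and s2_mag must share a shape")
    re1, re2 = np.real(c1), np.real(c2)
    if abs(re1 - re2) < 1e-12:
        raise ValueError(
            "Re(C1) == Re(C2): the dual-echo magnitude system is ill-posed "
            "for this echo-time pair"
        )

    a1 = s1_mag**2
    a2 = s2_mag**2
    p = (a1 - a2) / (2.0 * (re1 - re2))
    clamped = p < 0
    p = np.maximum(p, 0.0)
    q = a1 - 2.0 * p * re1
    sum_sq = q + 2.0 * p  # (W + F)^2
    diff_sq = q - 2.0 * p  # (W - F)^2
    clamped |= sum_sq < 0
    clamped |= diff_sq < 0
    s = np.sqrt(np.maximum(sum_sq, 0.0))
    d = np.sqrt(np.maximum(diff_sq, 0.0))
    w1 = (s + d) / 2.0
    f1 = np.maximum((s - d) / 2.0, 0.0)
    scale = np.maximum(a1, a2)
    coincide = d**2 <= 1e-12 * np.maximum(scale, 1e-300)
    return PhasorCandidates(
        w1=w1,
        f1=f1,
        w2=f1.copy(),
        f2=w1.copy(),
        degenerate_mask=clamped | coincide,
    )


def phasor_candidates(
    img: DualEchoImage,
    cands: PhasorCandidates,
    c1: complex | None = None,
    c2: complex | None = None,
) -> PhasorCandidates:
    """Attach the two candidate unit phasors to the amplitude candidates.

    Pk = conj(S1) S2 / ((Wk + conj(C1) Fk)(Wk + C2 Fk)), normalized to unit
    modulus.  For the candidate matching the truth this equals the exact
    inter-echo B0 phasor exp(i 2 pi b0 (TE2 - TE1)).  Pixels where the
    formula is undefined (zero numerator or denominator, e.g. background)
    get phasor 1 and are added to ``degenerate_mask``.
    """
    if c1 is None:
        c1 = img.params.c1
    if c2 is None:
        c2 = img.params.c2
    num = np.conj(img.s1) * img.s2
    mask = (
        np.zeros(img.shape, dtype=bool)
        if cands.degenerate_mask is None
        else cands.degenerate_mask.copy()
    )
    phasors = []
    for w, f in ((cands.w1, cands.f1), (cands.w2, cands.f2)):
        den = (w + np.conj(c1) * f) * (w + c2 * f)
        raw = np.where(den != 0, num / np.where(den == 0, 1.0, den), 0.0)
        mag = np.abs(raw)
        bad = mag < 1e-300
        p = np.where(bad, 1.0 + 0.0j, raw / np.where(bad, 1.0, mag))
        mask |= bad
        phasors.append(p)
    return PhasorCandidates(
        w1=cands.w1,
        f1=cands.f1,
        w2=cands.w2,
        f2=cands.f2,
        p1=phasors[0],
        p2=phasors[1],
        degenerate_mask=mask,
    )


def amplitudes_from_phasor(
    img: DualEchoImage,
    phasor: np.ndarray,
    c1: complex | None = None,
    c2: complex | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover water/fat amplitudes given a chosen inter-echo phasor.

    Demodulates the second echo, S2' = S2 conj(P), and solves the exact
    2x2 linear system [1, C1; 1, C2] [u; v] = [S1; S2'] per pixel.
    Returns (|u|, |v|, residual) where the residual |Im(u conj(v))|
    measures the phase inconsistency between the complex water and fat
    solutions; it is zero for noiseless data with the true phasor.
    """
    if c1 is None:
        c1 = img.params.c1
    if c2 is None:
        c2 = img.params.c2
    if abs(c1 - c2) < 1e-12:
        raise ValueError("c1 == c2: singular amplitude system")
    s2_demod = img.s2 * np.conj(phasor)
    v = (img.s1 - s2_demod) / (c1 - c2)
    u = img.s1 - c1 * v
    residual = np.abs(np.imag(u * np.conj(v)))
    return np.abs(u), np.abs(v), residual
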