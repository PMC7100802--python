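"""Steady-state signal models for two-pool exchanging tissue.

The tissue is described by a fast-relaxing (myelin water) pool and a
slow-relaxing (intra/extra-cellular water) pool coupled by first-order
exchange.  Longitudinal magnetisation obeys

    dM_z/dt = A M_z + C,
    A = [[-1/T1F - k_FS,  k_SF         ],
         [ k_FS,         -1/T1S - k_SF]],
    C = (M0F/T1F, M0S/T1S)^T,

with equilibrium fractions M0F = MWF, M0S = 1 - MWF and detailed balance
k_SF = k_FS * MWF / (1 - MWF).  Transverse magnetisation relaxes with T2F,
T2S, exchanges at the same rates and precesses at the effective
off-resonance angular frequency.  Excitation is an instantaneous rotation
about the x axis; signals are evaluated immediately post-pulse (no echo-time
decay) and spoiling of the SPGR sequence is assumed perfect.

The steady state of the pulse train is obtained in closed form.  Writing
E = exp(A * TR) for the free-evolution propagator, the pre-pulse SPGR
longitudinal state solves

    Mz- = (I - E cos(a))^-1 (E - I) A^-1 C,

and the bSSFP six-dimensional analogue replaces cos(a) by the full rotation
R_x(a).  Internally the 6x6 system is reduced to chained 2x2 solves by
exploiting the block structure (transverse x/y pairs and longitudinal pair),
which keeps everything expressible as vectorised closed-form algebra over
arbitrarily large batches of candidate parameter sets.

All computational routines broadcast over a leading batch axis: the public
single-tissue functions are thin wrappers over the batch kernels used by the
fitting and search-space modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidParameterError, NumericalModelError

if TYPE_CHECKING:  # pragma: no cover
    from .study_config import AcquisitionScheme

__all__ = [
    "PARAM_NAMES",
    "TissueParams",
    "SignalVector",
    "spgr_single_pool",
    "spgr_two_pool",
    "bssfp_two_pool",
    "forward_signals",
    "normalize",
    "signal_matrix",
    "normalize_matrix",
    "normalization_groups",
]

#: Canonical parameter ordering used by every array-based interface.
PARAM_NAMES: tuple[str, ...] = ("t1f", "t1s", "t2f", "t2s", "mwf", "kfs")

_DET_FLOOR = 1e-300


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth or estimated two-pool tissue state.

    Parameters
    ----------
    t1f, t1s : float
        Longitudinal relaxation times of the fast (myelin water) and slow
        (intra/extra-cellular water) pools, in seconds.
    t2f, t2s : float
        Transverse relaxation times, in seconds.
    mwf : float
        Myelin water fraction, the equilibrium fraction of the fast pool
        (``M0F``; the slow pool is ``1 - mwf``).
    kfs : float
        Fast-to-slow exchange rate in 1/s.  The reverse rate ``ksf`` follows
        from detailed balance and is exposed as a property.
    delta_f : float
        Off-resonance frequency in Hz (default 0: on-resonance).
    """

    t1f: float
    t1s: float
    t2f: float
    t2s: float
    mwf: float
    kfs: float
    delta_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t1f", "t1s", "t2f", "t2s"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.t2f > self.t1f or self.t2s > self.t1s:
            raise InvalidParameterError("T2 may not exceed T1 for either pool")
        if not (0 <= self.mwf < 1):
            raise InvalidParameterError("mwf must lie in [0, 1)")
        if self.kfs < 0:
            raise InvalidParameterError("kfs must be nonnegative")

    @property
    def ksf(self) -> float:
        """Slow-to-fast exchange rate from detailed balance (0 when mwf=0)."""
        if self.mwf == 0.0:
            return 0.0
        return self.kfs * self.mwf / (1.0 - self.mwf)

    def to_array(self) -> np.ndarray:
        """Return the six fit parameters in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray, delta_f: float = 0.0) -> "TissueParams":
        values = {n: float(v) for n, v in zip(PARAM_NAMES, np.asarray(theta, float))}
        return cls(delta_f=delta_f, **values)

    def with_(self, **updates: float) -> "TissueParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class SignalVector:
    """Ordered, labelled signal values for one tissue under one scheme."""

    values: np.ndarray
    sequences: tuple[str, ...]
    flip_angles_deg: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "flip_angles_deg", np.asarray(self.flip_angles_deg, dtype=float)
        )
        object.__setattr__(self, "sequences", tuple(self.sequences))
        n = len(self.values)
        if len(self.sequences) != n or len(self.flip_angles_deg) != n:
            raise InvalidParameterError("values, sequences and flip angles must align")

    def __len__(self) -> int:
        return len(self.values)

    def mask(self, *sequences: str) -> np.ndarray:
        """Boolean mask selecting entries from the given sequence tags."""
        tags = set(sequences)
        return np.array([s in tags for s in self.sequences], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": list(self.sequences),
                "flip_angle_deg": self.flip_angles_deg,
                "value": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "SignalVector":
        df = pd.read_csv(path)
        return cls(
            values=df["value"].to_numpy(float),
            sequences=tuple(df["sequence"]),
            flip_angles_deg=df["flip_angle_deg"].to_numpy(float),
            normalized=normalized,
        )


# ---------------------------------------------------------------------------
# 2x2 matrix algebra on component arrays (broadcastable, real or complex)
# ---------------------------------------------------------------------------

def _mat_mul(a, b):
    a11, a12, a21, a22 = a
    b11, b12, b21, b22 = b
    return (
        a11 * b11 + a12 * b21,
        a11 * b12 + a12 * b22,
        a21 * b11 + a22 * b21,
        a21 * b12 + a22 * b22,
    )


def _mat_vec(m, v):
    m11, m12, m21, m22 = m
    v1, v2 = v
    return (m11 * v1 + m12 * v2, m21 * v1 + m22 * v2)


def _mat_det(m):
    m11, m12, m21, m22 = m
    return m11 * m22 - m12 * m21


def _mat_inv(m, context: str):
    det = _mat_det(m)
    if np.any(np.abs(det) < _DET_FLOOR):
        raise NumericalModelError(f"singular 2x2 system while solving {context}")
    m11, m12, m21, m22 = m
    inv = 1.0 / det
    return (m22 * inv, -m12 * inv, -m21 * inv, m11 * inv)


def _expm2(m, dt):
    """Closed-form matrix exponential of a (batched) 2x2 matrix times dt.

    Uses exp(M) = e^mu (cosh(d) I + sinh(d)/d (M - mu I)) with mu the mean of
    the diagonal and d^2 = ((a-d)/2)^2 + bc; the removable singularity at
    d -> 0 is handled by a series expansion of sinh(d)/d.
    """
    a, b, c, d = (x * dt for x in m)
    mu = 0.5 * (a + d)
    half_diff = 0.5 * (a - d)
    disc = half_diff * half_diff + b * c
    delta = np.sqrt(disc.astype(complex))
    small = np.abs(delta) < 1e-6
    safe = np.where(small, 1.0, delta)
    sinhc = np.where(small, 1.0 + disc / 6.0, np.sinh(safe) / safe)
    coshd = np.cosh(delta)
    emu = np.exp(mu)
    e11 = emu * (coshd + sinhc * half_diff)
    e22 = emu * (coshd - sinhc * half_diff)
    e12 = emu * sinhc * b
    e21 = emu * sinhc * c
    if np.isrealobj(a) and np.isrealobj(b) and np.isrealobj(c) and np.isrealobj(d):
        return (e11.real, e12.real, e21.real, e22.real)
    return (e11, e12, e21, e22)


# ---------------------------------------------------------------------------
# Batch steady-state kernels
# ---------------------------------------------------------------------------

def _split_params(theta: np.ndarray):
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != len(PARAM_NAMES):
        raise InvalidParameterError(
            f"parameter array must have {len(PARAM_NAMES)} columns, got {theta.shape[1]}"
        )
    cols = [theta[:, i][:, None] for i in range(theta.shape[1])]
    return cols  # each (N, 1)


def _ksf_from(mwf, kfs):
    with np.errstate(divide="ignore", invalid="ignore"):
        ksf = np.where(mwf > 0, kfs * mwf / (1.0 - mwf), 0.0)
    return ksf


def _longitudinal_system(t1f, t1s, mwf, kfs, tr):
    """Propagator L = exp(A_L tr) and drive b = (L - I) A_L^-1 C."""
    ksf = _ksf_from(mwf, kfs)
    a11 = -1.0 / t1f - kfs
    a12 = ksf
    a21 = kfs
    a22 = -1.0 / t1s - ksf
    a_mat = (a11, a12, a21, a22)
    c_vec = (mwf / t1f, (1.0 - mwf) / t1s)
    w = _mat_vec(_mat_inv(a_mat, "longitudinal relaxation matrix"), c_vec)
    L = _expm2(a_mat, tr)
    lw = _mat_vec(L, w)
    b = (lw[0] - w[0], lw[1] - w[1])
    return L, b


def _check_angles(fa_rad: np.ndarray) -> None:
    if np.any(fa_rad < 0) or np.any(fa_rad > math.pi):
        raise InvalidParameterError("flip angles must lie in [0, 180] degrees")


def spgr_matrix(theta: np.ndarray, fa_deg: Sequence[float], tr: float) -> np.ndarray:
    """Batched two-pool SPGR steady-state signals, shape (N, len(fa_deg))."""
    if tr <= 0:
        raise InvalidParameterError("tr must be strictly positive")
    t1f, t1s, t2f, t2s, mwf, kfs = _split_params(theta)
    fa = np.deg2rad(np.asarray(fa_deg, dtype=float))[None, :]
    _check_angles(fa)
    L, b = _longitudinal_system(t1f, t1s, mwf, kfs, tr)
    c = np.cos(fa)
    m = (1.0 - c * L[0], -c * L[1], -c * L[2], 1.0 - c * L[3])
    mz = _mat_vec(_mat_inv(m, "SPGR steady state"), b)
    return np.sin(fa) * (mz[0] + mz[1])


def bssfp_matrix(
    theta: np.ndarray,
    fa_deg: Sequence[float],
    tr: float,
    phase_increment: float,
    delta_f: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Batched two-pool bSSFP steady-state signals, shape (N, len(fa_deg)).

    The RF phase-cycling increment adds directly to the per-TR off-resonance
    precession angle: beta = 2 pi delta_f tr + phase_increment.
    """
    if tr <= 0:
        raise InvalidParameterError("tr must be strictly positive")
    t1f, t1s, t2f, t2s, mwf, kfs = _split_params(theta)
    fa = np.deg2rad(np.asarray(fa_deg, dtype=float))[None, :]
    _check_angles(fa)
    delta_f = np.asarray(delta_f, dtype=float)
    if delta_f.ndim == 1:
        delta_f = delta_f[:, None]
    omega = 2.0 * math.pi * delta_f + phase_increment / tr

    ksf = _ksf_from(mwf, kfs)
    L, b = _longitudinal_system(t1f, t1s, mwf, kfs, tr)

    # Complex transverse propagator for M+ = Mx + i My of both pools.
    at = (
        -1.0 / t2f - kfs + 1j * omega,
        ksf + 0j,
        kfs + 0j,
        -1.0 / t2s - ksf + 1j * omega,
    )
    P = _expm2(at, tr)
    Ct = tuple(p.real for p in P)
    St = tuple(p.imag for p in P)

    eye = (1.0, 0.0, 0.0, 1.0)
    G = _mat_inv((1.0 - Ct[0], -Ct[1], -Ct[2], 1.0 - Ct[3]), "bSSFP transverse block")
    GSt = _mat_mul(G, St)
    H = _mat_mul(St, GSt)
    K = tuple(h - ct for h, ct in zip(H, Ct))

    c = np.cos(fa)
    s = np.sin(fa)
    ick = (1.0 + c * K[0], c * K[1], c * K[2], 1.0 + c * K[3])
    W = _mat_mul(_mat_inv(ick, "bSSFP y-block"), K)
    LW = _mat_mul(L, W)
    s2 = s * s
    mz_sys = (
        1.0 - c * L[0] - s2 * LW[0],
        -c * L[1] - s2 * LW[1],
        -c * L[2] - s2 * LW[2],
        1.0 - c * L[3] - s2 * LW[3],
    )
    Z = _mat_vec(_mat_inv(mz_sys, "bSSFP longitudinal steady state"), b)
    Y = tuple(-s * v for v in _mat_vec(W, Z))
    cy_sz = (c * Y[0] + s * Z[0], c * Y[1] + s * Z[1])
    X = tuple(-v for v in _mat_vec(GSt, cy_sz))
    # Post-pulse transverse components (rotation about x by the flip angle).
    x_sum = X[0] + X[1]
    y_sum = cy_sz[0] + cy_sz[1]
    return np.hypot(x_sum, y_sum)


def signal_matrix(
    theta: np.ndarray,
    scheme: "AcquisitionScheme",
    delta_f: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Raw concatenated signals for a batch of parameter sets under a scheme.

    Columns follow the scheme order: SPGR block, bSSFP180 block, bSSFP0 block.
    """
    blocks = [spgr_matrix(theta, scheme.fa_spgr, scheme.tr_spgr)]
    if len(scheme.fa_bssfp180):
        blocks.append(
            bssfp_matrix(theta, scheme.fa_bssfp180, scheme.tr_ssfp, math.pi, delta_f)
        )
    if len(scheme.fa_bssfp0):
        blocks.append(
            bssfp_matrix(theta, scheme.fa_bssfp0, scheme.tr_ssfp, 0.0, delta_f)
        )
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# Public single-tissue operations
# ---------------------------------------------------------------------------

def spgr_single_pool(
    t1: float, m0: float, flip_angles_deg: Sequence[float], tr: float
) -> SignalVector:
    """Single-pool SPGR (Ernst) steady state: S = m0 sin(a)(1-E1)/(1-E1 cos(a))."""
    if t1 <= 0 or tr <= 0:
        raise InvalidParameterError("t1 and tr must be strictly positive")
    fa = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    _check_angles(fa)
    e1 = math.exp(-tr / t1)
    values = m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))
    return SignalVector(
        values=values,
        sequences=("SPGR",) * len(fa),
        flip_angles_deg=np.asarray(flip_angles_deg, dtype=float),
    )


def spgr_two_pool(
    tissue: TissueParams, flip_angles_deg: Sequence[float], tr: float
) -> SignalVector:
    """Two-pool SPGR steady state (exchange in the longitudinal 2-vector)."""
    values = spgr_matrix(tissue.to_array()[None, :], flip_angles_deg, tr)[0]
    return SignalVector(
        values=values,
        sequences=("SPGR",) * len(values),
        flip_angles_deg=np.asarray(flip_angles_deg, dtype=float),
    )


def bssfp_two_pool(
    tissue: TissueParams,
    flip_angles_deg: Sequence[float],
    tr: float,
    phase_increment: float = math.pi,
) -> SignalVector:
    """Two-pool phase-cycled bSSFP steady state (full Bloch-McConnell)."""
    values = bssfp_matrix(
        tissue.to_array()[None, :],
        flip_angles_deg,
        tr,
        phase_increment,
        tissue.delta_f,
    )[0]
    if phase_increment == 0.0:
        tag = "bSSFP0"
    elif abs(phase_increment - math.pi) < 1e-12:
        tag = "bSSFP180"
    else:
        tag = f"bSSFP{math.degrees(phase_increment):g}"
    return SignalVector(
        values=values,
        sequences=(tag,) * len(values),
        flip_angles_deg=np.asarray(flip_angles_deg, dtype=float),
    )


def forward_signals(tissue: TissueParams, scheme: "AcquisitionScheme") -> SignalVector:
    """Concatenated raw SPGR + bSSFP180 + bSSFP0 signal vector for a scheme."""
    values = signal_matrix(tissue.to_array()[None, :], scheme, tissue.delta_f)[0]
    sequences: list[str] = []
    angles: list[float] = []
    for tag, fas in (
        ("SPGR", scheme.fa_spgr),
        ("bSSFP180", scheme.fa_bssfp180),
        ("bSSFP0", scheme.fa_bssfp0),
    ):
        sequences.extend([tag] * len(fas))
        angles.extend(fas)
    return SignalVector(
        values=values, sequences=tuple(sequences), flip_angles_deg=np.array(angles)
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalization_groups(
    sequences: Iterable[str], grouping: str = "pooled"
) -> list[np.ndarray]:
    """Index groups used for per-sequence mean normalization.

    ``grouping="pooled"`` (default) treats SPGR as one group and both bSSFP
    phase cycles as a single pooled group; ``grouping="per_sequence"`` keeps
    every sequence tag separate.
    """
    sequences = list(sequences)
    if grouping == "pooled":
        keys = ["bSSFP" if s.startswith("bSSFP") else s for s in sequences]
    elif grouping == "per_sequence":
        keys = sequences
    else:
        raise InvalidParameterError(f"unknown normalization grouping: {grouping!r}")
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return [np.array(idx, dtype=int) for idx in groups.values()]


def normalize_matrix(
    values: np.ndarray, sequences: Iterable[str], grouping: str = "pooled"
) -> np.ndarray:
    """Divide each normalization group of each row by its own mean."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    out = np.empty_like(values)
    for idx in normalization_groups(sequences, grouping):
        means = values[:, idx].mean(axis=1, keepdims=True)
        if np.any(means == 0):
            raise DegenerateInputError("normalization group has zero mean signal")
        out[:, idx] = values[:, idx] / means
    return out


def normalize(signals: SignalVector, grouping: str = "pooled") -> SignalVector:
    """Normalize a signal vector to the mean signal of each sequence group."""
    values = normalize_matrix(signals.values[None, :], signals.sequences, grouping)[0]
    return SignalVector(
        values=values,
        sequences=signals.sequences,
        flip_angles_deg=signals.flip_angles_deg,
        normalized=True,
    )
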