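"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's closed-form steady-state solver:
steady states are obtained by brute-force TR-by-TR propagation of the full
Bloch-McConnell system from thermal equilibrium, with scipy's general
matrix exponential.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

from despotsim.signal_model import TissueParams


def _two_pool_rates(tissue: TissueParams):
    ksf = tissue.ksf
    return tissue.kfs, ksf


def propagate_spgr(tissue: TissueParams, fa_deg, tr: float, n_tr: int = 5000):
    """Two-pool SPGR signal by discrete propagation from equilibrium."""
    kfs, ksf = _two_pool_rates(tissue)
    A = np.array(
        [
            [-1.0 / tissue.t1f - kfs, ksf],
            [kfs, -1.0 / tissue.t1s - ksf],
        ]
    )
    C = np.array([tissue.mwf / tissue.t1f, (1.0 - tissue.mwf) / tissue.t1s])
    E = expm(A * tr)
    b = (E - np.eye(2)) @ np.linalg.solve(A, C)
    out = []
    for a in np.deg2rad(np.asarray(fa_deg, float)):
        M = np.array([tissue.mwf, 1.0 - tissue.mwf])
        for _ in range(n_tr):
            M = E @ (M * np.cos(a)) + b
        out.append(np.sin(a) * M.sum())
    return np.array(out)


def propagate_bssfp(
    tissue: TissueParams, fa_deg, tr: float, phase_increment: float, n_tr: int = 5000
):
    """Two-pool bSSFP signal by discrete 6-D Bloch-McConnell propagation.

    State ordering (MxF, MxS, MyF, MyS, MzF, MzS); the phase-cycling
    increment enters as extra per-TR precession.
    """
    kfs, ksf = _two_pool_rates(tissue)
    omega = 2.0 * math.pi * tissue.delta_f + phase_increment / tr
    A = np.zeros((6, 6))
    r2 = (1.0 / tissue.t2f, 1.0 / tissue.t2s)
    r1 = (1.0 / tissue.t1f, 1.0 / tissue.t1s)
    k = ((-kfs, ksf), (kfs, -ksf))
    for i in range(2):
        for j in range(2):
            A[i, j] += k[i][j]
            A[2 + i, 2 + j] += k[i][j]
            A[4 + i, 4 + j] += k[i][j]
        A[i, i] -= r2[i]
        A[2 + i, 2 + i] -= r2[i]
        A[4 + i, 4 + i] -= r1[i]
        # d(Mx+iMy)/dt = i*omega*(Mx+iMy)
        A[i, 2 + i] -= omega
        A[2 + i, i] += omega
    C = np.zeros(6)
    C[4] = tissue.mwf / tissue.t1f
    C[5] = (1.0 - tissue.mwf) / tissue.t1s
    E = expm(A * tr)
    b = (E - np.eye(6)) @ np.linalg.solve(A, C)

    fa = np.deg2rad(np.asarray(fa_deg, float))
    n_angles = len(fa)
    R = np.tile(np.eye(6), (n_angles, 1, 1))
    c, s = np.cos(fa), np.sin(fa)
    R[:, 2, 2] = c
    R[:, 3, 3] = c
    R[:, 2, 4] = s
    R[:, 3, 5] = s
    R[:, 4, 2] = -s
    R[:, 5, 3] = -s
    R[:, 4, 4] = c
    R[:, 5, 5] = c
    M = np.zeros((n_angles, 6, 1))
    M[:, 4, 0] = tissue.mwf
    M[:, 5, 0] = 1.0 - tissue.mwf
    b = b[None, :, None]
    for _ in range(n_tr):
        M = E @ (R @ M) + b
    Mp = (R @ M)[:, :, 0]
    return np.hypot(Mp[:, 0] + Mp[:, 1], Mp[:, 2] + Mp[:, 3])


def ernst_spgr(t1: float, m0: float, fa_deg, tr: float):
    """Closed-form single-pool spoiled gradient-echo steady state."""
    a = np.deg2rad(np.asarray(fa_deg, float))
    e1 = math.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def bssfp_single_pool_closed_form(t1: float, t2: float, m0: float, fa_deg, tr: float):
    """On-resonance phase-cycled (180 deg) single-pool bSSFP closed form."""
    a = np.deg2rad(np.asarray(fa_deg, float))
    e1 = math.exp(-tr / t1)
    e2 = math.exp(-tr / t2)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * e2 - (e1 - e2) * np.cos(a))
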