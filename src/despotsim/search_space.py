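"""Cost-surface degeneracy analysis for the two-pool fitting problem.

The central quantity is the normalized RMS residual

    eta(theta, theta_hat) = sqrt( (1/N) sum_j (S_j(theta) - S_j(theta_hat))^2 ) / sigma

between the signals of a candidate parameter set and those of the true
solution, in units of a notional noise standard deviation sigma: eta = 1
means the candidate's signals sit one noise SD from the truth on average.
Signals are compared after the same per-sequence normalization used in
fitting, and sigma defaults to the mean-SPGR SNR convention applied to the
normalized clean signals (sigma = 1/SNR).

Tools provided: large-scale uniform sampling of the search box with
streaming retention of the lowest-eta candidates (the degenerate solution
set), kernel-PCA embedding of that set for visualization, 2-D minimum
projections of eta (minimum over random nuisance-parameter draws per grid
cell) and 2-D planar cuts through chosen anchor points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import KernelPCA, PCA
from sklearn.metrics import pairwise_distances

from ._seeding import derive_seed_sequence
from .exceptions import InvalidParameterError
from .signal_model import (
    PARAM_NAMES,
    TissueParams,
    forward_signals,
    normalize_matrix,
    signal_matrix,
)
from .study_config import AcquisitionScheme, BoundSet
from .synthetic_data import noise_sigma

__all__ = [
    "TopSolutionSet",
    "EmbeddingResult",
    "eta",
    "eta_sigma",
    "sample_top_solutions",
    "kpca_embed",
    "min_projection_grid",
    "planar_cut",
]

logger = logging.getLogger(__name__)

#: Parameters entering the kPCA embedding (exchange rate excluded).
EMBED_PARAMS: tuple[str, ...] = ("t1f", "t1s", "t2f", "t2s", "mwf")


def eta_sigma(truth: TissueParams, scheme: AcquisitionScheme, snr: float = 100.0,
              grouping: str = "pooled") -> float:
    """Default notional sigma: mean-SPGR SNR rule on the normalized signals."""
    clean = forward_signals(truth, scheme)
    norm = normalize_matrix(clean.values, clean.sequences, grouping)[0]
    spgr = norm[clean.mask("SPGR")]
    return float(spgr.mean() / snr)


def _normalized_signals(theta: np.ndarray, scheme: AcquisitionScheme,
                        grouping: str) -> np.ndarray:
    return normalize_matrix(
        signal_matrix(theta, scheme), scheme.sequences, grouping
    )


def eta(
    theta: TissueParams,
    theta_hat: TissueParams,
    scheme: AcquisitionScheme,
    sigma: float,
    grouping: str = "pooled",
) -> float:
    """Normalized RMS signal distance between two parameter sets."""
    if not sigma > 0:
        raise InvalidParameterError("sigma must be strictly positive")
    pair = np.stack([theta.to_array(), theta_hat.to_array()])
    s = _normalized_signals(pair, scheme, grouping)
    return float(np.sqrt(np.mean((s[0] - s[1]) ** 2)) / sigma)


def _eta_batch(theta: np.ndarray, ref: np.ndarray, scheme, sigma, grouping):
    s = _normalized_signals(theta, scheme, grouping)
    return np.sqrt(np.mean((s - ref[None, :]) ** 2, axis=1)) / sigma


@dataclass(frozen=True)
class TopSolutionSet:
    """The k lowest-eta candidates from a uniform search-box sampling."""

    theta: np.ndarray  # (k, 6) in PARAM_NAMES order, sorted by ascending eta
    etas: np.ndarray
    truth: TissueParams
    scheme: AcquisitionScheme
    sigma: float
    n_sampled: int
    bounds: BoundSet
    seed: int

    def __len__(self) -> int:
        return len(self.etas)

    def tissues(self) -> list[TissueParams]:
        return [TissueParams.from_array(row) for row in self.theta]

    def column(self, name: str) -> np.ndarray:
        return self.theta[:, PARAM_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=list(PARAM_NAMES))
        df["eta"] = self.etas
        return df

    def signal_matrix(self, normalized: bool = True) -> np.ndarray:
        s = signal_matrix(self.theta, self.scheme)
        if normalized:
            s = normalize_matrix(s, self.scheme.sequences, "pooled")
        return s


def sample_top_solutions(
    n_samples: int,
    bounds: BoundSet,
    truth: TissueParams,
    scheme: AcquisitionScheme,
    sigma: Optional[float] = None,
    k: int = 1000,
    seed: int = 0,
    chunk_size: int = 100_000,
    grouping: str = "pooled",
    fixed_kfs: Optional[float] = None,
) -> TopSolutionSet:
    """Uniformly sample the search box and keep the exact k lowest-eta sets.

    Memory stays O(k + chunk_size): each chunk's etas are merged with the
    running retained set and cut back to k.  Ties are broken by global draw
    index, so the result equals a full sort of all n_samples candidates.

    ``fixed_kfs`` pins the exchange-rate dimension (5-D sampling), matching
    the no-exchange model scenario.
    """
    if k > n_samples:
        raise InvalidParameterError("k must not exceed n_samples")
    if sigma is None:
        sigma = eta_sigma(truth, scheme, grouping=grouping)
    lo = np.array(bounds.lowers())
    hi = np.array(bounds.uppers())
    ref = _normalized_signals(truth.to_array()[None, :], scheme, grouping)[0]
    rng = np.random.default_rng(derive_seed_sequence(seed, "sample_top"))

    best_theta = np.empty((0, len(PARAM_NAMES)))
    best_eta = np.empty(0)
    best_idx = np.empty(0, dtype=np.int64)
    done = 0
    while done < n_samples:
        m = min(chunk_size, n_samples - done)
        cand = lo + rng.uniform(size=(m, len(PARAM_NAMES))) * (hi - lo)
        if fixed_kfs is not None:
            cand[:, PARAM_NAMES.index("kfs")] = fixed_kfs
        e = _eta_batch(cand, ref, scheme, sigma, grouping)
        idx = np.arange(done, done + m, dtype=np.int64)
        pool_theta = np.concatenate([best_theta, cand])
        pool_eta = np.concatenate([best_eta, e])
        pool_idx = np.concatenate([best_idx, idx])
        order = np.lexsort((pool_idx, pool_eta))[:k]
        best_theta, best_eta, best_idx = (
            pool_theta[order],
            pool_eta[order],
            pool_idx[order],
        )
        done += m
    return TopSolutionSet(
        theta=best_theta,
        etas=best_eta,
        truth=truth,
        scheme=scheme,
        sigma=float(sigma),
        n_sampled=n_samples,
        bounds=bounds,
        seed=seed,
    )


@dataclass(frozen=True)
class EmbeddingResult:
    """Low-dimensional coordinates of a degenerate solution set."""

    coordinates: np.ndarray  # (k, n_components)
    etas: np.ndarray
    truth_coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    method: str  # "kpca" or "pca"


def kpca_embed(
    solutions: TopSolutionSet,
    n_components: int = 3,
    kernel: str = "rbf",
) -> EmbeddingResult:
    """Embed the retained candidates with kernel PCA (RBF, median bandwidth).

    The five non-exchange parameters are z-scored before the kernel is
    evaluated; the true solution is projected into the same coordinates.
    A degenerate kernel matrix triggers a linear-PCA fallback with a warning.
    """
    if len(solutions) < n_components + 1:
        raise InvalidParameterError("need at least n_components + 1 candidates")
    cols = [PARAM_NAMES.index(p) for p in EMBED_PARAMS]
    x = solutions.theta[:, cols]
    truth_row = solutions.truth.to_array()[cols][None, :]
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    xs = (x - mean) / std
    ts = (truth_row - mean) / std

    if kernel == "rbf":
        med = float(np.median(pairwise_distances(xs) ** 2))
        if med > 0:
            gamma = 1.0 / med
            try:
                kp = KernelPCA(
                    n_components=n_components,
                    kernel="rbf",
                    gamma=gamma,
                    fit_inverse_transform=False,
                )
                coords = kp.fit_transform(xs)
                if np.all(np.isfinite(coords)) and np.any(kp.eigenvalues_ > 0):
                    ratio = kp.eigenvalues_ / kp.eigenvalues_.sum()
                    return EmbeddingResult(
                        coordinates=coords,
                        etas=solutions.etas.copy(),
                        truth_coordinates=kp.transform(ts)[0],
                        explained_variance_ratio=ratio,
                        method="kpca",
                    )
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                pass
        logger.warning("degenerate kernel matrix; falling back to linear PCA")
    elif kernel != "linear":
        raise InvalidParameterError("kernel must be 'rbf' or 'linear'")

    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(xs)
    return EmbeddingResult(
        coordinates=coords,
        etas=solutions.etas.copy(),
        truth_coordinates=pca.transform(ts)[0],
        explained_variance_ratio=pca.explained_variance_ratio_,
        method="pca",
    )


def _grid_axes(param_x, param_y, grid_shape, bounds):
    if param_x == param_y:
        raise InvalidParameterError("param_x and param_y must differ")
    nx, ny = grid_shape
    gx = np.linspace(*getattr(bounds, param_x), nx)
    gy = np.linspace(*getattr(bounds, param_y), ny)
    return gx, gy


def min_projection_grid(
    param_x: str,
    param_y: str,
    grid_shape: tuple[int, int],
    bounds: BoundSet,
    truth: TissueParams,
    scheme: AcquisitionScheme,
    sigma: Optional[float] = None,
    n_random: int = 10_000,
    seed: int = 0,
    grouping: str = "pooled",
):
    """Minimum-eta projection onto a 2-D parameter grid.

    For every grid cell the remaining four parameters are drawn uniformly
    within the bounds ``n_random`` times and the minimum eta is stored.
    Returns ``(grid_x, grid_y, eta_grid)`` with ``eta_grid[i, j]`` at
    ``(grid_x[i], grid_y[j])``.
    """
    if sigma is None:
        sigma = eta_sigma(truth, scheme, grouping=grouping)
    gx, gy = _grid_axes(param_x, param_y, grid_shape, bounds)
    ix = PARAM_NAMES.index(param_x)
    iy = PARAM_NAMES.index(param_y)
    nuisance = [i for i in range(len(PARAM_NAMES)) if i not in (ix, iy)]
    lo = np.array(bounds.lowers())[nuisance]
    hi = np.array(bounds.uppers())[nuisance]
    ref = _normalized_signals(truth.to_array()[None, :], scheme, grouping)[0]
    out = np.empty((len(gx), len(gy)))
    theta = np.empty((n_random, len(PARAM_NAMES)))
    for i, xv in enumerate(gx):
        for j, yv in enumerate(gy):
            rng = np.random.default_rng(derive_seed_sequence(seed, "proj", i, j))
            theta[:, nuisance] = lo + rng.uniform(size=(n_random, len(nuisance))) * (
                hi - lo
            )
            theta[:, ix] = xv
            theta[:, iy] = yv
            out[i, j] = _eta_batch(theta, ref, scheme, sigma, grouping).min()
    return gx, gy, out


def planar_cut(
    param_x: str,
    param_y: str,
    anchor: TissueParams,
    grid_shape: tuple[int, int],
    bounds: BoundSet,
    truth: TissueParams,
    scheme: AcquisitionScheme,
    sigma: Optional[float] = None,
    grouping: str = "pooled",
):
    """Eta over a 2-D grid with all other parameters pinned to ``anchor``.

    Returns ``(grid_x, grid_y, eta_grid)``.
    """
    if sigma is None:
        sigma = eta_sigma(truth, scheme, grouping=grouping)
    gx, gy = _grid_axes(param_x, param_y, grid_shape, bounds)
    ix = PARAM_NAMES.index(param_x)
    iy = PARAM_NAMES.index(param_y)
    ref = _normalized_signals(truth.to_array()[None, :], scheme, grouping)[0]
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    theta = np.tile(anchor.to_array(), (xx.size, 1))
    theta[:, ix] = xx.ravel()
    theta[:, iy] = yy.ravel()
    e = _eta_batch(theta, ref, scheme, sigma, grouping)
    return gx, gy, e.reshape(xx.shape)
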