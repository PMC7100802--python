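"""Noisy measurement generation for Monte Carlo fitting studies.

Additive i.i.d. Gaussian noise is applied to the *unnormalized* forward
signals, after which each realization is normalized exactly as measured data
would be — the fitter normalizes its model predictions with the same
grouping.  The noise level is set through an SNR defined with respect to the
mean SPGR signal across flip angles, so the effective SNR of individual data
points varies (the bSSFP points sit higher by up to about a factor of two).

Real-valued Gaussian noise is used throughout (no Rician magnitude model).
Each realization draws from its own spawned RNG substream, so datasets are
reproducible independent of chunking or worker scheduling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from ._seeding import derive_seed_sequence
from .exceptions import DegenerateInputError, InvalidParameterError
from .signal_model import SignalVector, TissueParams, forward_signals, normalize_matrix
from .study_config import AcquisitionScheme

__all__ = ["NoisyDataset", "noise_sigma", "make_dataset"]


def noise_sigma(clean: SignalVector, snr: float) -> float:
    """Noise standard deviation: mean SPGR signal across flip angles / SNR."""
    if not snr > 0:
        raise InvalidParameterError("snr must be strictly positive")
    spgr = clean.values[clean.mask("SPGR")]
    if spgr.size == 0:
        raise DegenerateInputError("signal vector contains no SPGR entries")
    if math.isinf(snr):
        return 0.0
    return float(spgr.mean() / snr)


@dataclass(frozen=True)
class NoisyDataset:
    """Clean signals plus normalized noisy realizations.

    ``realizations`` holds one normalized noisy signal vector per row, in the
    label order of ``clean``.
    """

    clean: SignalVector
    sigma: float
    realizations: np.ndarray
    seed: int
    snr: float
    tissue: TissueParams
    scheme: AcquisitionScheme
    grouping: str = "pooled"
    noise_before_normalization: bool = True

    @property
    def n_realizations(self) -> int:
        return self.realizations.shape[0]

    def realization(self, i: int) -> SignalVector:
        return SignalVector(
            values=self.realizations[i],
            sequences=self.clean.sequences,
            flip_angles_deg=self.clean.flip_angles_deg,
            normalized=True,
        )

    def raw_realization(self, i: int) -> np.ndarray:
        """Regenerate the unnormalized noisy vector of realization ``i``.

        Only meaningful when noise was applied before normalization.
        """
        if not self.noise_before_normalization:
            raise InvalidParameterError(
                "raw realizations undefined when noise is added after normalization"
            )
        return self.clean.values + _noise_block(
            self.seed, i, len(self.clean), self.sigma
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("clean", data=self.clean.values)
            f.create_dataset("realizations", data=self.realizations)
            f.create_dataset(
                "sequences",
                data=np.array(self.clean.sequences, dtype=h5py.string_dtype()),
            )
            f.create_dataset("flip_angles_deg", data=self.clean.flip_angles_deg)
            f.attrs["sigma"] = self.sigma
            f.attrs["seed"] = self.seed
            f.attrs["snr"] = self.snr
            f.attrs["grouping"] = self.grouping
            f.attrs["noise_before_normalization"] = self.noise_before_normalization
            f.attrs["tissue"] = self.tissue.to_array()
            f.attrs["tissue_delta_f"] = self.tissue.delta_f
            f.attrs["tr_spgr"] = self.scheme.tr_spgr
            f.attrs["tr_ssfp"] = self.scheme.tr_ssfp
            f.attrs["fa_spgr"] = np.array(self.scheme.fa_spgr)
            f.attrs["fa_bssfp180"] = np.array(self.scheme.fa_bssfp180)
            f.attrs["fa_bssfp0"] = np.array(self.scheme.fa_bssfp0)

    @classmethod
    def from_hdf5(cls, path) -> "NoisyDataset":
        with h5py.File(path, "r") as f:
            scheme = AcquisitionScheme(
                tr_spgr=float(f.attrs["tr_spgr"]),
                tr_ssfp=float(f.attrs["tr_ssfp"]),
                fa_spgr=tuple(f.attrs["fa_spgr"]),
                fa_bssfp180=tuple(f.attrs["fa_bssfp180"]),
                fa_bssfp0=tuple(f.attrs["fa_bssfp0"]),
            )
            clean = SignalVector(
                values=f["clean"][...],
                sequences=tuple(s.decode() for s in f["sequences"][...]),
                flip_angles_deg=f["flip_angles_deg"][...],
            )
            return cls(
                clean=clean,
                sigma=float(f.attrs["sigma"]),
                realizations=f["realizations"][...],
                seed=int(f.attrs["seed"]),
                snr=float(f.attrs["snr"]),
                tissue=TissueParams.from_array(
                    f.attrs["tissue"], delta_f=float(f.attrs["tissue_delta_f"])
                ),
                scheme=scheme,
                grouping=str(f.attrs["grouping"]),
                noise_before_normalization=bool(
                    f.attrs["noise_before_normalization"]
                ),
            )


def _noise_block(seed: int, index: int, n: int, sigma: float) -> np.ndarray:
    rng = np.random.default_rng(derive_seed_sequence(seed, "noise", index))
    return rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)


def make_dataset(
    tissue: TissueParams,
    scheme: AcquisitionScheme,
    snr: float,
    n_realizations: int,
    seed: int,
    grouping: str = "pooled",
    noise_before_normalization: bool = True,
) -> NoisyDataset:
    """Generate ``n_realizations`` normalized noisy signal vectors.

    With the default ordering, noise is added to the raw forward signals and
    each noisy vector is then normalized per sequence group.  Setting
    ``noise_before_normalization=False`` instead adds noise to the normalized
    clean signals, with sigma re-expressed in normalized units by the same
    mean-SPGR SNR rule.
    """
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    clean = forward_signals(tissue, scheme)
    n = len(clean)
    if noise_before_normalization:
        sigma = noise_sigma(clean, snr)
        base = clean.values
    else:
        base = normalize_matrix(clean.values, clean.sequences, grouping)[0]
        sigma = noise_sigma(
            SignalVector(base, clean.sequences, clean.flip_angles_deg, True), snr
        )
    rows = np.empty((n_realizations, n))
    for i in range(n_realizations):
        rows[i] = base + _noise_block(seed, i, n, sigma)
    if noise_before_normalization:
        rows = normalize_matrix(rows, clean.sequences, grouping)
    return NoisyDataset(
        clean=clean,
        sigma=float(sigma),
        realizations=rows,
        seed=seed,
        snr=float(snr),
        tissue=tissue,
        scheme=scheme,
        grouping=grouping,
        noise_before_normalization=noise_before_normalization,
    )
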