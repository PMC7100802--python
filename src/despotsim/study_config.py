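"""Built-in study configurations: search bound sets, acquisition schemes and
reference tissue parameter sets, plus JSON/YAML load/save for user-defined
configurations.

Unit conventions follow the quantitative-MRI literature: T1 in seconds, T2 in
milliseconds *in configuration files and constructors named ``*_ms``*, flip
angles in degrees, repetition times in milliseconds in files.  Internally
everything is seconds and Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigError, InvalidParameterError
from .signal_model import PARAM_NAMES, TissueParams

__all__ = [
    "BoundSet",
    "AcquisitionScheme",
    "builtin_bound_set",
    "builtin_scheme",
    "builtin_tissue",
    "load_config",
    "save_config",
    "BOUND_SET_NAMES",
    "SCHEME_NAMES",
    "TISSUE_NAMES",
]


@dataclass(frozen=True)
class BoundSet:
    """Per-parameter lower/upper search limits (seconds, fractions, 1/s).

    The attribute for each parameter in :data:`PARAM_NAMES` is a
    ``(lower, upper)`` tuple in the same units as :class:`TissueParams`.
    """

    t1f: tuple[float, float]
    t1s: tuple[float, float]
    t2f: tuple[float, float]
    t2s: tuple[float, float]
    mwf: tuple[float, float]
    kfs: tuple[float, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(
                    f"bound set invalid for {name}: lower {lo} must be < upper {hi}"
                )
            if lo < 0:
                raise InvalidParameterError(f"bound set lower for {name} is negative")

    def lowers(self) -> tuple[float, ...]:
        return tuple(getattr(self, n)[0] for n in PARAM_NAMES)

    def uppers(self) -> tuple[float, ...]:
        return tuple(getattr(self, n)[1] for n in PARAM_NAMES)

    def contains(self, tissue: TissueParams) -> bool:
        """True when every fit parameter of ``tissue`` lies within the bounds."""
        theta = tissue.to_array()
        return bool(
            all(lo <= v <= hi for v, lo, hi in zip(theta, self.lowers(), self.uppers()))
        )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Repetition times (s) and flip-angle lists (deg) of the three blocks."""

    tr_spgr: float
    tr_ssfp: float
    fa_spgr: tuple[float, ...]
    fa_bssfp180: tuple[float, ...]
    fa_bssfp0: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.tr_spgr <= 0 or self.tr_ssfp <= 0:
            raise InvalidParameterError("repetition times must be positive")
        object.__setattr__(self, "fa_spgr", tuple(float(a) for a in self.fa_spgr))
        object.__setattr__(
            self, "fa_bssfp180", tuple(float(a) for a in self.fa_bssfp180)
        )
        object.__setattr__(self, "fa_bssfp0", tuple(float(a) for a in self.fa_bssfp0))
        if not self.fa_spgr or not self.fa_bssfp180:
            raise InvalidParameterError("SPGR and bSSFP180 angle lists must be nonempty")
        for a in self.fa_spgr + self.fa_bssfp180 + self.fa_bssfp0:
            if not (0 < a <= 180):
                raise InvalidParameterError(f"flip angle {a} out of (0, 180] degrees")

    @property
    def n_images(self) -> int:
        return len(self.fa_spgr) + len(self.fa_bssfp180) + len(self.fa_bssfp0)

    @property
    def sequences(self) -> tuple[str, ...]:
        return (
            ("SPGR",) * len(self.fa_spgr)
            + ("bSSFP180",) * len(self.fa_bssfp180)
            + ("bSSFP0",) * len(self.fa_bssfp0)
        )


def _bounds_ms(t1f, t1s, t2f_ms, t2s_ms, mwf, kfs) -> BoundSet:
    return BoundSet(
        t1f=t1f,
        t1s=t1s,
        t2f=(t2f_ms[0] / 1e3, t2f_ms[1] / 1e3),
        t2s=(t2s_ms[0] / 1e3, t2s_ms[1] / 1e3),
        mwf=mwf,
        kfs=kfs,
    )


# Literature bound sets.  B1: restricted bounds with extra exchange limits;
# B2: default mcDESPOT boundary conditions; B3: in-house; B4: wide-T2S set;
# WPB: the widest envelope of B1-B4.  T2 entries given in ms, mwf lower
# bounds kept exactly as published (B3: 1e-3, B4: 1e-7).
_BOUND_SETS: dict[str, BoundSet] = {
    "B1": _bounds_ms((0.2, 0.7), (0.8, 2.0), (2, 40), (60, 160), (0.0, 0.5), (0.5, 20)),
    "B2": _bounds_ms((0.3, 0.65), (0.9, 5.0), (1, 30), (50, 165), (0.0, 0.35), (1.67, 40)),
    "B3": _bounds_ms((0.3, 0.8), (0.9, 1.5), (10, 30), (40, 150), (0.001, 0.35), (1.67, 40)),
    "B4": _bounds_ms((0.2, 0.5), (0.7, 2.5), (2, 45), (75, 200), (1e-7, 0.3), (0.5, 20)),
    "WPB": _bounds_ms((0.2, 0.8), (0.7, 5.0), (1, 45), (40, 200), (0.0, 0.5), (0.5, 40)),
}

_SCHEMES: dict[str, AcquisitionScheme] = {
    "S1": AcquisitionScheme(
        tr_spgr=6.5e-3,
        tr_ssfp=6.5e-3,
        fa_spgr=(2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
        fa_bssfp180=(2, 6, 14, 22, 30, 38, 46, 54, 62, 70),
        fa_bssfp0=(2, 6, 14, 22, 30, 38, 46, 54, 62, 70),
    ),
    "S2": AcquisitionScheme(
        tr_spgr=5.6e-3,
        tr_ssfp=4.4e-3,
        fa_spgr=(4, 5, 6, 7, 9, 11, 14, 18),
        fa_bssfp180=(12, 16, 19, 23, 27, 34, 50, 70),
        fa_bssfp0=(12, 16, 19, 23, 27, 34, 50, 70),
    ),
    "S3": AcquisitionScheme(
        tr_spgr=7.0e-3,
        tr_ssfp=7.0e-3,
        fa_spgr=(6, 8, 10, 12, 14, 16),
        fa_bssfp180=(15, 25, 35, 45, 55, 65),
        fa_bssfp0=(25, 55),
    ),
}

# Reference tissue sets: HB from human-brain imaging literature (exchange
# switchable 8 or 0 1/s), WML white-matter-like, GML grey-matter-like, INT
# intermediate.  On-resonance throughout.
_TISSUES: dict[str, TissueParams] = {
    "HB": TissueParams(t1f=0.45, t1s=1.4, t2f=0.015, t2s=0.090, mwf=0.15, kfs=8.0),
    "WML": TissueParams(t1f=0.35, t1s=1.0, t2f=0.015, t2s=0.080, mwf=0.25, kfs=10.0),
    "INT": TissueParams(t1f=0.4, t1s=1.15, t2f=0.020, t2s=0.110, mwf=0.175, kfs=7.5),
    "GML": TissueParams(t1f=0.45, t1s=1.3, t2f=0.025, t2s=0.140, mwf=0.1, kfs=5.0),
}

BOUND_SET_NAMES = tuple(_BOUND_SETS)
SCHEME_NAMES = tuple(_SCHEMES)
TISSUE_NAMES = tuple(_TISSUES)


def builtin_bound_set(name: str) -> BoundSet:
    """Return one of the built-in search bound sets (B1-B4, WPB)."""
    try:
        return _BOUND_SETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown bound set {name!r}; valid names: {', '.join(BOUND_SET_NAMES)}"
        ) from None


def builtin_scheme(name: str) -> AcquisitionScheme:
    """Return one of the built-in acquisition schemes (S1-S3)."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown scheme {name!r}; valid names: {', '.join(SCHEME_NAMES)}"
        ) from None


def builtin_tissue(name: str, exchange: bool = True) -> TissueParams:
    """Return a built-in tissue set; ``exchange=False`` zeroes HB's kfs."""
    try:
        tissue = _TISSUES[name]
    except KeyError:
        raise ConfigError(
            f"unknown tissue {name!r}; valid names: {', '.join(TISSUE_NAMES)}"
        ) from None
    if not exchange:
        tissue = tissue.with_(kfs=0.0)
    return tissue


# ---------------------------------------------------------------------------
# File round-trip.  T2 (and TR) values are written and read in milliseconds,
# as printed in the literature tables; everything else in SI.
# ---------------------------------------------------------------------------

_KIND_TISSUE = "tissue"
_KIND_BOUNDS = "bound_set"
_KIND_SCHEME = "scheme"


def _tissue_to_dict(t: TissueParams) -> dict:
    return {
        "kind": _KIND_TISSUE,
        "t1f": t.t1f,
        "t1s": t.t1s,
        "t2f": t.t2f * 1e3,
        "t2s": t.t2s * 1e3,
        "mwf": t.mwf,
        "kfs": t.kfs,
        "delta_f": t.delta_f,
    }


def _bounds_to_dict(b: BoundSet) -> dict:
    d: dict = {"kind": _KIND_BOUNDS}
    for name in PARAM_NAMES:
        lo, hi = getattr(b, name)
        if name in ("t2f", "t2s"):
            lo, hi = lo * 1e3, hi * 1e3
        d[name] = [lo, hi]
    return d


def _scheme_to_dict(s: AcquisitionScheme) -> dict:
    return {
        "kind": _KIND_SCHEME,
        "tr_spgr": s.tr_spgr * 1e3,
        "tr_ssfp": s.tr_ssfp * 1e3,
        "fa_spgr": list(s.fa_spgr),
        "fa_bssfp180": list(s.fa_bssfp180),
        "fa_bssfp0": list(s.fa_bssfp0),
    }


def _require(d: Mapping, field: str, kind: str):
    if field not in d:
        raise ConfigError(f"{kind} configuration is missing field {field!r}")
    return d[field]


def _object_from_dict(d: Mapping):
    kind = _require(d, "kind", "config")
    try:
        if kind == _KIND_TISSUE:
            return TissueParams(
                t1f=float(_require(d, "t1f", kind)),
                t1s=float(_require(d, "t1s", kind)),
                t2f=float(_require(d, "t2f", kind)) / 1e3,
                t2s=float(_require(d, "t2s", kind)) / 1e3,
                mwf=float(_require(d, "mwf", kind)),
                kfs=float(_require(d, "kfs", kind)),
                delta_f=float(d.get("delta_f", 0.0)),
            )
        if kind == _KIND_BOUNDS:
            fields = {}
            for name in PARAM_NAMES:
                lo, hi = (float(v) for v in _require(d, name, kind))
                if name in ("t2f", "t2s"):
                    lo, hi = lo / 1e3, hi / 1e3
                fields[name] = (lo, hi)
            return BoundSet(**fields)
        if kind == _KIND_SCHEME:
            return AcquisitionScheme(
                tr_spgr=float(_require(d, "tr_spgr", kind)) / 1e3,
                tr_ssfp=float(_require(d, "tr_ssfp", kind)) / 1e3,
                fa_spgr=tuple(_require(d, "fa_spgr", kind)),
                fa_bssfp180=tuple(_require(d, "fa_bssfp180", kind)),
                fa_bssfp0=tuple(d.get("fa_bssfp0", ())),
            )
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc
    raise ConfigError(f"unknown configuration kind {kind!r}")


def save_config(obj, path) -> None:
    """Write a tissue, bound set or scheme as JSON (``.json``) or YAML."""
    if isinstance(obj, TissueParams):
        d = _tissue_to_dict(obj)
    elif isinstance(obj, BoundSet):
        d = _bounds_to_dict(obj)
    elif isinstance(obj, AcquisitionScheme):
        d = _scheme_to_dict(obj)
    else:
        raise ConfigError(f"cannot serialize object of type {type(obj).__name__}")
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path):
    """Load a tissue, bound set or scheme from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if not isinstance(d, Mapping):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return _object_from_dict(d)


def resolve_bounds(spec: str) -> BoundSet:
    """Resolve a CLI-style spec: a built-in name or a config file path."""
    if spec in _BOUND_SETS:
        return _BOUND_SETS[spec]
    return _as_kind(load_config(spec), BoundSet, spec)


def resolve_scheme(spec: str) -> AcquisitionScheme:
    if spec in _SCHEMES:
        return _SCHEMES[spec]
    return _as_kind(load_config(spec), AcquisitionScheme, spec)


def resolve_tissue(spec: str, exchange: bool = True) -> TissueParams:
    if spec in _TISSUES:
        return builtin_tissue(spec, exchange=exchange)
    return _as_kind(load_config(spec), TissueParams, spec)


def _as_kind(obj, cls, spec):
    if not isinstance(obj, cls):
        raise ConfigError(f"{spec} does not contain a {cls.__name__} configuration")
    return obj
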