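"""Epoch container, portable on-disk fixture format, and run configuration.

The :class:`EpochSet` is the currency of the whole pipeline: a
``(trial, channel, sample)`` array of microvolt values plus labels and
sampling metadata.  Fixtures are written as a three-file directory —
``meta.json`` (metadata), ``data.f32`` (row-major little-endian float32)
and ``labels.csv`` (one integer per line) — which round-trips bit-exactly
for 32-bit values on any platform.

Run configuration is a YAML file; absent keys fall back to the package
defaults listed in :class:`RunConfig` (population 10, 20 iterations,
producer/scrounger split 70/30, scout ratio 0.2, m=2, alpha=0.4,
beta=0.01, five folds, C and gamma grids 1e-3..1e3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .tfsegment import SearchBounds

__all__ = [
    "EpochSet",
    "RunConfig",
    "SSASettings",
    "CCSSettings",
    "RCSPSettings",
    "SVMSettings",
    "SplitSettings",
    "FixtureError",
    "ValidationError",
    "MissingFileError",
    "ShapeMismatchError",
    "LabelParseError",
    "NonFiniteDataError",
    "ConfigError",
    "write_fixture",
    "read_fixture",
    "load_config",
]

FIXTURE_VERSION = 1
DEFAULT_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
# 3x3 subgrid used only inside the optimizer's fitness loop when
# SVMSettings.fast_grid is set; the final model always uses the full grid.
FAST_GRID = (0.1, 1.0, 10.0)


class FixtureError(Exception):
    """Base class for fixture I/O failures."""

    code = "fixture_error"


class ValidationError(FixtureError, ValueError):
    code = "invalid_epochs"

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class MissingFileError(FixtureError, FileNotFoundError):
    code = "missing_file"


class ShapeMismatchError(FixtureError, ValueError):
    code = "shape_mismatch"


class LabelParseError(FixtureError, ValueError):
    code = "label_parse"


class NonFiniteDataError(FixtureError, ValueError):
    code = "non_finite"


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a config file."""


@dataclass
class EpochSet:
    """Labeled multichannel EEG trials.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial; exactly two distinct values when fitting.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel identifiers, ordered like the channel axis.
    t0 : float
        Time in seconds of the first sample relative to task onset
        (negative means a pre-onset baseline is present).
    """

    data: np.ndarray
    labels: np.ndarray
    sfreq: float
    channel_names: list
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_names = list(self.channel_names)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to task onset."""
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def validate(self, require_two_classes: bool = True) -> None:
        if self.data.ndim != 3:
            raise ValidationError("data", f"expected 3 axes (trial, channel, sample), got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data", "contains non-finite values")
        if self.labels.shape != (self.n_trials,):
            raise ValidationError(
                "labels", f"length {self.labels.shape} does not match trial count {self.n_trials}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels", f"must be integers, got dtype {self.labels.dtype}")
        if require_two_classes and len(np.unique(self.labels)) != 2:
            raise ValidationError(
                "labels", f"expected exactly 2 classes, got {len(np.unique(self.labels))}"
            )
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                "channel_names",
                f"{len(self.channel_names)} names for {self.n_channels} channels",
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel_names", "names are not unique")
        if not (np.isfinite(self.sfreq) and self.sfreq > 0):
            raise ValidationError("sfreq", f"must be positive and finite, got {self.sfreq}")
        if not np.isfinite(self.t0):
            raise ValidationError("t0", "must be finite")

    # -- convenience views ----------------------------------------------
    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            labels=self.labels.copy(),
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            t0=self.t0,
        )

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.labels[idx], self.sfreq, list(self.channel_names), self.t0)

    def select_channels(self, idx: Sequence[int]) -> "EpochSet":
        idx = list(idx)
        return EpochSet(
            self.data[:, idx, :],
            self.labels,
            self.sfreq,
            [self.channel_names[i] for i in idx],
            self.t0,
        )


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(epochs: EpochSet, path) -> dict:
    """Write an :class:`EpochSet` as a portable fixture directory.

    Returns a manifest dict mapping file names to byte sizes.  The data file
    stores little-endian 32-bit floats in row-major (trial, channel, sample)
    order, so the same ``EpochSet`` produces byte-identical files on every
    platform.
    """
    epochs.validate(require_two_classes=True)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "version": FIXTURE_VERSION,
        "sfreq": float(epochs.sfreq),
        "t0": float(epochs.t0),
        "channel_names": list(epochs.channel_names),
        "shape": [int(s) for s in epochs.data.shape],
        "byte_order": "little",
        "dtype": "float32",
        "order": "C",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    raw = np.ascontiguousarray(epochs.data, dtype="<f4").tobytes()
    (path / "data.f32").write_bytes(raw)
    labels_text = "".join(f"{int(v)}\n" for v in epochs.labels)
    (path / "labels.csv").write_text(labels_text)
    return {
        "meta.json": len((path / "meta.json").read_bytes()),
        "data.f32": len(raw),
        "labels.csv": len(labels_text.encode()),
    }


def read_fixture(path) -> EpochSet:
    """Read a fixture directory written by :func:`write_fixture`."""
    path = Path(path)
    for name in ("meta.json", "data.f32", "labels.csv"):
        if not (path / name).exists():
            raise MissingFileError(f"fixture file missing: {path / name}")

    meta = json.loads((path / "meta.json").read_text())
    shape = tuple(int(s) for s in meta["shape"])
    if len(shape) != 3:
        raise ShapeMismatchError(f"meta.json shape must have 3 axes, got {shape}")

    raw = (path / "data.f32").read_bytes()
    expected = int(np.prod(shape)) * 4
    if len(raw) != expected:
        raise ShapeMismatchError(
            f"data.f32 holds {len(raw)} bytes but shape {shape} requires {expected}"
        )
    data = np.frombuffer(raw, dtype="<f4").reshape(shape).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise NonFiniteDataError("data.f32 contains non-finite values")

    labels = []
    for lineno, line in enumerate((path / "labels.csv").read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            labels.append(int(line))
        except ValueError as exc:
            raise LabelParseError(f"labels.csv line {lineno}: not an integer: {line!r}") from exc
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != shape[0]:
        raise ShapeMismatchError(
            f"labels.csv has {labels.shape[0]} entries for {shape[0]} trials"
        )

    epochs = EpochSet(
        data=data,
        labels=labels,
        sfreq=float(meta["sfreq"]),
        channel_names=list(meta["channel_names"]),
        t0=float(meta["t0"]),
    )
    epochs.validate(require_two_classes=False)
    return epochs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSASettings:
    n: int = 10
    itermax: int = 20
    producer_ratio: float = 0.7
    scout_ratio: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class CCSSettings:
    # n_select None -> keep all channels; n_trials None -> use all training trials
    n_select: Optional[int] = None
    n_trials: Optional[int] = None
    exclude_diagonal: bool = False


@dataclass(frozen=True)
class RCSPSettings:
    m: int = 2
    alpha: float = 0.4
    beta: float = 0.01


@dataclass(frozen=True)
class SVMSettings:
    C_grid: tuple = DEFAULT_GRID
    g_grid: tuple = DEFAULT_GRID
    k: int = 5
    fast_grid: bool = True
    standardize: bool = True


@dataclass(frozen=True)
class SplitSettings:
    train_fraction: float = 0.7
    stratified: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved pipeline configuration with field-wise defaults."""

    ssa: SSASettings = field(default_factory=SSASettings)
    bounds: SearchBounds = field(default_factory=SearchBounds)
    ccs: CCSSettings = field(default_factory=CCSSettings)
    rcsp: RCSPSettings = field(default_factory=RCSPSettings)
    svm: SVMSettings = field(default_factory=SVMSettings)
    split: SplitSettings = field(default_factory=SplitSettings)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


_SECTION_TYPES = {
    "ssa": SSASettings,
    "bounds": SearchBounds,
    "ccs": CCSSettings,
    "rcsp": RCSPSettings,
    "svm": SVMSettings,
    "split": SplitSettings,
}

_TUPLE_FIELDS = {"C_grid", "g_grid"}


def _check_ranges(cfg: RunConfig) -> None:
    checks = [
        (cfg.ssa.n >= 2, "ssa.n must be >= 2"),
        (cfg.ssa.itermax >= 1, "ssa.itermax must be >= 1"),
        (0 < cfg.ssa.producer_ratio <= 1, "ssa.producer_ratio must be in (0, 1]"),
        (0 <= cfg.ssa.scout_ratio <= 1, "ssa.scout_ratio must be in [0, 1]"),
        (cfg.rcsp.m >= 1, "rcsp.m must be >= 1"),
        (0 <= cfg.rcsp.alpha <= 1, "rcsp.alpha must be in [0, 1]"),
        (0 <= cfg.rcsp.beta <= 1, "rcsp.beta must be in [0, 1]"),
        (cfg.svm.k >= 2, "svm.k must be >= 2"),
        (len(cfg.svm.C_grid) > 0 and len(cfg.svm.g_grid) > 0, "svm grids must be non-empty"),
        (all(c > 0 for c in cfg.svm.C_grid), "svm.C_grid values must be positive"),
        (all(g > 0 for g in cfg.svm.g_grid), "svm.g_grid values must be positive"),
        (0 < cfg.split.train_fraction < 1, "split.train_fraction must be in (0, 1)"),
        (cfg.ccs.n_select is None or cfg.ccs.n_select >= 1, "ccs.n_select must be >= 1"),
        (cfg.ccs.n_trials is None or cfg.ccs.n_trials >= 1, "ccs.n_trials must be >= 1"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ConfigError(msg)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a nested dict, defaulting absent keys."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = RunConfig()
    updates = {}
    for section, value in raw.items():
        if section not in _SECTION_TYPES:
            raise ConfigError(f"unknown config section: {section!r}")
        cls = _SECTION_TYPES[section]
        if not isinstance(value, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {}
        for key, v in value.items():
            if key not in known:
                raise ConfigError(f"unknown key {section}.{key}")
            if key in _TUPLE_FIELDS:
                v = tuple(float(x) for x in v)
            kwargs[key] = v
        updates[section] = replace(getattr(cfg, section), **kwargs)
    cfg = replace(cfg, **updates)
    _check_ranges(cfg)
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys take the package defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)
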