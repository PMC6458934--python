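"""One-dimensional temporal encoding of scalar features into spike times.

Each feature value ``f`` is mapped linearly onto a temporal window [a, b]
(milliseconds) using the per-feature minimum ``m`` and maximum ``M`` observed
on the design subset:

    Y(f) = ((b - a) / r) * f + (a*M - b*m) / r,      r = M - m,

so that Y(m) = a and Y(M) = b.  The encoding preserves the dimensionality of
the sample; each feature becomes the firing time of one input neuron.

Two conventions guard the edges.  Values outside the design range are clamped
to [m, M] first, keeping all spike times inside the window the simulator
expects.  A degenerate feature (r = 0 on the design subset) maps every value
to the window midpoint (a + b)/2, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = [
    "EncodingSpec",
    "EncodedPattern",
    "encode_feature",
    "fit_encoding",
    "encode_dataset",
    "encode_matrix",
]


@dataclass(frozen=True)
class EncodingSpec:
    """Fitted encoding window plus per-feature design-set min/max."""

    a: float
    b: float
    m: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.m, dtype=float))
        M = np.atleast_1d(np.asarray(self.M, dtype=float))
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "M", M)
        if not self.a < self.b:
            raise ValueError(f"need a < b, got [{self.a}, {self.b}]")
        if m.shape != M.shape:
            raise ValueError("m and M must have matching shapes")
        if (M < m).any():
            raise ValueError("per-feature max below min")

    @property
    def r(self) -> np.ndarray:
        return self.M - self.m

    @property
    def n_features(self) -> int:
        return self.m.size


@dataclass(frozen=True)
class EncodedPattern:
    """Input spike times (ms), one per feature, plus the class label."""

    spike_times: tuple[float, ...]
    label: int


def encode_feature(f: float, a: float, b: float, m: float, M: float) -> float:
    """Map one feature value to a spike time in [a, b]; clamps f into [m, M]."""
    if M < m:
        raise ValueError("need M >= m")
    if not a < b:
        raise ValueError("need a < b")
    r = M - m
    if r == 0:
        return (a + b) / 2.0
    f = min(max(f, m), M)
    return ((b - a) / r) * f + (a * M - b * m) / r


def fit_encoding(design: Dataset, a: float = 0.01, b: float = 9.0) -> EncodingSpec:
    """Learn per-feature min/max from the design subset only."""
    if design.n_samples == 0:
        raise ValueError("cannot fit encoding on an empty dataset")
    m = design.X.min(axis=0)
    M = design.X.max(axis=0)
    degenerate = np.flatnonzero(M == m)
    if degenerate.size:
        warnings.warn(
            f"feature(s) {degenerate.tolist()} are constant on the design set; "
            "their spike times collapse to the window midpoint",
            stacklevel=2,
        )
    return EncodingSpec(a=a, b=b, m=m, M=M)


def encode_matrix(X: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Vectorised encoding of a feature matrix into a spike-time matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_features:
        raise ValueError(
            f"matrix shape {X.shape} incompatible with {spec.n_features} features"
        )
    a, b, m, M = spec.a, spec.b, spec.m, spec.M
    r = spec.r
    clamped = np.clip(X, m, M)
    safe_r = np.where(r == 0, 1.0, r)
    out = ((b - a) / safe_r) * clamped + (a * M - b * m) / safe_r
    return np.where(r == 0, (a + b) / 2.0, out)


def encode_dataset(ds: Dataset, spec: EncodingSpec) -> list[EncodedPattern]:
    """Encode every sample; dimension-preserving."""
    spikes = encode_matrix(ds.X, spec)
    return [
        EncodedPattern(spike_times=tuple(row), label=int(lbl))
        for row, lbl in zip(spikes, ds.y)
    ]
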