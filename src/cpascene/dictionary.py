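"""Dictionaries of candidate source spectra.

A dictionary holds ``n`` candidate source templates ("elements"), each an
``f``-dimensional feature vector (for sounds, typically a spectrum).  Every
element is mean-subtracted and then scaled to unit L2 norm, so that the inner
product of an observation with an element is a similarity that ignores overall
offset and template scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import rng_from

__all__ = [
    "DictionaryElement",
    "Dictionary",
    "normalize_element",
    "make_random_dictionary",
    "dictionary_from_vectors",
    "gram_matrix",
    "read_dictionary",
    "write_dictionary",
]

_NORM_TOL = 1e-10


class DictionaryElement(NamedTuple):
    """A single labelled, zero-mean, unit-norm feature vector."""

    values: np.ndarray
    label: str


def normalize_element(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Mean-subtract then unit-normalize a vector, in that order.

    Raises
    ------
    ValueError
        If the vector has fewer than 2 components or all components are
        equal (zero vector after mean subtraction), in which case no
        normalization is possible.
    """
    u = np.asarray(v, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("element must be a vector with at least 2 components")
    u = u - u.mean()
    norm = float(np.linalg.norm(u))
    if norm < 1e-12:
        raise ValueError("cannot normalize: all components equal")
    return u / norm


def default_labels(n: int, prefix: str = "elem") -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"{prefix}_{i + 1:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class Dictionary:
    """An ordered collection of ``n`` zero-mean unit-norm elements of length ``f``.

    ``matrix`` stores one element per row, shape ``(n, f)``.
    """

    matrix: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("dictionary matrix must be 2-D (n elements x f features)")
        n, f = m.shape
        if n < 1 or f < 2:
            raise ValueError("dictionary needs n >= 1 elements of f >= 2 features")
        labels = self.labels or default_labels(n)
        if len(labels) != n:
            raise ValueError("one label per element required")
        if len(set(labels)) != n:
            raise ValueError("labels must be unique")
        if np.max(np.abs(m.mean(axis=1))) > _NORM_TOL:
            raise ValueError("elements must be zero-mean")
        if np.max(np.abs(np.linalg.norm(m, axis=1) - 1.0)) > _NORM_TOL:
            raise ValueError("elements must have unit norm")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def f(self) -> int:
        return self.matrix.shape[1]

    def element(self, i: int) -> DictionaryElement:
        return DictionaryElement(self.matrix[i], self.labels[i])

    def __iter__(self):
        return (self.element(i) for i in range(self.n))


def dictionary_from_vectors(
    vectors: Iterable[Sequence[float]], labels: Sequence[str] | None = None
) -> Dictionary:
    """Build a dictionary by normalizing each raw vector in turn."""
    rows = [normalize_element(v) for v in vectors]
    m = np.vstack(rows)
    return Dictionary(m, tuple(labels) if labels is not None else ())


_DISTRIBUTIONS = ("uniform01", "standard_normal", "lognormal")


def make_random_dictionary(
    n: int,
    f: int,
    distribution: str = "uniform01",
    seed: int = 0,
) -> Dictionary:
    """Draw ``n`` i.i.d. random elements of ``f`` features and normalize them.

    ``distribution`` is one of ``uniform01`` (uniform on [0, 1)),
    ``standard_normal``, or ``lognormal`` (log-mean 0, log-sd 1).
    Deterministic given ``seed``.
    """
    if n < 1 or f < 2:
        raise ValueError("need n >= 1 and f >= 2")
    rng = rng_from(seed)
    if distribution == "uniform01":
        raw = rng.random((n, f))
    elif distribution == "standard_normal":
        raw = rng.standard_normal((n, f))
    elif distribution == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=(n, f))
    else:
        raise ValueError(
            f"unknown distribution {distribution!r}; choose from {_DISTRIBUTIONS}"
        )
    return dictionary_from_vectors(raw)


def gram_matrix(d: Dictionary) -> np.ndarray:
    """All pairwise inner products b_i . b_j, shape (n, n).

    Diagonal entries are 1 (unit-norm elements); off-diagonal magnitudes
    measure how far the dictionary is from orthogonal.
    """
    return d.matrix @ d.matrix.T


def write_dictionary(d: Dictionary, path) -> None:
    """Write as tab-delimited text: first column label, then one column per feature."""
    df = pd.DataFrame(d.matrix, index=list(d.labels))
    df.index.name = "label"
    df.to_csv(path, sep="\t")


def read_dictionary(path) -> Dictionary:
    df = pd.read_csv(path, sep="\t", index_col="label")
    return Dictionary(df.to_numpy(dtype=float), tuple(str(x) for x in df.index))
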