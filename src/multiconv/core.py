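"""Sequence encoding, the multinomial kernel transform, and LLR scanning.

This module is the mathematical core of the package and is independent of
any learning machinery.  A *multinomial kernel* is an ``L x 4`` row-stochastic
matrix obtained from an unconstrained weight matrix ``X`` through a
temperature-``alpha`` softmax applied per row:

    ``T[i, j] = exp(alpha * X[i, j]) / sum_j' exp(alpha * X[i, j'])``

Scoring a one-hot encoded window ``s`` of length ``L`` against a kernel ``T``
and a background base distribution ``B`` yields a log-likelihood ratio

    ``sum_i sum_j ln(T[i, j] / B[j]) * s[i, j]``

i.e. the log of the probability of generating ``s`` from the kernel's
per-position multinomial distributions divided by the probability of
generating it from the background.  Natural logarithms throughout.

Column order is fixed to A, C, G, T everywhere.  Coordinates are 0-based
with half-open windows ``[k, k + L)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import (
    AlphabetError,
    DimensionError,
    NumericError,
    SequenceTooShortError,
)

__all__ = [
    "ALPHABET",
    "DEFAULT_BACKGROUND",
    "BackgroundDistribution",
    "MultinomialKernel",
    "OneHotSequence",
    "RawConvolution",
    "llr_score",
    "multinomial_transform",
    "one_hot_encode",
    "reverse_complement",
    "scan",
]

#: Fixed column order of every 4-wide matrix in the package.
ALPHABET = "ACGT"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class OneHotSequence:
    """An ``N x 4`` indicator-matrix encoding of a DNA sequence.

    Rows encoding an unambiguous base sum to 1; rows for ambiguous bases
    (``N``) are all-zero so that they contribute nothing to any LLR term.
    """

    matrix: np.ndarray
    strand: str = "forward"

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise DimensionError(
                f"one-hot matrix must be N x 4, got shape {matrix.shape}"
            )
        if self.strand not in ("forward", "reverse_complement"):
            raise ValueError(f"unknown strand {self.strand!r}")
        object.__setattr__(self, "matrix", matrix)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OneHotSequence):
            return NotImplemented
        return (
            self.strand == other.strand
            and self.matrix.shape == other.matrix.shape
            and bool(np.array_equal(self.matrix, other.matrix))
        )


@dataclass(frozen=True)
class BackgroundDistribution:
    """A strictly positive probability vector over A, C, G, T."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4,):
            raise DimensionError(f"background must have 4 entries, got {probs.shape}")
        if not np.all(probs > 0):
            raise ValueError("background probabilities must be strictly positive")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"background probabilities must sum to 1 (got {probs.sum()!r})"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


#: Human genomic background used throughout: A 0.295, C 0.205, G 0.205, T 0.295.
DEFAULT_BACKGROUND = BackgroundDistribution(np.array([0.295, 0.205, 0.205, 0.295]))


@dataclass(frozen=True)
class RawConvolution:
    """An unconstrained ``L x 4`` real weight matrix."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != 4:
            raise DimensionError(
                f"raw convolution must be L x 4, got shape {weights.shape}"
            )
        if not np.all(np.isfinite(weights)):
            raise NumericError("raw convolution weights must be finite")
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class MultinomialKernel:
    """An ``L x 4`` row-stochastic matrix, directly interpretable as a motif.

    ``log_probs`` is carried alongside ``probs``: when the kernel comes from
    :func:`multinomial_transform` it is computed as
    ``alpha * X - logsumexp(alpha * X)`` per row, which stays finite even when
    the softmax saturates at large ``alpha``.
    """

    probs: np.ndarray
    alpha: float = 1.0
    source: RawConvolution | None = None
    log_probs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise DimensionError(f"kernel must be L x 4, got shape {probs.shape}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not np.all((probs > 0) & (probs < 1)):
            raise ValueError("kernel probabilities must lie strictly in (0, 1)")
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-6):
            raise ValueError("every kernel row must sum to 1 within 1e-6")
        object.__setattr__(self, "probs", probs)
        if self.log_probs is None:
            object.__setattr__(self, "log_probs", np.log(probs))
        else:
            object.__setattr__(
                self, "log_probs", np.asarray(self.log_probs, dtype=float)
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def one_hot_encode(sequence: str) -> OneHotSequence:
    """Encode a DNA string (case-insensitive, alphabet ACGTN) as one-hot rows.

    Raises
    ------
    AlphabetError
        If a character outside ``{A, C, G, T, N}`` is found; the error names
        the 0-based position and the offending character.
    """
    if len(sequence) == 0:
        raise ValueError("sequence must have length >= 1")
    upper = sequence.upper()
    matrix = np.zeros((len(upper), 4))
    for i, base in enumerate(upper):
        if base == "N":
            continue
        j = _BASE_INDEX.get(base)
        if j is None:
            raise AlphabetError(i, sequence[i])
        matrix[i, j] = 1.0
    return OneHotSequence(matrix=matrix, strand="forward")


def reverse_complement(encoded: OneHotSequence) -> OneHotSequence:
    """Reverse the rows and swap columns A<->T, C<->G; flips the strand label.

    Applying the operation twice restores the input.
    """
    flipped = encoded.matrix[::-1, ::-1].copy()
    strand = "reverse_complement" if encoded.strand == "forward" else "forward"
    return OneHotSequence(matrix=flipped, strand=strand)


def multinomial_transform(x: RawConvolution, alpha: float) -> MultinomialKernel:
    """Row-wise temperature softmax turning raw weights into a kernel.

    ``log_probs`` is computed directly as ``alpha*X - logsumexp(alpha*X)``
    rather than as the log of the softmax output, so LLR terms stay accurate
    at the large temperatures (alpha ~ 100-140) used in practice.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    scaled = alpha * x.weights
    if not np.all(np.isfinite(scaled)):
        raise NumericError("non-finite values in scaled weights")
    log_probs = scaled - logsumexp(scaled, axis=1, keepdims=True)
    probs = np.exp(log_probs)
    # Guard against exact 0/1 after saturation; the log-space representation
    # is exact, only the linear-space probabilities are clipped.
    probs /= probs.sum(axis=1, keepdims=True)
    probs = np.clip(probs, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return MultinomialKernel(probs=probs, alpha=alpha, source=x, log_probs=log_probs)


def _llr_weights(
    kernel: MultinomialKernel, background: BackgroundDistribution
) -> np.ndarray:
    """Per-position, per-base LLR contributions ``ln(T[i,j] / B[j])``."""
    return kernel.log_probs - background.log_probs[np.newaxis, :]


def llr_score(
    kernel: MultinomialKernel,
    subseq: OneHotSequence,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> float:
    """Log-likelihood ratio of one window against the background.

    All-zero rows (ambiguous bases) contribute 0.
    """
    if subseq.length != kernel.length:
        raise DimensionError(
            f"window length {subseq.length} != kernel length {kernel.length}"
        )
    return float(np.sum(_llr_weights(kernel, background) * subseq.matrix))


def scan(
    kernel: MultinomialKernel,
    seq: OneHotSequence,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> np.ndarray:
    """LLR score of every length-``L`` window; output has length ``N - L + 1``.

    No padding: element ``k`` scores the half-open window ``[k, k + L)``.
    """
    n, length = seq.length, kernel.length
    if n < length:
        raise SequenceTooShortError(
            f"sequence length {n} shorter than kernel length {length}"
        )
    weights = _llr_weights(kernel, background)
    windows = np.lib.stride_tricks.sliding_window_view(seq.matrix, length, axis=0)
    # windows: (N - L + 1, 4, L); weights: (L, 4)
    return np.einsum("kjl,lj->k", windows, weights)
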