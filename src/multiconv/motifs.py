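"""Motif extraction, specificity (information content), and MEME text I/O.

A trained multinomial network's kernels *are* motifs: each is re-derived from
its raw weights through the temperature softmax and paired with its dense
weight, whose sign designates the motif as an activator (positive) or
repressor (negative).

Specificity is quantified as information content per position (ICP), the
mean per-position KL divergence (base 2) of the motif from the background:

    ``ICP = (1/L) * sum_i sum_j M[i, j] * log2(M[i, j] / B[j])``

with rows renormalized by their sums first and ``0 * log2(0 / B) := 0``.

MEME minimal text format (version 4) is written and read here directly:
the writer emits a version line, an ACGT alphabet line, a strands line, a
background frequency line, and one ``letter-probability matrix`` block per
motif with 6-decimal probabilities; the reader accepts rows whose sums
deviate from 1 by at most 1e-3 and renormalizes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DEFAULT_BACKGROUND, BackgroundDistribution, multinomial_transform
from .exceptions import (
    DataError,
    DegenerateMotifError,
    DimensionError,
    InsufficientDataError,
    MemeParseError,
)
from .model import TrainedModel

__all__ = [
    "ICPReport",
    "Motif",
    "compare_icp",
    "extract_motifs",
    "icp",
    "read_meme",
    "trim_motif",
    "write_meme",
]

_ROW_SUM_TOLERANCE = 1e-3


@dataclass
class Motif:
    """An ``L x 4`` row-stochastic probability matrix with optional metadata."""

    probs: np.ndarray
    name: str = "motif"
    dense_weight: float | None = None
    role: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise DimensionError(f"motif must be L x 4, got shape {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("motif probabilities must be non-negative")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("every motif row must sum to 1 within 1e-6")
        self.probs = probs
        if self.role is None:
            self.role = _role_from_weight(self.dense_weight)
        if self.role not in ("activator", "repressor", "unassigned"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "Motif":
        return Motif(
            probs=self.probs[::-1, ::-1].copy(),
            name=f"{self.name}_rc",
            dense_weight=self.dense_weight,
            role=self.role,
        )


def _role_from_weight(weight: float | None) -> str:
    if weight is None or weight == 0:
        return "unassigned"
    return "activator" if weight > 0 else "repressor"


def extract_motifs(model: TrainedModel) -> list[Motif]:
    """One motif per filter, with its dense weight and activator/repressor role.

    Kernels are re-derived from the stored raw convolutions with the model's
    temperature, so the motifs match the network's forward pass exactly.
    """
    network = model.network
    alpha = network.alpha
    weights, _intercept = model.dense_weights()
    motifs = []
    for index, raw in enumerate(model.raw_convolutions):
        kernel = multinomial_transform(raw, alpha)
        weight = float(weights[index])
        motifs.append(
            Motif(
                probs=kernel.probs,
                name=f"filter_{index:03d}",
                dense_weight=weight,
                role=_role_from_weight(weight),
            )
        )
    return motifs


def icp(
    motif: Motif | np.ndarray,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> float:
    """Information content per position, in bits.

    Accepts a :class:`Motif` or a bare ``L x 4`` count/probability matrix.
    Rows are first renormalized by their sums; a zero-sum row raises
    :class:`DegenerateMotifError`.  Always non-negative (mean KL divergence).
    """
    probs = np.asarray(motif.probs if isinstance(motif, Motif) else motif,
                       dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 4:
        raise DimensionError(f"motif must be L x 4, got shape {probs.shape}")
    row_sums = probs.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise DegenerateMotifError("motif contains a row summing to 0")
    normalized = probs / row_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = normalized * np.log2(normalized / background.probs)
    terms = np.where(normalized == 0, 0.0, terms)
    return float(terms.sum() / probs.shape[0])


@dataclass(frozen=True)
class ICPReport:
    """Welch t-test of reference-vs-learned motif information content."""

    icp_values_a: np.ndarray
    icp_values_b: np.ndarray
    t_statistic: float
    p_value: float
    alternative: str = "less"


def compare_icp(
    reference: Sequence[Motif],
    learned: Sequence[Motif],
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> ICPReport:
    """Welch two-sample t-test: is reference mean ICP *less* than learned?

    Unequal variances; one-sided alternative ``reference < learned``.
    """
    if len(reference) == 0 or len(learned) == 0:
        raise DataError("both motif sets must be non-empty")
    if len(reference) < 2 or len(learned) < 2:
        raise InsufficientDataError("each motif set needs >= 2 motifs")
    values_a = np.array([icp(m, background) for m in reference])
    values_b = np.array([icp(m, background) for m in learned])
    result = stats.ttest_ind(values_a, values_b, equal_var=False, alternative="less")
    return ICPReport(
        icp_values_a=values_a,
        icp_values_b=values_b,
        t_statistic=float(result.statistic),
        p_value=float(result.pvalue),
    )


def trim_motif(
    motif: Motif,
    min_icp: float,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> Motif:
    """Trim low-information flanks below ``min_icp`` bits/position (optional

    convenience; exported motifs are untrimmed by default).
    """
    per_position = np.array(
        [icp(Motif(probs=row[np.newaxis, :]), background) for row in motif.probs]
    )
    keep = np.where(per_position >= min_icp)[0]
    if keep.size == 0:
        return motif
    return Motif(
        probs=motif.probs[keep[0] : keep[-1] + 1].copy(),
        name=motif.name,
        dense_weight=motif.dense_weight,
        role=motif.role,
    )


# ---------------------------------------------------------------------------
# MEME minimal text format
# ---------------------------------------------------------------------------


def write_meme(
    motifs: Sequence[Motif],
    path: str | Path,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> None:
    """Write motifs in MEME minimal text format (version 4)."""
    motifs = list(motifs)
    if not motifs:
        raise DataError("no motifs to write")
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A {0:.6f} C {1:.6f} G {2:.6f} T {3:.6f}".format(*background.probs),
        "",
    ]
    for motif in motifs:
        lines.append(f"MOTIF {motif.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {motif.length} "
            f"nsites= 20 E= 0"
        )
        for row in motif.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> list[Motif]:
    """Parse a MEME minimal text file into motifs.

    Rows whose sums deviate from 1 by at most 1e-3 are renormalized; larger
    deviations raise :class:`MemeParseError` with the offending line number.
    """
    lines = Path(path).read_text().splitlines()
    motifs: list[Motif] = []
    name: str | None = None
    expected_width: int | None = None
    rows: list[list[float]] = []
    row_line_numbers: list[int] = []

    def flush(line_number: int) -> None:
        nonlocal name, expected_width, rows, row_line_numbers
        if name is None:
            return
        if not rows:
            raise MemeParseError(line_number, f"motif {name!r} has no probability rows")
        if expected_width is not None and len(rows) != expected_width:
            raise MemeParseError(
                line_number,
                f"motif {name!r}: expected {expected_width} rows, got {len(rows)}",
            )
        matrix = np.array(rows, dtype=float)
        sums = matrix.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOLERANCE)[0]
        if bad.size:
            raise MemeParseError(
                row_line_numbers[bad[0]],
                f"motif {name!r}: row sums to {sums[bad[0]]:.6f}, "
                f"outside 1 +/- {_ROW_SUM_TOLERANCE}",
            )
        matrix = matrix / sums[:, np.newaxis]
        motifs.append(Motif(probs=matrix, name=name))
        name, expected_width, rows, row_line_numbers = None, None, [], []

    for number, raw_line in enumerate(lines, start=1):
        line = raw_line.strip()
        if line.startswith("MOTIF"):
            flush(number)
            parts = line.split()
            if len(parts) < 2:
                raise MemeParseError(number, "MOTIF line lacks a name")
            name = parts[1]
        elif line.startswith("letter-probability matrix"):
            if name is None:
                raise MemeParseError(number, "matrix header before any MOTIF line")
            tokens = line.replace("=", " = ").split()
            if "w" in tokens:
                try:
                    expected_width = int(tokens[tokens.index("w") + 2])
                except (IndexError, ValueError) as err:
                    raise MemeParseError(number, f"bad w= field: {err}") from err
        elif name is not None and line and line[0] in "0123456789.-":
            values = line.split()
            if len(values) != 4:
                raise MemeParseError(
                    number, f"expected 4 probabilities, got {len(values)}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as err:
                raise MemeParseError(number, f"non-numeric probability: {err}") from err
            row_line_numbers.append(number)
    flush(len(lines) + 1)
    if not motifs:
        raise MemeParseError(1, "no motifs found in file")
    return motifs
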