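"""Synthetic MPRA-style data with planted activator/repressor motifs.

Sequences are drawn i.i.d. per base from a background distribution; motif
instances (sites sampled from the motif's per-position distributions, on a
random strand) are planted at non-overlapping uniform positions.  Activity
is a noisy linear function of each motif's best log-likelihood-ratio score
over all positions of both strands — the same quantity the network's
max-pooled multinomial convolutions compute — so parameter recovery is
well-posed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ALPHABET, DEFAULT_BACKGROUND, BackgroundDistribution
from .data import MPRADataset
from .exceptions import PlacementError, SimulationSpecError
from .motifs import Motif

__all__ = [
    "GroundTruth",
    "MotifMatch",
    "PlantRecord",
    "SimulationSpec",
    "consensus_motif",
    "generate",
    "max_llr_scores",
    "recovery_report",
]

_PLACEMENT_RETRIES = 100


def consensus_motif(consensus: str, concentration: float = 0.85,
                    name: str | None = None) -> Motif:
    """A motif putting ``concentration`` on each consensus base, rest uniform."""
    if not 0.25 < concentration < 1:
        raise SimulationSpecError("concentration must be in (0.25, 1)")
    index = {b: i for i, b in enumerate(ALPHABET)}
    off = (1.0 - concentration) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus.upper()):
        probs[i, index[base]] = concentration
    return Motif(probs=probs, name=name or f"consensus_{consensus.upper()}")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``planted_motifs`` pairs each motif with its linear weight on activity;
    a positive weight makes it an activator, a negative one a repressor.
    """

    n_sequences: int = 2000
    seq_length: int = 150
    background: BackgroundDistribution = DEFAULT_BACKGROUND
    planted_motifs: list[tuple[Motif, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    plant_probability: float = 1.0
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.seq_length < 1:
            raise SimulationSpecError("n_sequences and seq_length must be >= 1")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be non-negative")
        if not 0.0 <= self.plant_probability <= 1.0:
            raise SimulationSpecError("plant_probability must be in [0, 1]")
        for motif, _ in self.planted_motifs:
            if motif.length > self.seq_length:
                raise SimulationSpecError(
                    f"motif {motif.name!r} (length {motif.length}) exceeds "
                    f"seq_length {self.seq_length}"
                )


@dataclass(frozen=True)
class PlantRecord:
    sequence_id: str
    motif_name: str
    position: int
    strand: str


@dataclass
class GroundTruth:
    """Everything needed to score recovery of a simulation."""

    spec: SimulationSpec
    plants: list[PlantRecord]
    noiseless_activities: np.ndarray


def _llr_weights_from_motif(motif: Motif,
                            background: BackgroundDistribution) -> np.ndarray:
    # Floor zero probabilities so planted consensus-style motifs with exact
    # zeros still yield finite LLRs.
    probs = np.clip(motif.probs, 1e-9, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return np.log(probs) - background.log_probs[np.newaxis, :]


def max_llr_scores(onehot: np.ndarray, motif: Motif,
                   background: BackgroundDistribution = DEFAULT_BACKGROUND
                   ) -> np.ndarray:
    """Best LLR per sequence over all positions of both strands.

    ``onehot`` has shape (n, N, 4).
    """
    weights = _llr_weights_from_motif(motif, background)
    windows = np.lib.stride_tricks.sliding_window_view(
        onehot, motif.length, axis=1
    )  # (n, K, 4, L)
    fwd = np.einsum("bkjl,lj->bk", windows, weights)
    rev = np.einsum("bkjl,lj->bk", windows, weights[::-1, ::-1])
    return np.maximum(fwd.max(axis=1), rev.max(axis=1))


def _sample_site(rng: np.random.Generator, motif: Motif) -> np.ndarray:
    cumulative = motif.probs.cumsum(axis=1)
    draws = rng.random(motif.length)
    return (draws[:, np.newaxis] < cumulative).argmax(axis=1)


def generate(spec: SimulationSpec) -> tuple[MPRADataset, GroundTruth]:
    """Draw a dataset and its ground truth from ``spec``; seeded, deterministic."""
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_sequences, spec.seq_length
    codes = rng.choice(4, size=(n, length), p=spec.background.probs)
    width = len(str(n))
    ids = [f"sim{i:0{width}d}" for i in range(n)]
    plants: list[PlantRecord] = []

    for row in range(n):
        occupied: list[tuple[int, int]] = []
        for motif, _weight in spec.planted_motifs:
            if rng.random() >= spec.plant_probability:
                continue
            site = _sample_site(rng, motif)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = 3 - site[::-1]
            placed = False
            for _ in range(_PLACEMENT_RETRIES):
                start = int(rng.integers(0, length - motif.length + 1))
                stop = start + motif.length
                if all(stop <= a or start >= b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place motif {motif.name!r} in sequence {ids[row]} "
                    f"after {_PLACEMENT_RETRIES} tries"
                )
            codes[row, start:stop] = site
            occupied.append((start, stop))
            plants.append(PlantRecord(ids[row], motif.name, start, strand))

    onehot = np.eye(4)[codes]  # (n, N, 4)
    noiseless = np.full(n, spec.intercept, dtype=float)
    for motif, weight in spec.planted_motifs:
        noiseless += weight * max_llr_scores(onehot, motif, spec.background)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    activities = noiseless + noise

    bases = np.array(list(ALPHABET))
    sequences = ["".join(bases[c]) for c in codes]
    dataset = MPRADataset(sequences=sequences, activities=activities, ids=ids)
    truth = GroundTruth(spec=spec, plants=plants, noiseless_activities=noiseless)
    return dataset, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Tab-delimited plant table: sequence_id, motif_name, position, strand."""
    pd.DataFrame(
        [
            {
                "sequence_id": p.sequence_id,
                "motif_name": p.motif_name,
                "position": p.position,
                "strand": p.strand,
            }
            for p in truth.plants
        ],
        columns=["sequence_id", "motif_name", "position", "strand"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MotifMatch:
    """Best learned match for one true motif."""

    true_name: str
    learned_name: str
    correlation: float
    orientation: str  # "forward" or "reverse_complement"
    offset: int
    weight_sign_match: bool | None


def _best_alignment(
    true_probs: np.ndarray,
    learned_probs: np.ndarray,
    min_overlap: int | None = None,
) -> tuple[float, int]:
    """Max Pearson correlation of flattened probability rows over alignments.

    Overhanging alignments are allowed; at least ``min_overlap`` positions
    (default: half the shorter motif, minimum 3) must overlap, and the
    correlation is computed over the overlapping columns only.  ``offset`` is
    the position of the learned motif's first row relative to the true
    motif's (may be negative).  Returns ``(nan, 0)`` when no alignment has a
    defined correlation (e.g. an exactly uniform motif).
    """
    n_true, n_learned = true_probs.shape[0], learned_probs.shape[0]
    if min_overlap is None:
        min_overlap = max(3, min(n_true, n_learned) // 2)
    best, best_offset = float("nan"), 0
    for offset in range(-(n_learned - min_overlap), n_true - min_overlap + 1):
        lo, hi = max(0, offset), min(n_true, offset + n_learned)
        a = true_probs[lo:hi].ravel()
        b = learned_probs[lo - offset : hi - offset].ravel()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        corr = float(np.corrcoef(a, b)[0, 1])
        if not (corr <= best):  # also replaces the initial nan
            best, best_offset = corr, offset
    return best, best_offset


def recovery_report(
    truth: GroundTruth | Sequence[tuple[Motif, float]],
    learned_motifs: Sequence[Motif],
) -> list[MotifMatch]:
    """Score how well learned motifs recover each planted motif.

    Every (true, learned) pair is compared in both orientations and over all
    alignments; the best learned match per true motif is reported, along with
    whether the matched filter's dense-weight sign agrees with the true
    weight's sign.
    """
    planted = truth.spec.planted_motifs if isinstance(truth, GroundTruth) else truth
    if not planted or not learned_motifs:
        raise SimulationSpecError("need at least one true and one learned motif")
    matches = []
    for true_motif, true_weight in planted:
        best: MotifMatch | None = None
        for learned in learned_motifs:
            for orientation, probs in (
                ("forward", learned.probs),
                ("reverse_complement", learned.probs[::-1, ::-1]),
            ):
                corr, offset = _best_alignment(true_motif.probs, probs)
                if best is None or (
                    not np.isnan(corr)
                    and (np.isnan(best.correlation) or corr > best.correlation)
                ):
                    sign_match = None
                    if learned.dense_weight is not None:
                        sign_match = bool(
                            np.sign(learned.dense_weight) == np.sign(true_weight)
                        )
                    best = MotifMatch(
                        true_name=true_motif.name,
                        learned_name=learned.name,
                        correlation=corr,
                        orientation=orientation,
                        offset=offset,
                        weight_sign_match=sign_match,
                    )
        matches.append(best)
    return matches
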