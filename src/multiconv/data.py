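"""Activity datasets: paired equal-length sequences and real-valued activities."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlphabetError, DataError

__all__ = ["MPRADataset", "read_activity_table", "write_activity_table"]

_VALID = set("ACGTN")


@dataclass
class MPRADataset:
    """Equal-length DNA sequences with one real-valued activity per sequence."""

    sequences: list[str]
    activities: np.ndarray
    ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise DataError("dataset is empty")
        self.sequences = [s.upper() for s in self.sequences]
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 1 or len(self.activities) != len(self.sequences):
            raise DataError(
                f"{len(self.sequences)} sequences but "
                f"{self.activities.shape} activities"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DataError(f"sequences have unequal lengths: {sorted(lengths)}")
        for s in self.sequences:
            for pos, base in enumerate(s):
                if base not in _VALID:
                    raise AlphabetError(pos, base)
        if self.ids is None:
            width = len(str(len(self.sequences)))
            self.ids = [f"seq{i:0{width}d}" for i in range(len(self.sequences))]
        elif len(self.ids) != len(self.sequences):
            raise DataError("ids and sequences have different counts")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def sequence_length(self) -> int:
        return len(self.sequences[0])

    def subset(self, indices: Sequence[int]) -> "MPRADataset":
        indices = list(indices)
        return MPRADataset(
            sequences=[self.sequences[i] for i in indices],
            activities=self.activities[indices],
            ids=[self.ids[i] for i in indices],
        )


def read_activity_table(path: str | Path) -> MPRADataset:
    """Read a delimited text table with header columns id, sequence, activity.

    The delimiter (tab or comma) is sniffed by pandas.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "sequence", "activity"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"activity table missing columns: {sorted(missing)}")
    return MPRADataset(
        sequences=[str(s) for s in frame["sequence"]],
        activities=frame["activity"].to_numpy(dtype=float),
        ids=[str(i) for i in frame["id"]],
    )


def write_activity_table(dataset: MPRADataset, path: str | Path) -> None:
    """Write the dataset as a tab-delimited id/sequence/activity table."""
    frame = pd.DataFrame(
        {
            "id": dataset.ids,
            "sequence": dataset.sequences,
            "activity": dataset.activities,
        }
    )
    frame.to_csv(path, sep="\t", index=False)
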