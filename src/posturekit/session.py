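"""Session containers: 1 Hz time series of per-sample angle measurements."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Generic, Iterator, Sequence, TypeVar

import pandas as pd


class Quality(str, enum.Enum):
    """Per-sample completeness flag."""

    COMPLETE = "complete"
    PARTIAL = "partial"
    EMPTY = "empty"


S = TypeVar("S")


@dataclass
class SessionSeries(Generic[S]):
    """An ordered sequence of timestamped samples from one session.

    Samples are dataclasses with a ``t`` attribute in seconds from session
    start; the series preserves acquisition order and performs no
    interpolation across gaps.
    """

    samples: list[S] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[S]:
        return iter(self.samples)

    def __getitem__(self, i):
        return self.samples[i]

    @property
    def times(self) -> list[float]:
        return [s.t for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame with one row per sample; enums become strings."""
        rows = []
        for s in self.samples:
            row = {}
            for k, v in vars(s).items():
                row[k] = v.value if isinstance(v, enum.Enum) else v
            rows.append(row)
        return pd.DataFrame(rows)


def monotone_times(samples: Sequence) -> bool:
    ts = [s.t for s in samples]
    return all(b > a for a, b in zip(ts, ts[1:]))
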