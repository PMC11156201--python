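"""Windowed statistic tracks (pi, FST, external sweep scores)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "n_snps", "value"]


@dataclass
class WindowTrack:
    """Per-window statistic values over half-open [start, end) bp intervals.

    ``value`` is NaN where the statistic is undefined (e.g. too few SNPs).
    """

    windows: pd.DataFrame
    statistic: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.windows.columns]
        if missing:
            raise ValueError(f"WindowTrack missing columns: {missing}")
        self.windows = (
            self.windows.loc[:, COLUMNS]
            .sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def values(self) -> np.ndarray:
        return self.windows["value"].to_numpy(dtype=float)

    def keys(self) -> list[tuple]:
        return list(
            zip(self.windows["chrom"], self.windows["start"], self.windows["end"])
        )

    def to_tsv(self, path) -> None:
        df = self.windows.copy()
        df.insert(0, "statistic", self.statistic or ".")
        df.insert(1, "label", self.label or ".")
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, statistic: str = "", label: str = "") -> "WindowTrack":
        return cls(windows=df.reset_index(drop=True), statistic=statistic, label=label)
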