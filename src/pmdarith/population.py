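"""Binned spike-count container shared by all neural analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import task as task_mod


@dataclass
class BinnedPopulation:
    """Spike counts for a cell population, cells x trials x 100-ms bins.

    ``trials`` carries one row per trial (axis 1), including the derived
    factor labels; only labelled analyses subset on ``label_valid``. Bins
    span the concern period: 0-16 aligned to preoperational-numerosity
    onset, 17-23 to the Go signal.
    """

    counts: np.ndarray
    trials: pd.DataFrame
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_width_ms: int = 100
    alignment: str = "preop_onset|go_spliced"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be cells x trials x bins")
        if (self.counts < 0).any():
            raise ValueError("spike counts must be non-negative")
        if self.counts.shape[1] != len(self.trials):
            raise ValueError("trial table does not match counts axis 1")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.counts.shape[0])
        self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def rates(self) -> np.ndarray:
        """Firing rate per bin in spikes/s (count / bin width)."""
        return self.counts / (self.bin_width_ms / 1000.0)

    def subset_valid(self) -> "BinnedPopulation":
        """Restrict to trials with valid factor labels."""
        if "label_valid" not in self.trials.columns:
            raise ValueError("trials are not labelled; run task.label_trials first")
        keep = self.trials["label_valid"].to_numpy(dtype=bool)
        return BinnedPopulation(
            self.counts[:, keep, :],
            self.trials.loc[keep].reset_index(drop=True),
            cell_ids=self.cell_ids,
            bin_width_ms=self.bin_width_ms,
            alignment=self.alignment,
        )

    # -- external interface: HDF5 counts + CSV trial table ------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts.astype(np.int32))
            f.create_dataset("cell_ids", data=np.asarray(self.cell_ids, dtype=np.int64))
            f.attrs["bin_width_ms"] = self.bin_width_ms
            f.attrs["alignment"] = self.alignment
        task_mod.write_trials(self.trials, path.with_suffix(".trials.csv"))
        return path

    @classmethod
    def load(cls, path: str | Path, expected_bins: int | None = 24) -> "BinnedPopulation":
        path = Path(path)
        with h5py.File(path, "r") as f:
            counts = f["counts"][()]
            cell_ids = f["cell_ids"][()]
            bin_width = int(f.attrs["bin_width_ms"])
            alignment = str(f.attrs["alignment"])
        if expected_bins is not None and counts.shape[2] != expected_bins:
            raise ValueError(
                f"counts array has {counts.shape[2]} bins, expected {expected_bins}"
            )
        trials = task_mod.read_trials(path.with_suffix(".trials.csv"))
        trials = task_mod.label_trials(trials)
        return cls(counts, trials, cell_ids=cell_ids,
                   bin_width_ms=bin_width, alignment=alignment)
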