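"""In-memory containers shared across the pipeline, with HDF5/CSV round-trips.

All containers are thin dataclasses over numpy arrays plus pandas metadata;
the time axis is always in milliseconds relative to stimulus onset and
strictly increasing on a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

_METADATA_COLUMNS = ("condition_id", "subject_id", "run_id")


def _check_times(times: np.ndarray) -> None:
    steps = np.diff(times)
    if len(times) > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
        raise ValueError("time axis must be strictly increasing and regular")


@dataclass
class EpochSet:
    """Epoched sensor data: trials x channels x time, in femtotesla.

    ``metadata`` has one row per trial with at least ``condition_id``,
    ``subject_id`` and ``run_id``; extra columns (e.g. artifact flags) are
    carried along untouched.
    """

    data: np.ndarray
    times: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length does not match data")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length does not match trial count")
        for col in _METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        _check_times(self.times)
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_step_ms(self) -> float:
        return float(self.times[1] - self.times[0])

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.metadata.copy())

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, self.metadata.loc[mask])

    def check_against_design(self, design) -> None:
        known = set(design.condition_ids)
        present = set(self.metadata["condition_id"])
        if not present <= known:
            raise ValueError(f"metadata contains unknown condition ids {sorted(present - known)}")

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("times", data=self.times)
            md = f.create_group("metadata")
            for col in self.metadata.columns:
                values = self.metadata[col].to_numpy()
                if values.dtype == object:
                    values = values.astype("S")
                md.create_dataset(col, data=values)

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            times = f["times"][...]
            cols = {}
            for col, ds in f["metadata"].items():
                values = ds[...]
                if values.dtype.kind == "S":
                    values = values.astype(str)
                cols[col] = values
        return cls(data, times, pd.DataFrame(cols))

    @classmethod
    def from_fif(cls, path, subject_id: int = 1) -> "EpochSet":
        """Import epochs from an MNE FIF file (optional; requires mne)."""
        import mne  # local import: optional dependency

        epochs = mne.read_epochs(path, preload=True, verbose="error")
        data = epochs.get_data() * 1e15  # T -> fT
        times = epochs.times * 1e3  # s -> ms
        metadata = pd.DataFrame(
            {
                "condition_id": epochs.events[:, 2],
                "subject_id": subject_id,
                "run_id": 1,
            }
        )
        return cls(data, times, metadata)


@dataclass
class RDMSeries:
    """Time-resolved representational dissimilarity matrices for one subject.

    ``accuracies`` is time x condition x condition in percent correct,
    symmetric with NaN on the diagonal (pairwise decoding of a condition
    with itself is undefined).
    """

    accuracies: np.ndarray
    times: np.ndarray
    condition_ids: np.ndarray
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        t, c1, c2 = self.accuracies.shape
        if c1 != c2 or c1 != len(self.condition_ids) or t != len(self.times):
            raise ValueError("accuracies must be time x condition x condition")
        _check_times(self.times)

    @property
    def n_conditions(self) -> int:
        return self.accuracies.shape[1]

    def lower_triangle(self) -> np.ndarray:
        """time x n_pairs matrix of the strictly lower triangle."""
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.accuracies[:, i, j]

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("accuracies", data=self.accuracies, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.create_dataset("condition_ids", data=np.asarray(self.condition_ids, dtype=np.int64))
            f.attrs["subject_id"] = self.subject_id

    @classmethod
    def load_h5(cls, path) -> "RDMSeries":
        with h5py.File(path, "r") as f:
            return cls(
                f["accuracies"][...],
                f["times"][...],
                f["condition_ids"][...],
                int(f.attrs.get("subject_id", 0)),
            )


@dataclass
class GroupTimeCourse:
    """Per-subject statistic over time: subjects x time.

    ``chance`` is the null reference value of the statistic (50 for percent
    decoding accuracy, 0 for accuracy differences and correlations).
    """

    values: np.ndarray
    times: np.ndarray
    subject_ids: np.ndarray
    label: str = ""
    chance: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.times = np.asarray(self.times, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.shape != (len(self.subject_ids), len(self.times)):
            raise ValueError("values must be subjects x time")
        _check_times(self.times)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def group_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (subject, time)."""
        subj = np.repeat(self.subject_ids, len(self.times))
        time = np.tile(self.times, self.n_subjects)
        return pd.DataFrame({"subject": subj, "time_ms": time, "value": self.values.ravel()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "", chance: float = 0.0) -> "GroupTimeCourse":
        wide = frame.pivot(index="subject", columns="time_ms", values="value")
        return cls(
            values=wide.to_numpy(),
            times=wide.columns.to_numpy(dtype=float),
            subject_ids=wide.index.to_numpy(),
            label=label,
            chance=chance,
        )

    @classmethod
    def stack(cls, courses: list, label: str = "", chance: float | None = None) -> "GroupTimeCourse":
        """Stack single-subject courses (1 x T each) into a group course."""
        if not courses:
            raise ValueError("no time courses to stack")
        times = courses[0].times
        values = np.vstack([c.values for c in courses])
        subject_ids = np.concatenate([c.subject_ids for c in courses])
        return cls(
            values=values,
            times=times,
            subject_ids=subject_ids,
            label=label or courses[0].label,
            chance=courses[0].chance if chance is None else chance,
        )

    def with_values(self, values: np.ndarray) -> "GroupTimeCourse":
        return replace(self, values=values)
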