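"""Time-series concentration datasets.

A :class:`TimeSeriesDataset` is a (species x time) matrix of observed
concentrations with NaN marking missing values.  It is the source of the
fitting loss and of initial conditions at the earliest observed time.
CSV layout: first column ``time``, remaining columns one per species;
empty cells are missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import KinfitError, ZeroMeanSpeciesError

__all__ = ["TimeSeriesDataset"]


@dataclass
class TimeSeriesDataset:
    times: np.ndarray  # shape (T,), ascending
    species: list[str]
    values: np.ndarray  # shape (n_species, T), NaN = missing
    name: str = "dataset"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise KinfitError("times must be one-dimensional")
        if self.values.shape != (len(self.species), self.times.size):
            raise KinfitError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.species)} species, {self.times.size} times)"
            )
        if np.any(np.diff(self.times) < 0):
            raise KinfitError("times must be ascending")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            empty = [s for s, row in zip(self.species, self.values) if np.all(np.isnan(row))]
            raise KinfitError(f"species with no observations: {empty}")

    # ------------------------------------------------------------------ stats
    @property
    def n_observations(self) -> int:
        """Count of non-missing (species, time) pairs."""
        return int(np.sum(~np.isnan(self.values)))

    def species_means(self, check_nonzero: bool = True) -> np.ndarray:
        """Per-species mean over non-missing observations (the loss scale)."""
        means = np.nanmean(self.values, axis=1)
        if check_nonzero and np.any(means == 0):
            zero = [s for s, m in zip(self.species, means) if m == 0]
            raise ZeroMeanSpeciesError(f"zero-mean-species: {zero}")
        return means

    @property
    def t0(self) -> float:
        return float(self.times[0])

    def first_observation(self, species_id: str) -> float:
        """Value at the earliest time, NaN if missing or species absent."""
        if species_id not in self.species:
            return np.nan
        return float(self.values[self.species.index(species_id), 0])

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_column: str = "time", name: str = "dataset"):
        df = df.sort_values(time_column)
        species = [c for c in df.columns if c != time_column]
        return cls(
            times=df[time_column].to_numpy(float),
            species=species,
            values=df[species].to_numpy(float).T,
            name=name,
        )

    @classmethod
    def from_csv(cls, path, time_column: str = "time"):
        return cls.from_dataframe(pd.read_csv(path), time_column=time_column, name=str(path))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def restrict_to(self, species_ids) -> "TimeSeriesDataset":
        """Dataset restricted to the given species (e.g. model observables)."""
        keep = [s for s in self.species if s in set(species_ids)]
        idx = [self.species.index(s) for s in keep]
        return TimeSeriesDataset(
            times=self.times.copy(), species=keep, values=self.values[idx], name=self.name
        )
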