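"""Per-species time series shared by the ABM output and the ODE twin."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import N_A


@dataclass
class CountsTimeSeries:
    """Species amounts on a time grid, in counts or mol L^-1.

    ``values`` is (n_times, n_species) in the unit given by ``unit``;
    ``volume`` (m^3) converts between the two representations.
    """

    times: np.ndarray
    values: np.ndarray
    species: list[str]
    volume: float
    unit: str = "counts"  # "counts" | "molar"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values)
        if self.values.shape != (self.times.size, len(self.species)):
            raise ValueError("values shape inconsistent with times and species")
        if self.unit not in ("counts", "molar"):
            raise ValueError("unit must be 'counts' or 'molar'")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def to_molar(self) -> "CountsTimeSeries":
        if self.unit == "molar":
            return self
        conc = self.values / (1e3 * N_A * self.volume)
        return CountsTimeSeries(self.times, conc, self.species, self.volume, "molar")

    def to_counts(self) -> "CountsTimeSeries":
        if self.unit == "counts":
            return self
        n = self.values * (1e3 * N_A * self.volume)
        return CountsTimeSeries(self.times, n, self.species, self.volume, "counts")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time_s", self.times)
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, volume: float, unit: str = "counts"):
        df = pd.read_csv(path)
        times = df.pop("time_s").to_numpy()
        return cls(times, df.to_numpy(), list(df.columns), volume, unit)
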