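"""Time-stamped collective-variable samples — the currency between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class CVSeries:
    """One or more named coordinate time series at a fixed temperature.

    Attributes
    ----------
    times : ndarray, shape (n,)
        Frame times in ps, strictly increasing.
    values : ndarray, shape (n, k)
        One row per frame, one column per named coordinate (Å or
        composite-CV units).
    labels : list of str
        Coordinate names, one per column.
    temperature : float
        Sampling temperature in K.
    """

    times: np.ndarray
    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not self.labels:
            self.labels = [f"cv{i}" for i in range(self.values.shape[1])]
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValidationError(
                f"{self.values.shape[0]} value rows for {self.times.shape[0]} times"
            )
        if len(self.labels) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValidationError("non-finite entries in CVSeries")
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")

    def __len__(self) -> int:
        return self.times.shape[0]

    def column(self, label: str) -> np.ndarray:
        """Return the series for one named coordinate."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"no coordinate {label!r}; available: {self.labels}"
            ) from None
        return self.values[:, j]

    def select(self, mask_or_slice) -> "CVSeries":
        return CVSeries(
            times=self.times[mask_or_slice],
            values=self.values[mask_or_slice],
            labels=list(self.labels),
            temperature=self.temperature,
        )


def concatenate(series_list: list[CVSeries]) -> tuple[np.ndarray, list[str], float]:
    """Pool values from several series sharing labels and temperature.

    Returns (values, labels, temperature); times are not meaningful for a pool.
    """
    if not series_list:
        raise ValidationError("nothing to concatenate")
    first = series_list[0]
    for s in series_list[1:]:
        if s.labels != first.labels:
            raise ValidationError(f"label mismatch: {s.labels} vs {first.labels}")
        if s.temperature != first.temperature:
            raise ValidationError("temperature mismatch between pooled series")
    values = np.concatenate([s.values for s in series_list], axis=0)
    return values, list(first.labels), first.temperature
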