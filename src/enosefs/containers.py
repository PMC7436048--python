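"""In-memory containers shared across modules: feature tables and sensor recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureTable:
    """Samples x features matrix with integer class labels.

    Parameters
    ----------
    values
        2-D float array, one row per sample.
    labels
        1-D integer class labels, aligned with rows of ``values``.
    feature_names
        Unique column names encoding (sensor, feature type, parameter).
    informative_mask
        Optional {0,1} vector marking columns that derive from sensors whose
        response actually depends on the class (synthetic ground truth only).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=int)
            if self.informative_mask.shape[0] != self.values.shape[1]:
                raise ValueError("informative_mask length must match number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
            informative_mask=None if self.informative_mask is None else self.informative_mask.copy(),
        )


@dataclass
class SensorRecording:
    """Multi-channel gas-sensor response time series for one sample.

    ``times`` is strictly increasing in seconds; ``channels`` holds one row per
    sensor.  The baseline window precedes gas onset and supplies the reference
    level subtracted before curve features are computed.
    """

    times: np.ndarray
    channels: np.ndarray
    gas_on: float
    gas_off: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("times must be 1-D with at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.channels.shape[1] != self.times.size:
            raise ValueError("channels must have one column per time point")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("recording contains missing or non-finite values")
        t0, t1 = self.baseline_window
        if not (t0 < t1 <= self.gas_on < self.gas_off <= self.times[-1]):
            raise ValueError(
                "require baseline_start < baseline_end <= gas_on < gas_off <= last time"
            )

    @property
    def n_sensors(self) -> int:
        return self.channels.shape[0]
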