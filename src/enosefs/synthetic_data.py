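"""Synthetic e-nose recordings and feature tables with known informative structure.

The response model is the simplest family that reproduces the
rise/plateau/decay morphology of metal-oxide gas-sensor curves: from gas
onset a saturating exponential climbs toward a class- and sensor-specific
plateau amplitude, after gas-off the excess response decays exponentially,
and i.i.d. Gaussian noise rides on every sample.  It is a test harness, not a
claim about real sensor physics: no drift, no humidity/temperature
covariates, no sensor-specific kinetics.

Two noise sources act on every recording.  Additive white noise perturbs each
time point; on its own it is nearly averaged out by integrating features, so
it mostly affects point-wise descriptors.  Multiplicative gain jitter — a
per-recording, per-sensor random rescaling of the plateau amplitude — models
the sample-to-sample response variability of metal-oxide sensors and puts a
common noise floor under every amplitude-derived feature of a sensor: no
single column can separate the classes, and reliable classification requires
pooling several informative sensors, as with a real cross-sensitive array.

Informative sensors have class-separated plateau amplitudes; the remaining
sensors share one amplitude across classes, so every feature column derived
from them is class-independent by construction.  The ground-truth informative
mask is propagated to the extracted feature table.

``make_reference_benchmark`` builds the canonical evaluation instance used
throughout the test-suite and examples: 4 classes x 40 samples, 8 sensors of
which 3 are informative, curve features with 9 interval values -> 128
columns, and a noise level calibrated once so that full-feature 5-NN test
error lands near 0.2 — enough headroom for feature selection to matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureTable, SensorRecording
from .feature_extraction import build_feature_table
from .fitness import DataSplit, make_split


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator; defaults define the reference benchmark."""

    n_classes: int = 4
    n_sensors: int = 8
    n_informative_sensors: int = 3
    samples_per_class: int = 40
    baseline_level: float = 10.0
    class_sep: float = 0.20
    gain_jitter_sd: float = 0.07
    noise_sd: float = 0.15
    tau_rise: float = 8.0
    tau_decay: float = 12.0
    sampling_rate: float = 2.0
    gas_on: float = 20.0
    gas_off: float = 80.0
    duration: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_sensors > self.n_sensors:
            raise ValueError("n_informative_sensors cannot exceed n_sensors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def amplitudes(self) -> np.ndarray:
        """Plateau amplitude A[class, sensor].

        Informative sensors: a sensor-specific base scaled by a relative
        class step of ``class_sep`` per class (all informative sensors
        respond in the same direction — partial redundancy, as in real
        cross-sensitive arrays).  Non-informative sensors: one shared
        amplitude, identical across classes.
        """
        amp = np.full((self.n_classes, self.n_sensors), 2.5)
        for s in range(self.n_informative_sensors):
            base = 2.0 + 0.8 * s
            for c in range(self.n_classes):
                amp[c, s] = base * (1.0 + self.class_sep * c)
        return amp


def simulate_recording(
    class_label: int, config: SimulationConfig, rng: np.random.Generator
) -> SensorRecording:
    """One multi-channel recording: exponential rise, plateau, exponential decay + noise.

    Per-sensor multiplicative gain jitter is drawn once per recording; additive
    white noise is drawn per time point.
    """
    n_pts = int(round(config.duration * config.sampling_rate)) + 1
    times = np.arange(n_pts) / config.sampling_rate
    amp = config.amplitudes()[class_label]
    if config.gain_jitter_sd > 0:
        amp = amp * (1.0 + rng.normal(0.0, config.gain_jitter_sd, amp.shape))
    rise = np.where(
        times >= config.gas_on, 1.0 - np.exp(-(times - config.gas_on) / config.tau_rise), 0.0
    )
    plateau = 1.0 - np.exp(-(config.gas_off - config.gas_on) / config.tau_rise)
    decay = plateau * np.exp(-(times - config.gas_off) / config.tau_decay)
    shape = np.where(times <= config.gas_off, rise, decay)
    channels = config.baseline_level + amp[:, None] * shape[None, :]
    if config.noise_sd > 0:
        channels = channels + rng.normal(0.0, config.noise_sd, channels.shape)
    return SensorRecording(
        times=times,
        channels=channels,
        gas_on=config.gas_on,
        gas_off=config.gas_off,
        baseline_window=(2.0, config.gas_on * 0.9),
    )


def simulate_recordings(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SensorRecording], np.ndarray]:
    """All recordings of the study: samples_per_class per class, class-major order."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    recordings, labels = [], []
    for c in range(config.n_classes):
        for _ in range(config.samples_per_class):
            recordings.append(simulate_recording(c, config, rng))
            labels.append(c)
    return recordings, np.array(labels)


def make_feature_dataset(
    config: SimulationConfig, scheme: str = "curve", n_interval_values: int = 10
) -> FeatureTable:
    """Simulate recordings and extract features; informative_mask marks columns
    deriving from the class-separated sensors.  Deterministic under config.seed."""
    recordings, labels = simulate_recordings(config)
    informative = np.zeros(config.n_sensors, dtype=bool)
    informative[: config.n_informative_sensors] = True
    return build_feature_table(
        recordings, labels, scheme=scheme,
        n_interval_values=n_interval_values, informative_sensors=informative,
    )


def make_reference_benchmark(seed: int = 0) -> DataSplit:
    """The canonical 128-feature benchmark split (see module docstring)."""
    config = SimulationConfig(seed=seed)
    table = make_feature_dataset(config, scheme="curve", n_interval_values=9)
    return make_split(table, split_fraction=0.7, seed=seed)


def make_tabular_dataset(
    n_samples: int = 60,
    n_features: int = 10,
    n_informative: int = 3,
    n_classes: int = 3,
    class_sep: float = 1.5,
    seed: int = 0,
) -> FeatureTable:
    """Plain Gaussian feature table for small exact-enumeration studies.

    Informative columns have class-dependent means (class index times
    class_sep, scaled per column); the rest are standard-normal noise.
    """
    rng = np.random.default_rng(seed)
    labels = np.arange(n_samples) % n_classes
    values = rng.normal(size=(n_samples, n_features))
    for j in range(n_informative):
        scale = 1.0 - 0.2 * (j % 3)
        values[:, j] += class_sep * scale * labels
    mask = np.zeros(n_features, dtype=int)
    mask[:n_informative] = 1
    return FeatureTable(values, labels, informative_mask=mask)
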