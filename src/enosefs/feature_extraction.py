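"""Turn raw gas-sensor response curves into feature tables.

Two extraction schemes are provided, matching the two styles of e-nose
feature engineering:

``transient``
    Eight features per sensor: the maximal absolute resistance change from
    baseline (dR) and its baseline-normalized version, plus — for each of
    three smoothing constants alpha in (0.1, 0.01, 0.001) — the maximum of an
    exponential-moving-average of the response increments over the exposure
    (rising) window and its minimum over the post-exposure (decaying) window.

``curve``
    Per sensor: max response above baseline; max and min first derivative;
    the times (from gas onset, first-crossing, linearly interpolated) at
    which the response reaches 30/60/90% of its max; the trapezoidal integral
    of (response - baseline) over the exposure window; and n equally
    time-spaced response values across the exposure window (default 10,
    giving 17 features; n = 9 yields the classical 16-features-per-sensor
    layout).

The baseline is the mean response over the recording's baseline window.  If a
threshold is never reached its time constant saturates at the window length;
a zero baseline makes the normalized dR fall back to dR (both logged).

File formats: long-format recording CSV (sample_id, sensor_id, time_s,
response) with a metadata CSV (sample_id, label, gas_on, gas_off,
baseline_start, baseline_end); wide feature CSV with a ``label`` column; and
a sparse "label index:value" text format with 1-based feature indices,
compatible with the UCI gas-sensor-array-drift archive layout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import FeatureTable, SensorRecording

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.1, 0.01, 0.001)


def ema_transient(response: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average of response increments.

    y[0] = 0; y[k] = (1-alpha)*y[k-1] + alpha*(R[k]-R[k-1]).  alpha = 1
    collapses to the raw first difference; a constant series maps to zeros.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    response = np.asarray(response, dtype=float)
    if response.size < 2:
        raise ValueError("series must have at least 2 points")
    y = np.empty_like(response)
    y[0] = 0.0
    dr = np.diff(response)
    for k in range(1, response.size):
        y[k] = (1.0 - alpha) * y[k - 1] + alpha * dr[k - 1]
    return y


def _baseline(rec: SensorRecording) -> np.ndarray:
    t0, t1 = rec.baseline_window
    sel = (rec.times >= t0) & (rec.times <= t1)
    return rec.channels[:, sel].mean(axis=1)


def transient_feature_names(n_sensors: int, alphas=DEFAULT_ALPHAS) -> list[str]:
    names = []
    for s in range(n_sensors):
        names += [f"s{s}_dR", f"s{s}_dR_norm"]
        for a in alphas:
            names += [f"s{s}_ema_rise_a{a}", f"s{s}_ema_decay_a{a}"]
    return names


def extract_transient_features(
    rec: SensorRecording, alphas=DEFAULT_ALPHAS, signed: bool = False
) -> np.ndarray:
    """dR, normalized dR, and EMA rise/decay extrema: 2 + 2*len(alphas) per channel.

    ``signed=False`` (default) takes dR as the max absolute deviation from
    baseline over the exposure window; ``signed=True`` takes the signed
    deviation of largest magnitude.
    """
    base = _baseline(rec)
    expo = (rec.times >= rec.gas_on) & (rec.times <= rec.gas_off)
    decay = rec.times > rec.gas_off
    feats = []
    for s in range(rec.n_sensors):
        x = rec.channels[s]
        dev = x[expo] - base[s]
        if signed:
            dr = float(dev[np.abs(dev).argmax()])
        else:
            dr = float(np.abs(dev).max())
        if base[s] != 0.0:
            dr_norm = dr / base[s]
        else:
            logger.warning("zero baseline on sensor %d; dR_norm falls back to dR", s)
            dr_norm = dr
        feats += [dr, dr_norm]
        for a in alphas:
            y = ema_transient(x, a)
            rise = float(y[expo].max())
            fall = float(y[decay].min()) if decay.any() else 0.0
            feats += [rise, fall]
    return np.array(feats)


def curve_feature_names(n_sensors: int, n_interval_values: int = 10) -> list[str]:
    names = []
    for s in range(n_sensors):
        names += [f"s{s}_max_resp", f"s{s}_deriv_max", f"s{s}_deriv_min",
                  f"s{s}_t30", f"s{s}_t60", f"s{s}_t90", f"s{s}_integral"]
        names += [f"s{s}_iv{i}" for i in range(n_interval_values)]
    return names


def _first_crossing(times: np.ndarray, x: np.ndarray, thr: float,
                    t_start: float, t_end: float) -> float:
    """Time after t_start at which x first reaches thr (linear interpolation).

    Saturates at t_end - t_start when the threshold is never reached.
    """
    sel = (times >= t_start) & (times <= t_end)
    tt, xx = times[sel], x[sel]
    above = xx >= thr
    if not above.any():
        return t_end - t_start
    i = int(above.argmax())
    if i == 0 or xx[i] == xx[i - 1]:
        return float(tt[i] - t_start)
    frac = (thr - xx[i - 1]) / (xx[i] - xx[i - 1])
    return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]) - t_start)


def extract_curve_features(rec: SensorRecording, n_interval_values: int = 10) -> np.ndarray:
    """Curve-descriptor block per channel; see the module docstring for the layout."""
    base = _baseline(rec)
    expo = (rec.times >= rec.gas_on) & (rec.times <= rec.gas_off)
    if expo.sum() < n_interval_values:
        raise ValueError("gas window holds fewer samples than n_interval_values")
    feats = []
    window = rec.gas_off - rec.gas_on
    # integration grid: exact window endpoints plus every interior sample
    inner = rec.times[(rec.times > rec.gas_on) & (rec.times < rec.gas_off)]
    grid = np.concatenate(([rec.gas_on], inner, [rec.gas_off]))
    iv_times = np.linspace(rec.gas_on, rec.gas_off, n_interval_values)
    for s in range(rec.n_sensors):
        x = rec.channels[s] - base[s]
        max_resp = float(x[expo].max())
        deriv = np.gradient(rec.channels[s], rec.times)
        tcs = [
            _first_crossing(rec.times, x, frac * max_resp, rec.gas_on, rec.gas_off)
            if max_resp > 0 else window
            for frac in (0.3, 0.6, 0.9)
        ]
        if max_resp <= 0:
            logger.info("sensor %d never rises above baseline; time constants saturate", s)
        integral = float(np.trapezoid(np.interp(grid, rec.times, x), grid))
        ivals = np.interp(iv_times, rec.times, x)
        feats += [max_resp, float(deriv.max()), float(deriv.min()), *tcs, integral, *ivals]
    return np.array(feats)


def build_feature_table(
    recordings: list[SensorRecording],
    labels,
    scheme: str = "curve",
    n_interval_values: int = 10,
    alphas=DEFAULT_ALPHAS,
    informative_sensors: np.ndarray | None = None,
) -> FeatureTable:
    """Stack per-recording feature vectors into a table, sensor-major column order.

    ``informative_sensors`` (boolean per sensor) propagates a ground-truth
    informative mask to the derived columns.
    """
    if scheme not in ("curve", "transient"):
        raise ValueError("scheme must be 'curve' or 'transient'")
    n_sensors = recordings[0].n_sensors
    if any(r.n_sensors != n_sensors for r in recordings):
        raise ValueError("recordings must have identical channel counts")
    if scheme == "curve":
        rows = [extract_curve_features(r, n_interval_values) for r in recordings]
        names = curve_feature_names(n_sensors, n_interval_values)
        per_sensor = 7 + n_interval_values
    else:
        rows = [extract_transient_features(r, alphas) for r in recordings]
        names = transient_feature_names(n_sensors, alphas)
        per_sensor = 2 + 2 * len(alphas)
    mask = None
    if informative_sensors is not None:
        mask = np.repeat(np.asarray(informative_sensors, dtype=int), per_sensor)
    return FeatureTable(np.array(rows), np.asarray(labels, dtype=int), names, mask)


# ---------------------------------------------------------------------------
# file formats


def write_recordings_csv(
    recordings: list[SensorRecording], labels, data_path, meta_path
) -> None:
    frames, meta = [], []
    for sid, (rec, lab) in enumerate(zip(recordings, labels)):
        for s in range(rec.n_sensors):
            frames.append(pd.DataFrame({
                "sample_id": sid, "sensor_id": s,
                "time_s": rec.times, "response": rec.channels[s],
            }))
        meta.append({
            "sample_id": sid, "label": int(lab),
            "gas_on": rec.gas_on, "gas_off": rec.gas_off,
            "baseline_start": rec.baseline_window[0],
            "baseline_end": rec.baseline_window[1],
        })
    pd.concat(frames, ignore_index=True).to_csv(data_path, index=False)
    pd.DataFrame(meta).to_csv(meta_path, index=False)


def read_recordings_csv(data_path, meta_path) -> tuple[list[SensorRecording], np.ndarray]:
    data = pd.read_csv(data_path)
    meta = pd.read_csv(meta_path).set_index("sample_id")
    recordings, labels = [], []
    for sid, grp in data.groupby("sample_id", sort=True):
        m = meta.loc[sid]
        channels = []
        times = None
        for _, ch in grp.groupby("sensor_id", sort=True):
            ch = ch.sort_values("time_s")
            times = ch["time_s"].to_numpy()
            channels.append(ch["response"].to_numpy())
        recordings.append(SensorRecording(
            times=times, channels=np.array(channels),
            gas_on=float(m["gas_on"]), gas_off=float(m["gas_off"]),
            baseline_window=(float(m["baseline_start"]), float(m["baseline_end"])),
        ))
        labels.append(int(m["label"]))
    return recordings, np.array(labels)


def write_feature_csv(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "label", table.labels)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return FeatureTable(df.to_numpy(float), labels, list(df.columns))


def write_sparse(table: FeatureTable, path) -> None:
    """UCI-drift-style lines: ``label idx:value ...`` with 1-based indices."""
    with open(path, "w") as fh:
        for row, lab in zip(table.values, table.labels):
            toks = [str(int(lab))] + [
                f"{j + 1}:{v:.17g}" for j, v in enumerate(row) if v != 0.0
            ]
            fh.write(" ".join(toks) + "\n")


def read_sparse(path, n_features: int | None = None) -> FeatureTable:
    rows, labels = [], []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            labels.append(int(float(toks[0])))
            rows.append({int(t.split(":")[0]): float(t.split(":")[1]) for t in toks[1:]})
    width = n_features or max((max(r) for r in rows if r), default=0)
    values = np.zeros((len(rows), width))
    for i, r in enumerate(rows):
        for j, v in r.items():
            values[i, j - 1] = v
    return FeatureTable(values, np.array(labels))
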