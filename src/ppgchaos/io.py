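"""Record readers/writers and the pipeline configuration.

Records travel as plain columnar CSV with header ``t,ppg[,abp][,co]`` at a
fixed sampling rate, with an optional JSON metadata sidecar
(``<record>.meta.json`` holding subject_id, fs, age, sex, height, weight).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import ComplexityConfig
from .irasa import DEFAULT_BAND, DEFAULT_HSET
from .preprocess import VitalRecord

logger = logging.getLogger("ppgchaos")

__all__ = ["PipelineConfig", "read_record", "write_record"]


@dataclass
class PipelineConfig:
    """Defaults mirror the analysis conventions: 50 Hz sampling, 100 s
    windows with a 5 s hop, IRASA band 0.5-10 Hz, Higuchi k_max 10,
    embedding dimension 4, Granger alpha 0.05 with a 50 s lag cap."""

    fs: float = 50.0
    window_s: float = 100.0
    hop_s: float = 5.0
    beats_per_window: int = 100
    band: tuple[float, float] = DEFAULT_BAND
    hset: tuple[float, ...] = DEFAULT_HSET
    complexity: ComplexityConfig = field(default_factory=ComplexityConfig)
    measures: tuple[str, ...] = ("HFD", "KFD", "LF_HF")
    granger_alpha: float = 0.05
    granger_max_lag_s: float = 50.0
    group_labels: dict = field(default_factory=dict)  # subject_id -> group
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "complexity" in d and isinstance(d["complexity"], dict):
            d["complexity"] = ComplexityConfig(**d["complexity"])
        for key in ("band", "hset", "measures"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def read_record(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
) -> VitalRecord:
    """Read a CSV record (columns t, ppg and optionally abp, co).

    The sampling rate is taken from the metadata sidecar or ``fs`` and
    validated against the t column spacing (<= 1% deviation); non-monotone t
    or NaN runs longer than 1 s are errors, shorter gaps are bridged by
    linear interpolation and logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "ppg" not in df.columns:
        raise ValueError(f"{path}: missing required column 'ppg'")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fs is None:
        fs = meta.get("fs")
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        dt_med = float(np.median(dt))
        if fs is None:
            fs = 1.0 / dt_med
        elif abs(1.0 / fs - dt_med) > 0.01 * dt_med:
            raise ValueError(
                f"{path}: fs={fs} inconsistent with t spacing {dt_med:.6g}s"
            )
    if fs is None:
        raise ValueError(f"{path}: sampling rate unknown (no t column, no fs)")

    channels = {}
    for col in ("ppg", "abp", "co"):
        if col not in df.columns:
            continue
        x = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(x)
        if bad.any():
            run = _longest_run(bad)
            if run > fs:
                raise ValueError(
                    f"{path}: NaN gap of {run / fs:.2f}s in column {col!r}"
                )
            idx = np.arange(len(x))
            x = x.copy()
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
            logger.info("%s: bridged %d NaN samples in %s", path.name, bad.sum(), col)
        channels[col] = x
    sid = subject_id or meta.get("subject_id") or path.stem
    return VitalRecord(
        subject_id=sid, fs=float(fs), ppg=channels["ppg"],
        abp=channels.get("abp"), co=channels.get("co"), meta=meta,
    )


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[0::2]).max())


def write_record(record: VitalRecord, path: str | Path) -> Path:
    """Write a record to CSV plus a JSON metadata sidecar."""
    path = Path(path)
    n = len(record.ppg)
    data = {"t": np.arange(n) / record.fs, "ppg": record.ppg}
    if record.abp is not None:
        data["abp"] = record.abp
    if record.co is not None:
        data["co"] = record.co
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(record.meta)
    meta.update({"subject_id": record.subject_id, "fs": record.fs})
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
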