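"""Canonical recording container and flat-file round trip.

A recording is a synchronized multi-channel session: per-eye pupil size
with per-sample validity flags, plus an airflow channel, on a common
millisecond time base.  The canonical on-disk layout is a UTF-8 CSV with
columns ``time_ms, pupil_left, pupil_right, valid_left, valid_right,
airflow``; session metadata (participant, route, unit, sampling rate)
lives in a JSON sidecar next to the CSV.  Results tables are TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = (
    "time_ms",
    "pupil_left",
    "pupil_right",
    "valid_left",
    "valid_right",
    "airflow",
)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class FormatError(ValueError):
    """File content violates the recording invariants."""


@dataclass
class Recording:
    """One session of synchronized pupil + airflow data.

    Validity flags are authoritative: the numeric content of a sample
    flagged invalid is never used downstream.  Missing numeric cells are
    NaN with the validity flag forced to False.
    """

    participant_id: str
    session_id: str
    route: str  # "nose" | "mouth" | "n/a"
    sampling_rate: float
    time_ms: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    airflow: np.ndarray
    unit: str = "px"  # "px" | "mm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for name in ("pupil_left", "pupil_right", "valid_left", "valid_right", "airflow"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"channel {name!r} has length {len(getattr(self, name))}, expected {n}")
        if n < 2:
            raise FormatError("a recording needs at least 2 samples")
        if not np.all(np.diff(self.time_ms) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.route not in ("nose", "mouth", "n/a"):
            raise SchemaError(f"unknown breathing route {self.route!r}")
        if self.unit not in ("px", "mm"):
            raise SchemaError(f"unknown pupil unit {self.unit!r}")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        spacing = float(np.median(np.diff(self.time_ms)))
        if abs(spacing - 1000.0 / self.sampling_rate) > 0.01 * (1000.0 / self.sampling_rate):
            raise FormatError(
                f"median timestamp spacing {spacing:.3f} ms inconsistent with "
                f"sampling_rate {self.sampling_rate} Hz"
            )
        # validity is authoritative: a non-finite cell can never be valid
        for pupil, valid in ((self.pupil_left, self.valid_left), (self.pupil_right, self.valid_right)):
            valid[~np.isfinite(pupil)] = False

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def duration_s(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0]) / 1000.0


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_recording(path: str | Path, schema: dict[str, str] | None = None) -> Recording:
    """Read a canonical recording CSV (+ JSON sidecar, if present).

    Parameters
    ----------
    path
        CSV file with the canonical columns.
    schema
        Optional map from canonical column name to the column name used
        in the file, for files exported under different headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rename = {v: k for k, v in (schema or {}).items()}
    df = pd.read_csv(path)
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    time_ms = df["time_ms"].to_numpy(dtype=float)
    rate = float(meta.get("sampling_rate", 1000.0 / np.median(np.diff(time_ms))))
    return Recording(
        participant_id=str(meta.get("participant_id", path.stem)),
        session_id=str(meta.get("session_id", path.stem)),
        route=str(meta.get("route", "n/a")),
        sampling_rate=rate,
        time_ms=time_ms,
        pupil_left=df["pupil_left"].to_numpy(dtype=float),
        pupil_right=df["pupil_right"].to_numpy(dtype=float),
        valid_left=df["valid_left"].to_numpy(dtype=float).astype(bool) if df["valid_left"].dtype != bool else df["valid_left"].to_numpy(),
        valid_right=df["valid_right"].to_numpy(dtype=float).astype(bool) if df["valid_right"].dtype != bool else df["valid_right"].to_numpy(),
        airflow=df["airflow"].to_numpy(dtype=float),
        unit=str(meta.get("unit", "px")),
        meta=meta,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to the canonical CSV plus JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": rec.time_ms,
            "pupil_left": rec.pupil_left,
            "pupil_right": rec.pupil_right,
            "valid_left": rec.valid_left.astype(int),
            "valid_right": rec.valid_right.astype(int),
            "airflow": rec.airflow,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    meta = dict(rec.meta)
    meta.update(
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        route=rec.route,
        sampling_rate=rec.sampling_rate,
        unit=rec.unit,
    )
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


RESULTS_COLUMNS = ("participant", "session", "bin_index", "mean_z_pupil", "derivative_z", "n_observations")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(participant, session, bin) results table as TSV."""
    for col in RESULTS_COLUMNS:
        if col not in table.columns and len(table):
            raise SchemaError(f"results table missing column {col!r}")
    out = table if len(table) else pd.DataFrame(columns=list(RESULTS_COLUMNS))
    bad = out["bin_index"].to_numpy()
    if len(out) and (np.any(bad < 0) or np.any(bad > 17)):
        raise FormatError("bin_index must be within 0..17")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
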