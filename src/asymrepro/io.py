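"""Summary-statistics table I/O and run configuration.

The canonical on-disk format is TSV (UTF-8, '.' decimal, header row, empty
fields for missing values); CSV is accepted on read.  The summary table has
one row per (dataset, measure) with required columns ``dataset_id``,
``measure_id``, ``n`` and at least one of ``d`` or ``t``; ``var_d`` and ``p``
are reconstructed when absent.  Optional dataset-level columns
(field_strength, fs_version, age_min, age_max) populate the metadata table.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from asymrepro.effects import EffectRecord, effect_from_t, sampling_variance
from asymrepro.errors import SchemaError
from asymrepro.reproducibility import (
    DEFAULT_BINS,
    DEFAULT_THRESHOLDS,
    ReproCriterion,
)

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "read_summary_table",
    "write_summary_table",
    "RunConfig",
]

REQUIRED_COLUMNS = ("dataset_id", "measure_id", "n")
METADATA_COLUMNS = ("field_strength", "fs_version", "age_min", "age_max", "site")
KNOWN_METRIC_TYPES = ("thickness", "area")


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    """Effect records as the shared summary-table schema (one row each)."""
    rows = [
        {
            "dataset_id": r.dataset_id,
            "measure_id": r.measure_id,
            "n": r.n,
            "t": r.t,
            "d": r.d,
            "var_d": r.var_d,
            "p": r.p,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no records to convert")
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[EffectRecord]:
    """Validated EffectRecords from a schema-conforming DataFrame."""
    records = []
    for _, row in frame.iterrows():
        n = int(row["n"])
        d = float(row["d"])
        t = float(row["t"]) if "t" in row and pd.notna(row.get("t")) else d * math.sqrt(n)
        var_d = (
            float(row["var_d"])
            if "var_d" in row and pd.notna(row.get("var_d"))
            else sampling_variance(d, n)
        )
        if "p" in row and pd.notna(row.get("p")):
            p = float(row["p"])
            records.append(
                EffectRecord(
                    dataset_id=str(row["dataset_id"]),
                    measure_id=str(row["measure_id"]),
                    n=n,
                    t=t,
                    d=d,
                    var_d=var_d,
                    p=p,
                    df=n - 1,
                )
            )
        else:
            rec = effect_from_t(t, n, str(row["dataset_id"]), str(row["measure_id"]))
            records.append(rec)
    return records


def _read_frame(path: Path) -> pd.DataFrame:
    # round_trip parsing so write-then-read is the exact identity
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, float_precision="round_trip")
    if path.suffix.lower() in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    return pd.read_csv(path, sep=None, engine="python")


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[EffectRecord], pd.DataFrame]:
    """Read and validate a summary-statistics table.

    Returns (effect records, dataset metadata table).  Missing ``d`` is
    reconstructed from ``t``; missing ``var_d``/``p`` from ``d`` and ``n``.
    All validation failures are reported together with 1-based data row
    numbers.

    ``column_map`` renames source columns to the canonical schema, e.g.
    ``{"cohort": "dataset_id"}``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = _read_frame(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))

    problems: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            problems.append(f"missing required column {col!r}")
    if "d" not in frame.columns and "t" not in frame.columns:
        problems.append("table must carry a 'd' or a 't' column")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))

    n_numeric = pd.to_numeric(frame["n"], errors="coerce")
    for idx, (raw, val) in enumerate(zip(frame["n"], n_numeric), start=1):
        if pd.isna(val):
            problems.append(f"row {idx}: non-numeric n ({raw!r})")
        elif float(val) != int(val) or int(val) < 2:
            problems.append(f"row {idx}: n must be an integer >= 2 (got {raw!r})")

    dupes = frame.duplicated(subset=["dataset_id", "measure_id"], keep=False)
    for idx in frame.index[dupes]:
        problems.append(
            f"row {int(idx) + 1}: duplicate (dataset_id, measure_id) = "
            f"({frame.at[idx, 'dataset_id']!r}, {frame.at[idx, 'measure_id']!r})"
        )

    if "d" in frame.columns:
        d_numeric = pd.to_numeric(frame["d"], errors="coerce")
        for idx, val in enumerate(d_numeric, start=1):
            if not np.isfinite(val):
                problems.append(f"row {idx}: d is missing or not finite")
    if "metric_type" in frame.columns:
        for idx, val in enumerate(frame["metric_type"], start=1):
            if pd.notna(val) and val not in KNOWN_METRIC_TYPES:
                problems.append(
                    f"row {idx}: unknown metric_type {val!r}; expected one of "
                    f"{KNOWN_METRIC_TYPES}"
                )
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))

    frame = frame.assign(n=n_numeric.astype(int))
    if "d" not in frame.columns:
        frame = frame.assign(d=pd.to_numeric(frame["t"]) / np.sqrt(frame["n"]))
    records = frame_to_records(frame)

    meta_cols = ["dataset_id", "n"] + [
        c for c in METADATA_COLUMNS if c in frame.columns
    ]
    metadata = (
        frame[meta_cols].drop_duplicates(subset="dataset_id").reset_index(drop=True)
    )
    return records, metadata


def write_summary_table(
    records: Iterable[EffectRecord] | pd.DataFrame, path: str | Path
) -> Path:
    """Write effect records (or an equivalent frame) as canonical TSV."""
    frame = (
        records
        if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run."""

    seed: int
    input_path: str | None = None  # None -> simulate with the default profile
    out_dir: str = "results"
    method: str = "REML"
    alpha_meta: float = 0.05
    alpha_single: float = 0.05
    n_effects_for_correction: int = 70
    min_n: int = 15
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    bins: tuple[float, ...] = DEFAULT_BINS
    n_datasets: int = 99
    n_measures: int = 70
    tau: float = 0.10
    mode: str = "summary"
    column_map: Mapping[str, str] | None = None
    write_detail: bool = True

    def criterion(self) -> ReproCriterion:
        return ReproCriterion(
            alpha_meta=self.alpha_meta,
            alpha_single=self.alpha_single,
            n_effects_for_correction=self.n_effects_for_correction,
            min_n=self.min_n,
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        out["thresholds"] = list(self.thresholds)
        out["bins"] = list(self.bins)
        out["column_map"] = dict(self.column_map) if self.column_map else None
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = tuple(data["thresholds"])
        if "bins" in data and data["bins"] is not None:
            data["bins"] = tuple(data["bins"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
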