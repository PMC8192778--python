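"""Tabular input/output and pipeline configuration.

Manifests and item tables are comma-separated; network time series are tab-
or comma-separated (auto-detected from the header) with the sampling
interval carried in a leading ``# tr_seconds=<x>`` comment line.  All files
are UTF-8.
"""
from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError, ValidationError
from .windows import DEFAULT_NETWORKS, NetworkTimeSeries

MANIFEST_COLUMNS = ("subject_id", "group", "age", "sex", "iq", "motion")


@dataclass(frozen=True)
class SubjectRecord:
    """One manifest row: identity, group and confound covariates."""

    subject_id: str
    group: str  # "ASD" or "TD"
    age: float  # years
    sex: str  # "M" or "F"
    iq: float
    motion: float  # mean framewise displacement, mm

    def __post_init__(self):
        if self.group not in ("ASD", "TD"):
            raise ValidationError(f"group must be ASD or TD, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if not self.age > 0:
            raise ValidationError("age must be > 0")
        if self.motion < 0:
            raise ValidationError("motion must be >= 0")


@dataclass
class PipelineConfig:
    """All knobs of the analysis pipeline, loadable from YAML."""

    window_length: float = 30.0  # seconds
    window_shape: str = "exponential"  # or "rectangular"
    decay_rate: float | None = None  # None -> 3 / window samples
    window_step: int = 1  # samples
    k_range: tuple = (2, 8)
    n_restarts: int = 50
    fisher_z: bool = True
    cnii_aggregation: str = "by_state"
    mnii_aggregation: str = "by_window"
    n_permutations: int = 5000
    cv_folds: int = 5
    silhouette_subsample: int | None = None
    welch: bool = False
    seed: int = 0

    def validate(self):
        if self.window_length <= 0:
            raise ValidationError("window_length must be > 0")
        if self.window_step < 1:
            raise ValidationError("window_step must be >= 1")
        if int(self.k_range[0]) < 2:
            raise ValidationError("k_min must be >= 2")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        for agg in (self.cnii_aggregation, self.mnii_aggregation):
            if agg not in ("by_state", "by_window"):
                raise ValidationError(f"unknown aggregation {agg!r}")

    def window_samples(self, tr_seconds: float) -> int:
        """Window length in samples: nearest integer, at least 2."""
        return max(2, int(round(self.window_length / tr_seconds)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        cfg.validate()
        return cfg

    def to_yaml(self, path):
        data = asdict(self)
        data["k_range"] = list(self.k_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path) -> list:
    """Read a subject manifest CSV into SubjectRecords."""
    df = pd.read_csv(path, dtype={"subject_id": str},
                     float_precision="round_trip")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest missing required column(s): {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate subject_id: {dup.iloc[0]!r}")
    return [
        SubjectRecord(subject_id=row.subject_id, group=row.group,
                      age=float(row.age), sex=row.sex, iq=float(row.iq),
                      motion=float(row.motion))
        for row in df.itertuples()
    ]


def manifest_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=MANIFEST_COLUMNS)


def write_manifest(records, path):
    manifest_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_network_timeseries(path, expected_networks=DEFAULT_NETWORKS,
                            subject_id: str | None = None) -> NetworkTimeSeries:
    """Read one subject's series; columns reordered to ``expected_networks``."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        tr = None
        if first.startswith("#"):
            key, _, val = first.lstrip("#").strip().partition("=")
            if key.strip() != "tr_seconds":
                raise InputError(f"unrecognized header comment {first.strip()!r}")
            tr = float(val)
            header = fh.readline()
        else:
            header = first
        sep = "\t" if "\t" in header else ","
        body = header + fh.read()
    if tr is None:
        raise InputError(f"{path}: missing '# tr_seconds=<x>' header line")
    df = pd.read_csv(_io.StringIO(body), sep=sep,
                     float_precision="round_trip")
    missing = [n for n in expected_networks if n not in df.columns]
    if missing:
        raise InputError(f"{path}: missing network column(s): {missing}")
    df = df[list(expected_networks)]
    bad = ~np.isfinite(df.to_numpy(dtype=float))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValidationError(f"{path}: non-finite value at row {row}")
    if subject_id is None:
        stem = path.replace("\\", "/").rsplit("/", 1)[-1]
        subject_id = stem.rsplit(".", 1)[0]
    return NetworkTimeSeries(subject_id=subject_id,
                             network_names=tuple(expected_networks),
                             values=df.to_numpy(dtype=float), tr_seconds=tr)


def write_network_timeseries(ts: NetworkTimeSeries, path, sep: str = "\t"):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tr_seconds={ts.tr_seconds}\n")
        fh.write(sep.join(ts.network_names) + "\n")
        np.savetxt(fh, ts.values, delimiter=sep, fmt="%.17g")


def read_items(path) -> pd.DataFrame:
    """Read an item-score CSV (index subject_id, one column per item)."""
    df = pd.read_csv(path, dtype={"subject_id": str},
                     float_precision="round_trip").set_index("subject_id")
    df.attrs["provenance"] = "raw"
    return df


def write_items(items: pd.DataFrame, path):
    items.to_csv(path, index_label="subject_id")


def write_cohort(cohort, out_dir, sep: str = "\t"):
    """Write a synthetic cohort (time series + manifest) to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in cohort.timeseries:
        write_network_timeseries(ts, ts_dir / f"{ts.subject_id}.tsv", sep=sep)
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv", ts_dir
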