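"""Readers and writers for the pipeline's tabular interchange formats.

All tables are UTF-8, tab-separated, '.' decimal, with a mandatory header
row; missing values are empty fields.  The on-disk layout of a dataset
directory is

    participants.tsv            one row per subject
    atlas.tsv                   parcel_id -> network lookup
    timeseries/<subject>.tsv    T rows x P columns, header = parcel ids

Result writers emit tidy TSVs plus a JSON provenance sidecar recording
the configuration, seed, package version and subject counts after each
filter, so that two runs with identical config and seed are byte-identical
and auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (Cohort, NetworkAtlas, ParcelTimeSeries, SubjectRecord,
                     frame_to_records, records_to_frame)
from .features import Exclusion

_PARTICIPANT_COLUMNS = ["subject_id", "site_id", "group", "age", "sex",
                        "mean_fd", "medication", "severity"]


def write_participants(records: Sequence[SubjectRecord], path: Path | str) -> None:
    df = records_to_frame(records)[_PARTICIPANT_COLUMNS]
    # %.17g keeps the write->read round trip bit-exact for doubles
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_participants(path: Path | str) -> list[SubjectRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site_id": str},
                     float_precision="round_trip")
    missing = set(_PARTICIPANT_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        lines = (dup.index + 2).tolist()  # +2: header and 1-based lines
        raise ValueError(f"{path}: duplicate subject ids {sorted(set(dup))} "
                         f"at lines {lines}")
    for col in ("medication", "severity"):
        if col not in df.columns:
            df[col] = None
    return frame_to_records(df)


def write_timeseries(ts: ParcelTimeSeries, directory: Path | str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{ts.subject_id}.tsv"
    pd.DataFrame(ts.values, columns=list(ts.parcel_ids)).to_csv(
        out, sep="\t", index=False, float_format="%.10g")
    return out


def read_timeseries(path: Path | str, subject_id: str | None = None) -> ParcelTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty time-series file")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise ValueError(f"{path}: non-numeric values in time series")
    return ParcelTimeSeries(subject_id or path.stem, df.to_numpy(float),
                            tuple(str(c) for c in df.columns))


def write_atlas(atlas: NetworkAtlas, path: Path | str) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_atlas(path: Path | str) -> NetworkAtlas:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("parcel_id", "network"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        return NetworkAtlas.from_frame(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def check_atlas_timeseries(atlas: NetworkAtlas, ts: ParcelTimeSeries,
                           path: Path | str | None = None) -> None:
    """Fail loudly when a series' parcels do not match the atlas."""
    if tuple(ts.parcel_ids) != tuple(atlas.parcel_ids):
        extra = set(ts.parcel_ids) - set(atlas.parcel_ids)
        missing = set(atlas.parcel_ids) - set(ts.parcel_ids)
        where = f" in {path}" if path else ""
        raise ValueError(
            f"parcel mismatch for subject {ts.subject_id}{where}: "
            f"{len(missing)} atlas parcels absent, {len(extra)} unknown "
            f"(first missing: {sorted(missing)[:3]})")


def write_cohort(cohort: Cohort, directory: Path | str) -> None:
    """Materialise a generated cohort as a dataset directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_participants(cohort.records, directory / "participants.tsv")
    write_atlas(cohort.atlas, directory / "atlas.tsv")
    for ts in cohort.series:
        write_timeseries(ts, directory / "timeseries")


def read_cohort_dir(directory: Path | str) -> tuple[list[SubjectRecord], list[ParcelTimeSeries], NetworkAtlas]:
    directory = Path(directory)
    records = read_participants(directory / "participants.tsv")
    atlas = read_atlas(directory / "atlas.tsv")
    series = []
    for rec in records:
        path = directory / "timeseries" / f"{rec.subject_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing time series for {rec.subject_id}: {path}")
        ts = read_timeseries(path, rec.subject_id)
        check_atlas_timeseries(atlas, ts, path)
        series.append(ts)
    return records, series, atlas


def write_exclusions(exclusions: Sequence[Exclusion], path: Path | str) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in exclusions],
                 columns=["subject_id", "reason", "detail"]).to_csv(
        path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: Path | str,
                  provenance: dict | None = None) -> None:
    """Tidy result TSV plus a JSON provenance sidecar (<path>.json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep="\t", index=False, na_rep="")
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(_jsonable(provenance), indent=2,
                                      sort_keys=True) + "\n")


def provenance_record(config: dict, seed: int | None,
                      counts: dict[str, int]) -> dict:
    """Standard provenance payload: config echo, seed, version, flow counts.

    ``counts`` should read like a subject-flow accounting: input n, one
    entry per exclusion reason, and the analysed n; callers are expected
    to keep ``n_input - sum(excluded_*) == n_analysed``.
    """
    return {"package": "fcmega", "version": __version__, "seed": seed,
            "config": config, "counts": counts}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj
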