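"""Epoch-table input/output.

The native layout is delimited text with one row per epoch and a header:
``subject_id, epoch_idx, timestamp, activity, stage, annotation``; missing
values are empty fields. A dialect maps other epoch-table layouts onto the
native fields; the registered ``mesa`` dialect covers the overlap-file
layout distributed with the MESA Sleep actigraphy release (columns
``mesaid, linetime, activity, stage, interval, wake``), where the expert
``interval`` channel marks ``ACTIVE`` / ``REST`` / ``REST-S`` /
``EXCLUDED`` spans and rest intervals are read as sleep annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import EpochSeries
from .errors import ConfigurationError, ValidationError

NATIVE_COLUMNS = ("subject_id", "epoch_idx", "timestamp", "activity", "stage", "annotation")


@dataclass(frozen=True)
class Dialect:
    """Column mapping from an on-disk epoch table onto the native fields."""

    name: str
    subject_col: str
    time_col: str
    activity_col: str
    stage_col: str | None = None
    annotation_col: str | None = None
    epoch_idx_col: str | None = None
    sep: str = ","
    annotation_parser: Callable[[pd.Series], pd.Series] | None = None


def _parse_mesa_interval(col: pd.Series) -> pd.Series:
    """MESA rest-interval channel -> binary annotation (rest counts as sleep)."""
    mapping = {"ACTIVE": 0.0, "REST": 1.0, "REST-S": 1.0, "EXCLUDED": np.nan}
    out = col.astype(str).str.strip().str.upper().map(mapping)
    out[col.isna()] = np.nan
    return out


DIALECTS: dict[str, Dialect] = {
    "native": Dialect(
        name="native",
        subject_col="subject_id",
        time_col="timestamp",
        activity_col="activity",
        stage_col="stage",
        annotation_col="annotation",
        epoch_idx_col="epoch_idx",
    ),
    "mesa": Dialect(
        name="mesa",
        subject_col="mesaid",
        time_col="linetime",
        activity_col="activity",
        stage_col="stage",
        annotation_col="interval",
        annotation_parser=_parse_mesa_interval,
    ),
}


def register_dialect(dialect: Dialect) -> None:
    DIALECTS[dialect.name] = dialect


def read_epoch_table(
    path: str | Path,
    dialect: str = "native",
    epoch_length_s: float = 30.0,
) -> dict[str, EpochSeries]:
    """Read a delimited epoch table into one :class:`EpochSeries` per subject.

    Rows are ordered by epoch index (when the dialect provides one) or by
    timestamp; duplicated or non-monotone epoch positions raise a
    validation error naming the subject and row. The PSG window is
    inferred per subject as the span of non-missing stages.
    """
    try:
        spec = DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"epoch table not found: {path}")
    df = pd.read_csv(path, sep=spec.sep)
    required = [spec.subject_col, spec.time_col, spec.activity_col]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols} for dialect {dialect!r}")

    out: dict[str, EpochSeries] = {}
    for sid, grp in df.groupby(spec.subject_col, sort=False):
        sid = str(sid)
        if spec.epoch_idx_col and spec.epoch_idx_col in grp.columns:
            keys = grp[spec.epoch_idx_col].to_numpy()
            grp = grp.sort_values(spec.epoch_idx_col, kind="stable")
            keys = grp[spec.epoch_idx_col].to_numpy()
        else:
            ts = pd.to_datetime(grp[spec.time_col], format="mixed")
            grp = grp.assign(_ts=ts).sort_values("_ts", kind="stable")
            keys = grp["_ts"].to_numpy()
        diffs_bad = pd.Series(keys).duplicated()
        if diffs_bad.any():
            row = int(np.flatnonzero(diffs_bad.to_numpy())[0])
            raise ValidationError(
                f"subject {sid!r}: duplicated or non-monotone epoch position at sorted row {row}"
            )
        counts = pd.to_numeric(grp[spec.activity_col], errors="coerce").to_numpy(dtype=float)
        if np.nanmin(counts) < 0 if np.isfinite(counts).any() else False:
            raise ValidationError(f"subject {sid!r}: negative activity count in {path}")
        stage = (
            pd.to_numeric(grp[spec.stage_col], errors="coerce").to_numpy(dtype=float)
            if spec.stage_col and spec.stage_col in grp.columns
            else None
        )
        if spec.annotation_col and spec.annotation_col in grp.columns:
            ann_raw = grp[spec.annotation_col]
            ann = (
                spec.annotation_parser(ann_raw)
                if spec.annotation_parser
                else pd.to_numeric(ann_raw, errors="coerce")
            ).to_numpy(dtype=float)
        else:
            ann = None
        start = None
        if spec.time_col in grp.columns:
            try:
                start = pd.to_datetime(grp[spec.time_col].iloc[0])
            except (ValueError, TypeError):
                start = None
            if pd.isna(start):
                start = None
        out[sid] = EpochSeries(
            subject_id=sid,
            counts=counts,
            psg_stage=stage,
            annotation=ann,
            epoch_length_s=epoch_length_s,
            start_time=start,
        )
    return out


def write_epoch_table(
    records: Mapping[str, EpochSeries] | list[EpochSeries],
    path: str | Path,
    extra_columns: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> Path:
    """Write records in the native layout; ``extra_columns`` adds per-subject
    channels (e.g. a prediction column) keyed as ``{column: {subject: values}}``."""
    if isinstance(records, Mapping):
        records = list(records.values())
    frames = []
    for rec in records:
        n = len(rec)
        if rec.start_time is not None:
            ts = pd.date_range(rec.start_time, periods=n, freq=pd.Timedelta(seconds=rec.epoch_length_s))
            ts = ts.strftime("%Y-%m-%dT%H:%M:%S")
        else:
            ts = [""] * n
        frame = pd.DataFrame(
            {
                "subject_id": rec.subject_id,
                "epoch_idx": np.arange(n),
                "timestamp": ts,
                "activity": rec.counts,
                "stage": rec.psg_stage,
                "annotation": rec.annotation,
            }
        )
        if extra_columns:
            for col, per_subject in extra_columns.items():
                if rec.subject_id in per_subject:
                    frame[col] = np.asarray(per_subject[rec.subject_id], dtype=float)
        frames.append(frame)
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
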