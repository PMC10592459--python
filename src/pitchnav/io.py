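"""Raw per-frame trace (``.dlm``) and experiment-metadata I/O.

Each acquisition run produces one ``.dlm`` file: a tab-delimited, headerless
text table with one row per accepted video frame and eight columns, in
order::

    time_stamp  body_x  body_z  head_x  head_z  pitch  epoch_id  animal_length

``time_stamp`` is seconds since the start of the run, coordinates are in
pixels (z increasing upward), ``pitch`` is in degrees (nose-up positive,
in [-180, 180)), ``epoch_id`` is a non-negative integer labelling each
contiguous interval of valid single-animal detection, and ``animal_length``
is in pixels.  A trace is held in memory as a :class:`pandas.DataFrame`
with those column names.

Run metadata (frame rate, spatial calibration, light schedule, wall-clock
start time, chamber type) is a flat ``key = value`` text file; the light
schedule plus the start time let :func:`filter_zeitgeber_day` restrict a
trace to the 14 h light phase, which is the only portion quantified.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from datetime import datetime, time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DLM_COLUMNS",
    "DlmFormatError",
    "DlmIntegrityError",
    "RunMetadata",
    "read_dlm",
    "write_dlm",
    "validate_trace",
    "read_metadata",
    "write_metadata",
    "filter_zeitgeber_day",
]

DLM_COLUMNS = [
    "time_stamp",
    "body_x",
    "body_z",
    "head_x",
    "head_z",
    "pitch",
    "epoch_id",
    "animal_length",
]


class DlmFormatError(ValueError):
    """The file cannot be interpreted as a ``.dlm`` table at all."""


class DlmIntegrityError(ValueError):
    """The file parses but violates a trace invariant (e.g. time order)."""


def empty_trace() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in DLM_COLUMNS})
    df["epoch_id"] = df["epoch_id"].astype(int)
    return df


def read_dlm(path: str | Path, *, validate: bool = True) -> pd.DataFrame:
    """Read a ``.dlm`` file into a trace DataFrame.

    Malformed lines (wrong field count or unparseable numbers) are skipped;
    their count is reported via a :class:`UserWarning` and stored in
    ``trace.attrs["n_malformed"]``.  Long acquisitions tolerate isolated
    glitches, so a bad line is not fatal.
    """
    path = Path(path)
    bad = []

    def _on_bad(line: list[str]) -> None:
        bad.append(line)
        return None

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=DLM_COLUMNS,
            engine="python",
            on_bad_lines=_on_bad,
        )
    except pd.errors.EmptyDataError:
        df = empty_trace()
        df.attrs["n_malformed"] = 0
        return df

    if df.shape[1] != len(DLM_COLUMNS):
        raise DlmFormatError(
            f"{path}: expected {len(DLM_COLUMNS)} columns, found {df.shape[1]}"
        )
    # a line with the right field count but non-numeric content shows up as
    # NaN after coercion; count and drop it like any other malformed line
    for col in DLM_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_nan = int(df.isna().any(axis=1).sum())
    if n_nan:
        df = df.dropna()
    n_malformed = n_nan + len(bad)
    if n_malformed and len(df) == 0:
        # nothing parsed at all: wrong dialect/column count, not a glitch
        raise DlmFormatError(f"{path}: no parseable lines (missing columns?)")
    if n_malformed:
        warnings.warn(f"{path}: skipped {n_malformed} malformed line(s)", stacklevel=2)
    df = df.reset_index(drop=True)
    df["epoch_id"] = df["epoch_id"].astype(np.int64)
    df.attrs["n_malformed"] = n_malformed
    if validate and len(df):
        validate_trace(df, source=str(path))
    return df


def validate_trace(trace: pd.DataFrame, source: str = "trace") -> None:
    """Raise :class:`DlmIntegrityError` on invariant violations."""
    missing = [c for c in DLM_COLUMNS if c not in trace.columns]
    if missing:
        raise DlmFormatError(f"{source}: missing columns {missing}")
    for _, grp in trace.groupby("epoch_id", sort=False):
        t = grp["time_stamp"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DlmIntegrityError(f"{source}: non-monotonic time within an epoch")
    if (trace["epoch_id"] < 0).any():
        raise DlmIntegrityError(f"{source}: negative epoch_id")


def write_dlm(trace: pd.DataFrame, path: str | Path) -> Path:
    """Write a trace as a tab-delimited, headerless ``.dlm`` file.

    Floats are written in shortest round-trip representation, so
    ``read_dlm(write_dlm(x))`` reproduces ``x`` field-for-field.
    """
    path = Path(path)
    buf = _io.StringIO()
    for row in trace[DLM_COLUMNS].itertuples(index=False):
        fields = [repr(float(v)) if i != 6 else str(int(v)) for i, v in enumerate(row)]
        buf.write("\t".join(fields) + "\n")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# metadata


@dataclass
class RunMetadata:
    """Acquisition-run metadata.

    ``light_on``/``light_off`` are clock times delimiting the zeitgeber day
    (the light phase of the 14/10 h light/dark cycle); ``start_time`` is the
    wall-clock time of ``time_stamp == 0``, which the ``.dlm`` itself lacks.
    """

    frame_rate: float = 166.0
    mm_per_pixel: float = 60.0 / 1200.0  # 60 mm field of view on 1200 px default
    light_on: time = time(8, 0)
    light_off: time = time(22, 0)
    chamber_type: str = "standard"
    start_time: datetime = datetime(2000, 1, 1, 9, 0, 0)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.chamber_type not in ("standard", "narrow"):
            raise ValueError("chamber_type must be 'standard' or 'narrow'")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def _parse_time(s: str) -> time:
    for fmt in ("%H:%M:%S", "%H:%M"):
        try:
            return datetime.strptime(s.strip(), fmt).time()
        except ValueError:
            continue
    raise ValueError(f"cannot parse clock time {s!r}")


def read_metadata(path: str | Path) -> RunMetadata:
    """Parse a flat ``key = value`` metadata text file."""
    data: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"metadata line without '=': {line!r}")
        key, val = line.split("=", 1)
        data[key.strip()] = val.strip()
    kwargs: dict = {}
    if "frame_rate" in data:
        kwargs["frame_rate"] = float(data["frame_rate"])
    if "mm_per_pixel" in data:
        kwargs["mm_per_pixel"] = float(data["mm_per_pixel"])
    if "light_on" in data:
        kwargs["light_on"] = _parse_time(data["light_on"])
    if "light_off" in data:
        kwargs["light_off"] = _parse_time(data["light_off"])
    if "chamber_type" in data:
        kwargs["chamber_type"] = data["chamber_type"]
    if "start_time" in data:
        kwargs["start_time"] = datetime.fromisoformat(data["start_time"])
    return RunMetadata(**kwargs)


def write_metadata(meta: RunMetadata, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "\n".join(
            [
                f"frame_rate = {meta.frame_rate!r}",
                f"mm_per_pixel = {meta.mm_per_pixel!r}",
                f"light_on = {meta.light_on.strftime('%H:%M:%S')}",
                f"light_off = {meta.light_off.strftime('%H:%M:%S')}",
                f"chamber_type = {meta.chamber_type}",
                f"start_time = {meta.start_time.isoformat(sep=' ')}",
                "",
            ]
        )
    )
    return path


# ---------------------------------------------------------------------------
# zeitgeber-day filter


def _seconds_of_day(t: time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def filter_zeitgeber_day(trace: pd.DataFrame, meta: RunMetadata) -> pd.DataFrame:
    """Keep only records whose wall-clock time falls in the light phase.

    The wall-clock time of each record is ``start_time + time_stamp``.  A
    record is kept iff its time of day lies in ``[light_on, light_off)``;
    epochs straddling a light transition are truncated (frames outside the
    window are dropped, the epoch_id of the surviving frames is unchanged).
    The operation is idempotent.
    """
    if not len(trace):
        return trace.copy()
    sod0 = _seconds_of_day(meta.start_time.time())
    sod = (sod0 + trace["time_stamp"].to_numpy()) % 86400.0
    on = _seconds_of_day(meta.light_on)
    off = _seconds_of_day(meta.light_off)
    if on <= off:
        keep = (sod >= on) & (sod < off)
    else:  # light window crosses midnight
        keep = (sod >= on) | (sod < off)
    out = trace.loc[keep].reset_index(drop=True)
    out.attrs = dict(trace.attrs)
    return out
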