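"""Reading, writing and segmenting wearable-sensor sessions.

A *session* is one interviewer–interviewee pair: up to eight gyroscope
streams (2 roles x 4 body sites), experimenter task markers, and condition
labels.  On disk a session is a directory of plain CSV files:

* one stream file per (role, site), named ``<role>_<site>.csv`` with header
  ``t_ms,gx,gy,gz`` — integer milliseconds on the capture clock and the
  three gyroscope axis readings in device units;
* ``markers.csv`` with header ``task,boundary,t_ms`` marking the start and
  end of the questioning about each task;
* ``manifest.yaml`` naming the dyad, the stream files and condition labels.

Timestamps share the capture host's clock, but devices do not start
recording at the same moment, so streams begin at different times; the
alignment step downstream drops samples before the first timestamp covered
by both streams of a pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, SegmentationError

logger = logging.getLogger("dyadwarp.sensor_io")

ROLES = ("interviewer", "interviewee")
SITES = ("head", "torso", "left_wrist", "right_wrist")
TASKS = ("truth", "easy_lie", "difficult_lie", "very_difficult_lie")
STREAM_COLUMNS = ["t_ms", "gx", "gy", "gz"]
MARKER_COLUMNS = ["task", "boundary", "t_ms"]

# Task order established by the difficulty manipulation check: the easy
# (concealment) lie is experienced as easier than the truth.
DIFFICULTY_ORDER = ("easy_lie", "truth", "difficult_lie", "very_difficult_lie")


@dataclass
class DyadSession:
    """All raw streams, markers and condition labels for one dyad.

    ``streams`` maps (role, site) to a DataFrame with columns
    ``t_ms, gx, gy, gz`` sorted by ``t_ms``; absent streams (sensor
    failure) are simply missing keys.  ``markers`` is a DataFrame with
    columns ``task, boundary, t_ms``.
    """

    dyad_id: str
    streams: Dict[Tuple[str, str], pd.DataFrame]
    markers: pd.DataFrame
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions.setdefault("order_variant", "forward")
        self.conditions.setdefault("attention_instruction", "n/a")
        self.conditions.setdefault("nominal_rate_hz", 120)
        self.validate()

    def validate(self) -> None:
        for (role, site) in self.streams:
            if role not in ROLES or site not in SITES:
                raise FormatError(f"unknown stream key {(role, site)!r}")
        for key, df in self.streams.items():
            t = df["t_ms"].to_numpy()
            if len(t) and np.any(t < 0):
                raise FormatError(f"negative timestamp in stream {key}")
            bad = np.nonzero(np.diff(t) < 0)[0]
            if bad.size:
                raise FormatError(
                    f"unsorted timestamps in stream {key} at row {int(bad[0]) + 1}"
                )
        spans = self.task_spans()
        items = sorted(spans.items(), key=lambda kv: kv[1][0])
        for (task, (t0, t1)) in items:
            if t0 >= t1:
                raise SegmentationError(f"task {task!r}: start must precede end")
        for (ta, (_, e0)), (tb, (s1, _)) in zip(items, items[1:]):
            if s1 <= e0:
                raise SegmentationError(f"tasks {ta!r} and {tb!r} overlap")

    def task_spans(self) -> Dict[str, Tuple[int, int]]:
        """Map task -> (start_ms, end_ms) from the marker stream."""
        spans: Dict[str, list] = {}
        for rec in self.markers.itertuples(index=False):
            if rec.task not in TASKS:
                raise FormatError(f"unknown task label {rec.task!r}")
            if rec.boundary not in ("start", "end"):
                raise FormatError(f"unknown marker boundary {rec.boundary!r}")
            slot = spans.setdefault(rec.task, [None, None])
            slot[0 if rec.boundary == "start" else 1] = int(rec.t_ms)
        out = {}
        for task, (s, e) in spans.items():
            if s is None or e is None:
                raise SegmentationError(
                    f"task {task!r} has a {'start' if e is None else 'end'} "
                    "marker but not its counterpart"
                )
            out[task] = (s, e)
        return out

    @property
    def tasks(self) -> List[str]:
        return [t for t in TASKS if t in self.task_spans()]


def _parse_stream_key(path: Path) -> Tuple[str, str]:
    stem = path.stem
    for role in ROLES:
        for site in SITES:
            if stem == f"{role}_{site}":
                return role, site
    raise FormatError(
        f"cannot infer (role, site) from file name {path.name!r}; expected "
        "'<role>_<site>.csv'"
    )


def _read_numeric_csv(path: Path, columns: List[str], int_cols: Iterable[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise FormatError(f"missing file {path}") from None
    if list(df.columns) != columns:
        raise FormatError(f"{path}: expected header {columns}, got {list(df.columns)}")
    out = {}
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise FormatError(
                f"{path}: {bad.size} malformed row(s); first bad value in "
                f"column {col!r} at data row {int(bad[0]) + 1}"
            )
        out[col] = vals.to_numpy()
    res = pd.DataFrame(out)
    for col in int_cols:
        as_int = res[col].astype(np.int64)
        if not np.array_equal(as_int, res[col].to_numpy()):
            raise FormatError(f"{path}: column {col!r} must be integer-valued")
        res[col] = as_int
    return res


def read_session(
    paths: Iterable,
    marker_file,
    dyad_id: str = "session",
    conditions: Optional[dict] = None,
) -> DyadSession:
    """Read stream files plus a marker file into a :class:`DyadSession`.

    Stream identity (role, site) is taken from each file's name.  Malformed
    rows are fatal, reported with their row index; duplicate (role, site)
    streams and missing marker files are fatal.
    """
    marker_file = Path(marker_file)
    if not marker_file.exists():
        raise FormatError(f"missing marker file {marker_file}")
    markers = pd.read_csv(marker_file, dtype=str)
    if list(markers.columns) != MARKER_COLUMNS:
        raise FormatError(
            f"{marker_file}: expected header {MARKER_COLUMNS}, got {list(markers.columns)}"
        )
    t = pd.to_numeric(markers["t_ms"], errors="coerce")
    bad = np.nonzero(t.isna().to_numpy())[0]
    if bad.size:
        raise FormatError(f"{marker_file}: non-numeric t_ms at data row {int(bad[0]) + 1}")
    markers = markers.assign(t_ms=t.astype(np.int64))

    streams: Dict[Tuple[str, str], pd.DataFrame] = {}
    for p in paths:
        p = Path(p)
        key = _parse_stream_key(p)
        if key in streams:
            raise FormatError(f"duplicate stream for {key} ({p.name})")
        gyro_cols_are_int = True
        df = _read_numeric_csv(p, STREAM_COLUMNS, int_cols=["t_ms"])
        for col in ("gx", "gy", "gz"):
            arr = df[col].to_numpy()
            if np.array_equal(arr, arr.astype(np.int64)):
                df[col] = arr.astype(np.int64)
            else:
                gyro_cols_are_int = False
        if not gyro_cols_are_int:
            logger.debug("%s: non-integer gyro values kept as float", p.name)
        streams[key] = df
    return DyadSession(
        dyad_id=dyad_id, streams=streams, markers=markers, conditions=dict(conditions or {})
    )


def read_session_dir(directory) -> DyadSession:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    paths = [directory / name for name in manifest.get("streams", {}).values()]
    return read_session(
        paths,
        directory / "markers.csv",
        dyad_id=manifest.get("dyad_id", directory.name),
        conditions=manifest.get("conditions", {}),
    )


def _format_stream(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("gx", "gy", "gz"):
        arr = out[col].to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            out[col] = np.asarray([format(v, ".6f") for v in arr])
    return out


def write_session(session: DyadSession, directory) -> List[Path]:
    """Write a session to ``directory``; returns the written file paths.

    Round-trips exactly with :func:`read_session_dir`: timestamps and
    integer gyro readings bit-exact, real-valued readings in fixed 6-decimal
    formatting.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create directory {directory}: {exc}") from exc
    written: List[Path] = []
    stream_names = {}
    for (role, site), df in sorted(session.streams.items()):
        name = f"{role}_{site}.csv"
        path = directory / name
        _format_stream(df).to_csv(path, index=False)
        stream_names[f"{role}_{site}"] = name
        written.append(path)
    marker_path = directory / "markers.csv"
    session.markers.to_csv(marker_path, index=False)
    written.append(marker_path)
    manifest = {
        "dyad_id": session.dyad_id,
        "conditions": session.conditions,
        "streams": stream_names,
    }
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written.append(manifest_path)
    return written


def segment_stream(df: pd.DataFrame, start_ms: int, end_ms: int) -> pd.DataFrame:
    """Samples with start_ms <= t_ms <= end_ms (closed interval)."""
    t = df["t_ms"].to_numpy()
    mask = (t >= start_ms) & (t <= end_ms)
    return df.loc[mask].reset_index(drop=True)


def segment_tasks(
    session: DyadSession,
) -> Dict[Tuple[str, str], Tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-task, per-site stream pairs (interviewer, interviewee).

    Pairs are emitted only for sites present in both roles; segments with no
    samples for either role are excluded with a warning.
    """
    spans = session.task_spans()
    out: Dict[Tuple[str, str], Tuple[pd.DataFrame, pd.DataFrame]] = {}
    for task, (t0, t1) in spans.items():
        for site in SITES:
            a = session.streams.get(("interviewer", site))
            b = session.streams.get(("interviewee", site))
            if a is None or b is None:
                continue
            sa = segment_stream(a, t0, t1)
            sb = segment_stream(b, t0, t1)
            if sa.empty or sb.empty:
                logger.warning(
                    "dyad %s task %s site %s: empty segment, excluded",
                    session.dyad_id, task, site,
                )
                continue
            out[(task, site)] = (sa, sb)
    return out
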