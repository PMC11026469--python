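"""Annotated beat streams: data model, readers/writers, NN-interval extraction.

All times are milliseconds from recording start (0-based, stored as floats).
Beat labels follow the usual Holter annotation classes:

``N``
    normal (sinus) beat
``V``
    premature ventricular beat
``S``
    supraventricular ectopic beat
``A``
    artifact / unclassifiable

An RR interval qualifies as an NN (normal-to-normal) interval only when both
flanking beats are labelled ``N``; this drops every interval preceding or
following an ectopic or artifact beat.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_LABELS = ("N", "V", "S", "A")

#: default plausibility window for NN intervals, ms; telemetry dropouts
#: otherwise masquerade as giant RR intervals
DEFAULT_NN_RANGE_MS: tuple[float, float] = (200.0, 3000.0)

BEATS_CSV_HEADER = [
    "t_r_ms",
    "label",
    "morph_id",
    "p_on_ms",
    "qrs_on_ms",
    "qrs_off_ms",
    "t_end_ms",
    "fqrs",
]


@dataclass(frozen=True)
class BeatRecord:
    """One annotated beat.

    Fiducial fields are optional (``None`` when the wave was not marked).
    """

    t_r: float
    label: str
    morph_id: int = 0
    p_on: Optional[float] = None
    qrs_on: Optional[float] = None
    qrs_off: Optional[float] = None
    t_end: Optional[float] = None
    fragmented_qrs: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.t_r < 0:
            raise ValueError(f"beat time must be >= 0, got {self.t_r}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown beat label {self.label!r}")
        fids = [self.p_on, self.qrs_on, self.qrs_off, self.t_end]
        present = [f for f in fids if f is not None]
        if len(present) > 1 and any(
            a >= b for a, b in zip(present[:-1], present[1:])
        ):
            raise ValueError(
                f"fiducials must be ordered p_on < qrs_on < qrs_off < t_end, got {fids}"
            )
        if self.qrs_on is not None and self.qrs_on > self.t_r:
            raise ValueError("qrs_on must not exceed t_r")
        if self.qrs_off is not None and self.qrs_off < self.t_r:
            raise ValueError("qrs_off must not precede t_r")


@dataclass(frozen=True)
class RecordingMeta:
    """Recording-level metadata attached to a beat stream."""

    recording_id: str = ""
    subject_id: str = ""
    group: str = ""
    age_months: Optional[float] = None
    duration_ms: Optional[float] = None
    fs_hz: float = 500.0
    seed: Optional[int] = None


class BeatSeries:
    """A validated, time-ordered beat stream of one recording.

    Internally columnar (parallel numpy arrays); absent fiducials are NaN.
    """

    def __init__(
        self,
        t_r: np.ndarray,
        labels: np.ndarray,
        morph_id: Optional[np.ndarray] = None,
        p_on: Optional[np.ndarray] = None,
        qrs_on: Optional[np.ndarray] = None,
        qrs_off: Optional[np.ndarray] = None,
        t_end: Optional[np.ndarray] = None,
        fqrs: Optional[np.ndarray] = None,
        meta: Optional[RecordingMeta] = None,
    ) -> None:
        n = len(t_r)
        self.t_r = np.asarray(t_r, dtype=float)
        self.labels = np.asarray(labels, dtype="U1")

        def _col(x, fill):
            if x is None:
                return np.full(n, fill, dtype=float)
            return np.asarray(x, dtype=float)

        self.morph_id = (
            np.zeros(n, dtype=int) if morph_id is None else np.asarray(morph_id, dtype=int)
        )
        self.p_on = _col(p_on, np.nan)
        self.qrs_on = _col(qrs_on, np.nan)
        self.qrs_off = _col(qrs_off, np.nan)
        self.t_end = _col(t_end, np.nan)
        self.fqrs = _col(fqrs, np.nan)
        if meta is None:
            meta = RecordingMeta()
        if meta.duration_ms is None and n:
            meta = replace(meta, duration_ms=float(self.t_r[-1]))
        self.meta = meta
        self._validate()

    def _validate(self) -> None:
        n = len(self.t_r)
        for name, col in (
            ("labels", self.labels),
            ("morph_id", self.morph_id),
            ("p_on", self.p_on),
            ("qrs_on", self.qrs_on),
            ("qrs_off", self.qrs_off),
            ("t_end", self.t_end),
            ("fqrs", self.fqrs),
        ):
            if len(col) != n:
                raise ValueError(f"column {name} has length {len(col)}, expected {n}")
        if n and self.t_r[0] < 0:
            raise ValueError("beat times must be >= 0")
        bad = np.nonzero(np.diff(self.t_r) <= 0)[0]
        if bad.size:
            # row numbering is 1-based over data rows; offender is the later beat
            raise ValueError(f"non-monotonic beat time at row {bad[0] + 2}")
        unknown = ~np.isin(self.labels, VALID_LABELS)
        if unknown.any():
            raise ValueError(
                f"unknown beat label {self.labels[unknown][0]!r} at row "
                f"{int(np.nonzero(unknown)[0][0]) + 1}"
            )
        if self.meta.duration_ms is not None and n:
            if self.meta.duration_ms < self.t_r[-1]:
                raise ValueError("recording duration shorter than last beat time")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.t_r)

    def __getitem__(self, i: int) -> BeatRecord:
        def _opt(col):
            v = col[i]
            return None if math.isnan(v) else float(v)

        f = self.fqrs[i]
        return BeatRecord(
            t_r=float(self.t_r[i]),
            label=str(self.labels[i]),
            morph_id=int(self.morph_id[i]),
            p_on=_opt(self.p_on),
            qrs_on=_opt(self.qrs_on),
            qrs_off=_opt(self.qrs_off),
            t_end=_opt(self.t_end),
            fragmented_qrs=None if math.isnan(f) else bool(f),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def duration_ms(self) -> float:
        d = self.meta.duration_ms
        return float(d) if d is not None else (float(self.t_r[-1]) if len(self) else 0.0)

    @property
    def n_raw_intervals(self) -> int:
        return max(len(self) - 1, 0)

    @classmethod
    def from_records(
        cls, records: Sequence[BeatRecord], meta: Optional[RecordingMeta] = None
    ) -> "BeatSeries":
        def _nan(v):
            return np.nan if v is None else v

        return cls(
            t_r=np.array([r.t_r for r in records], dtype=float),
            labels=np.array([r.label for r in records], dtype="U1"),
            morph_id=np.array([r.morph_id for r in records], dtype=int),
            p_on=np.array([_nan(r.p_on) for r in records], dtype=float),
            qrs_on=np.array([_nan(r.qrs_on) for r in records], dtype=float),
            qrs_off=np.array([_nan(r.qrs_off) for r in records], dtype=float),
            t_end=np.array([_nan(r.t_end) for r in records], dtype=float),
            fqrs=np.array(
                [np.nan if r.fragmented_qrs is None else float(r.fragmented_qrs) for r in records],
                dtype=float,
            ),
            meta=meta,
        )


@dataclass
class NNSeries:
    """Cleaned normal-to-normal intervals.

    ``start_ms[i]`` is the time of the opening beat of interval *i* and
    ``rr_ms[i]`` its duration; intervals are time-ordered and non-overlapping.
    ``n_excluded`` counts raw consecutive-beat intervals dropped by cleaning
    (arrhythmia-adjacent plus out-of-range), so kept + excluded equals the
    number of beats minus one.
    """

    start_ms: np.ndarray
    rr_ms: np.ndarray
    n_excluded: int
    n_range_excluded: int = 0
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.start_ms = np.asarray(self.start_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if (self.rr_ms <= 0).any():
            raise ValueError("NN intervals must be positive")
        ends = self.start_ms + self.rr_ms
        if len(self.start_ms) > 1 and (self.start_ms[1:] < ends[:-1] - 1e-9).any():
            raise ValueError("NN intervals overlap or are unordered")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def end_ms(self) -> np.ndarray:
        return self.start_ms + self.rr_ms

    @property
    def mean_nn(self) -> float:
        return float(np.mean(self.rr_ms))

    def contiguous_pair_mask(self) -> np.ndarray:
        """Boolean mask over successive kept-interval pairs (length n-1).

        A pair is contiguous when the two intervals share a beat, i.e. no
        interval between them was excluded by cleaning.
        """
        if len(self) < 2:
            return np.zeros(0, dtype=bool)
        return np.abs(self.start_ms[1:] - self.end_ms[:-1]) < 1e-6

    @property
    def duration_ms(self) -> float:
        d = self.meta.duration_ms
        if d is not None:
            return float(d)
        return float(self.end_ms[-1]) if len(self) else 0.0


def clean_to_nn(
    series: BeatSeries,
    nn_range_ms: Optional[tuple[float, float]] = DEFAULT_NN_RANGE_MS,
) -> NNSeries:
    """Extract NN intervals, excluding any interval adjacent to a non-N beat.

    An interval between beats *i* and *i+1* is kept iff both are labelled
    ``N`` (which excludes the RR preceding and following every arrhythmic
    or artifact beat) and, when ``nn_range_ms`` is given, its duration lies
    inside that plausibility window.
    """
    if len(series) < 2:
        raise ValueError("no intervals: need at least 2 beats")
    rr = np.diff(series.t_r)
    start = series.t_r[:-1]
    keep = (series.labels[:-1] == "N") & (series.labels[1:] == "N")
    n_range_excl = 0
    if nn_range_ms is not None:
        lo, hi = nn_range_ms
        in_range = (rr >= lo) & (rr <= hi)
        n_range_excl = int(np.count_nonzero(keep & ~in_range))
        if n_range_excl:
            logger.warning(
                "%d NN interval(s) outside [%g, %g] ms excluded", n_range_excl, lo, hi
            )
        keep &= in_range
    n_excluded = int(len(rr) - np.count_nonzero(keep))
    return NNSeries(
        start_ms=start[keep],
        rr_ms=rr[keep],
        n_excluded=n_excluded,
        n_range_excluded=n_range_excl,
        meta=series.meta,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_WFDB_LABEL_MAP = {"N": "N", "V": "V", "S": "S", "A": "S", "a": "S", "J": "S"}


def read_beats(
    path: str | Path,
    dialect: str = "beats-csv",
    meta: Optional[RecordingMeta] = None,
) -> BeatSeries:
    """Read an annotated beat stream.

    Supported dialects: ``beats-csv`` (canonical columnar CSV) and
    ``wfdb-ann`` (WFDB annotation file, requires the optional ``wfdb``
    package). Unknown beat labels are kept but mapped to artifact (``A``)
    with a warning; non-monotonic times are a hard error naming the first
    offending data row.
    """
    path = Path(path)
    if dialect == "beats-csv":
        return _read_beats_csv(path, meta)
    if dialect == "wfdb-ann":
        return _read_wfdb_ann(path, meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_beats_csv(path: Path, meta: Optional[RecordingMeta]) -> BeatSeries:
    if not path.exists():
        raise FileNotFoundError(path)
    t_r: list[float] = []
    labels: list[str] = []
    morph: list[int] = []
    fid = {k: [] for k in ("p_on_ms", "qrs_on_ms", "qrs_off_ms", "t_end_ms", "fqrs")}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"empty beats file: {path}")
        missing = {"t_r_ms", "label"} - set(reader.fieldnames)
        if missing:
            raise ValueError(f"beats-csv missing required column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            t = float(row["t_r_ms"])
            if t_r and t <= t_r[-1]:
                raise ValueError(f"non-monotonic beat time at row {i}")
            lab = (row["label"] or "").strip()
            if lab not in VALID_LABELS:
                logger.warning(
                    "row %d: unknown label %r mapped to artifact 'A'", i, lab
                )
                lab = "A"
            t_r.append(t)
            labels.append(lab)
            morph.append(int(row.get("morph_id") or 0))
            for k in fid:
                cell = (row.get(k) or "").strip()
                fid[k].append(float(cell) if cell else np.nan)
    if not t_r:
        raise ValueError(f"empty beats file: {path}")
    if meta is None:
        meta = RecordingMeta(recording_id=path.stem)
    return BeatSeries(
        t_r=np.array(t_r),
        labels=np.array(labels, dtype="U1"),
        morph_id=np.array(morph, dtype=int),
        p_on=np.array(fid["p_on_ms"]),
        qrs_on=np.array(fid["qrs_on_ms"]),
        qrs_off=np.array(fid["qrs_off_ms"]),
        t_end=np.array(fid["t_end_ms"]),
        fqrs=np.array(fid["fqrs"]),
        meta=meta,
    )


def _read_wfdb_ann(path: Path, meta: Optional[RecordingMeta]) -> BeatSeries:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'wfdb-ann' dialect requires the optional wfdb package"
        ) from exc
    record = str(path.with_suffix(""))
    ext = path.suffix.lstrip(".") or "atr"
    ann = wfdb.rdann(record, ext)
    fs = float(ann.fs or 500.0)
    t_ms = np.asarray(ann.sample, dtype=float) / fs * 1000.0
    labels = []
    for sym in ann.symbol:
        mapped = _WFDB_LABEL_MAP.get(sym)
        if mapped is None:
            logger.warning("wfdb symbol %r mapped to artifact 'A'", sym)
            mapped = "A"
        labels.append(mapped)
    if meta is None:
        meta = RecordingMeta(recording_id=path.stem, fs_hz=fs)
    return BeatSeries(t_r=t_ms, labels=np.array(labels, dtype="U1"), meta=meta)


def write_beats(series: BeatSeries, path: str | Path) -> Path:
    """Write a BeatSeries in the canonical beats-csv dialect."""
    path = Path(path)

    def _cell(v: float) -> str:
        return "" if math.isnan(v) else repr(float(v))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(BEATS_CSV_HEADER)
        for i in range(len(series)):
            f = series.fqrs[i]
            w.writerow(
                [
                    repr(float(series.t_r[i])),
                    str(series.labels[i]),
                    int(series.morph_id[i]),
                    _cell(series.p_on[i]),
                    _cell(series.qrs_on[i]),
                    _cell(series.qrs_off[i]),
                    _cell(series.t_end[i]),
                    "" if math.isnan(f) else int(f),
                ]
            )
    return path


def write_summary(rows: Sequence[Mapping[str, object]], path: str | Path) -> Path:
    """Write per-recording summary rows as CSV.

    Column order is first-seen order across rows; floats are written with
    ``repr`` so a decimal-text round trip is exact. Absent values are empty
    cells, never zero.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("write_summary: no rows")
    columns: list[str] = []
    for row in rows:
        for k in row:
            if k not in columns:
                columns.append(k)
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            out = []
            for c in columns:
                v = row.get(c)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    out.append("")
                elif isinstance(v, float):
                    out.append(repr(v))
                else:
                    out.append(str(v))
            w.writerow(out)
    return path


def read_summary(path: str | Path):
    """Read a summary CSV written by :func:`write_summary` (pandas frame)."""
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")


def read_manifest(path: str | Path):
    """Read a cohort manifest CSV.

    Columns: ``subject,group,age_months,recording_path`` plus optional
    outcome/covariate columns (``lvfs_24m,ctni,ntprobnp``).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject", "group", "age_months", "recording_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    return df
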