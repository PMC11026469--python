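"""Trace-level ECG interval summaries and heart-rate correction of QT.

Four QT-correction formulas are provided (all take QT in ms and the
preceding RR in ms):

``B``  (Bazett)        QTc = QT / sqrt(RR_s)
``F``  (Fridericia)    QTc = QT / RR_s ** (1/3)
``V``  (Van de Water)  QTc = QT - 87 * (RR_s - 1)
``M``  (Matsunaga)     QTc = QT * log(600) / log(RR_ms)

B, F and V are the identity at RR = 1000 ms; M normalizes to RR = 600 ms
(its published reference cycle length), so it equals QT at RR = 600 ms.
The log base cancels in the ratio.

The selection procedure computes, per formula, the Pearson correlation of
QTc against HR and the OLS slope of QTc on HR, plus a Shapiro-Wilk
normality screen, and picks the formula that best decorrelates QTc from
heart rate (smallest |r|, ties broken by smaller |slope|).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core_beats import BeatSeries, clean_to_nn, DEFAULT_NN_RANGE_MS

logger = logging.getLogger(__name__)

QTC_FORMULAS = ("B", "F", "V", "M")

#: linear rate-correction coefficient of the Van de Water formula, ms per s of RR
VAN_DE_WATER_SLOPE_MS_PER_S = 87.0
#: reference cycle length of the Matsunaga formula, ms
MATSUNAGA_REF_RR_MS = 600.0


def qtc(qt_ms: float, rr_ms: float, formula: str) -> float:
    """Rate-corrected QT for one beat. ``rr_ms`` is the preceding RR."""
    if np.any(np.asarray(qt_ms) <= 0) or np.any(np.asarray(rr_ms) <= 0):
        raise ValueError("qt_ms and rr_ms must be positive")
    qt = np.asarray(qt_ms, dtype=float)
    rr_s = np.asarray(rr_ms, dtype=float) / 1000.0
    if formula == "B":
        out = qt / np.sqrt(rr_s)
    elif formula == "F":
        out = qt / np.cbrt(rr_s)
    elif formula == "V":
        out = qt - VAN_DE_WATER_SLOPE_MS_PER_S * (rr_s - 1.0)
    elif formula == "M":
        out = qt * math.log(MATSUNAGA_REF_RR_MS) / np.log(np.asarray(rr_ms, dtype=float))
    else:
        raise ValueError(f"unknown QTc formula {formula!r}")
    if np.ndim(qt_ms) == 0 and np.ndim(rr_ms) == 0:
        return float(out)
    return out


@dataclass
class IntervalSummary:
    """Whole-trace means of HR, PR, QT and the four corrected QTs."""

    hr_bpm: float
    pr_ms: Optional[float]
    qt_ms: Optional[float]
    qtc_ms: dict[str, float] = field(default_factory=dict)
    n_beats_used: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be positive")
        for name in ("pr_ms", "qt_ms"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


def summarize_intervals(
    series: BeatSeries,
    qtc_mode: str = "per-beat",
    nn_range_ms: Optional[tuple[float, float]] = DEFAULT_NN_RANGE_MS,
) -> IntervalSummary:
    """Average HR, PR, QT and QTc over the whole trace.

    HR is 60000 / mean NN. PR and QT are averaged over normal beats that
    carry the needed fiducials; beats lacking them are skipped and counted.
    QTc uses, per beat, the RR ending at that beat; beats following a non-N
    beat are skipped (post-extrasystolic RR bias). ``qtc_mode`` is
    ``"per-beat"`` (correct each beat, then average; default) or
    ``"trace-mean"`` (correct the trace-mean QT by the trace-mean NN).
    """
    if qtc_mode not in ("per-beat", "trace-mean"):
        raise ValueError(f"unknown qtc_mode {qtc_mode!r}")
    nn = clean_to_nn(series, nn_range_ms=nn_range_ms)
    if len(nn) == 0:
        raise ValueError("no NN intervals; cannot compute heart rate")
    mean_nn = nn.mean_nn
    hr = 60000.0 / mean_nn

    is_n = series.labels == "N"
    flags: list[str] = []
    n_used: dict[str, int] = {"nn": len(nn)}

    pr_all = series.qrs_on - series.p_on
    pr_ok = is_n & np.isfinite(pr_all) & (pr_all > 0)
    n_used["pr"] = int(pr_ok.sum())
    pr_ms = float(np.mean(pr_all[pr_ok])) if pr_ok.any() else None
    if pr_ms is None:
        flags.append("pr_absent_no_fiducials")

    qt_all = series.t_end - series.qrs_on
    qt_ok = is_n & np.isfinite(qt_all) & (qt_all > 0)
    n_used["qt"] = int(qt_ok.sum())
    qt_ms = float(np.mean(qt_all[qt_ok])) if qt_ok.any() else None
    if qt_ms is None:
        flags.append("qt_absent_no_fiducials")

    qtc_ms: dict[str, float] = {}
    if qt_ms is not None:
        if qtc_mode == "per-beat":
            rr_prev = np.diff(series.t_r)
            # beat i (i >= 1): own QT, preceded by an N beat, RR in guard range
            ok = qt_ok[1:] & is_n[:-1] & (rr_prev > 0)
            if nn_range_ms is not None:
                lo, hi = nn_range_ms
                ok &= (rr_prev >= lo) & (rr_prev <= hi)
            n_used["qtc"] = int(ok.sum())
            if ok.any():
                qts = qt_all[1:][ok]
                rrs = rr_prev[ok]
                for f in QTC_FORMULAS:
                    qtc_ms[f] = float(np.mean(qtc(qts, rrs, f)))
            else:
                flags.append("qtc_absent_no_eligible_beats")
        else:
            n_used["qtc"] = n_used["qt"]
            for f in QTC_FORMULAS:
                qtc_ms[f] = float(qtc(qt_ms, mean_nn, f))
    return IntervalSummary(
        hr_bpm=hr, pr_ms=pr_ms, qt_ms=qt_ms, qtc_ms=qtc_ms,
        n_beats_used=n_used, flags=flags,
    )


@dataclass
class FormulaFit:
    """Regression of one formula's QTc values against heart rate."""

    pearson_r: float
    slope: float
    shapiro_p: float
    n: int


@dataclass
class QtcSelectionResult:
    per_formula: dict[str, FormulaFit]
    selected: str
    normality_p: float

    def __post_init__(self) -> None:
        for f, fit in self.per_formula.items():
            if not -1.0 - 1e-12 <= fit.pearson_r <= 1.0 + 1e-12:
                raise ValueError(f"pearson r out of range for formula {f}")


def _shapiro_p(x: np.ndarray, max_n: int = 4999) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return float("nan")
    if len(x) > max_n:
        # Shapiro-Wilk is undefined for huge n; screen a deterministic stride sample
        idx = np.linspace(0, len(x) - 1, max_n).astype(int)
        x = x[idx]
    return float(stats.shapiro(x).pvalue)


def select_qtc(
    pairs: Sequence[tuple[float, float, float]] | np.ndarray,
    formulas: Sequence[str] = QTC_FORMULAS,
) -> QtcSelectionResult:
    """Pick the formula that best decorrelates QTc from heart rate.

    ``pairs`` are (hr_bpm, qt_ms, rr_ms) observations, either pooled beats
    or per-trace means (see :func:`qtc_pairs`). Selection minimizes |Pearson
    r| of QTc vs HR; ties are broken by smaller |OLS slope|.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("pairs must be (n, 3): hr_bpm, qt_ms, rr_ms")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 (hr, qt, rr) observations")
    hr, qt, rr = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.var(hr) == 0:
        raise ValueError("zero HR variance: correlation undefined")

    per: dict[str, FormulaFit] = {}
    for f in formulas:
        y = np.asarray(qtc(qt, rr, f), dtype=float)
        if np.ptp(y) == 0:
            r, slope = 0.0, 0.0  # perfectly decorrelated
        else:
            slope = float(np.cov(hr, y, ddof=0)[0, 1] / np.var(hr))
            r = float(np.corrcoef(hr, y)[0, 1])
        per[f] = FormulaFit(pearson_r=r, slope=slope, shapiro_p=_shapiro_p(y), n=len(y))
    selected = min(per, key=lambda f: (abs(per[f].pearson_r), abs(per[f].slope)))
    return QtcSelectionResult(
        per_formula=per, selected=selected, normality_p=per[selected].shapiro_p
    )


def qtc_pairs(
    series_list: Iterable[BeatSeries],
    mode: str = "per-beat",
    nn_range_ms: Optional[tuple[float, float]] = DEFAULT_NN_RANGE_MS,
) -> np.ndarray:
    """Assemble (hr, qt, rr) observations for :func:`select_qtc`.

    ``per-beat`` pools every eligible beat across traces, using each beat's
    instantaneous HR (60000/RR); ``trace-mean`` contributes one row of trace
    means per recording.
    """
    rows: list[tuple[float, float, float]] = []
    for series in series_list:
        if mode == "per-beat":
            is_n = series.labels == "N"
            qt_all = series.t_end - series.qrs_on
            rr_prev = np.diff(series.t_r)
            ok = (
                is_n[1:] & is_n[:-1]
                & np.isfinite(qt_all[1:]) & (qt_all[1:] > 0)
                & (rr_prev > 0)
            )
            if nn_range_ms is not None:
                lo, hi = nn_range_ms
                ok &= (rr_prev >= lo) & (rr_prev <= hi)
            for rr_i, qt_i in zip(rr_prev[ok], qt_all[1:][ok]):
                rows.append((60000.0 / rr_i, float(qt_i), float(rr_i)))
        elif mode == "trace-mean":
            s = summarize_intervals(series, qtc_mode="trace-mean", nn_range_ms=nn_range_ms)
            if s.qt_ms is None:
                logger.warning("trace without QT fiducials skipped in qtc_pairs")
                continue
            mean_nn = 60000.0 / s.hr_bpm
            rows.append((s.hr_bpm, s.qt_ms, mean_nn))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return np.asarray(rows, dtype=float)
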