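"""Time-domain HRV indices and Poincare-plot quantification.

All dispersion statistics use the population convention (divide by n).
Successive-difference indices (RMSSD, pNN50, pNN10%(meanNN), Poincare) use
only pairs of NN intervals that are contiguous in time — no cleaned-out
interval between them — so post-extrasystolic jumps created by cleaning do
not contaminate them.

Poincare conventions: for points (x, y) = (RR_n, RR_{n+1}), the short-term
variability STV (SD1) is the root-mean-square of (x - y)/sqrt(2), i.e. the
dispersion about the line of identity, which makes STV = RMSSD/sqrt(2) an
exact identity; the long-term variability LTV (SD2) is the mean-removed
population SD of (x + y)/sqrt(2), the dispersion along the identity line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_beats import NNSeries

logger = logging.getLogger(__name__)

#: triangular-index histogram bin width: one tick of a 128 Hz discretization
TRIANGULAR_BIN_MS = 1000.0 / 128.0


def _contiguous_diffs(nn: NNSeries) -> np.ndarray:
    """Successive NN differences (RR_{n+1} - RR_n) over contiguous pairs."""
    mask = nn.contiguous_pair_mask()
    return (nn.rr_ms[1:] - nn.rr_ms[:-1])[mask]


@dataclass
class TimeDomainHRV:
    mean_nn_ms: float
    sdnn_ms: float
    cv_rr: float
    rmssd_ms: Optional[float]
    hrv_ti: float
    pnn50_pct: Optional[float]
    pnn10pct_meanrr_pct: Optional[float]
    n_nn: int
    n_pairs: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sdnn_ms < 0 or self.cv_rr < 0:
            raise ValueError("dispersion indices must be >= 0")
        for name in ("pnn50_pct", "pnn10pct_meanrr_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")


def triangular_index(nn: NNSeries) -> float:
    """Total NN count over the modal bin count of the NN histogram.

    Bins are 1000/128 ms = 7.8125 ms wide and anchored at 0 (bin k covers
    [k*7.8125, (k+1)*7.8125)).
    """
    if len(nn) < 1:
        raise ValueError("need at least one NN interval")
    bins = np.floor(nn.rr_ms / TRIANGULAR_BIN_MS).astype(int)
    counts = np.bincount(bins)
    return float(len(nn) / counts.max())


def time_domain(nn: NNSeries, pnn_rel_threshold: float = 0.10) -> TimeDomainHRV:
    """Classical time-domain HRV indices for one recording.

    pNN50 counts contiguous successive differences exceeding 50 ms; the
    rate-adapted variant counts differences exceeding ``pnn_rel_threshold``
    (default 10 %) of the trace mean NN.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 NN intervals")
    rr = nn.rr_ms
    mean_nn = float(np.mean(rr))
    sdnn = float(np.std(rr))  # population SD
    cv = sdnn / mean_nn
    diffs = _contiguous_diffs(nn)
    flags: list[str] = []
    if diffs.size == 0:
        flags.append("no_contiguous_pairs_difference_indices_absent")
        rmssd = pnn50 = pnn10 = None
    else:
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size)
        thr = pnn_rel_threshold * mean_nn
        pnn10 = float(100.0 * np.count_nonzero(np.abs(diffs) > thr) / diffs.size)
    return TimeDomainHRV(
        mean_nn_ms=mean_nn,
        sdnn_ms=sdnn,
        cv_rr=cv,
        rmssd_ms=rmssd,
        hrv_ti=triangular_index(nn),
        pnn50_pct=pnn50,
        pnn10pct_meanrr_pct=pnn10,
        n_nn=len(nn),
        n_pairs=int(diffs.size),
        flags=flags,
    )


@dataclass
class PoincareHRV:
    stv_ms: float
    ltv_ms: float
    stv_ltv_ratio: Optional[float]
    points: np.ndarray  # (n_pairs, 2) array of (RR_n, RR_{n+1})

    def __post_init__(self) -> None:
        if self.stv_ms < 0 or self.ltv_ms < 0:
            raise ValueError("stv and ltv must be >= 0")


def poincare(nn: NNSeries) -> PoincareHRV:
    """Poincare-plot dispersions from contiguous (RR_n, RR_{n+1}) pairs."""
    mask = nn.contiguous_pair_mask()
    x = nn.rr_ms[:-1][mask]
    y = nn.rr_ms[1:][mask]
    if x.size < 2:
        raise ValueError("need at least 2 contiguous NN pairs")
    d = (x - y) / np.sqrt(2.0)
    s = (x + y) / np.sqrt(2.0)
    stv = float(np.sqrt(np.mean(d**2)))  # about the identity line
    ltv = float(np.std(s))  # population SD about the mean point
    ratio = stv / ltv if ltv > 0 else None
    return PoincareHRV(
        stv_ms=stv,
        ltv_ms=ltv,
        stv_ltv_ratio=ratio,
        points=np.column_stack([x, y]),
    )
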