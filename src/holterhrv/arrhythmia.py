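"""Ventricular ectopy quantification and Lown severity grading.

Grading order (highest applicable wins):
5 (R-on-T) > 4b (VT, run of more than 3) > 4a (doublets/triplets) >
3b (bigeminy) > 3a (isolated polymorphic) > 2 (isolated > 30/hr) >
1 (isolated < 30/hr) > 0 (none). A rate of exactly 30/hr grades 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_beats import BeatSeries, clean_to_nn

logger = logging.getLogger(__name__)

LOWN_GRADES = ("0", "1", "2", "3a", "3b", "4a", "4b", "5")

#: isolated-PVB rate separating Lown 1 from 2, events per hour
FREQUENT_PVB_PER_HR = 30.0
#: fallback R-on-T rule when the preceding T-end is unmarked:
#: coupling interval shorter than this fraction of the mean NN
R_ON_T_COUPLING_FRAC = 0.5


@dataclass(frozen=True)
class VRun:
    """A maximal run of consecutive ventricular beats."""

    start_index: int
    start_ms: float
    length: int


def find_runs(series: BeatSeries) -> list[VRun]:
    """Maximal runs of consecutive V-labelled beats, in time order."""
    runs: list[VRun] = []
    is_v = series.labels == "V"
    if not is_v.any():
        return runs
    padded = np.concatenate(([False], is_v, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    for s, e in zip(starts, ends):
        runs.append(VRun(start_index=int(s), start_ms=float(series.t_r[s]), length=int(e - s)))
    return runs


def detect_bigeminy(series: BeatSeries, min_alternations: int = 4) -> bool:
    """True iff >= ``min_alternations`` consecutive N,V pairs occur (N V N V ...)."""
    labels = series.labels
    n = len(labels)
    i = 0
    while i + 1 < n:
        if labels[i] == "N" and labels[i + 1] == "V":
            count = 0
            j = i
            while j + 1 < n and labels[j] == "N" and labels[j + 1] == "V":
                count += 1
                j += 2
            if count >= min_alternations:
                return True
            i = j
        else:
            i += 1
    return False


@dataclass(frozen=True)
class RonTResult:
    present: bool
    heuristic: bool  # True when the decision used the coupling fallback


def detect_r_on_t(series: BeatSeries) -> RonTResult:
    """R-on-T: a V beat firing before the preceding beat's T wave has ended.

    Primary rule compares the V beat's R time with the preceding beat's
    marked T end. When that fiducial is absent, a heuristic fallback flags
    couplings shorter than half the mean NN interval.
    """
    v_idx = np.nonzero(series.labels == "V")[0]
    v_idx = v_idx[v_idx >= 1]
    if v_idx.size == 0:
        return RonTResult(False, False)
    mean_nn: Optional[float] = None
    heuristic = False
    for i in v_idx:
        t_end_prev = series.t_end[i - 1]
        if np.isfinite(t_end_prev):
            if series.t_r[i] < t_end_prev:
                return RonTResult(True, False)
        else:
            if mean_nn is None:
                try:
                    nn = clean_to_nn(series)
                except ValueError:
                    continue
                if len(nn) == 0:
                    continue
                mean_nn = nn.mean_nn
            coupling = series.t_r[i] - series.t_r[i - 1]
            if coupling < R_ON_T_COUPLING_FRAC * mean_nn:
                heuristic = True
                logger.warning(
                    "R-on-T flagged by coupling heuristic (coupling %.0f ms, mean NN %.0f ms)",
                    coupling, mean_nn,
                )
                return RonTResult(True, True)
    return RonTResult(False, heuristic)


def is_polymorphic(series: BeatSeries) -> bool:
    """>= 2 distinct nonzero morphology ids among V beats.

    All-zero morph ids mean morphology was never assigned; monomorphic is
    then assumed with a logged caveat.
    """
    v_morphs = series.morph_id[series.labels == "V"]
    if v_morphs.size == 0:
        return False
    nonzero = np.unique(v_morphs[v_morphs != 0])
    if nonzero.size == 0:
        logger.warning("all V beats have morph_id 0; assuming monomorphic")
        return False
    return nonzero.size >= 2


def grade_lown(
    n_pvb: int,
    isolated_rate_per_hr: float,
    polymorphic: bool,
    bigeminy: bool,
    n_doublets: int,
    n_triplets: int,
    max_run_len: int,
    r_on_t: bool,
) -> str:
    """Highest applicable Lown grade for one trace."""
    if n_pvb == 0:
        return "0"
    if r_on_t:
        return "5"
    if max_run_len >= 4:
        return "4b"
    if n_doublets > 0 or n_triplets > 0:
        return "4a"
    if bigeminy:
        return "3b"
    if polymorphic:
        return "3a"
    if isolated_rate_per_hr >= FREQUENT_PVB_PER_HR:
        return "2"
    return "1"


@dataclass
class ArrhythmiaSummary:
    n_pvb: int
    pvb_per_hr: float
    pvb_pct: float
    n_isolated: int
    n_doublets: int
    n_triplets: int
    n_salvos: int
    max_run_len: int
    bigeminy: bool
    polymorphic: bool
    r_on_t: bool
    r_on_t_heuristic: bool
    lown: str
    duration_hr: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_pvb, self.n_isolated, self.n_doublets,
            self.n_triplets, self.n_salvos, self.max_run_len,
        )
        if any(c < 0 for c in counts):
            raise ValueError("arrhythmia counts must be >= 0")
        if (self.lown == "0") != (self.n_pvb == 0):
            raise ValueError("lown grade 0 iff no PVBs")

    def to_dict(self) -> dict:
        return {
            "n_pvb": self.n_pvb,
            "pvb_per_hr": self.pvb_per_hr,
            "pvb_pct": self.pvb_pct,
            "n_isolated": self.n_isolated,
            "n_doublets": self.n_doublets,
            "n_triplets": self.n_triplets,
            "n_salvos": self.n_salvos,
            "max_run_len": self.max_run_len,
            "bigeminy": self.bigeminy,
            "polymorphic": self.polymorphic,
            "r_on_t": self.r_on_t,
            "r_on_t_heuristic": self.r_on_t_heuristic,
            "lown": self.lown,
            "duration_hr": self.duration_hr,
            "flags": list(self.flags),
        }


def summarize_arrhythmia(
    series: BeatSeries, bigeminy_min_alternations: int = 4
) -> ArrhythmiaSummary:
    """Full ventricular-ectopy summary with Lown grade for one recording."""
    duration_hr = series.duration_ms / 3_600_000.0
    if duration_hr <= 0:
        raise ValueError("recording duration must be positive")
    runs = find_runs(series)
    n_pvb = int(np.count_nonzero(series.labels == "V"))
    n_isolated = sum(1 for r in runs if r.length == 1)
    n_doublets = sum(1 for r in runs if r.length == 2)
    n_triplets = sum(1 for r in runs if r.length == 3)
    n_salvos = sum(1 for r in runs if r.length >= 4)
    max_run = max((r.length for r in runs), default=0)
    big = detect_bigeminy(series, min_alternations=bigeminy_min_alternations)
    ront = detect_r_on_t(series)
    poly = is_polymorphic(series)
    flags: list[str] = []
    if ront.heuristic:
        flags.append("r_on_t_coupling_heuristic")
    if n_pvb and not (series.morph_id[series.labels == "V"] != 0).any():
        flags.append("morphology_unassigned_monomorphic_assumed")
    total = len(series)
    isolated_rate = n_isolated / duration_hr
    lown = grade_lown(
        n_pvb=n_pvb,
        isolated_rate_per_hr=isolated_rate,
        polymorphic=poly,
        bigeminy=big,
        n_doublets=n_doublets,
        n_triplets=n_triplets,
        max_run_len=max_run,
        r_on_t=ront.present,
    )
    return ArrhythmiaSummary(
        n_pvb=n_pvb,
        pvb_per_hr=n_pvb / duration_hr,
        pvb_pct=100.0 * n_pvb / total if total else 0.0,
        n_isolated=n_isolated,
        n_doublets=n_doublets,
        n_triplets=n_triplets,
        n_salvos=n_salvos,
        max_run_len=max_run,
        bigeminy=big,
        polymorphic=poly,
        r_on_t=ront.present,
        r_on_t_heuristic=ront.heuristic,
        lown=lown,
        duration_hr=duration_hr,
        flags=flags,
    )
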