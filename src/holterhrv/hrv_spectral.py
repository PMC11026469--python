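"""Frequency-domain HRV: epoching, Welch spectra of the NN tachogram, band powers.

The NN tachogram is resampled to an even grid (default 2 Hz) by linear
interpolation of interval durations at interval end times; cleaning gaps
longer than ``max_gap_s`` are not interpolated across and split the epoch
into independent stretches. Each 15-min epoch is analysed with 512-sample
rectangular-window segments (50 % overlap, per-segment mean removal),
periodograms scaled so the integral over (0, Nyquist] equals the tachogram
variance in ms^2, and band powers integrated by the rectangle rule over
bins whose centre lies in the half-open band [low, high).

Bands (Hz): VLF 0.003-0.04, LF 0.04-0.15, HF 0.15-0.4. Total power is
defined as VLF + LF + HF; HF n.u. = 100 * HF / (LF + HF).

Note on segment geometry: a 512-point transform spanning a full 15-min
epoch would imply a ~0.57 Hz sampling whose Nyquist (~0.28 Hz) cannot reach
the 0.4 Hz upper edge of the HF band; the band edges are treated as
authoritative, hence the 2 Hz resampling with Welch-averaged 512-point
segments inside each epoch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core_beats import NNSeries

logger = logging.getLogger(__name__)

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class SpectralConfig:
    resample_hz: float = 2.0
    epoch_min: float = 15.0
    min_coverage: float = 0.8
    nperseg: int = 512
    overlap: float = 0.5
    max_gap_s: float = 5.0


def combine_band_powers(vlf: float, lf: float, hf: float) -> float:
    """Total power under the band-additivity convention: VLF + LF + HF."""
    return vlf + lf + hf


@dataclass
class SpectralEpoch:
    start_ms: float
    coverage_frac: float
    used: bool
    reject_reason: Optional[str] = None
    vlf_ms2: Optional[float] = None
    lf_ms2: Optional[float] = None
    hf_ms2: Optional[float] = None
    total_ms2: Optional[float] = None
    lf_hf: Optional[float] = None
    hf_nu_pct: Optional[float] = None
    n_segments: int = 0
    vlf_estimable: bool = True


@dataclass
class SpectralSummary:
    epochs: list[SpectralEpoch]
    mean_vlf_ms2: Optional[float]
    mean_lf_ms2: Optional[float]
    mean_hf_ms2: Optional[float]
    mean_total_ms2: Optional[float]
    mean_lf_hf: Optional[float]
    mean_hf_nu_pct: Optional[float]
    n_epochs_used: int
    n_epochs_rejected: int
    flags: list[str] = field(default_factory=list)


def epochize(
    nn: NNSeries,
    duration_ms: Optional[float] = None,
    config: SpectralConfig = SpectralConfig(),
) -> list[SpectralEpoch]:
    """Contiguous non-overlapping epochs from recording start.

    Coverage is the fraction of the (full-length) epoch window covered by
    kept NN time; epochs under ``min_coverage`` are rejected with a reason.
    A trailing partial window is included (and rejected on coverage).
    """
    if duration_ms is None:
        duration_ms = nn.duration_ms
    epoch_ms = config.epoch_min * 60_000.0
    n_epochs = max(int(math.ceil(duration_ms / epoch_ms)), 0)
    epochs: list[SpectralEpoch] = []
    starts = nn.start_ms
    ends = nn.end_ms
    for k in range(n_epochs):
        t0 = k * epoch_ms
        t1 = t0 + epoch_ms
        covered = np.clip(np.minimum(ends, t1) - np.maximum(starts, t0), 0.0, None).sum()
        frac = float(covered / epoch_ms)
        if frac >= config.min_coverage:
            epochs.append(SpectralEpoch(start_ms=t0, coverage_frac=frac, used=True))
        else:
            reason = f"coverage {frac:.2f} below threshold {config.min_coverage:.2f}"
            logger.info("epoch at %.0f ms rejected: %s", t0, reason)
            epochs.append(
                SpectralEpoch(start_ms=t0, coverage_frac=frac, used=False, reject_reason=reason)
            )
    return epochs


def _tachogram_grid(
    nn: NNSeries, t0: float, t1: float, config: SpectralConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly sampled tachogram on [t0, t1) plus a validity mask.

    Samples are valid when bracketed by tachogram points (interval end
    times) no further apart than ``max_gap_s``.
    """
    dt_ms = 1000.0 / config.resample_hz
    n = int(round((t1 - t0) / dt_ms))
    grid = t0 + np.arange(n) * dt_ms
    # tachogram support: a margin around the epoch so edge samples interpolate
    margin = config.max_gap_s * 1000.0
    sel = (nn.end_ms >= t0 - margin) & (nn.end_ms <= t1 + margin)
    times = nn.end_ms[sel]
    values = nn.rr_ms[sel]
    if times.size < 2:
        return grid, np.zeros(n, dtype=bool)
    vals = np.interp(grid, times, values)
    idx = np.searchsorted(times, grid)
    valid = (idx > 0) & (idx < times.size)
    gap_ok = np.zeros(n, dtype=bool)
    inb = valid.nonzero()[0]
    if inb.size:
        gaps = times[idx[inb]] - times[idx[inb] - 1]
        gap_ok[inb] = gaps <= config.max_gap_s * 1000.0
    return np.where(gap_ok, vals, np.nan), gap_ok


def _welch_runs(
    x: np.ndarray, valid: np.ndarray, config: SpectralConfig
) -> tuple[Optional[np.ndarray], Optional[np.ndarray], int]:
    """Average Welch periodograms over contiguous valid stretches.

    Returns (freqs, mean PSD density, total segment count); stretches shorter
    than one segment are skipped.
    """
    fs = config.resample_hz
    nps = config.nperseg
    nov = int(round(nps * config.overlap))
    step = nps - nov
    padded = np.concatenate(([False], valid, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    psd_sum = None
    freqs = None
    n_segments = 0
    for s, e in zip(starts, ends):
        run = x[s:e]
        if run.size < nps:
            continue
        nseg = 1 + (run.size - nps) // step
        f, pxx = signal.welch(
            run,
            fs=fs,
            window="boxcar",
            nperseg=nps,
            noverlap=nov,
            detrend="constant",
            scaling="density",
        )
        if psd_sum is None:
            psd_sum = pxx * nseg
            freqs = f
        else:
            psd_sum += pxx * nseg
        n_segments += nseg
    if n_segments == 0:
        return None, None, 0
    return freqs, psd_sum / n_segments, n_segments


def band_power(
    nn: NNSeries,
    t0: float,
    t1: float,
    config: SpectralConfig = SpectralConfig(),
) -> tuple[float, float, float, float, int]:
    """(vlf, lf, hf, total) band powers in ms^2 for one epoch, plus segment count.

    Raises ``ValueError`` when the epoch yields no stretch long enough for a
    single analysis segment.
    """
    vals, valid = _tachogram_grid(nn, t0, t1, config)
    x = np.where(valid, vals, 0.0)
    freqs, psd, n_segments = _welch_runs(x, valid, config)
    if n_segments == 0:
        raise ValueError("epoch too short after resampling: no full analysis segment")
    df = freqs[1] - freqs[0]
    powers = []
    for lo, hi in (VLF_BAND, LF_BAND, HF_BAND):
        in_band = (freqs >= lo) & (freqs < hi)
        powers.append(float(np.sum(psd[in_band]) * df))
    vlf, lf, hf = powers
    return vlf, lf, hf, combine_band_powers(vlf, lf, hf), n_segments


def spectral_summary(
    nn: NNSeries,
    duration_ms: Optional[float] = None,
    config: SpectralConfig = SpectralConfig(),
) -> SpectralSummary:
    """Per-epoch band powers plus arithmetic means over used epochs."""
    epochs = epochize(nn, duration_ms=duration_ms, config=config)
    epoch_ms = config.epoch_min * 60_000.0
    flags: list[str] = []
    vlf_cycles = (config.epoch_min * 60.0) * VLF_BAND[0]
    vlf_estimable = vlf_cycles >= 3.0
    if not vlf_estimable:
        flags.append(
            f"vlf_estimability_warning_{vlf_cycles:.1f}_cycles_of_band_floor_in_epoch"
        )
    for ep in epochs:
        if not ep.used:
            continue
        try:
            vlf, lf, hf, total, nseg = band_power(
                nn, ep.start_ms, ep.start_ms + epoch_ms, config
            )
        except ValueError as exc:
            ep.used = False
            ep.reject_reason = str(exc)
            continue
        ep.vlf_ms2, ep.lf_ms2, ep.hf_ms2, ep.total_ms2 = vlf, lf, hf, total
        ep.n_segments = nseg
        ep.lf_hf = lf / hf if hf > 0 else None
        ep.hf_nu_pct = 100.0 * hf / (lf + hf) if (lf + hf) > 0 else None
        ep.vlf_estimable = vlf_estimable
    used = [e for e in epochs if e.used]
    n_rejected = len(epochs) - len(used)

    def _mean(attr: str) -> Optional[float]:
        vals = [getattr(e, attr) for e in used if getattr(e, attr) is not None]
        return float(np.mean(vals)) if vals else None

    if not used:
        flags.append("no_usable_epochs")
    return SpectralSummary(
        epochs=epochs,
        mean_vlf_ms2=_mean("vlf_ms2"),
        mean_lf_ms2=_mean("lf_ms2"),
        mean_hf_ms2=_mean("hf_ms2"),
        mean_total_ms2=_mean("total_ms2"),
        mean_lf_hf=_mean("lf_hf"),
        mean_hf_nu_pct=_mean("hf_nu_pct"),
        n_epochs_used=len(used),
        n_epochs_rejected=n_rejected,
        flags=flags,
    )
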