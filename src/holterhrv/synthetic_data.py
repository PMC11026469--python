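"""Synthetic beat streams and cohorts with known ground truth.

Beat times come from integral-pulse-frequency-modulation (IPFM): an
instantaneous heart-period signal m(t) = base_rr + sum of modulators (ms)
drives a counter that fires a beat whenever the integral of dt/m(t) accrues
one unit, so modulator frequencies are defined in real time (Hz) exactly as
the downstream band analysis assumes. Sinusoidal modulators of amplitude
``a`` plant a tachogram band power of a^2/2 ms^2; band-limited noise
modulators are expanded into equal-amplitude random-phase sinusoids whose
powers sum to the requested target.

Ectopy is injected afterwards by replacing sinus beats with premature V
beats at a configurable coupling fraction of the local NN; the sinus clock
is untouched for a fully compensatory pause (factor 2.0), or subsequent
beats are shifted for other factors. Every generator is deterministic given
its seed, and a ground-truth event log / truth table is emitted alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core_beats import (
    BeatSeries,
    RecordingMeta,
    write_beats,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# generative parameter objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sinusoid:
    """One deterministic RR modulator: rr(t) += amp * sin(2*pi*f*t + phase)."""

    freq_hz: float
    amp_ms: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amp_ms < 0:
            raise ValueError("modulator amplitude must be >= 0")


@dataclass(frozen=True)
class BandNoise:
    """Band-limited stochastic modulator with a target total power in ms^2.

    Realized as ``n_components`` equal-power sinusoids at rng-drawn
    frequencies (uniform in the band) and phases.
    """

    low_hz: float
    high_hz: float
    power_ms2: float
    n_components: int = 24

    def __post_init__(self) -> None:
        if self.power_ms2 < 0:
            raise ValueError("band power must be >= 0")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class RSA:
    """Respiratory sinus arrhythmia: a sinusoid at the breathing frequency."""

    amp_ms: float
    breathing_hz: float = 0.25


@dataclass(frozen=True)
class FiducialLaws:
    """HR-dependent wave-timing laws used to place per-beat fiducials.

    PR = pr_intercept + pr_slope * RR (ms); QT = qt_intercept +
    qt_rr_slope * (RR_s - 1) (ms). Gaussian noise SDs apply per beat.
    """

    pr_intercept_ms: float = 40.0
    pr_slope: float = 0.08
    qt_intercept_ms: float = 230.0
    qt_rr_slope_ms_per_s: float = 87.0
    pr_noise_sd_ms: float = 0.0
    qt_noise_sd_ms: float = 0.0
    qrs_width_ms: float = 40.0


@dataclass(frozen=True)
class EctopySpec:
    """Grammar of injected premature ventricular beats."""

    rate_per_hr: float = 0.0
    coupling_frac: float = 0.6
    compensatory_factor: float = 2.0
    #: run length -> probability; defaults to isolated PVBs only
    run_length_probs: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    bigeminy: bool = False
    n_bigeminy_pairs: int = 6
    r_on_t: bool = False
    morph_ids: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not 0 < self.coupling_frac < 1:
            raise ValueError("coupling_frac must be in (0, 1)")
        total = sum(self.run_length_probs.values())
        if self.run_length_probs and abs(total - 1.0) > 1e-9:
            raise ValueError("run_length_probs must sum to 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of one synthetic recording."""

    duration_min: float
    base_rr_ms: float = 500.0
    modulators: tuple = ()
    rsa: Optional[RSA] = None
    ectopy: Optional[EctopySpec] = None
    fiducials: Optional[FiducialLaws] = FiducialLaws()
    seed: int = 0
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        if not 200.0 <= self.base_rr_ms <= 3000.0:
            raise ValueError("base_rr_ms must lie in [200, 3000] ms")
        power = self.planted_power_ms2()
        if power >= (self.base_rr_ms / 3.0) ** 2:
            raise ValueError("modulation too deep: planted power too large for base RR")

    def planted_power_ms2(self) -> float:
        """Total tachogram power the modulators are meant to plant (ms^2)."""
        p = 0.0
        for m in self.modulators:
            if isinstance(m, Sinusoid):
                p += m.amp_ms**2 / 2.0
            elif isinstance(m, BandNoise):
                p += m.power_ms2
            else:
                raise TypeError(f"unknown modulator type {type(m)!r}")
        if self.rsa is not None:
            p += self.rsa.amp_ms**2 / 2.0
        return p


# ---------------------------------------------------------------------------
# beat generation (IPFM)
# ---------------------------------------------------------------------------

_IPFM_DT_MS = 10.0  # integration grid; far finer than any modulator period


def _expand_modulators(spec: SyntheticSpec, rng: np.random.Generator) -> list[Sinusoid]:
    comps: list[Sinusoid] = []
    for m in spec.modulators:
        if isinstance(m, Sinusoid):
            comps.append(m)
        elif isinstance(m, BandNoise):
            amp = math.sqrt(2.0 * m.power_ms2 / m.n_components)
            freqs = rng.uniform(m.low_hz, m.high_hz, size=m.n_components)
            phases = rng.uniform(0.0, 2.0 * math.pi, size=m.n_components)
            comps.extend(
                Sinusoid(freq_hz=float(f), amp_ms=amp, phase_rad=float(ph))
                for f, ph in zip(freqs, phases)
            )
    if spec.rsa is not None:
        comps.append(Sinusoid(freq_hz=spec.rsa.breathing_hz, amp_ms=spec.rsa.amp_ms))
    return comps


def gen_beats(spec: SyntheticSpec) -> BeatSeries:
    """Generate an all-normal beat stream by IPFM from the heart-period signal."""
    rng = np.random.default_rng(spec.seed)
    duration_ms = spec.duration_min * 60_000.0
    t = np.arange(0.0, duration_ms + _IPFM_DT_MS, _IPFM_DT_MS)
    m = np.full_like(t, spec.base_rr_ms)
    for comp in _expand_modulators(spec, rng):
        m += comp.amp_ms * np.sin(2.0 * math.pi * comp.freq_hz * (t / 1000.0) + comp.phase_rad)
    if m.min() <= 0:
        raise ValueError("modulation too deep: instantaneous heart period <= 0")
    u = cumulative_trapezoid(1.0 / m, t, initial=0.0)
    n_beats = int(math.floor(u[-1]))
    ks = np.arange(0, n_beats + 1, dtype=float)  # beat 0 fires at t = 0
    beat_t = np.interp(ks, u, t)
    beat_t = beat_t[beat_t <= duration_ms]
    labels = np.full(len(beat_t), "N", dtype="U1")
    meta = replace(spec.meta, duration_ms=duration_ms, seed=spec.seed)

    fid: dict[str, Optional[np.ndarray]] = dict(
        p_on=None, qrs_on=None, qrs_off=None, t_end=None
    )
    if spec.fiducials is not None:
        law = spec.fiducials
        rr_prev = np.empty(len(beat_t))
        rr_prev[1:] = np.diff(beat_t)
        rr_prev[0] = spec.base_rr_ms
        half_qrs = law.qrs_width_ms / 2.0
        qrs_on = beat_t - half_qrs
        qrs_off = beat_t + half_qrs
        pr = law.pr_intercept_ms + law.pr_slope * rr_prev
        qt = law.qt_intercept_ms + law.qt_rr_slope_ms_per_s * (rr_prev / 1000.0 - 1.0)
        if law.pr_noise_sd_ms > 0:
            pr = pr + rng.normal(0.0, law.pr_noise_sd_ms, size=len(pr))
        if law.qt_noise_sd_ms > 0:
            qt = qt + rng.normal(0.0, law.qt_noise_sd_ms, size=len(qt))
        fid["p_on"] = qrs_on - pr
        fid["qrs_on"] = qrs_on
        fid["qrs_off"] = qrs_off
        fid["t_end"] = qrs_on + qt
        # the very first beat's p_on may fall before t = 0; drop its fiducials
        if len(beat_t) and fid["p_on"][0] < 0:
            for k in fid:
                fid[k][0] = np.nan
    return BeatSeries(t_r=beat_t, labels=labels, meta=meta, **fid)


# ---------------------------------------------------------------------------
# ectopy injection
# ---------------------------------------------------------------------------


def inject_ectopy(
    series: BeatSeries, espec: EctopySpec, seed: int = 0
) -> tuple[BeatSeries, pd.DataFrame]:
    """Replace sinus beats with premature V beats per the ectopy grammar.

    Returns the modified series plus a ground-truth event log (one row per
    planted event: type, first beat index, time, run length, morph ids).
    Raises when the requested rate cannot be placed without overlap.
    """
    if (series.labels != "N").any():
        raise ValueError("inject_ectopy expects an all-N series")
    rng = np.random.default_rng(seed)
    n = len(series)
    duration_hr = series.duration_ms / 3_600_000.0

    t_r = series.t_r.copy()
    labels = series.labels.copy()
    morph = series.morph_id.copy()
    p_on = series.p_on.copy()
    qrs_on = series.qrs_on.copy()
    qrs_off = series.qrs_off.copy()
    t_end = series.t_end.copy()
    blocked = np.zeros(n, dtype=bool)

    lengths = sorted(espec.run_length_probs)
    probs = np.array([espec.run_length_probs[k] for k in lengths], dtype=float)

    events: list[dict] = []

    def _mark_run(i: int, run_len: int, ev_type: str, r_on_t: bool) -> None:
        rr_local = t_r[i] - t_r[i - 1]
        coupling = espec.coupling_frac * rr_local
        if r_on_t:
            prev_t_end = t_end[i - 1]
            if np.isfinite(prev_t_end):
                first = prev_t_end - 10.0
            else:
                first = t_r[i - 1] + 0.3 * rr_local
            coupling = first - t_r[i - 1]
        morphs = []
        for j in range(run_len):
            k = i + j
            t_new = t_r[i - 1] + coupling * (j + 1)
            mid = espec.morph_ids[
                int(rng.integers(len(espec.morph_ids))) if len(espec.morph_ids) > 1 else 0
            ]
            t_r[k] = t_new
            labels[k] = "V"
            morph[k] = mid
            morphs.append(mid)
            # ventricular complexes: wide QRS, no P wave
            half = 35.0
            p_on[k] = np.nan
            qrs_on[k] = t_new - half
            qrs_off[k] = t_new + half
            if np.isfinite(t_end[k]):
                t_end[k] = qrs_on[k] + 200.0
        blocked[max(i - 2, 0) : min(i + run_len + 2, n)] = True
        if espec.compensatory_factor != 2.0 and i + run_len < n:
            last_v = t_r[i + run_len - 1]
            desired_next = last_v + (espec.compensatory_factor - espec.coupling_frac) * rr_local
            shift = desired_next - t_r[i + run_len]
            t_r[i + run_len :] += shift
            for col in (p_on, qrs_on, qrs_off, t_end):
                col[i + run_len :] += shift
        events.append(
            dict(
                type=ev_type,
                index=i,
                t_ms=float(t_r[i]),
                run_length=run_len,
                morph_ids=",".join(str(m) for m in morphs),
            )
        )

    # optional structured patterns first (they reserve room)
    if espec.bigeminy:
        need = 2 * espec.n_bigeminy_pairs + 2
        if n < need + 4:
            raise ValueError("series too short for requested bigeminy stretch")
        start = n // 3
        for k in range(espec.n_bigeminy_pairs):
            _mark_run(start + 2 * k + 1, 1, "bigeminy", False)

    n_events = int(round(espec.rate_per_hr * duration_hr))
    if n_events:
        max_len = max(lengths)
        candidates = np.arange(2, n - max_len - 2)
        rng.shuffle(candidates)
        placed = 0
        want_r_on_t = espec.r_on_t
        for i in candidates:
            if placed >= n_events:
                break
            run_len = int(rng.choice(lengths, p=probs))
            if blocked[i - 2 : i + run_len + 2].any():
                continue
            _mark_run(int(i), run_len, "r_on_t" if want_r_on_t else "pvb", want_r_on_t)
            want_r_on_t = False
            placed += 1
        if placed < n_events:
            raise ValueError(
                f"ectopy rate too high to place without overlap: placed {placed}/{n_events}"
            )
    elif espec.r_on_t:
        # explicit R-on-T toggle with no background rate: plant one event
        i = n // 2
        if i < 2 or i > n - 3:
            raise ValueError("series too short to plant an R-on-T event")
        _mark_run(i, 1, "r_on_t", True)

    out = BeatSeries(
        t_r=t_r,
        labels=labels,
        morph_id=morph,
        p_on=p_on,
        qrs_on=qrs_on,
        qrs_off=qrs_off,
        t_end=t_end,
        fqrs=series.fqrs.copy(),
        meta=series.meta,
    )
    log = pd.DataFrame(events, columns=["type", "index", "t_ms", "run_length", "morph_ids"])
    return out, log


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: healthy-group mean HR (bpm) by age in months; intermediate ages interpolate
DEFAULT_HR_BY_AGE = {2.0: 133.0, 4.0: 120.0, 6.0: 106.0, 9.0: 92.0, 12.0: 79.0, 24.0: 68.0}
#: healthy-group planted band powers (ms^2) by age; dystrophic scaling applies
#: on top. Kept modest so the worst-case subject factor still leaves the
#: instantaneous heart period positive.
DEFAULT_VLF_BY_AGE = {2.0: 150.0, 4.0: 300.0, 6.0: 450.0, 12.0: 700.0, 24.0: 900.0}
DEFAULT_LF_BY_AGE = {2.0: 170.0, 4.0: 300.0, 6.0: 450.0, 12.0: 800.0, 24.0: 1000.0}
DEFAULT_HF_BY_AGE = {2.0: 400.0, 4.0: 650.0, 6.0: 1000.0, 12.0: 1500.0, 24.0: 1700.0}


def _interp_age(table: dict[float, float], age: float) -> float:
    ages = np.array(sorted(table))
    vals = np.array([table[a] for a in ages])
    return float(np.interp(age, ages, vals))


@dataclass(frozen=True)
class GroupEffects:
    """Dystrophic-group deviations from the healthy age laws."""

    delta_hr_bpm: float = 20.0
    vlf_factor: float = 0.35
    lf_factor: float = 1.0
    hf_factor: float = 0.8
    qtc_shift_ms: float = 10.0
    #: isolated-PVB rate per hour by age (months)
    ectopy_rate_by_age: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OutcomeLaw:
    """Planted late-outcome law: lvfs_24m = alpha + beta * VLF(predictor age) + eps."""

    alpha: float = 18.0
    beta_per_ms2: float = 0.004
    eps_sd: float = 0.3
    predictor_age: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 8
    timepoints: tuple[float, ...] = (2.0, 4.0, 12.0, 24.0)
    duration_min: float = 16.0
    hr_by_age: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_HR_BY_AGE))
    hr_subject_sd: float = 5.0
    vlf_by_age: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_VLF_BY_AGE))
    lf_by_age: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_LF_BY_AGE))
    hf_by_age: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_HF_BY_AGE))
    #: log-normal sigma of the per-subject spectral scaling (drives the outcome spread)
    power_subject_sigma: float = 0.5
    group_effects: GroupEffects = field(default_factory=GroupEffects)
    outcome: OutcomeLaw = field(default_factory=OutcomeLaw)
    include_fiducials: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_subject_sd < 0 or self.power_subject_sigma < 0:
            raise ValueError("spread parameters must be >= 0")


def build_subject_spec(
    cspec: CohortSpec,
    group: str,
    age: float,
    hr_offset_bpm: float,
    power_factor: float,
    seed: int,
    subject_id: str = "",
) -> tuple[SyntheticSpec, dict]:
    """Per-recording SyntheticSpec plus its planted-truth record."""
    eff = cspec.group_effects
    grmd = group == "GRMD"
    hr = _interp_age(cspec.hr_by_age, age) + hr_offset_bpm + (eff.delta_hr_bpm if grmd else 0.0)
    base_rr = 60000.0 / hr
    vlf = _interp_age(cspec.vlf_by_age, age) * power_factor * (eff.vlf_factor if grmd else 1.0)
    lf = _interp_age(cspec.lf_by_age, age) * power_factor * (eff.lf_factor if grmd else 1.0)
    hf = _interp_age(cspec.hf_by_age, age) * power_factor * (eff.hf_factor if grmd else 1.0)
    modulators = (
        BandNoise(0.004, 0.039, vlf),
        BandNoise(0.041, 0.149, lf),
    )
    rsa = RSA(amp_ms=math.sqrt(2.0 * hf), breathing_hz=0.25)
    fiducials = None
    if cspec.include_fiducials:
        fiducials = FiducialLaws(
            qt_intercept_ms=230.0 + (eff.qtc_shift_ms if grmd else 0.0),
            pr_noise_sd_ms=1.0,
            qt_noise_sd_ms=2.0,
        )
    ectopy = None
    rate = _interp_age(eff.ectopy_rate_by_age, age) if (grmd and eff.ectopy_rate_by_age) else 0.0
    if rate > 0:
        ectopy = EctopySpec(rate_per_hr=rate)
    spec = SyntheticSpec(
        duration_min=cspec.duration_min,
        base_rr_ms=base_rr,
        modulators=modulators,
        rsa=rsa,
        ectopy=ectopy,
        fiducials=fiducials,
        seed=seed,
        meta=RecordingMeta(
            recording_id=f"{subject_id}_{age:g}m", subject_id=subject_id,
            group=group, age_months=age,
        ),
    )
    truth = dict(
        subject=subject_id, group=group, age_months=age, hr_true_bpm=hr,
        base_rr_ms=base_rr, vlf_true_ms2=vlf, lf_true_ms2=lf, hf_true_ms2=hf,
        ectopy_rate_per_hr=rate, seed=seed,
    )
    return spec, truth


def gen_cohort(
    cspec: CohortSpec, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full synthetic cohort to disk; return (manifest, truth table).

    Layout under ``out_dir``: one beats-csv per subject x timepoint,
    ``manifest.csv`` (with the planted lvfs_24m outcome and simple biomarker
    covariates) and ``truth.csv`` recording every planted parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cspec.seed)
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    subjects = [("GRMD", i) for i in range(cspec.n_per_group)] + [
        ("healthy", i) for i in range(cspec.n_per_group)
    ]
    # per-group spectral random effects are stratified log-normal (shuffled
    # quantiles): same marginal spread as free draws, but no accidental
    # clumping of two subjects at near-identical planted power, and the
    # quantile bound keeps IPFM positivity for every subject
    from scipy.stats import norm

    seqs = root.spawn(len(subjects) + 1)
    strat_rng = np.random.default_rng(seqs[0])
    n = cspec.n_per_group
    quantiles = norm.ppf((np.arange(n) + 0.5) / n) * cspec.power_subject_sigma
    factors = {
        g: np.exp(strat_rng.permutation(quantiles)) for g in ("GRMD", "healthy")
    }
    child_seqs = seqs[1:]
    for (group, i), seq in zip(subjects, child_seqs):
        subject_id = f"{'grmd' if group == 'GRMD' else 'ctrl'}{i:02d}"
        srng = np.random.default_rng(seq)
        hr_offset = float(srng.normal(0.0, cspec.hr_subject_sd))
        power_factor = float(factors[group][i])
        # planted outcome uses the true VLF at the predictor age
        vlf_pred = (
            _interp_age(cspec.vlf_by_age, cspec.outcome.predictor_age)
            * power_factor
            * (cspec.group_effects.vlf_factor if group == "GRMD" else 1.0)
        )
        lvfs = (
            cspec.outcome.alpha
            + cspec.outcome.beta_per_ms2 * vlf_pred
            + float(srng.normal(0.0, cspec.outcome.eps_sd))
        )
        ctni = max(float(srng.normal(0.08 if group == "GRMD" else 0.02, 0.01)), 0.0)
        ntprobnp = max(float(srng.normal(900.0 if group == "GRMD" else 500.0, 150.0)), 0.0)
        for age in cspec.timepoints:
            rec_seed = int(srng.integers(0, 2**31 - 1))
            spec, truth = build_subject_spec(
                cspec, group, age, hr_offset, power_factor, rec_seed, subject_id
            )
            series = gen_beats(spec)
            if spec.ectopy is not None:
                series, _log = inject_ectopy(series, spec.ectopy, seed=rec_seed + 1)
            rel = f"{subject_id}_{age:g}m.csv"
            write_beats(series, out_dir / rel)
            manifest_rows.append(
                dict(
                    subject=subject_id, group=group, age_months=age,
                    recording_path=rel, lvfs_24m=lvfs, ctni=ctni, ntprobnp=ntprobnp,
                )
            )
            truth.update(lvfs_24m=lvfs)
            truth_rows.append(truth)
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return manifest, truth
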