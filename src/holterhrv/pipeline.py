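"""Per-recording orchestration into TraceSummary rows and the cohort stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .arrhythmia import ArrhythmiaSummary, summarize_arrhythmia
from .cohort_stats import (
    CorrelationResult,
    GroupComparisonResult,
    early_late_screen,
    lsd_compare,
    to_long,
)
from .core_beats import (
    BeatSeries,
    clean_to_nn,
    read_beats,
    read_manifest,
    write_summary,
)
from .hrv_spectral import SpectralConfig, SpectralSummary, spectral_summary
from .hrv_time import PoincareHRV, TimeDomainHRV, poincare, time_domain
from .intervals_qtc import IntervalSummary, summarize_intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Single configuration object governing every analysis stage."""

    nn_range_ms: Optional[tuple[float, float]] = (200.0, 3000.0)
    qtc_mode: str = "per-beat"
    bigeminy_min_alternations: int = 4
    pnn_rel_threshold: float = 0.10
    resample_hz: float = 2.0
    epoch_min: float = 15.0
    min_coverage: float = 0.8
    max_gap_s: float = 5.0

    @property
    def spectral(self) -> SpectralConfig:
        return SpectralConfig(
            resample_hz=self.resample_hz,
            epoch_min=self.epoch_min,
            min_coverage=self.min_coverage,
            max_gap_s=self.max_gap_s,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML (or JSON) mapping mirroring the CLI flags."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        if "nn_range_ms" in data and data["nn_range_ms"] is not None:
            data["nn_range_ms"] = tuple(data["nn_range_ms"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class TraceSummary:
    """One recording's flattened results row with provenance."""

    meta: dict
    intervals: Optional[IntervalSummary]
    arrhythmia: ArrhythmiaSummary
    time_domain: Optional[TimeDomainHRV]
    poincare: Optional[PoincareHRV]
    spectral: Optional[SpectralSummary]
    flags: list[str] = field(default_factory=list)
    version: str = __version__
    config_hash: str = ""

    def to_row(self) -> dict:
        """Flatten to one mapping for CSV/long-table output; absent = None."""
        row: dict = dict(self.meta)
        row["version"] = self.version
        row["config_hash"] = self.config_hash
        iv = self.intervals
        row["hr_bpm"] = iv.hr_bpm if iv else None
        row["pr_ms"] = iv.pr_ms if iv else None
        row["qt_ms"] = iv.qt_ms if iv else None
        for f in ("B", "F", "V", "M"):
            row[f"qtc{f.lower()}_ms"] = iv.qtc_ms.get(f) if iv else None
        a = self.arrhythmia
        row.update(
            n_pvb=a.n_pvb, pvb_per_hr=a.pvb_per_hr, pvb_pct=a.pvb_pct,
            n_doublets=a.n_doublets, n_triplets=a.n_triplets, n_salvos=a.n_salvos,
            max_run_len=a.max_run_len, bigeminy=a.bigeminy,
            polymorphic=a.polymorphic, r_on_t=a.r_on_t, lown=a.lown,
        )
        td = self.time_domain
        row["mean_nn_ms"] = td.mean_nn_ms if td else None
        row["sdnn_ms"] = td.sdnn_ms if td else None
        row["cv_rr"] = td.cv_rr if td else None
        row["rmssd_ms"] = td.rmssd_ms if td else None
        row["hrv_ti"] = td.hrv_ti if td else None
        row["pnn50_pct"] = td.pnn50_pct if td else None
        row["pnn10pct_meanrr_pct"] = td.pnn10pct_meanrr_pct if td else None
        pc = self.poincare
        row["stv_ms"] = pc.stv_ms if pc else None
        row["ltv_ms"] = pc.ltv_ms if pc else None
        row["stv_ltv_ratio"] = pc.stv_ltv_ratio if pc else None
        sp = self.spectral
        row["vlf_ms2"] = sp.mean_vlf_ms2 if sp else None
        row["lf_ms2"] = sp.mean_lf_ms2 if sp else None
        row["hf_ms2"] = sp.mean_hf_ms2 if sp else None
        row["total_ms2"] = sp.mean_total_ms2 if sp else None
        row["lf_hf"] = sp.mean_lf_hf if sp else None
        row["hf_nu_pct"] = sp.mean_hf_nu_pct if sp else None
        row["n_epochs_used"] = sp.n_epochs_used if sp else None
        row["flags"] = ";".join(self.flags) if self.flags else None
        return row


def run_trace(
    source: str | Path | BeatSeries,
    config: AnalysisConfig = AnalysisConfig(),
) -> TraceSummary:
    """Full per-recording analysis; partial failures degrade to flagged absences."""
    if isinstance(source, BeatSeries):
        series = source
    else:
        series = read_beats(source)
    flags: list[str] = []

    arr = summarize_arrhythmia(
        series, bigeminy_min_alternations=config.bigeminy_min_alternations
    )

    intervals = None
    try:
        intervals = summarize_intervals(
            series, qtc_mode=config.qtc_mode, nn_range_ms=config.nn_range_ms
        )
        flags.extend(intervals.flags)
    except ValueError as exc:
        flags.append(f"intervals_absent:{exc}")

    td = pc = sp = None
    try:
        nn = clean_to_nn(series, nn_range_ms=config.nn_range_ms)
        td = time_domain(nn, pnn_rel_threshold=config.pnn_rel_threshold)
        flags.extend(td.flags)
        try:
            pc = poincare(nn)
        except ValueError as exc:
            flags.append(f"poincare_absent:{exc}")
        sp = spectral_summary(nn, duration_ms=series.duration_ms, config=config.spectral)
        flags.extend(sp.flags)
    except ValueError as exc:
        flags.append(f"hrv_absent:{exc}")

    meta = dict(
        recording_id=series.meta.recording_id,
        subject=series.meta.subject_id,
        group=series.meta.group,
        age_months=series.meta.age_months,
        duration_ms=series.duration_ms,
        seed=series.meta.seed,
    )
    return TraceSummary(
        meta=meta, intervals=intervals, arrhythmia=arr, time_domain=td,
        poincare=pc, spectral=sp, flags=flags, config_hash=config.config_hash(),
    )


DEFAULT_COMPARE_VARIABLES = (
    "hr_bpm", "qtcv_ms", "pr_ms", "pnn50_pct", "stv_ms", "stv_ltv_ratio",
    "vlf_ms2", "lf_ms2", "hf_ms2", "total_ms2", "hf_nu_pct",
)


@dataclass
class CohortResult:
    summaries: pd.DataFrame
    table: pd.DataFrame
    comparisons: dict[str, GroupComparisonResult]
    screen: list[CorrelationResult]
    report_md: str
    n_skipped: int = 0


def _report_markdown(
    comparisons: dict[str, GroupComparisonResult],
    screen: Sequence[CorrelationResult],
) -> str:
    lines = ["# Cohort report", "", "## Group means by age (mean ± SD)", ""]
    for var, res in comparisons.items():
        lines.append(f"### {var}")
        lines.append("")
        header = "| group | " + " | ".join(
            f"{c.age_months:g} mo" for c in res.contrasts
        ) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(res.contrasts) + 1))
        groups = sorted({g for c in res.contrasts for g in c.mean_by_group})
        for g in groups:
            cells = []
            for c in res.contrasts:
                if g in c.mean_by_group:
                    cells.append(f"{c.mean_by_group[g]:.1f} (± {c.sd_by_group[g]:.1f})")
                else:
                    cells.append("-")
            lines.append(f"| {g} | " + " | ".join(cells) + " |")
        pvals = " | ".join(
            "-" if c.p_value is None else f"{c.p_value:.3f}" for c in res.contrasts
        )
        lines.append(f"| LSD p | {pvals} |")
        lines.append("")
    if screen:
        lines += ["## Outcome screen (Spearman)", ""]
        lines.append("| predictor | age (mo) | rho | n | p | BH q |")
        lines.append("|---|---|---|---|---|---|")
        for r in screen:
            lines.append(
                f"| {r.variable} | {r.predictor_age:g} | {r.spearman_rho:.3f} "
                f"| {r.n} | {r.p_value:.4f} | {r.bh_q:.4f} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_cohort(
    manifest_path: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: Optional[str | Path] = None,
    compare_variables: Sequence[str] = DEFAULT_COMPARE_VARIABLES,
    screen: Sequence[tuple[str, float]] = (),
    outcome: str = "lvfs_24m",
    screen_group: Optional[str] = "GRMD",
) -> CohortResult:
    """Analyse every manifest recording, then the cohort stage.

    Rows whose recording is missing or unreadable are skipped with a logged
    reason; the run continues. Covariate columns of the manifest (the
    outcome among them) are carried into the long table as variables.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    if manifest.empty:
        raise ValueError("empty manifest")
    base = manifest_path.parent
    rows = []
    n_skipped = 0
    for rec in manifest.itertuples(index=False):
        path = Path(rec.recording_path)
        if not path.is_absolute():
            path = base / path
        try:
            series = read_beats(path)
        except (OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            n_skipped += 1
            continue
        summary = run_trace(series, config)
        row = summary.to_row()
        row["subject"] = rec.subject
        row["group"] = rec.group
        row["age_months"] = rec.age_months
        rows.append(row)
    if not rows:
        raise ValueError("no readable recordings in manifest")
    summaries = pd.DataFrame(rows)

    numeric = [
        c for c in summaries.columns
        if c not in ("subject", "group", "age_months")
        and pd.api.types.is_numeric_dtype(summaries[c])
    ]
    table = to_long(summaries, variables=numeric)

    # covariates: one value per subject, attached at their manifest age
    for cov in ("lvfs_24m", "ctni", "ntprobnp"):
        if cov in manifest.columns:
            cov_rows = (
                manifest[["subject", "group", "age_months", cov]]
                .dropna(subset=[cov])
                .drop_duplicates(subset=["subject"])
                .rename(columns={cov: "value"})
            )
            cov_rows["variable"] = cov
            table = pd.concat([table, cov_rows[LONG_ORDER]], ignore_index=True)

    comparisons: dict[str, GroupComparisonResult] = {}
    for var in compare_variables:
        try:
            comparisons[var] = lsd_compare(table, var)
        except ValueError as exc:
            logger.warning("comparison for %s skipped: %s", var, exc)

    screen_results: list[CorrelationResult] = []
    if screen:
        try:
            screen_results = early_late_screen(
                table, predictors=list(screen), outcome=outcome, group=screen_group
            )
        except ValueError as exc:
            logger.warning("outcome screen skipped: %s", exc)

    report = _report_markdown(comparisons, screen_results)
    result = CohortResult(
        summaries=summaries, table=table, comparisons=comparisons,
        screen=screen_results, report_md=report, n_skipped=n_skipped,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_summary([r for r in rows], out_dir / "summary.csv")
        table.to_csv(out_dir / "cohort_long.csv", index=False)
        (out_dir / "report.md").write_text(report, encoding="utf-8")
        payload = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "comparisons": {
                var: {
                    "pooled_mse": res.pooled_mse,
                    "pooled_df": res.pooled_df,
                    "contrasts": [
                        {
                            "age_months": c.age_months,
                            "mean_by_group": c.mean_by_group,
                            "sd_by_group": c.sd_by_group,
                            "n_by_group": c.n_by_group,
                            "t": c.t_stat,
                            "p": c.p_value,
                        }
                        for c in res.contrasts
                    ],
                }
                for var, res in comparisons.items()
            },
            "screen": [
                {
                    "variable": r.variable, "age_months": r.predictor_age,
                    "outcome": r.outcome, "rho": r.spearman_rho,
                    "n": r.n, "p": r.p_value, "bh_q": r.bh_q,
                }
                for r in screen_results
            ],
        }
        with open(out_dir / "cohort.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    return result


LONG_ORDER = ["subject", "group", "age_months", "variable", "value"]
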