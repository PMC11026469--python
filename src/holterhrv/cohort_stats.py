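"""Cohort-level statistics for longitudinal group comparisons and outcome screens.

The group contrast is the Fisher-LSD construction: within each group x age
cell of a variable, squared deviations are pooled into a single error mean
square; each per-timepoint contrast is then
t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2)) with the pooled error df. The
outcome screen reports Spearman rank correlations (average ranks for ties;
exact permutation p for n <= 9, t approximation otherwise), unadjusted, with
a Benjamini-Hochberg column alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("GRMD", "healthy")
LONG_COLUMNS = ["subject", "group", "age_months", "variable", "value"]


def to_long(
    wide: pd.DataFrame,
    id_vars: Sequence[str] = ("subject", "group", "age_months"),
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Melt a wide per-recording summary table into the long cohort format."""
    if variables is None:
        variables = [c for c in wide.columns if c not in id_vars]
    long = wide.melt(
        id_vars=list(id_vars), value_vars=list(variables),
        var_name="variable", value_name="value",
    )
    long = long.dropna(subset=["value"])
    dup = long.duplicated(subset=["subject", "age_months", "variable"])
    if dup.any():
        raise ValueError("cohort table has duplicate subject x age x variable rows")
    return long.reset_index(drop=True)


@dataclass
class AgeContrast:
    age_months: float
    mean_by_group: dict[str, float]
    sd_by_group: dict[str, float]
    n_by_group: dict[str, int]
    t_stat: Optional[float]
    p_value: Optional[float]


@dataclass
class GroupComparisonResult:
    variable: str
    contrasts: list[AgeContrast]
    pooled_mse: float
    pooled_df: int
    age_effect_p: dict[str, float] = field(default_factory=dict)

    def p_at(self, age: float) -> Optional[float]:
        for c in self.contrasts:
            if c.age_months == age:
                return c.p_value
        return None


def lsd_compare(table: pd.DataFrame, variable: str) -> GroupComparisonResult:
    """Per-timepoint group contrast with a pooled within-cell error term."""
    sub = table[table["variable"] == variable]
    if sub.empty:
        raise ValueError(f"variable {variable!r} not in table")
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"no contrast possible: variable {variable!r} present in one group only")

    # pooled within-cell error mean square over all group x age cells
    ss, df = 0.0, 0
    for (_, _), cell in sub.groupby(["group", "age_months"]):
        v = cell["value"].to_numpy(dtype=float)
        if v.size >= 2:
            ss += float(np.sum((v - v.mean()) ** 2))
            df += v.size - 1
    if df == 0:
        raise ValueError("pooled error df is zero: no cell has n >= 2")
    mse = ss / df

    contrasts: list[AgeContrast] = []
    for age in sorted(sub["age_months"].unique()):
        cell = sub[sub["age_months"] == age]
        means, sds, ns = {}, {}, {}
        for g in groups:
            v = cell.loc[cell["group"] == g, "value"].to_numpy(dtype=float)
            if v.size:
                means[g] = float(v.mean())
                sds[g] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
                ns[g] = int(v.size)
        t_stat = p = None
        if len(means) == 2:
            g1, g2 = groups[:2]
            se = np.sqrt(mse * (1.0 / ns[g1] + 1.0 / ns[g2]))
            if se > 0:
                t_stat = float((means[g1] - means[g2]) / se)
                p = float(2.0 * stats.t.sf(abs(t_stat), df))
        contrasts.append(
            AgeContrast(
                age_months=float(age), mean_by_group=means, sd_by_group=sds,
                n_by_group=ns, t_stat=t_stat, p_value=p,
            )
        )

    age_effect: dict[str, float] = {}
    for g in groups:
        cells = [
            c["value"].to_numpy(dtype=float)
            for _, c in sub[sub["group"] == g].groupby("age_months")
        ]
        cells = [c for c in cells if c.size >= 2]
        if len(cells) >= 2:
            age_effect[g] = float(stats.f_oneway(*cells).pvalue)
    return GroupComparisonResult(
        variable=variable, contrasts=contrasts, pooled_mse=mse,
        pooled_df=df, age_effect_p=age_effect,
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

EXACT_PERMUTATION_MAX_N = 9


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho on average ranks, with exact permutation p for small n.

    For n <= 9 the p-value enumerates all permutations of one rank vector
    (two-sided, counting |rho_perm| >= |rho_obs|); larger samples use the
    t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = _rank_rho(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        rxc = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
        ryc = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = ryc[perms] @ rxc
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class CorrelationResult:
    variable: str
    predictor_age: float
    outcome: str
    spearman_rho: float
    n: int
    p_value: float
    bh_q: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.spearman_rho <= 1.0 + 1e-12:
            raise ValueError("rho out of range")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def early_late_screen(
    table: pd.DataFrame,
    predictors: Sequence[tuple[str, float]],
    outcome: str = "lvfs_24m",
    group: Optional[str] = None,
) -> list[CorrelationResult]:
    """Spearman screen of (variable @ age) predictors against a late outcome.

    The outcome is read from rows ``variable == outcome`` (any age, one
    value per subject). Results are sorted by |rho| descending; predictor
    rows with fewer than 3 complete pairs are skipped with a logged reason.
    An unadjusted p is reported, with a Benjamini-Hochberg q alongside.
    """
    sub = table if group is None else table[table["group"] == group]
    out_rows = sub[sub["variable"] == outcome]
    if out_rows.empty:
        raise ValueError(f"outcome {outcome!r} not found in table")
    outcome_by_subject = out_rows.groupby("subject")["value"].first()

    results: list[CorrelationResult] = []
    for var, age in predictors:
        pred = sub[(sub["variable"] == var) & (sub["age_months"] == age)]
        merged = pred.set_index("subject")["value"].to_frame("x").join(
            outcome_by_subject.to_frame("y"), how="inner"
        ).dropna()
        if len(merged) < 3:
            logger.warning(
                "screen %s@%g skipped: only %d complete pairs", var, age, len(merged)
            )
            continue
        try:
            rho, p = spearman(merged["x"].to_numpy(), merged["y"].to_numpy())
        except ValueError as exc:
            logger.warning("screen %s@%g skipped: %s", var, age, exc)
            continue
        results.append(
            CorrelationResult(
                variable=var, predictor_age=float(age), outcome=outcome,
                spearman_rho=rho, n=len(merged), p_value=p,
            )
        )
    if results:
        qs = _bh_adjust(np.array([r.p_value for r in results]))
        for r, q in zip(results, qs):
            r.bh_q = float(q)
    results.sort(key=lambda r: abs(r.spearman_rho), reverse=True)
    return results
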