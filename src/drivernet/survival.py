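"""Median-split Kaplan-Meier estimation and log-rank screening.

Each vital gene is screened as in a standard prognostic-marker analysis:
samples are split at the gene's median expression (ties to the low
group), follow-up is administratively censored at a fixed horizon
(default 3650 days = ten years), and the two groups are compared by the
two-group log-rank test.  The Kaplan-Meier estimator and the log-rank
statistic are implemented here from their defining formulas:

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over the distinct event times t_i with d_i events among n_i at risk, and

    chi2 = (sum_i (O_1i - E_1i))^2 / sum_i V_i,     E_1i = d_i n_1i / n_i,
    V_i = d_i (n_1i/n_i) (1 - n_1i/n_i) (n_i - d_i) / (n_i - 1),

referred to a chi-square distribution with one degree of freedom.

Raw (uncorrected) p-values are reported by default; Benjamini-Hochberg
is available behind ``correct="fdr_bh"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_DAYS = 3650
DEFAULT_ALPHA_LEVEL = 0.05

SURVIVAL_COLUMNS = ("sample", "time_days", "event")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns sample, time_days, event."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"survival table lacks column(s) {sorted(missing)}")
    return validate_survival(df)


def validate_survival(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["time_days"] = table["time_days"].astype(float)
    table["event"] = table["event"].astype(int)
    if (table["time_days"] <= 0).any():
        raise ConfigurationError("time_days must be positive")
    if not table["event"].isin((0, 1)).all():
        raise ConfigurationError("event must be 0 or 1")
    if table["sample"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in survival table")
    return table


def median_split(values: Sequence[float]) -> np.ndarray:
    """Label samples 'high' (value > median) or 'low' (value <= median)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise DegenerateInputError(f"need >= 4 samples, got {v.size}")
    if not np.isfinite(v).all():
        raise DegenerateInputError("non-finite expression values")
    med = np.median(v)
    labels = np.where(v > med, "high", "low")
    if len(set(labels)) < 2:
        raise DegenerateInputError("degenerate split: all values identical")
    return labels


def apply_horizon(table: pd.DataFrame, horizon: float = DEFAULT_HORIZON_DAYS
                  ) -> pd.DataFrame:
    """Administrative censoring: times past the horizon become censored."""
    if horizon <= 0:
        raise ConfigurationError(f"horizon must be > 0, got {horizon!r}")
    out = table.copy()
    late = out["time_days"] > horizon
    out.loc[late, "time_days"] = float(horizon)
    out.loc[late, "event"] = 0
    return out


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray      # distinct times with >= 1 event, ascending
    at_risk: np.ndarray    # n_i just before each event time
    events: np.ndarray     # d_i at each event time
    survival: np.ndarray   # S(t_i), non-increasing, starts below 1.0

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival})


def kaplan_meier(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate of one group's survival."""
    if len(table) == 0:
        raise DegenerateInputError("empty survival table")
    times = table["time_days"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    out_t, out_n, out_d, out_s = [], [], [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        out_t.append(t); out_n.append(n_i); out_d.append(d_i); out_s.append(s)
    return KMCurve(np.asarray(out_t), np.asarray(out_n),
                   np.asarray(out_d), np.asarray(out_s))


@dataclass
class LogRankResult:
    """Two-group log-rank test summary (1 df)."""

    statistic: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    degenerate: bool = False  # zero total events


def logrank_test(table: pd.DataFrame, group_col: str = "group") -> LogRankResult:
    """Two-group log-rank test from the O-E / variance sums."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly 2 groups, got {groups}")
    g0 = groups[0]
    times = table["time_days"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    in0 = (table[group_col] == g0).to_numpy()
    if not in0.any() or in0.all():
        raise ConfigurationError("both groups must be non-empty")

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        logger.warning("log-rank: zero events in either group")
        return LogRankResult(0.0, 1.0, {g: 0.0 for g in groups},
                             {g: 0.0 for g in groups}, degenerate=True)
    o0 = e0 = var = 0.0
    d_tot = 0.0
    for t in event_times:
        at_risk = times >= t
        n_i = at_risk.sum()
        n_0i = (at_risk & in0).sum()
        dying = (times == t) & (events == 1)
        d_i = dying.sum()
        d_0i = (dying & in0).sum()
        o0 += d_0i
        e0 += d_i * n_0i / n_i
        if n_i > 1:
            var += d_i * (n_0i / n_i) * (1 - n_0i / n_i) * (n_i - d_i) / (n_i - 1)
        d_tot += d_i
    if var <= 0:
        return LogRankResult(0.0, 1.0,
                             {groups[0]: float(o0), groups[1]: float(d_tot - o0)},
                             {groups[0]: float(e0), groups[1]: float(d_tot - e0)},
                             degenerate=True)
    stat = (o0 - e0) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(float(stat), max(p, np.nextafter(0, 1)),
                         {groups[0]: float(o0), groups[1]: float(d_tot - o0)},
                         {groups[0]: float(e0), groups[1]: float(d_tot - e0)})


def survival_screen(
    vital: Sequence[str],
    expression: ExpressionMatrix,
    surv: pd.DataFrame,
    horizon: float = DEFAULT_HORIZON_DAYS,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
    correct: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Median-split log-rank screen of every vital gene.

    Returns a per-gene result table (gene, chi2, p, n_high, n_low,
    significant) and the list of significant genes (p < ``alpha_level``;
    on the adjusted p-values when ``correct`` names a statsmodels
    multipletests method such as ``"fdr_bh"``).  Genes missing from the
    expression matrix, or with a degenerate split, are skipped with a log
    entry.
    """
    surv = validate_survival(surv)
    missing_samples = set(surv["sample"]) - set(expression.samples)
    if missing_samples:
        raise ConfigurationError(
            f"survival samples absent from expression: {sorted(missing_samples)[:5]}")
    surv = apply_horizon(surv, horizon)
    expr_cols = surv["sample"].tolist()
    rows = []
    for gene in vital:
        if gene not in expression.values.index:
            logger.warning("screen: gene %s absent from expression, skipped", gene)
            continue
        values = expression.values.loc[gene, expr_cols].to_numpy(dtype=float)
        try:
            groups = median_split(values)
        except DegenerateInputError as exc:
            logger.warning("screen: gene %s skipped (%s)", gene, exc)
            continue
        res = logrank_test(surv.assign(group=groups))
        rows.append({"gene": gene, "chi2": res.statistic, "p": res.p_value,
                     "n_high": int((groups == "high").sum()),
                     "n_low": int((groups == "low").sum())})
    result = pd.DataFrame(rows, columns=["gene", "chi2", "p", "n_high", "n_low"])
    if result.empty:
        result["significant"] = pd.Series(dtype=bool)
        return result, []
    p_screen = result["p"].to_numpy()
    if correct is not None:
        from statsmodels.stats.multitest import multipletests
        _, p_adj, _, _ = multipletests(p_screen, alpha=alpha_level, method=correct)
        result["p_adjusted"] = p_adj
        p_screen = p_adj
    result["significant"] = p_screen < alpha_level
    significant = list(result.loc[result["significant"], "gene"])
    return result, significant
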