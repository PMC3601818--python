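"""Genotype-level aggregation and hypothesis tests.

Per-animal recording summaries are aggregated within genotype: animal-level
means with t-distribution 95% confidence intervals (appropriate at the
11-12 animals per genotype typical of these assays), transient-level
pooling for the synchronous-double fraction with a Wilson score interval,
and pooled double-transient delays (synchronous doubles contribute 0 s).
Group comparisons use the classical tests for these designs: one-way ANOVA
for per-animal peak frequencies, a Pearson chi-squared test of homogeneity
for synchrony proportions, and the Fisher-Freeman-Halton exact test for
egg developmental-stage tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .transients import RecordingSummary

__all__ = [
    "GenotypeSummary",
    "EggStageTable",
    "aggregate_genotype",
    "compare_frequencies",
    "compare_sync_fractions",
    "egg_stage_compare",
    "proportion_ci",
    "t_interval",
    "EGG_STAGES",
]

EGG_STAGES = ("1-8 cell", "8-cell to comma", "post-comma")


def t_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for a mean; NaN bounds when n < 2."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return (float("nan"), float("nan"))
    m, se = x.mean(), x.std(ddof=1) / math.sqrt(n)
    half = sps.t.ppf(0.5 + level / 2.0, df=n - 1) * se
    return (float(m - half), float(m + half))


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Wilson score interval; returns (point estimate, (lower, upper))."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return (k / n, (float(lo), float(hi)))


@dataclass(frozen=True)
class GenotypeSummary:
    """Pooled statistics for one genotype across animals."""

    label: str
    n_animals: int
    mean_peaks_per_min: float
    ci_peaks_per_min: tuple[float, float]
    frac_sync_double: float
    ci_frac_sync_double: tuple[float, float]
    mean_delay_s: float
    ci_delay_s: tuple[float, float]
    n_transients: int
    n_doubles: int


def aggregate_genotype(
    summaries: Sequence[RecordingSummary],
    label: str,
    per_recording_delays: Optional[Sequence[Sequence[float]]] = None,
) -> GenotypeSummary:
    """Aggregate per-animal summaries into a genotype summary.

    Peak frequency is averaged at the animal level (t interval).  The
    synchronous-double fraction pools transients across animals (Wilson
    interval), matching how transient-level counts are reported.  The mean
    delay pools all double transients across animals, synchronous doubles
    contributing 0 s; pass ``per_recording_delays`` (one delay list per
    animal, delayed doubles only) to compute an exact pooled t interval,
    otherwise the interval is reconstructed from per-animal means.
    """
    if not summaries:
        raise ValueError("need at least one recording summary")
    n_animals = len(summaries)
    rates = [s.peaks_per_min for s in summaries]
    n_sync = sum(s.n_double_sync for s in summaries)
    n_trans = sum(s.n_transients for s in summaries)
    n_doubles = sum(s.n_doubles for s in summaries)
    if n_trans > 0:
        frac, ci_frac = proportion_ci(n_sync, n_trans)
    else:
        frac, ci_frac = float("nan"), (float("nan"), float("nan"))

    if per_recording_delays is not None:
        if len(per_recording_delays) != n_animals:
            raise ValueError("per_recording_delays must align with summaries")
        pooled = []
        for s, dl in zip(summaries, per_recording_delays):
            if len(dl) != s.n_double_delayed:
                raise ValueError("delay lists must contain the delayed doubles only")
            pooled.extend([0.0] * s.n_double_sync)
            pooled.extend(float(d) for d in dl)
    else:
        pooled = []
        for s in summaries:
            if s.n_doubles and not math.isnan(s.mean_delay_s):
                pooled.extend([s.mean_delay_s] * s.n_doubles)
    mean_delay = float(np.mean(pooled)) if pooled else float("nan")
    return GenotypeSummary(
        label=label,
        n_animals=n_animals,
        mean_peaks_per_min=float(np.mean(rates)),
        ci_peaks_per_min=t_interval(rates),
        frac_sync_double=frac,
        ci_frac_sync_double=ci_frac,
        mean_delay_s=mean_delay,
        ci_delay_s=t_interval(pooled),
        n_transients=n_trans,
        n_doubles=n_doubles,
    )


def compare_frequencies(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA p-value across per-animal peak rates."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise ValueError("degenerate within-group variance: ANOVA undefined")
    f, p = sps.f_oneway(*arrays)
    if f == 0.0:
        return 1.0
    return float(p)


def compare_sync_fractions(table: Sequence[Sequence[float]]) -> float:
    """Pearson chi-squared test of homogeneity, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-squared test undefined")
    _, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(p)


@dataclass(frozen=True)
class EggStageTable:
    """Per-genotype counts of eggs by developmental stage."""

    counts: pd.DataFrame  # rows: genotypes, columns: stages

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("egg counts must be nonnegative")

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "EggStageTable":
        """Build from long-form (genotype, stage, count) records."""
        need = {"genotype", "stage", "count"}
        if not need <= set(records.columns):
            raise ValueError(f"records must have columns {sorted(need)}")
        wide = records.pivot_table(
            index="genotype", columns="stage", values="count", aggfunc="sum", fill_value=0
        )
        return cls(counts=wide)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


_MAX_EXACT_TOTAL = 500


def _fisher_freeman_halton(table: np.ndarray) -> float:
    """Exact conditional p for a 2xK table: sum of the probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (log-probabilities compared with 1e-9 relative slack).
    """
    row = table.sum(axis=1).astype(int)
    col = table.sum(axis=0).astype(int)
    n = int(table.sum())
    lgam = math.lgamma

    def log_prob(first_row: tuple[int, ...]) -> float:
        lp = (
            lgam(row[0] + 1) + lgam(row[1] + 1) - lgam(n + 1)
            + sum(lgam(c + 1) for c in col)
        )
        for a, c in zip(first_row, col):
            lp -= lgam(a + 1) + lgam(c - a + 1)
        return lp

    obs = log_prob(tuple(int(x) for x in table[0]))
    p = 0.0
    ranges = [range(min(row[0], c) + 1) for c in col[:-1]]
    for head in product(*ranges):
        last = row[0] - sum(head)
        if last < 0 or last > col[-1]:
            continue
        lp = log_prob(head + (last,))
        if lp <= obs + 1e-9 * abs(obs) + 1e-12:
            p += math.exp(lp)
    return min(p, 1.0)


def egg_stage_compare(table: EggStageTable, genotype_pair: tuple[str, str]) -> float:
    """Fisher-Freeman-Halton exact test between two genotypes' stage counts."""
    for g in genotype_pair:
        if g not in table.counts.index:
            raise KeyError(f"genotype {g!r} not in table")
    sub = table.counts.loc[list(genotype_pair)].to_numpy(dtype=float)
    if sub.shape[1] < 2 or sub.shape[1] > 3:
        raise ValueError("expected 2-3 stage columns")
    if not np.allclose(sub, np.round(sub)):
        raise ValueError("exact test requires integer counts")
    if sub.sum() > _MAX_EXACT_TOTAL:
        raise ValueError(
            f"table total {int(sub.sum())} exceeds the exact enumeration bound "
            f"({_MAX_EXACT_TOTAL}); use a chi-squared test instead"
        )
    if sub.sum() == 0:
        raise ValueError("empty table")
    # drop all-zero columns: they admit a single value and do not affect p
    sub = sub[:, sub.sum(axis=0) > 0]
    if sub.shape[1] < 2 or (sub.sum(axis=1) == 0).any():
        return 1.0  # margins admit exactly one table
    return float(_fisher_freeman_halton(sub.astype(int)))
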