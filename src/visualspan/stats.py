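"""Group-level inference on span tables.

The experiment is a 2 (age group, between subjects) x 3 (pattern complexity,
within subjects) mixed design. The module wraps the standard analyses:
a mixed-design ANOVA with optional Greenhouse-Geisser correction of the
within-subject degrees of freedom, Bonferroni-corrected between-group t-tests
at each complexity level with pooled-SD Cohen's d, and Pearson correlation
for the span/reading-speed relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import (DegenerateDesignError, IncompleteDesignError,
                     UndefinedCorrelationError)


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F ratio, dfs, p, partial eta squared, optional GG eps."""

    effect: str
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-ANOVA table keyed by effect name.

    Effects: ``between`` (age group), ``within`` (complexity) and
    ``interaction``. When the Greenhouse-Geisser flag was set, the within and
    interaction dfs are epsilon-multiplied and p recomputed accordingly.
    """

    effects: dict[str, EffectResult]
    gg_corrected: bool = False

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.effect, e.F, e.df[0], e.df[1], e.p, e.partial_eta_sq,
                 e.gg_epsilon) for e in self.effects.values()]
        return pd.DataFrame(rows, columns=[
            "effect", "F", "df_num", "df_den", "p", "partial_eta_sq",
            "gg_epsilon"])


@dataclass(frozen=True)
class PairwiseResult:
    """Independent-samples contrast at one within-factor level."""

    contrast: str
    t: float
    df: int
    p: float
    p_bonferroni: float
    cohens_d: float


def _validate_span_table(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    required = {"participant_id", "age_group", "complexity", dv}
    missing = required - set(table.columns)
    if missing:
        raise IncompleteDesignError(f"span table missing columns: {sorted(missing)}")
    pivot = table.pivot_table(index="participant_id", columns="complexity",
                              values=dv, aggfunc="first")
    if pivot.isna().any().any():
        holes = [(str(i), str(c)) for i, c in
                 zip(*np.where(pivot.isna().to_numpy()))]
        raise IncompleteDesignError(
            f"incomplete within-subject design ({pivot.isna().to_numpy().sum()}"
            f" empty cells)")
    counts = table.groupby("age_group")["participant_id"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise DegenerateDesignError(
            f"need >= 2 participants in each of 2 groups, got {counts.to_dict()}")
    return pivot


def greenhouse_geisser_epsilon(table: pd.DataFrame, dv: str = "span") -> float:
    """GG epsilon for the within factor, from the sample covariance of the
    subject x level matrix."""
    pivot = table.pivot(index="participant_id", columns="complexity", values=dv)
    return float(pg.epsilon(pivot, correction="gg"))


def mixed_anova(table: pd.DataFrame, gg_correct: bool = False,
                dv: str = "span") -> AnovaResult:
    """2 x k mixed-design ANOVA on a long-format span table.

    Requires a complete, two-group design with >= 2 participants per group.
    With ``gg_correct`` the within-subject effects' dfs are multiplied by the
    Greenhouse-Geisser epsilon and p recomputed from the F distribution; the
    F ratios and partial eta squared are unchanged by the correction.
    """
    _validate_span_table(table, dv)
    aov = pg.mixed_anova(data=table, dv=dv, within="complexity",
                         between="age_group", subject="participant_id",
                         correction=False)
    aov = aov.set_index("Source")
    eps = greenhouse_geisser_epsilon(table, dv)
    effects: dict[str, EffectResult] = {}
    for name, source, within in (("between", "age_group", False),
                                 ("within", "complexity", True),
                                 ("interaction", "Interaction", True)):
        row = aov.loc[source]
        f = float(row["F"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if gg_correct and within:
            df1, df2 = eps * df1, eps * df2
            p = float(sps.f.sf(f, df1, df2))
        effects[name] = EffectResult(
            effect=source if source != "Interaction" else "age_group*complexity",
            F=f, df=(df1, df2), p=p,
            partial_eta_sq=float(row["np2"]),
            gg_epsilon=eps if within else None)
    return AnovaResult(effects=effects, gg_corrected=gg_correct)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (a minus b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                     / (n1 + n2 - 2))
    if pooled == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    return min(1.0, m * p)


def pairwise_age_by_complexity(table: pd.DataFrame,
                               dv: str = "span") -> list[PairwiseResult]:
    """Young-vs-older independent-samples t-test at each complexity level.

    Contrasts are young minus older; p values are Bonferroni-corrected over
    the number of complexity levels. A level with zero pooled variance gets
    NaN Cohen's d (flagged, not zero).
    """
    _validate_span_table(table, dv)
    levels = sorted(table["complexity"].unique())
    m = len(levels)
    results = []
    for level in levels:
        sub = table[table["complexity"] == level]
        young = sub.loc[sub["age_group"] == "young", dv].to_numpy(float)
        older = sub.loc[sub["age_group"] == "older", dv].to_numpy(float)
        t, p = sps.ttest_ind(young, older, equal_var=True)
        results.append(PairwiseResult(
            contrast=f"young - older @ {level}",
            t=float(t), df=len(young) + len(older) - 2, p=float(p),
            p_bonferroni=bonferroni(float(p), m),
            cohens_d=cohens_d(young, older)))
    return results


def pairwise_to_frame(results: Sequence[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.contrast, r.t, r.df, r.p, r.p_bonferroni, r.cohens_d)
         for r in results],
        columns=["contrast", "t", "df", "p", "p_bonferroni", "cohens_d"])


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with two-tailed p; returns (r, p, n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3 pairs, got {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n
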