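"""Symptom-level statistics.

Rank-correlation structure between the five symptom composites (Spearman
rho with Fisher-z confidence intervals), treatment-balance testing across
clusters (Pearson chi-squared), and severity-score distribution
diagnostics (square-root transform, Lilliefors-type Kolmogorov-Smirnov
normality test, summary statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import kstest_normal

from .records import SYMPTOMS


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; ties averaged).

    Returns ``nan`` when either argument has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    tanh(atanh(rho) +- z * (n-3)^(-1/2)); the large-sample normal
    approximation on the z scale.
    """
    if n <= 3:
        raise ValueError("Fisher interval requires n > 3")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z / np.sqrt(n - 3)
    centre = np.arctanh(rho)
    return float(np.tanh(centre - half)), float(np.tanh(centre + half))


@dataclass
class SymptomCorrMatrix:
    """5x5 pairwise Spearman structure over the symptom composites."""

    symptoms: tuple[str, ...]
    rho: pd.DataFrame       # symmetric, diagonal 1
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n: int

    @property
    def per_symptom_mean(self) -> pd.Series:
        """Mean of each symptom's four off-diagonal coefficients."""
        r = self.rho.to_numpy(dtype=float).copy()
        np.fill_diagonal(r, np.nan)
        return pd.Series(np.nanmean(r, axis=1), index=self.symptoms, name="mean_rho")

    @classmethod
    def from_pairwise(
        cls, pairwise: dict[tuple[str, str], float], n: int,
        symptoms: Sequence[str] = SYMPTOMS, level: float = 0.95,
    ) -> "SymptomCorrMatrix":
        """Build from the 10 pairwise coefficients (e.g. a published table)."""
        symptoms = tuple(symptoms)
        rho = pd.DataFrame(np.eye(len(symptoms)), index=symptoms, columns=symptoms)
        for (a, b), r in pairwise.items():
            rho.loc[a, b] = rho.loc[b, a] = r
        return cls._with_cis(symptoms, rho, n, level)

    @classmethod
    def _with_cis(cls, symptoms, rho, n, level) -> "SymptomCorrMatrix":
        lo = pd.DataFrame(np.nan, index=symptoms, columns=symptoms)
        hi = pd.DataFrame(np.nan, index=symptoms, columns=symptoms)
        for a in symptoms:
            for b in symptoms:
                if a != b:
                    lo.loc[a, b], hi.loc[a, b] = fisher_ci(rho.loc[a, b], n, level)
        return cls(symptoms=symptoms, rho=rho, ci_low=lo, ci_high=hi, n=n)


def symptom_matrix(
    profiles: pd.DataFrame, n: int | None = None, level: float = 0.95
) -> SymptomCorrMatrix:
    """Pairwise Spearman matrix with Fisher intervals from symptom profiles.

    ``profiles`` has one row per subject (deduplicate upstream: the
    correlation analysis uses one questionnaire per subject) and the five
    symptom columns.
    """
    cols = [s for s in SYMPTOMS if s in profiles.columns]
    if len(cols) != len(SYMPTOMS):
        raise ValueError(f"profiles must contain columns {SYMPTOMS}")
    if len(profiles) < 4:
        raise ValueError("need at least 4 subjects")
    n = n if n is not None else len(profiles)
    symptoms = tuple(SYMPTOMS)
    rho = pd.DataFrame(np.eye(5), index=symptoms, columns=symptoms)
    for i, a in enumerate(symptoms):
        for b in symptoms[i + 1:]:
            r = spearman_rho(profiles[a], profiles[b])
            rho.loc[a, b] = rho.loc[b, a] = r
    return SymptomCorrMatrix._with_cis(symptoms, rho, n, level)


def symptom_network(
    matrix: SymptomCorrMatrix | pd.DataFrame, cutoff: float = 0.4
) -> nx.Graph:
    """Threshold the 5x5 symptom matrix into a graph over the symptoms.

    Edge iff coefficient >= cutoff; isolated symptoms are kept as nodes so
    outliers (classically: sleep) are visible.
    """
    rho = matrix.rho if isinstance(matrix, SymptomCorrMatrix) else matrix
    g = nx.Graph()
    symptoms = list(rho.index)
    g.add_nodes_from(symptoms)
    for i, a in enumerate(symptoms):
        for b in symptoms[i + 1:]:
            if rho.loc[a, b] >= cutoff:
                g.add_edge(a, b, weight=float(rho.loc[a, b]))
    return g


def isolated_symptoms(graph: nx.Graph) -> list[str]:
    return sorted(n for n in graph.nodes if graph.degree[n] == 0)


# ---------------------------------------------------------------------------
# contingency analysis
# ---------------------------------------------------------------------------

def chi_squared_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns ``(statistic, dof, p)``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def treatment_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Column percentages (100 * count / column total) rounded to 1 dp."""
    counts = table.astype(float)
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero column total")
    return (100.0 * counts / sums).round(1)


def cluster_treatment_table(
    records: pd.DataFrame, assignment: dict[Hashable, int | None],
    treatments: Sequence[str] = ("placebo", "antioxidant", "sildenafil"),
) -> pd.DataFrame:
    """Treatment-arm x cluster contingency table of questionnaire counts."""
    rows = {t: {} for t in treatments}
    clusters = sorted({c for c in assignment.values() if c is not None})
    for t in treatments:
        for c in clusters:
            rows[t][f"cluster_{c + 1}"] = 0
    for node, c in assignment.items():
        if c is None:
            continue
        t = records.loc[node, "treatment"]
        if t in rows:
            rows[t][f"cluster_{c + 1}"] += 1
    return pd.DataFrame(rows).T[[f"cluster_{c + 1}" for c in clusters]]


# ---------------------------------------------------------------------------
# severity-score diagnostics
# ---------------------------------------------------------------------------

def sqrt_transform(scores: Sequence[float]) -> np.ndarray:
    """Elementwise square root (a variance-stabilising normalising map)."""
    x = np.asarray(scores, dtype=float)
    if (x < 0).any():
        raise ValueError("scores must be non-negative")
    return np.sqrt(x)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated mean and sd.

    Lilliefors-type: the null distribution accounts for estimating the
    normal parameters from the sample (Dallal-Wilkinson p approximation).
    Returns ``(KS distance, p)``; p is clipped by the approximation to
    roughly [0.001, 0.2] at the extremes.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    d, p = kstest_normal(x, dist="norm", pvalmethod="approx")
    return float(d), float(p)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]


def summary_stats(scores: Sequence[float]) -> SummaryStats:
    """Sample mean, sd (n-1), median and 25th-75th percentile range."""
    x = np.asarray(scores, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    if len(x) < 2:
        raise ValueError("sd undefined for a single observation")
    q1, q3 = np.percentile(x, [25, 75])
    return SummaryStats(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        iqr=(float(q1), float(q3)),
    )


def skewness(scores: Sequence[float]) -> float:
    """Sample skewness (Fisher-Pearson, bias-uncorrected)."""
    return float(sps.skew(np.asarray(scores, dtype=float)))
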