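"""Feature selection: R^2 redundancy reduction and Wilcoxon screening.

Redundancy reduction flags every feature pair with coefficient of
determination R^2 >= 0.99 across samples, groups flagged features into
connected components of the resulting dependency graph, and keeps one
representative per group — the member with the highest variability across
the cohort.  Component grouping makes the result independent of the order
in which pairs are examined.

Univariate screening tests each feature for a location difference between
the indolent and clinically significant groups with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test, exact for small cohorts.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .containers import CohortLabels, FeatureTable

DEFAULT_R2_THRESHOLD = 0.99
DEFAULT_ALPHA = 0.05

#: combined sample size at or below which the rank-sum p-value is computed
#: by exact enumeration rather than the normal approximation
EXACT_WILCOXON_MAX_N = 20


def compute_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two sample vectors.

    A constant vector has no linear relationship to anything; R^2 is
    defined as 0 for that case (with a warning) so that constant features
    are never flagged as redundant with others.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length vectors with n >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("constant vector: R^2 defined as 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)


@dataclasses.dataclass
class RedundancyReport:
    """Outcome of redundancy reduction at a given R^2 threshold."""

    r2_threshold: float
    groups: list[set[str]]  # every feature appears in exactly one group
    representative: dict[int, str]  # group index -> kept feature
    kept: list[str]
    removed: list[str]

    @property
    def percent_removed(self) -> float:
        total = len(self.kept) + len(self.removed)
        return 100.0 * len(self.removed) / total

    def to_dict(self) -> dict:
        return {
            "r2_threshold": self.r2_threshold,
            "groups": [sorted(g) for g in self.groups],
            "representative": {str(k): v for k, v in self.representative.items()},
            "kept": self.kept,
            "removed": self.removed,
            "percent_removed": self.percent_removed,
        }


def reduce_redundancy(
    table: FeatureTable, threshold: float = DEFAULT_R2_THRESHOLD
) -> tuple[FeatureTable, RedundancyReport]:
    """Drop all but the highest-variance member of each R^2-linked group.

    Groups are connected components of the graph with an edge wherever
    pairwise R^2 >= threshold; singleton features form their own group and
    are always kept.  Output column order follows the input.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for a stable R^2")
    x = table.values
    feats = table.feature_ids
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant features: R^2 := 0
    r2 = corr**2
    np.fill_diagonal(r2, 0.0)
    adj = csr_matrix(r2 >= threshold)
    n_comp, comp = connected_components(adj, directed=False)

    variance = x.var(axis=0, ddof=1)
    groups: list[set[str]] = []
    representative: dict[int, str] = {}
    kept_mask = np.zeros(len(feats), dtype=bool)
    for g in range(n_comp):
        members = np.nonzero(comp == g)[0]
        groups.append({feats[i] for i in members})
        # max variance; ties broken by original column order
        best = members[int(np.argmax(variance[members]))]
        representative[g] = feats[best]
        kept_mask[best] = True
    kept = [f for f, k in zip(feats, kept_mask) if k]
    removed = [f for f, k in zip(feats, kept_mask) if not k]
    report = RedundancyReport(threshold, groups, representative, kept, removed)
    return table.select(kept), report


@dataclasses.dataclass
class ScreenResult:
    feature_id: str
    p_value: float
    significant: bool


def wilcoxon_screen(
    table: FeatureTable,
    labels: CohortLabels,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> list[ScreenResult]:
    """Two-sided Wilcoxon rank-sum test per feature, indolent vs significant.

    Exact enumeration p-values for combined n <= 20 (and no ties), normal
    approximation with tie and continuity correction otherwise.  Raw
    p-values are compared against ``alpha`` by default; ``fdr=True``
    switches to Benjamini-Hochberg adjusted significance calls.
    """
    y = labels.binary()
    common = [s for s in table.sample_ids if s in y.index]
    y = y.loc[common]
    if y.nunique() < 2:
        raise ValueError("both classes must be present for screening")
    data = table.data.loc[common]
    g0 = data.loc[y == 0].to_numpy()
    g1 = data.loc[y == 1].to_numpy()
    n_total = len(common)
    pvals = np.empty(table.n_features)
    for j in range(table.n_features):
        a, b = g0[:, j], g1[:, j]
        has_ties = len(np.unique(np.concatenate([a, b]))) < n_total
        method = "exact" if (n_total <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pvals[j] = min(res.pvalue, 1.0)
    if fdr:
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals <= alpha
    return [
        ScreenResult(f, float(p), bool(s))
        for f, p, s in zip(table.feature_ids, pvals, sig)
    ]
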