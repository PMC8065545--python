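"""Inter-reader feature stability and redundancy reduction.

Stability: each feature is measured on the same patients under the two
readers' independent segmentations; a repeated-measures Friedman rank test
asks whether the reader systematically shifts the feature. Features with
p > alpha (default 0.05) are "stable"; the stability rank orders features
by descending p (most stable first).

Redundancy: among candidate features, Pearson correlation across patients
defines a graph with an edge where |r| exceeds the threshold (default
0.8); connected components form clusters and each cluster is represented
by its highest coefficient-of-variation member. Note that connected
components do not guarantee that representatives of different clusters are
themselves uncorrelated below the threshold (transitivity can fail); what
is guaranteed is that every pruned feature is highly correlated with at
least one member of its own cluster.

The Friedman statistic is implemented here (tie-corrected, chi-square
reference with k-1 df) rather than delegated: the common library routine
requires at least three conditions, while the pipeline's primary use has
k = 2 readers — where the test reduces to a sign test and the chi-square
p is approximate (documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .preprocessing import logger


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def friedman_test(readings: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman test on an (n subjects x k conditions) array.

    Ranks within each subject use mid-ranks for ties; the statistic

        Q = (k-1) * [sum_j R_j^2 - n^2 k (k+1)^2 / 4]
            / [sum_ij r_ij^2 - n k (k+1)^2 / 4]

    is referred to chi-square with k-1 degrees of freedom. Fully tied data
    (zero denominator) carry no evidence of a condition effect: Q = 0,
    p = 1.
    """
    readings = np.asarray(readings, dtype=np.float64)
    if readings.ndim != 2:
        raise ValueError("readings must be 2D (subjects x conditions)")
    n, k = readings.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    ranks = np.apply_along_axis(rankdata, 1, readings)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * (np.sum(col_sums ** 2) - n ** 2 * k * (k + 1) ** 2 / 4.0)
    den = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return 0.0, 1.0
    q = float(num / den)
    p = float(stats.chi2.sf(q, k - 1))
    return q, p


@dataclass
class StabilityReport:
    """Per-feature Friedman results plus stability flags and rank."""

    table: pd.DataFrame  # index: feature; columns: statistic, p_value, stable, rank

    @property
    def stable_features(self) -> list[str]:
        return self.table.index[self.table["stable"]].tolist()

    def top_stable(self, k: int) -> list[str]:
        """The first ``k`` features of the stability rank that are stable."""
        ranked = self.table.sort_values("rank")
        ranked = ranked[ranked["stable"]]
        return ranked.index[:k].tolist()


def stability_rank(reader_tables: list[pd.DataFrame],
                   alpha: float = 0.05) -> StabilityReport:
    """Friedman stability of every feature across readers' segmentations.

    ``reader_tables`` holds one (patients x features) table per reader, on
    identical patients and features. A feature is stable iff its Friedman
    p strictly exceeds ``alpha``; rank 1 is the most stable (largest p),
    ties broken by feature-name order.
    """
    if len(reader_tables) < 2:
        raise ValueError("need at least two reader tables")
    ref = reader_tables[0]
    for t in reader_tables[1:]:
        if not ref.index.equals(t.index) or not ref.columns.equals(t.columns):
            raise ValueError("reader tables disagree on patients or features")
    rows = []
    for feat in ref.columns:
        readings = np.column_stack([t[feat].to_numpy() for t in reader_tables])
        q, p = friedman_test(readings)
        rows.append({"feature": feat, "statistic": q, "p_value": p,
                     "stable": p > alpha})
    tab = pd.DataFrame(rows).set_index("feature")
    # stable sort on name-sorted rows: ties in p fall back to name order
    order = tab.loc[sorted(tab.index)].sort_values("p_value", ascending=False,
                                                   kind="mergesort")
    tab["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return StabilityReport(tab)


# ---------------------------------------------------------------------------
# redundancy reduction
# ---------------------------------------------------------------------------

def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD divided by |mean|; scale-free dispersion.

    A zero mean makes the ratio undefined — returned as +inf and logged
    (such a feature wins representative selection only against other
    infinite CoVs, where name order decides).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value set")
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if mean == 0.0:
        if sd == 0.0:
            return 0.0
        logger.warning("coefficient_of_variation: zero mean, returning +inf")
        return float("inf")
    return float(sd / abs(mean))


@dataclass
class RedundancyResult:
    """Correlation clusters and their CoV-selected representatives."""

    clusters: list[list[str]]
    representatives: list[str]
    correlation: pd.DataFrame
    cov: pd.Series

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for cid, members in enumerate(self.clusters):
            for f in members:
                rows.append({"feature": f, "cluster_id": cid,
                             "is_representative": f == self.representatives[cid],
                             "cov": self.cov[f]})
        return pd.DataFrame(rows)


def redundancy_reduce(feature_table: pd.DataFrame,
                      candidate_features: list[str] | None = None,
                      r_threshold: float = 0.8) -> RedundancyResult:
    """Collapse clusters of highly correlated features to representatives.

    Pearson correlation is computed across patients for the candidate
    columns; |r| > ``r_threshold`` defines edges, connected components the
    clusters, and the member with the highest coefficient of variation
    represents each cluster (ties and infinite-vs-infinite resolved by
    feature-name order). Constant columns correlate with nothing (r
    defined as 0, logged) and have CoV 0.
    """
    feats = list(candidate_features) if candidate_features is not None \
        else list(feature_table.columns)
    missing = [f for f in feats if f not in feature_table.columns]
    if missing:
        raise ValueError(f"candidates not in table: {missing}")
    if len(feature_table) < 2:
        raise ValueError("need >= 2 patients for correlations")
    sub = feature_table[feats].astype(float)
    arr = sub.to_numpy()
    sds = arr.std(axis=0, ddof=1)
    const = sds == 0
    if const.any():
        logger.warning("redundancy_reduce: constant feature(s) %s, correlation set to 0",
                       [f for f, c in zip(feats, const) if c])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    adj = (np.abs(corr) > r_threshold) & ~np.eye(len(feats), dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    cov = pd.Series({f: coefficient_of_variation(sub[f].to_numpy()) for f in feats})
    clusters: list[list[str]] = []
    reps: list[str] = []
    for cid in range(n_comp):
        members = sorted(np.array(feats)[labels == cid].tolist())
        # ties (incl. inf vs inf): keep first in name order
        top = max(cov[m] for m in members)
        best = [m for m in members if cov[m] == top][0]
        clusters.append(members)
        reps.append(best)
    return RedundancyResult(clusters=clusters, representatives=reps,
                            correlation=pd.DataFrame(corr, index=feats, columns=feats),
                            cov=cov)
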