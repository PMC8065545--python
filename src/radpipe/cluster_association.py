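"""Unsupervised radiomic phenotyping and clinical association.

Patients are grouped by hierarchical clustering of their (transformed,
standardized) feature vectors — Euclidean distance, complete linkage, tree
cut at two groups — and the resulting two-group partition is tested for
association with the clinical endpoints (high/low Gleason grade group,
extracapsular extension, nodal stage) by two-sided Fisher's exact tests
on 2x2 tables. Patients with unassessable nodes (pNx) are excluded from
the nodal table only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .preprocessing import logger
from .synthetic_cohort import PN_N0, PN_N1, PN_NX


# ---------------------------------------------------------------------------
# feature transforms
# ---------------------------------------------------------------------------

def log2_extreme_transform(column: pd.Series,
                           skew_threshold: float = 2.0) -> tuple[pd.Series, bool]:
    """log2-transform a heavily right/left-skewed nonnegative feature.

    Applied iff |sample skewness| exceeds ``skew_threshold`` and all values
    are nonnegative; zeros are first replaced by the column's smallest
    positive value. Returns (column, applied). Negative values with
    extreme skew are left untransformed with a warning.
    """
    x = column.astype(float)
    if x.nunique() < 2:
        return x, False
    skew = float(stats.skew(x, bias=False))
    if abs(skew) <= skew_threshold:
        return x, False
    if (x < 0).any():
        logger.warning("log2_extreme_transform: %s has negative values, skipped",
                       column.name)
        return x, False
    positive = x[x > 0]
    if positive.empty:
        return x, False
    x = x.mask(x == 0, positive.min())
    return np.log2(x), True


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to zero mean, unit sample SD.

    Constant columns cannot be standardized and are dropped with a warning.
    """
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("zscore_columns: dropping constant column %s", col)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Two-group patient partition plus the dendrogram it came from."""

    groups: pd.Series           # patient -> 1 | 2
    linkage_matrix: np.ndarray
    transformed: list[str] = field(default_factory=list)  # log2-applied features

    def __post_init__(self) -> None:
        vals = set(self.groups.unique().tolist())
        if vals != {1, 2}:
            raise ValueError(f"expected exactly two nonempty groups, got {vals}")

    def leaf_order(self) -> list:
        """Patients in dendrogram (heatmap row) order."""
        return self.groups.index[hierarchy.leaves_list(self.linkage_matrix)].tolist()


def hierarchical_two_groups(table: pd.DataFrame, linkage: str = "complete",
                            skew_threshold: float = 2.0,
                            transform: bool = True) -> ClusterAssignment:
    """Cluster patients into two groups on their radiomic pattern.

    Heavily skewed nonnegative features are log2-transformed, all features
    standardized, then agglomerative clustering (Euclidean distance,
    ``linkage`` criterion) is cut at k = 2. Deterministic: group 1 is the
    group containing the lowest-index patient.
    """
    if len(table) < 4:
        raise ValueError("need >= 4 patients to cluster")
    if table.shape[1] < 1:
        raise ValueError("need >= 1 feature")
    work = table.copy()
    applied = []
    if transform:
        for col in work.columns:
            work[col], did = log2_extreme_transform(work[col], skew_threshold)
            if did:
                applied.append(col)
    work = zscore_columns(work)
    if work.shape[1] == 0:
        raise ValueError("no non-constant features to cluster on")
    z = hierarchy.linkage(work.to_numpy(), method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    if len(set(labels)) != 2:  # pathological: force a split at the root
        labels = hierarchy.cut_tree(z, n_clusters=2).ravel() + 1
    # canonical numbering: the first patient's group is group 1
    if labels[0] != 1:
        labels = 3 - labels
    return ClusterAssignment(groups=pd.Series(labels, index=table.index),
                             linkage_matrix=z, transformed=applied)


# ---------------------------------------------------------------------------
# Fisher association
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sum of hypergeometric probabilities (fixed margins) of all tables no
    more probable than the observed one. A zero margin admits only one
    table: p = 1.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative integers")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def associate(assignment: ClusterAssignment, labels: pd.DataFrame) -> dict[str, float]:
    """Fisher p-values for group association with GGG, ECE and pN.

    Builds three 2x2 tables: group x GGG(high/low), group x ECE(yes/no),
    and group x pN(pN0 / pN>=1) with pNx patients dropped from the nodal
    table only. Endpoints with an entirely missing level are skipped with
    a warning.
    """
    lab = labels.set_index("patient_id").loc[assignment.groups.index] \
        if "patient_id" in labels.columns else labels.loc[assignment.groups.index]
    g = assignment.groups
    out: dict[str, float] = {}

    def crosstab(series: pd.Series, positive) -> np.ndarray | None:
        pos = series == positive
        if pos.all() or (~pos).all():
            return None
        return np.array([[int(((g == k) & pos).sum()),
                          int(((g == k) & ~pos).sum())] for k in (1, 2)])

    t = crosstab(lab["ggg_high"].astype(bool), True)
    if t is None:
        logger.warning("associate: GGG has a single level, test skipped")
    else:
        out["ggg"] = fisher_exact_2x2(t)
    t = crosstab(lab["ece"].astype(bool), True)
    if t is None:
        logger.warning("associate: ECE has a single level, test skipped")
    else:
        out["ece"] = fisher_exact_2x2(t)
    assessable = lab["pn"] != PN_NX
    if assessable.any():
        sub = lab.loc[assessable, "pn"]
        gg = g[assessable]
        pos = sub == PN_N1
        if pos.any() and (sub == PN_N0).any():
            tab = np.array([[int(((gg == k) & pos).sum()),
                             int(((gg == k) & ~pos).sum())] for k in (1, 2)])
            out["pn"] = fisher_exact_2x2(tab)
        else:
            logger.warning("associate: pN has a single assessable level, test skipped")
    return out


def plot_heatmap(table: pd.DataFrame, assignment: ClusterAssignment,
                 labels: pd.DataFrame, path) -> None:
    """Clustered heatmap (patients x features) with endpoint annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = assignment.leaf_order()
    data = zscore_columns(table).loc[order]
    lab = labels.set_index("patient_id") if "patient_id" in labels.columns else labels
    lab = lab.loc[order]
    fig, axes = plt.subplots(
        1, 2, figsize=(max(6, 0.12 * data.shape[1]), max(4, 0.12 * len(order))),
        gridspec_kw={"width_ratios": [12, 1]}, constrained_layout=True)
    im = axes[0].imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                        vmin=-2.5, vmax=2.5)
    axes[0].set_xlabel("features")
    axes[0].set_ylabel("patients (dendrogram order)")
    fig.colorbar(im, ax=axes[0], shrink=0.6, label="z-score")
    ann = np.column_stack([
        lab["ggg_high"].astype(int).to_numpy(),
        lab["ece"].astype(int).to_numpy(),
        (lab["pn"] == PN_N1).astype(int).to_numpy(),
    ])
    axes[1].imshow(ann, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    axes[1].set_xticks([0, 1, 2], ["GGG", "ECE", "pN"], rotation=90, fontsize=7)
    axes[1].set_yticks([])
    fig.savefig(path, dpi=120)
    plt.close(fig)
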