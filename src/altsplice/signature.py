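"""Splicing-signature analyses: cross-dataset coherence, correlation-distance
hierarchical clustering of samples, randomized-clustering significance, and
event-event correlation with bootstrap branch confidence.

Distances are 1 - Pearson correlation and linkage is average (UPGMA) unless
stated otherwise.  Branch support uses ordinary bootstrap probability
(fraction of resamples containing the branch).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .models import ClusterReport, CoherenceResult, SignaturePanel

__all__ = [
    "coherence",
    "cluster_samples",
    "misclassification_count",
    "randomized_cluster_pvalue",
    "event_correlation_cluster",
    "EventClusterResult",
]


def coherence(set_a: Mapping[str, float], set_b: Mapping[str, float]) -> CoherenceResult:
    """Direction agreement of per-event inclusion changes between two datasets.

    Compared over the event-id intersection; events with a zero delta in
    either set are excluded.  Symmetric in its two arguments.
    """
    shared = set(set_a) & set(set_b)
    if not shared:
        raise ValueError("no shared events between the two datasets")
    compared = coh = 0
    for eid in shared:
        da, db = set_a[eid], set_b[eid]
        if da == 0 or db == 0:
            continue
        compared += 1
        if (da > 0) == (db > 0):
            coh += 1
    if compared == 0:
        raise ValueError("no events with nonzero deltas in both datasets")
    return CoherenceResult(n_compared=compared, n_coherent=coh)


def _sample_correlation(values: pd.DataFrame) -> np.ndarray:
    """Sample-sample Pearson correlation on complete event rows."""
    complete = values.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete event rows")
    mat = complete.to_numpy(dtype=float)
    sds = mat.std(axis=0)
    if np.any(sds == 0):
        bad = complete.columns[np.nonzero(sds == 0)[0][0]]
        raise ValueError(f"sample {bad!r} is constant; correlation undefined")
    return np.corrcoef(mat.T)


def cluster_samples(panel: SignaturePanel, linkage_method: str = "average") -> ClusterReport:
    """Agglomerative clustering of samples on 1 - Pearson distance.

    Samples are cut into two groups at the top split; when the panel carries
    class labels the misclassification count is minimised over the two
    possible label-to-cluster mappings.
    """
    values = panel.values
    if values.shape[1] < 3:
        raise ValueError("clustering requires at least 3 samples")
    corr = _sample_correlation(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    cut = fcluster(Z, t=2, criterion="maxclust")
    assignments = dict(zip(values.columns, (int(c) for c in cut)))
    mis = None
    if panel.labels is not None:
        mis = misclassification_count(assignments, panel.labels)
    return ClusterReport(linkage=Z, assignments=assignments, misclassified=mis)


def misclassification_count(assignments: Mapping[str, int],
                            labels: Mapping[str, str]) -> int:
    """Minimum misclassifications over the two label-to-cluster mappings.

    Invariant to swapping the two label names.
    """
    names = sorted(set(labels.values()))
    if len(names) != 2:
        raise ValueError("exactly two class labels required")
    a, b = names
    m1 = sum((labels[s] == a) != (c == 1) for s, c in assignments.items())
    return min(m1, len(assignments) - m1)


def randomized_cluster_pvalue(
    full_panel: SignaturePanel,
    fg_event_ids: Sequence[str],
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    linkage_method: str = "average",
) -> tuple[float, int]:
    """Permutation significance of classification by a foreground event set.

    Each permutation draws |fg| rows uniformly without replacement from the
    full panel, clusters the samples, and counts misclassifications;
    p = (1 + #{permutation <= observed}) / (n_perm + 1), the add-one
    estimator, so p is never 0.  Returns (p, observed misclassifications).
    """
    all_ids = list(full_panel.values.index)
    fg = list(fg_event_ids)
    missing = set(fg) - set(all_ids)
    if missing:
        raise ValueError(f"foreground events not in panel: {sorted(missing)[:3]}")
    if len(fg) > len(all_ids):
        raise ValueError("foreground larger than panel")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def mis_for(ids) -> int:
        sub = SignaturePanel(values=full_panel.values.loc[ids], labels=labels,
                             measure=full_panel.measure)
        return cluster_samples(sub, linkage_method).misclassified

    observed = mis_for(fg)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(all_ids), size=len(fg), replace=False)
        if mis_for([all_ids[i] for i in draw]) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1), observed


# ---------------------------------------------------------------------------
# event-event correlation clustering with bootstrap branch support

@dataclass
class EventClusterResult:
    correlation: pd.DataFrame  # event x event Pearson (pairwise-complete)
    linkage: np.ndarray
    branch_support: dict[frozenset, float]  # leaf-name set -> bootstrap prob
    newick: str
    dropped: list[str]  # constant events excluded with notice


def _branches(Z: np.ndarray, names: Sequence[str]) -> set[frozenset]:
    tree = to_tree(Z)
    out: set[frozenset] = set()

    def leaves(node) -> list[int]:
        if node.is_leaf():
            return [node.id]
        l = leaves(node.left) + leaves(node.right)
        if 1 < len(l) < len(names):
            out.add(frozenset(names[i] for i in l))
        return l

    leaves(tree)
    return out


def _to_newick(Z: np.ndarray, names: Sequence[str],
               support: Optional[dict[frozenset, float]] = None) -> str:
    tree = to_tree(Z)

    def walk(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        label = ""
        if support is not None:
            key = frozenset(names[i] for i in node.pre_order(lambda n: n.id))
            if key in support:
                label = f"{support[key]:.3g}"
        return f"({left},{right}){label}:{length:.6g}"

    return walk(tree, tree.dist) + ";"


def event_correlation_cluster(
    panel: SignaturePanel,
    n_boot: int = 100,
    seed: int = 0,
    min_complete: int = 3,
    linkage_method: str = "average",
) -> EventClusterResult:
    """Pairwise event correlations, UPGMA dendrogram and bootstrap support.

    Correlations are pairwise-complete Pearson (pairs with fewer than
    ``min_complete`` shared non-missing samples are treated as missing, i.e.
    correlation 0 for clustering).  Branch support is the fraction of
    ordinary bootstrap resamples (samples drawn with replacement) whose
    dendrogram contains the branch.  Constant event rows are excluded.
    """
    values = panel.values
    sds = values.std(axis=1, skipna=True)
    dropped = list(values.index[(sds < 1e-12) | sds.isna()])
    values = values.drop(index=dropped)
    if values.shape[0] < 2:
        raise ValueError("fewer than 2 variable events")
    names = list(values.index)

    def corr_and_linkage(df: pd.DataFrame):
        corr = df.T.corr(min_periods=min_complete)
        filled = corr.fillna(0.0).to_numpy()
        np.fill_diagonal(filled, 1.0)
        dist = 1.0 - filled
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        Z = linkage(squareform(dist, checks=False), method=linkage_method)
        return corr, Z

    corr, Z = corr_and_linkage(values)
    observed_branches = _branches(Z, names)
    support = {b: 0 for b in observed_branches}
    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_samples, size=n_samples)
        boot = values.iloc[:, cols]
        try:
            _, Zb = corr_and_linkage(boot)
        except ValueError:
            continue
        for b in _branches(Zb, names):
            if b in support:
                support[b] += 1
    branch_support = {b: c / n_boot for b, c in support.items()}
    newick = _to_newick(Z, names, branch_support)
    return EventClusterResult(
        correlation=corr, linkage=Z, branch_support=branch_support,
        newick=newick, dropped=dropped,
    )


def normalize_to_reference(values: pd.DataFrame,
                           reference_samples: Sequence[str]) -> pd.DataFrame:
    """Divide each event row by its mean over the reference samples
    (e.g. inclusion ratios normalised to fibroadenoma reference samples)."""
    ref = values[list(reference_samples)].mean(axis=1, skipna=True)
    if (ref == 0).any():
        bad = list(values.index[ref == 0])
        raise ValueError(f"zero reference mean for events: {bad[:3]}")
    return values.div(ref, axis=0)
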