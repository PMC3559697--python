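"""Sample-level hierarchical clustering on the 2*(1 - cc) correlation scale.

Samples are agglomerated greedily: at each step the pair of clusters with
the smallest distance merges, where the distance between two clusters is
2*(1 - cc) and cc is the Pearson correlation between their average
cube-rooted expression profiles, clamped below at zero.  The clamp keeps
the dendrogram on the stated 0-2 scale (raw Pearson correlation can be
negative, which would exceed 2).  Centroid-style linkage can produce
non-monotone merge heights; a running maximum restores monotonicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["sample_cluster_distance", "agglomerative_cluster", "Dendrogram",
           "plot_dendrogram"]


def _clamped_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation clamped to [0, 1]; zero-variance input gives 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero-variance profile in correlation; treating cc=0")
        return 0.0
    cc = float(np.corrcoef(a, b)[0, 1])
    return max(cc, 0.0)


def sample_cluster_distance(sample_profile, cluster_profiles) -> float:
    """Distance 2*(1 - cc) between a sample and a cluster, with cc the
    Pearson correlation between the sample's cube-rooted profile and the
    entrywise mean of the cluster members' profiles.  Result in [0, 2]."""
    profiles = np.atleast_2d(np.asarray(cluster_profiles, dtype=float))
    if profiles.shape[0] == 0:
        raise ValueError("cluster must be nonempty")
    sample_profile = np.asarray(sample_profile, dtype=float)
    if sample_profile.ndim != 1 or len(sample_profile) < 3:
        raise ValueError("profiles must be 1-D vectors of length >= 3")
    if profiles.shape[1] != len(sample_profile):
        raise ValueError("profile lengths differ")
    cc = _clamped_corr(sample_profile, profiles.mean(axis=0))
    return 2.0 * (1.0 - cc)


@dataclass
class Dendrogram:
    """Binary merge tree over sample ids.

    merges: list of (step, members_a, members_b, height) with members as
    sorted tuples of sample ids; heights lie in [0, 2] and are
    non-decreasing along the merge sequence.
    """
    leaves: list
    merges: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, "|".join(a), "|".join(b), h) for s, a, b, h in self.merges],
            columns=["step", "member_A", "member_B", "height"])

    def write_merge_table(self, path) -> None:
        self.to_merge_table().to_csv(path, sep="\t", index=False)

    def to_newick(self) -> str:
        """Newick string with branch lengths; each merge at height h places
        its children at depth h/2 below it (half the 0-2 diameter scale)."""
        node_height = {(leaf,): 0.0 for leaf in self.leaves}
        node_repr = {(leaf,): leaf for leaf in self.leaves}
        for _, a, b, h in self.merges:
            merged = tuple(sorted(a + b))
            ra = node_repr.pop(tuple(a))
            rb = node_repr.pop(tuple(b))
            ha = node_height.pop(tuple(a))
            hb = node_height.pop(tuple(b))
            la = max(h - ha, 0.0) / 2.0
            lb = max(h - hb, 0.0) / 2.0
            node_repr[merged] = f"({ra}:{la:.6g},{rb}:{lb:.6g})"
            node_height[merged] = h
        (root_repr,) = node_repr.values()
        return root_repr + ";"

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix in scipy.cluster.hierarchy convention."""
        index = {(leaf,): i for i, leaf in enumerate(self.leaves)}
        Z = np.zeros((len(self.merges), 4))
        next_id = len(self.leaves)
        for row, (_, a, b, h) in enumerate(self.merges):
            ia = index.pop(tuple(a))
            ib = index.pop(tuple(b))
            merged = tuple(sorted(a + b))
            Z[row] = [min(ia, ib), max(ia, ib), h, len(merged)]
            index[merged] = next_id
            next_id += 1
        return Z


def agglomerative_cluster(m: pd.DataFrame, mirna_subset=None) -> Dendrogram:
    """Greedy agglomeration of samples (columns of ``m``) using the
    clamped-correlation distance between cluster average profiles.

    ``m`` should already be cube-root transformed; ``mirna_subset``
    optionally restricts to a feature subset (e.g. the zero-q miRNAs).
    Ties in the minimal distance are broken by the lexicographically
    smallest pair of sorted member-id tuples, making the tree
    deterministic.  Merge heights are made monotone by a running maximum.
    """
    if mirna_subset is not None:
        mirna_subset = list(mirna_subset)
        if len(mirna_subset) == 0:
            raise ValueError("miRNA subset must be nonempty")
        m = m.loc[mirna_subset]
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    samples = list(m.columns)
    clusters = {(s,): m[s].to_numpy(dtype=float) for s in samples}
    merges = []
    height = 0.0
    step = 0
    while len(clusters) > 1:
        keys = sorted(clusters.keys())
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                cc = _clamped_corr(clusters[keys[i]], clusters[keys[j]])
                d = 2.0 * (1.0 - cc)
                cand = (d, keys[i], keys[j])
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        height = max(height, d)  # running max keeps heights monotone
        step += 1
        merges.append((step, a, b, height))
        merged = tuple(sorted(a + b))
        del clusters[a], clusters[b]
        # cluster profile = mean over member samples (recomputed exactly)
        clusters[merged] = m[list(merged)].to_numpy(dtype=float).mean(axis=1)
    return Dendrogram(leaves=samples, merges=merges)


def plot_dendrogram(dendrogram: Dendrogram, ax=None):
    """Render the dendrogram (0-2 height scale) via scipy/matplotlib."""
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scipy_dendrogram(dendrogram.to_scipy_linkage(),
                         labels=dendrogram.leaves, ax=ax)
    ax.set_ylabel("2(1 - cc)")
    ax.set_ylim(0, 2)
    return ax
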