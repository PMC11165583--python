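"""Covariation structure of longitudinal concentration profiles.

Proteins whose plasma concentrations rise and fall together across samples
(for example the three fibrinogen chains of one stoichiometric complex, or
co-regulated acute-phase proteins) are found by hierarchical clustering:
pairwise distances are 1 - Pearson correlation of the z-scored log10
trajectories, agglomerated with complete linkage, and the tree is cut at a
height of 0.3 to delimit co-varying classes.  The same machinery applied to
the sample dimension yields a sample dendrogram in which donors' healthy
and inflamed states separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calibration import ConcentrationMatrix

DEFAULT_CLUSTER_CUT = 0.3
MIN_PAIRWISE_OVERLAP = 3


@dataclass
class Dendrogram:
    """A complete-linkage merge tree over labeled leaves."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: tuple[str, ...]
    method: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float = DEFAULT_CLUSTER_CUT) -> list[set[str]]:
        """Partition leaves into connected components of merges below height.

        The comparison is strict, so ``cut(0)`` returns singletons and any
        height above the root returns one cluster.
        """
        n = len(self.labels)
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for k, (a, b, h, _) in enumerate(self.linkage):
            if h < height:
                ra, rb = find(int(a)), find(int(b))
                parent[ra] = parent[rb] = n + k
        groups: dict[int, set[str]] = {}
        for i, lab in enumerate(self.labels):
            groups.setdefault(find(i), set()).add(lab)
        return sorted(groups.values(), key=lambda s: sorted(s)[0])

    def join_height(self, members: list[str] | set[str]) -> float:
        """Smallest height at which all given leaves share one cluster.

        Equals the maximum pairwise cophenetic distance among the members.
        """
        idx = [self.labels.index(m) for m in members]
        coph = squareform(hierarchy.cophenet(self.linkage))
        return float(max(coph[i, j] for i in idx for j in idx if i < j))

    def to_newick(self) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        return str(tree).strip()


def _correlation_distances(z: pd.DataFrame) -> pd.DataFrame:
    """1 - pairwise-complete Pearson correlation between the rows of z.

    Rows with zero variance (or fewer than :data:`MIN_PAIRWISE_OVERLAP`
    observations against every partner) are excluded with a warning.
    """
    variances = z.var(axis=1, ddof=1)
    degenerate = list(z.index[(variances == 0) | variances.isna()])
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance row(s): {degenerate}",
            stacklevel=3,
        )
        z = z.drop(index=degenerate)
    corr = z.T.corr(method="pearson", min_periods=MIN_PAIRWISE_OVERLAP)
    incomplete = list(corr.index[corr.isna().any(axis=1)])
    if incomplete:
        warnings.warn(
            f"excluding {len(incomplete)} row(s) with insufficient pairwise "
            f"overlap: {incomplete}",
            stacklevel=3,
        )
        corr = corr.drop(index=incomplete, columns=incomplete)
    dist = (1.0 - corr).clip(lower=0.0, upper=2.0)
    np.fill_diagonal(dist.values, 0.0)
    return dist


def protein_distance_matrix(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Protein-protein distances: 1 - Pearson r of z-scored log10 trajectories."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to correlate trajectories")
    # constant rows come out of zscore() as all-zero and are dropped below
    return _correlation_distances(matrix.zscore())


def sample_distance_matrix(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Sample-sample distances: 1 - Pearson r over the protein dimension.

    Computed on log10 concentrations (not z-scores): a sample's proteome
    profile is its abundance pattern across proteins, and per-protein
    standardization would erase exactly the shared profile that makes two
    proteomes alike.
    """
    logc = np.log10(matrix.values.where(matrix.values > 0))
    return _correlation_distances(logc.T)


def complete_linkage_tree(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage tree from a symmetric distance matrix.

    Leaves are ordered lexicographically before linkage so that equal-
    distance merges resolve deterministically.
    """
    if distances.shape[0] != distances.shape[1] or not np.allclose(
        distances.values, distances.values.T, atol=1e-12
    ):
        raise ValueError("distance matrix must be square and symmetric")
    labels = tuple(sorted(distances.index))
    d = distances.loc[list(labels), list(labels)]
    condensed = squareform(d.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(linkage=linkage, labels=labels)


def cut_clusters(
    tree: Dendrogram, height: float = DEFAULT_CLUSTER_CUT
) -> list[set[str]]:
    """Clusters at a cut height (merges strictly below the height join)."""
    if height < 0:
        raise ValueError("cut height must be >= 0")
    return tree.cut(height)


def protein_dendrogram(matrix: ConcentrationMatrix) -> Dendrogram:
    """Complete-linkage dendrogram over proteins."""
    return complete_linkage_tree(protein_distance_matrix(matrix))


def sample_dendrogram(matrix: ConcentrationMatrix) -> Dendrogram:
    """Complete-linkage dendrogram over samples (proteome similarity)."""
    return complete_linkage_tree(sample_distance_matrix(matrix))
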