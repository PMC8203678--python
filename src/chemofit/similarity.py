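"""Cofitness / coinhibition correlation matrices and Ward clustering.

Coinhibition is the pairwise Pearson correlation between screens' FD
profiles across genes (similar profiles suggest similar mechanism of
action); cofitness is the Pearson correlation between genes' FD profiles
across screens (high cofitness suggests functional relatedness).  Profiles
are hierarchically clustered with distance 1 - r and Ward's minimum-variance
agglomeration (classical Ward.D on the supplied dissimilarity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "coinhibition_matrix",
    "cofitness_matrix",
    "ward_cluster",
    "top_cofit",
]


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson-r matrix over screens (coinhibition) or genes
    (cofitness); ``n_pairs`` counts the pairwise-complete observations."""

    values: pd.DataFrame
    kind: str  # "cofitness" | "coinhibition"
    n_pairs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def labels(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path, sep="\t")
        return path


@dataclass
class Dendrogram:
    """Binary merge tree (scipy linkage encoding) over ``labels``."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) at k clusters."""
        assignment = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self, path: str | Path | None = None) -> str:
        from scipy.cluster.hierarchy import to_tree

        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        text = walk(tree, tree.dist) + ";"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _pearson(frame: pd.DataFrame, kind: str, min_pairs: int = 3) -> SimilarityMatrix:
    """Pairwise-complete Pearson correlation between the columns of frame."""
    stds = frame.std(axis=0, skipna=True)
    degenerate = stds[stds == 0].index
    if len(degenerate):
        warnings.warn(
            f"{kind}: zero-variance profiles reported as missing: "
            f"{list(degenerate)[:5]}",
            stacklevel=2,
        )
    r = frame.corr(method="pearson", min_periods=min_pairs)
    r.loc[:, degenerate] = np.nan
    r.loc[degenerate, :] = np.nan
    np.fill_diagonal(r.values, 1.0)
    notna = frame.notna().astype(float)
    n_pairs = notna.T @ notna
    return SimilarityMatrix(values=r, kind=kind, n_pairs=n_pairs)


def coinhibition_matrix(fd: pd.DataFrame, min_pairs: int = 3) -> SimilarityMatrix:
    """Screen x screen Pearson r of FD profiles (fd is genes x screens)."""
    return _pearson(fd, kind="coinhibition", min_pairs=min_pairs)


def cofitness_matrix(fd: pd.DataFrame, min_screens: int = 6) -> SimilarityMatrix:
    """Gene x gene Pearson r of FD profiles across screens.

    Genes observed in fewer than ``min_screens`` screens (or with zero
    variance) are excluded: Pearson r on very few points is noise.
    """
    if fd.shape[1] < min_screens:
        raise ValueError(f"need >= {min_screens} screens for cofitness")
    enough = fd.notna().sum(axis=1) >= min_screens
    varying = fd.std(axis=1, skipna=True) > 0
    kept = fd.index[enough & varying]
    return _pearson(fd.loc[kept].T, kind="cofitness", min_pairs=min_screens)


def ward_cluster(sim: SimilarityMatrix, variant: str = "ward_d") -> Dendrogram:
    """Agglomerative clustering of 1 - r with Ward's criterion.

    ``ward_d`` applies the classical Ward (Lance-Williams) recurrence to the
    1 - r dissimilarities themselves; ``ward_d2`` applies it to their
    squares.  Missing correlations are imputed as r = 0 with a warning.
    """
    values = sim.values.to_numpy(dtype=float).copy()
    if values.shape[0] < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if np.isnan(values).any():
        warnings.warn("missing correlations imputed as r=0 for clustering", stacklevel=2)
        values = np.where(np.isnan(values), 0.0, values)
        np.fill_diagonal(values, 1.0)
    d = np.clip(1.0 - values, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    condensed = squareform(d, checks=False)
    if variant == "ward_d":
        # scipy's 'ward' implements the recurrence on squared input
        # distances, i.e. R's ward.D2; feeding sqrt(d) and squaring the
        # heights recovers classical ward.D on d.
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    elif variant == "ward_d2":
        z = linkage(condensed, method="ward")
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    return Dendrogram(linkage_matrix=z, labels=list(sim.labels))


def top_cofit(gene: str, sim: SimilarityMatrix, k: int = 10) -> list[tuple[str, float]]:
    """The k most-correlated partners of ``gene``, descending r, self
    excluded, ties broken lexicographically."""
    if gene not in sim.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    col = sim.values[gene].drop(index=gene).dropna()
    ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, float(r)) for g, r in ranked[:k]]
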