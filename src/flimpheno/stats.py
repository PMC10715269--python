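"""Group-difference testing and low-dimensional visualization.

Pairwise two-sided Wilcoxon rank-sum (Mann-Whitney) tests with Bonferroni
correction over the pairwise family within one feature, and a seeded UMAP
embedding of the z-scored twelve-feature space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .synth import FEATURE_NAMES

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool

    def __post_init__(self):
        assert self.p_adjusted >= self.p_value - 1e-15
        assert self.p_adjusted <= 1.0 + 1e-15


def wilcoxon_bonferroni(features: pd.DataFrame, feature: str,
                        group_col: str = "group",
                        alpha: float = ALPHA) -> list:
    """All pairwise rank-sum tests for one feature, Bonferroni-adjusted.

    The correction factor is the number of pairwise comparisons performed for
    this feature.  Constant data yields p = 1, never an exception.
    """
    groups = sorted(features[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    out = []
    for ga, gb in pairs:
        xa = features.loc[features[group_col] == ga, feature].dropna().to_numpy()
        xb = features.loc[features[group_col] == gb, feature].dropna().to_numpy()
        if min(xa.size, xb.size) < 2:
            raise ValueError(f"groups {ga!r}/{gb!r} need >= 2 cells each")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            stat, p = float(xa.size * xb.size / 2), 1.0
        else:
            stat, p = mannwhitneyu(xa, xb, alternative="two-sided")
        p_adj = min(p * m, 1.0)
        out.append(GroupComparison(feature=feature, group_a=ga, group_b=gb,
                                   statistic=float(stat), p_value=float(p),
                                   p_adjusted=p_adj,
                                   significant=p_adj < alpha))
    return out


def compare_all_features(features: pd.DataFrame, group_col: str = "group",
                         feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Tidy table of every pairwise comparison for every feature."""
    rows = []
    for f in feature_names:
        for cmpn in wilcoxon_bonferroni(features, f, group_col=group_col):
            rows.append(vars(cmpn))
    return pd.DataFrame(rows)


def umap_embed(features: pd.DataFrame, seed: int = 0,
               feature_names=FEATURE_NAMES, n_neighbors: int = 15,
               min_dist: float = 0.1) -> np.ndarray:
    """Deterministic 2-D UMAP embedding of z-scored features (one row/cell)."""
    import umap  # deferred: numba-jitted import is slow

    X = features[list(feature_names)].to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells to embed")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    if n_neighbors >= X.shape[0]:
        n_neighbors = max(X.shape[0] - 1, 2)
        warnings.warn(f"reduced n_neighbors to {n_neighbors}", stacklevel=2)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return reducer.fit_transform(X)


def plot_embedding(coords: np.ndarray, groups, path):
    """Scatter of a 2-D embedding colored by group; writes a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in np.unique(groups):
        sel = groups == g
        ax.scatter(coords[sel, 0], coords[sel, 1], s=8, label=str(g), alpha=0.7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
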