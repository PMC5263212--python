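"""mRMR feature ranking and leave-one-out vote selection.

Relevance of a feature is its mutual information with the class; redundancy
is its mean mutual information with the features already picked. Greedy
forward selection with the MID (difference) criterion ranks candidates;
across leave-one-out folds each feature earns one vote per fold whose
top-N set contains it, and the N highest-voted features form the final set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

__all__ = ["mutual_information", "discretize", "mrmr_rank", "vote_select", "PRESET_FEATURES"]

# The study's headline final feature set: normalized mean intensity, one
# fractal-dimension band, two texton channels and mean curvature.
PRESET_FEATURES = ("int_mean", "frac_dim_1", "texton_1", "texton_2", "curv_mean")


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) from the joint contingency table."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("mutual_information requires equal-length inputs")
    return float(mutual_info_score(y, x) / np.log(2.0))


def discretize(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency discretization into at most n_bins integer codes."""
    x = np.asarray(x, dtype=np.float64)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mrmr_rank(X: np.ndarray | pd.DataFrame, y: np.ndarray, n_select: int = 5,
              n_bins: int = 10, scheme: str = "MID") -> list[int]:
    """Greedy mRMR forward selection; returns column indices in pick order.

    The first pick maximizes relevance I(f; c). Each later pick maximizes
    relevance - mean redundancy (MID) or relevance / mean redundancy (MIQ)
    against the already-selected set. Deterministic: ties go to the lowest
    column index.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=np.float64)
    n_features = X.shape[1]
    if n_select > n_features:
        raise ValueError("n_select exceeds the number of candidate features")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    disc = [discretize(X[:, j], n_bins) for j in range(n_features)]
    relevance = np.array([mutual_information(disc[j], y) for j in range(n_features)])
    selected: list[int] = []
    remaining = list(range(n_features))
    red_cache: dict[tuple[int, int], float] = {}

    def red(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in red_cache:
            red_cache[key] = mutual_information(disc[i], disc[j])
        return red_cache[key]

    while len(selected) < n_select:
        if not selected:
            scores = relevance[remaining]
        else:
            scores = np.empty(len(remaining))
            for pos, j in enumerate(remaining):
                mean_red = np.mean([red(j, s) for s in selected])
                if scheme == "MID":
                    scores[pos] = relevance[j] - mean_red
                else:
                    scores[pos] = relevance[j] / (mean_red + 1e-12)
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


def vote_select(per_fold_rankings: list[list[int]], n_fea: int = 5) -> list[int]:
    """Aggregate per-fold top-N rankings into the final feature set.

    A feature gets one vote per fold whose ranking contains it. The n_fea
    highest-voted features win; ties break on better (lower) mean rank
    within the folds that selected the feature, then on lower feature index.
    """
    if not per_fold_rankings:
        raise ValueError("vote_select requires at least one fold")
    votes: dict[int, int] = {}
    ranks: dict[int, list[int]] = {}
    for ranking in per_fold_rankings:
        for pos, f in enumerate(ranking[:n_fea]):
            votes[f] = votes.get(f, 0) + 1
            ranks.setdefault(f, []).append(pos)
    order = sorted(votes, key=lambda f: (-votes[f], float(np.mean(ranks[f])), f))
    return order[:n_fea]
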