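"""Background-cohort co-occurrence and the per-patient redundancy penalty.

Selected features are compared on a large *unlabeled* background corpus
(the stand-in for a pan-cancer cohort): K_ij is the Otsuka-Ochiai
coefficient |S_i & S_j| / sqrt(|S_i| |S_j|) of the background sample sets in
which features i and j occur — the cosine similarity of their indicator
vectors.  Features are then grouped by complete-linkage hierarchical
clustering, and for each patient the penalization factor of a present
feature i is the sum of K_ij over the patient's present features j in i's
cluster (self term included), so eps_i >= 1 always.  Restricting the sum to
the cluster removes the cumulative effect of many small, non-significant
overlaps.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import io as _io

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_HEIGHT = 2.0

#: Dissimilarities available for clustering the similarity matrix.
#: 'profile'    — Euclidean distance between rows of K (similarity profiles);
#:               this is the default because a tree cut at height 2 is
#:               meaningful on that scale.
#: 'one_minus_k' — 1 - K_ij directly (range [0, 1]).
CLUSTER_METRICS = ("profile", "one_minus_k")


class BackgroundCorpus:
    """feature id -> set of background-sample ids, over a declared universe."""

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None):
        self.sets: dict[str, frozenset[str]] = {f: frozenset(s) for f, s in sets.items()}
        if universe is None:
            universe = set().union(*self.sets.values()) if self.sets else set()
        self.universe: frozenset[str] = frozenset(universe)
        if not self.universe:
            raise ValueError("background corpus has an empty sample universe")
        stray = set().union(*self.sets.values(), frozenset()) - self.universe
        if stray:
            raise ValueError(f"corpus sets contain samples outside the universe: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.sets

    def get(self, feature_id: str) -> frozenset[str]:
        return self.sets.get(feature_id, frozenset())

    @classmethod
    def from_gmt(cls, path) -> "BackgroundCorpus":
        fm = _io.read_feature_gmt(path)
        cols = np.asarray(fm.columns, dtype=object)
        arr = fm.to_numpy()
        sets = {fid: frozenset(cols[arr[i] > 0]) for i, fid in enumerate(fm.index)}
        return cls(sets, universe=fm.columns)

    def to_gmt(self, path) -> None:
        ids = list(self.sets)
        cols = pd.Index(sorted(self.universe), name="sample_id")
        col = {s: j for j, s in enumerate(cols)}
        data = np.zeros((len(ids), len(cols)), dtype=np.uint8)
        for i, fid in enumerate(ids):
            for s in self.sets[fid]:
                data[i, col[s]] = 1
        _io.write_feature_gmt(pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=cols), path)


def ochiai_similarity(corpus: BackgroundCorpus, features: Sequence[str]) -> pd.DataFrame:
    """Otsuka-Ochiai similarity matrix over the given features.

    Features with an empty (or missing) background set get an identity row:
    K_ii = 1 by convention and K_ij = 0 for j != i, i.e. no penalty beyond
    the self term.  Missing features are logged.
    """
    features = list(features)
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature ids in similarity request")
    missing = [f for f in features if f not in corpus]
    if missing:
        logger.warning(
            "%d features absent from the background corpus get identity rows", len(missing)
        )
    universe = sorted(corpus.universe)
    col = {s: j for j, s in enumerate(universe)}
    A = np.zeros((len(features), len(universe)), dtype=np.float64)
    for i, f in enumerate(features):
        for s in corpus.get(f):
            A[i, col[s]] = 1.0
    sizes = A.sum(axis=1)
    inter = A @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        K = inter / np.sqrt(np.outer(sizes, sizes))
    K[~np.isfinite(K)] = 0.0
    np.fill_diagonal(K, 1.0)
    idx = pd.Index(features, name="feature_id")
    return pd.DataFrame(K, index=idx, columns=idx)


def cluster_features(
    K: pd.DataFrame,
    height: float = DEFAULT_CLUSTER_HEIGHT,
    metric: str = "profile",
) -> pd.Series:
    """Complete-linkage clustering of features, tree cut at ``height``.

    With the default 'profile' metric, items are the rows of K and the
    dissimilarity is their Euclidean distance, so two features belong
    together when they relate to *all* features similarly; exact duplicates
    are at distance 0 and can never be separated.  Singletons are allowed.
    """
    if metric not in CLUSTER_METRICS:
        raise ValueError(f"metric must be one of {CLUSTER_METRICS}")
    n = K.shape[0]
    if n == 0:
        return pd.Series([], dtype=int, index=K.index, name="cluster")
    if n == 1:
        return pd.Series([1], index=K.index, name="cluster")
    if metric == "profile":
        D = pdist(K.to_numpy(), metric="euclidean")
    else:
        D = squareform(1.0 - K.to_numpy(), checks=False)
    Z = linkage(D, method="complete")
    labels = fcluster(Z, t=height, criterion="distance")
    return pd.Series(labels.astype(int), index=K.index, name="cluster")


def penalization_factors(
    present_features: Sequence[str], K: pd.DataFrame, clusters: pd.Series
) -> pd.Series:
    """Per-feature redundancy penalties eps for one patient.

    eps_i = sum of K_ij over the patient's present features j sharing i's
    cluster, including j = i; hence 1 <= eps_i <= |cluster of i|.
    """
    present = list(present_features)
    missing = [f for f in present if f not in K.index]
    if missing:
        raise KeyError(f"features absent from the similarity matrix: {missing}")
    if not present:
        return pd.Series([], dtype=float, name="epsilon")
    pos = K.index.get_indexer(present)
    sub = K.to_numpy()[np.ix_(pos, pos)]
    labels = clusters.to_numpy()[pos]
    same = labels[:, None] == labels[None, :]
    eps = (sub * same).sum(axis=1)
    return pd.Series(eps, index=pd.Index(present, name="feature_id"), name="epsilon")
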