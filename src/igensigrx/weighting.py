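"""Phi-coefficient feature weighting and the selection/consistency filters.

Each binary genomic feature is weighted by its phi coefficient (the Pearson
correlation of two 0/1 vectors, equivalently the mean-square-contingency
coefficient of the 2x2 table) against the binary response.  Features with
phi >= cutoff against pCR form the *sensitive* class; features with
phi >= cutoff against the complement label (non-pCR) form the *resistant*
class, so every retained weight omega is positive and the classes are
symmetric.  A gene whose up- and down-regulation features both predict the
same class is internally inconsistent and all its expression features are
dropped from that class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import parse_feature_id

logger = logging.getLogger(__name__)

#: Default selection threshold on phi.
DEFAULT_PHI_CUTOFF = 0.13

SENSITIVE = "sensitive"
RESISTANT = "resistant"


def phi_coefficient(x, y) -> float:
    """Phi coefficient of two equal-length binary vectors.

    Returns NaN (undefined) when either vector is constant — never 0, so an
    undefined association can not masquerade as independence.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("phi_coefficient needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("phi_coefficient needs length >= 2")
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    n = x.size
    n11 = int(np.sum((x == 1) & (y == 1)))
    r1 = int(x.sum())
    c1 = int(y.sum())
    n10 = r1 - n11
    n01 = c1 - n11
    n00 = n - r1 - c1 + n11
    denom = r1 * (n - r1) * c1 * (n - c1)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def phi_profile(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized phi of every row of a 0/1 matrix against one 0/1 vector.

    Rows (or a constant y) with a zero margin get NaN.
    """
    X = np.asarray(X, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    n11 = X @ y
    r1 = X.sum(axis=1)
    c1 = int(y.sum())
    n10 = r1 - n11
    n01 = c1 - n11
    n00 = n - r1 - c1 + n11
    denom = r1 * (n - r1) * c1 * (n - c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n11 * n00 - n10 * n01) / np.sqrt(denom.astype(float))
    phi[denom == 0] = np.nan
    return phi


def select_predictive_features(
    fm: pd.DataFrame, y: pd.Series, cutoff: float = DEFAULT_PHI_CUTOFF
) -> pd.DataFrame:
    """Retain features whose phi against either class passes the cutoff.

    Returns a weight table indexed by feature id with columns ``class``
    (sensitive/resistant) and ``omega`` (the phi weight, always >= cutoff).
    phi(x, 1-y) = -phi(x, y), so the resistant class is exactly the features
    with phi <= -cutoff, carried with positive weight.  Features with
    undefined phi (constant across training samples) are silently excluded
    (logged).  Comparison is >= : the method removes features *below* the
    cutoff.
    """
    missing = [s for s in fm.columns if s not in y.index]
    if missing or len(y) != fm.shape[1]:
        raise ValueError("feature matrix and response cover different samples")
    yv = y.loc[fm.columns].to_numpy(dtype=np.int64)
    if yv.min() == yv.max():
        raise ValueError("training response must contain both classes")
    phi = phi_profile(fm.to_numpy(), yv)

    undefined = np.isnan(phi)
    if undefined.any():
        logger.info("excluding %d features with undefined phi", int(undefined.sum()))

    sens = ~undefined & (phi >= cutoff)
    res = ~undefined & (-phi >= cutoff)

    table = pd.DataFrame(
        {
            "class": np.where(sens, SENSITIVE, RESISTANT),
            "omega": np.where(sens, phi, -phi),
        },
        index=fm.index,
    )[sens | res]
    table.index.name = "feature_id"

    n_sens = int(sens.sum())
    n_res = int(res.sum())
    if n_sens == 0 and n_res == 0:
        raise ValueError(f"no predictive features at cutoff {cutoff}")
    if n_sens == 0 or n_res == 0:
        empty = SENSITIVE if n_sens == 0 else RESISTANT
        logger.warning("no features pass cutoff %.3g in the %s class", cutoff, empty)
    return table


def filter_same_trend_genes(wt: pd.DataFrame) -> pd.DataFrame:
    """Drop expression features of genes whose Up and Down both predict one class.

    Applied independently within each class, after selection.  A gene that is
    predictive of the same response whether up- or down-regulated is a sign
    of confounding rather than signal.  Mutation/AGR features are never
    removed here.
    """
    keep = np.ones(len(wt), dtype=bool)
    parsed = [parse_feature_id(f) for f in wt.index]
    for cls in (SENSITIVE, RESISTANT):
        in_cls = (wt["class"] == cls).to_numpy()
        dirs_by_gene: dict[str, set[str]] = {}
        for flag, name in zip(in_cls, parsed):
            if flag and name.modality == "expr":
                dirs_by_gene.setdefault(name.gene, set()).add(name.direction)
        bad = {g for g, d in dirs_by_gene.items() if {"up", "down"} <= d}
        if bad:
            logger.info("same-trend filter removes %d genes from %s class", len(bad), cls)
        for i, (flag, name) in enumerate(zip(in_cls, parsed)):
            if flag and name.modality == "expr" and name.gene in bad:
                keep[i] = False
    return wt[keep]
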