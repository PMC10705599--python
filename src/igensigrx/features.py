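"""Multi-level binary genomic feature extraction.

Continuous expression profiles are converted into a deliberately redundant
set of binary "genomic features": for every gene, twelve nested levels of
up-regulation and twelve of down-regulation, where level L flags the samples
whose within-gene rank places them in the top (or bottom) ``f_L`` fraction of
the cohort.  Gene-level mutation and adjacent-gene-rearrangement (AGR) calls
enter as additional binary features.  Binarization is always performed within
a cohort, never by transferring thresholds, which keeps the representation
comparable across platforms (RNA-seq vs microarray).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cohort fractions for levels 1..12; level 1 is the least stringent (largest
#: fraction of the cohort flagged), level 12 the most stringent.
DEFAULT_LEVEL_FRACTIONS: tuple[float, ...] = (
    0.60, 0.55, 0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05,
)

VARIANT_CLASSES = frozenset({"nonsynonymous", "AGR", "other"})

_EXPR_RE = re.compile(r"^(?P<gene>.+)_(?P<direction>Up|Down)_Level(?P<level>\d+)$")
_MUT_RE = re.compile(r"^(?P<gene>.+)_(?P<modality>Mut|AGR)$")


@dataclass(frozen=True)
class LevelScheme:
    """Ordered cohort-fraction cutoffs for the expression levels.

    ``fractions[L-1]`` is the fraction of the cohort flagged at level L.
    Fractions must be strictly decreasing in L and lie in (0, 1).
    """

    fractions: tuple[float, ...] = DEFAULT_LEVEL_FRACTIONS

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.fractions)
        object.__setattr__(self, "fractions", f)
        if not f:
            raise ValueError("LevelScheme needs at least one fraction")
        if any(not (0.0 < x < 1.0) for x in f):
            raise ValueError(f"level fractions must lie in (0, 1), got {f}")
        if any(b >= a for a, b in zip(f, f[1:])):
            raise ValueError(f"level fractions must be strictly decreasing, got {f}")

    @property
    def n_levels(self) -> int:
        return len(self.fractions)

    def counts(self, n_samples: int) -> list[int]:
        """Number of samples flagged at each level: ceil(f_L * n)."""
        return [math.ceil(f * n_samples) for f in self.fractions]


@dataclass(frozen=True)
class FeatureName:
    """Parsed structure of a feature identifier."""

    gene: str
    modality: str  # 'expr' | 'mut' | 'agr'
    direction: Optional[str] = None  # 'up' | 'down' for expression features
    level: Optional[int] = None


def expr_feature_id(gene: str, direction: str, level: int) -> str:
    tag = {"up": "Up", "down": "Down"}[direction]
    return f"{gene}_{tag}_Level{level}"


def mutation_feature_id(gene: str, modality: str) -> str:
    tag = {"mut": "Mut", "agr": "AGR"}[modality]
    return f"{gene}_{tag}"


def parse_feature_id(feature_id: str) -> FeatureName:
    m = _EXPR_RE.match(feature_id)
    if m:
        return FeatureName(
            gene=m.group("gene"),
            modality="expr",
            direction=m.group("direction").lower(),
            level=int(m.group("level")),
        )
    m = _MUT_RE.match(feature_id)
    if m:
        modality = {"Mut": "mut", "AGR": "agr"}[m.group("modality")]
        return FeatureName(gene=m.group("gene"), modality=modality)
    raise ValueError(f"unparseable feature id: {feature_id!r}")


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups}")


def derive_expression_features(
    expr: pd.DataFrame, scheme: LevelScheme | None = None
) -> pd.DataFrame:
    """Binarize a gene-by-sample expression matrix into leveled features.

    For gene g and level L, ``g_Up_LevelL`` flags the ceil(f_L * n) samples
    with the highest expression of g (descending rank); ``g_Down_LevelL`` the
    analog with ascending rank.  Ranks are taken within the cohort, so any
    strictly monotone transform of a gene's values yields identical features.

    Ties are broken by sample identifier (stable, deterministic).  Samples
    with missing values are excluded from that gene's ranking and receive 0.
    Constant genes emit no features (warning logged).
    """
    if scheme is None:
        scheme = LevelScheme()
    _validate_expression(expr)
    samples = expr.columns
    n_total = len(samples)
    if n_total < 2:
        raise ValueError("need at least 2 samples to derive expression features")

    # tie-break key: position of each sample id in lexicographic order
    sample_order = np.argsort(np.argsort(samples.to_numpy().astype(str), kind="stable"))

    values = expr.to_numpy(dtype=float)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    levels = range(1, scheme.n_levels + 1)
    for gi, gene in enumerate(expr.index):
        v = values[gi]
        valid = np.isfinite(v)
        n_valid = int(valid.sum())
        if n_valid < 2 or np.nanmin(v[valid]) == np.nanmax(v[valid]):
            logger.warning("gene %s is constant or too sparse; no expression features", gene)
            continue
        counts = scheme.counts(n_valid)
        vv = v[valid]
        key = sample_order[valid]
        for direction, sort_vals in (("up", -vv), ("down", vv)):
            order = np.lexsort((key, sort_vals))
            pos = np.empty(n_valid, dtype=int)
            pos[order] = np.arange(n_valid)
            for lvl, k in zip(levels, counts):
                row = np.zeros(n_total, dtype=np.uint8)
                row[np.flatnonzero(valid)[pos < k]] = 1
                rows.append(row)
                ids.append(expr_feature_id(gene, direction, lvl))
    if rows:
        data = np.vstack(rows)
    else:
        data = np.zeros((0, n_total), dtype=np.uint8)
    return pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=samples)


def derive_mutation_features(
    muts: pd.DataFrame, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Collapse a MAF-lite table into per-(gene, modality) presence features.

    ``nonsynonymous`` records feed ``<gene>_Mut`` features, ``AGR`` records
    feed ``<gene>_AGR``; ``other`` records are ignored.  Presence is 1 iff a
    sample has at least one qualifying record (never a count).
    """
    sample_index = pd.Index(sample_ids)
    if sample_index.duplicated().any():
        raise ValueError("duplicate sample identifiers in cohort")
    required = {"sample_id", "gene_id", "variant_class"}
    if not required.issubset(muts.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")

    bad_class = set(muts["variant_class"]) - VARIANT_CLASSES
    if bad_class:
        raise ValueError(f"unknown variant_class values: {sorted(bad_class)}")
    unknown = sorted(set(muts["sample_id"]) - set(sample_index))
    if unknown:
        raise ValueError(f"mutation records name samples outside the cohort: {unknown}")

    modality_of = {"nonsynonymous": "mut", "AGR": "agr"}
    feats: dict[str, set[str]] = {}
    for rec in muts.itertuples(index=False):
        modality = modality_of.get(rec.variant_class)
        if modality is None:
            continue
        fid = mutation_feature_id(rec.gene_id, modality)
        feats.setdefault(fid, set()).add(rec.sample_id)

    ids = sorted(feats)
    data = np.zeros((len(ids), len(sample_index)), dtype=np.uint8)
    col = {s: j for j, s in enumerate(sample_index)}
    for i, fid in enumerate(ids):
        for s in feats[fid]:
            data[i, col[s]] = 1
    return pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=sample_index)


def merge_feature_matrices(parts: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Row-concatenate feature matrices sharing one sample set.

    Parts may list their samples in any order; columns are aligned to the
    first part.  Duplicate feature ids or mismatched sample sets are errors.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("no feature matrices to merge")
    ref = parts[0].columns
    aligned = [parts[0]]
    for p in parts[1:]:
        if set(p.columns) != set(ref):
            raise ValueError("feature matrices cover different sample sets")
        aligned.append(p.loc[:, ref])
    merged = pd.concat(aligned, axis=0)
    if merged.index.duplicated().any():
        dups = merged.index[merged.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids across parts: {dups}")
    return merged.astype(np.uint8)


def drop_weak_level_features(fm: pd.DataFrame) -> pd.DataFrame:
    """Remove all level-1 expression features (both directions).

    The least stringent level flags over half the cohort, so its features
    carry little signal and only add bias; mutation/AGR features are kept.
    """
    keep = []
    for fid in fm.index:
        name = parse_feature_id(fid)
        keep.append(not (name.modality == "expr" and name.level == 1))
    return fm.loc[keep]
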