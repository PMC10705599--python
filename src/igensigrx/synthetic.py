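"""Synthetic cohorts and background corpora with planted predictive structure.

The generator emulates the statistical skeleton the method assumes, not
breast-cancer biology: a binary response, a block of sensitive-driving genes
shifted up in responders and resistant-driving genes shifted up in
non-responders (log-normal expression, shift in within-gene SD units on the
log scale), sparse Bernoulli mutations with a few response-linked genes,
and an unlabeled background corpus whose features occur in block-correlated
sample sets — real redundancy for the penalty to act on.

Signature genes occupy fixed positions (the first genes of the panel), so
two cohorts drawn with different seeds share the planted structure and can
serve as train/validation pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .redundancy import BackgroundCorpus

_BG_STREAM = 0xB6  # distinguishes the corpus RNG stream from the cohort's


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic experiment; the seed is mandatory."""

    seed: int
    n_samples: int = 200
    n_genes: int = 500
    n_sensitive_genes: int = 25
    n_resistant_genes: int = 25
    effect_size: float = 3.0  # log-scale shift in within-gene SD units
    pcr_rate: float = 0.45  # responder fraction, neoadjuvant-trial-like
    mutation_rate: float = 0.03  # background per-gene per-sample rate
    n_mut_signature_genes: int = 5  # signature genes with response-linked mutations
    mut_signature_rate: float = 0.35
    n_background_samples: int = 1000
    n_correlation_blocks: int = 50
    cooccurrence_strength: float = 0.8  # within-block background set overlap
    background_occurrence: float = 0.2  # fraction of background cohort per feature
    holdout_fraction: float = 0.0  # fraction of features omitted from the corpus

    def __post_init__(self):
        if self.n_sensitive_genes + self.n_resistant_genes > self.n_genes:
            raise ValueError("more signature genes than genes")
        for name in ("pcr_rate", "mutation_rate", "background_occurrence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 <= self.cooccurrence_strength <= 1.0):
            raise ValueError("cooccurrence_strength must lie in [0, 1]")
        for name in ("n_samples", "n_genes", "n_background_samples", "n_correlation_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthSet:
    """Ground truth of a generated experiment."""

    sensitive_genes: list[str]
    resistant_genes: list[str]
    labels: pd.Series
    blocks: dict[str, int] = field(default_factory=dict)  # feature -> background block


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def gene_block(gene: str, cfg: GeneratorConfig) -> int:
    """Deterministic background block of a gene: contiguous chunks of the panel."""
    idx = int(gene[1:])
    per = -(-cfg.n_genes // cfg.n_correlation_blocks)  # ceil
    return idx // per


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, TruthSet]:
    """Draw one labeled cohort: expression, mutations, response, truth.

    Labels are Bernoulli(pcr_rate); expression is log-normal noise with the
    planted shift applied on the log scale; mutations are sparse background
    Bernoulli calls plus response-linked calls in a few signature genes
    (nonsynonymous in responders for sensitive genes, AGR in non-responders
    for resistant genes).  Byte-identical outputs for equal configs.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = _sample_names(cfg.n_samples)
    sens_genes = genes[: cfg.n_sensitive_genes]
    res_genes = genes[cfg.n_sensitive_genes : cfg.n_sensitive_genes + cfg.n_resistant_genes]

    y = rng.binomial(1, cfg.pcr_rate, cfg.n_samples)
    if y.min() == y.max():  # degenerate draw at tiny n: force both classes
        y[0] = 1 - y[0]
    labels = pd.Series(y, index=pd.Index(samples, name="sample_id"), name="response")

    z = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    z[: cfg.n_sensitive_genes, y == 1] += cfg.effect_size
    z[cfg.n_sensitive_genes : cfg.n_sensitive_genes + cfg.n_resistant_genes, y == 0] += cfg.effect_size
    expr = pd.DataFrame(
        np.exp(z), index=pd.Index(genes, name="gene_id"), columns=pd.Index(samples, name="sample_id")
    )

    # background mutations across the whole panel
    mut_mask = rng.random((cfg.n_genes, cfg.n_samples)) < cfg.mutation_rate
    # response-linked mutations: nonsynonymous in responders for the first
    # sensitive genes, AGRs in non-responders for the first resistant genes
    k = cfg.n_mut_signature_genes
    agr_mask = np.zeros_like(mut_mask)
    link_mut = rng.random((k, cfg.n_samples)) < cfg.mut_signature_rate
    link_mut[:, y == 0] = False
    mut_mask[:k] |= link_mut
    link_agr = rng.random((k, cfg.n_samples)) < cfg.mut_signature_rate
    link_agr[:, y == 1] = False
    agr_mask[cfg.n_sensitive_genes : cfg.n_sensitive_genes + k] |= link_agr

    records = []
    for gi, si in zip(*np.nonzero(mut_mask)):
        records.append((samples[si], genes[gi], "nonsynonymous"))
    for gi, si in zip(*np.nonzero(agr_mask)):
        records.append((samples[si], genes[gi], "AGR"))
    records.sort()
    muts = pd.DataFrame(records, columns=["sample_id", "gene_id", "variant_class"])

    truth = TruthSet(sensitive_genes=sens_genes, resistant_genes=res_genes, labels=labels)
    return expr, muts, labels, truth


def generate_background(cfg: GeneratorConfig, feature_ids: Sequence[str]) -> BackgroundCorpus:
    """Block-correlated background corpus over the given feature ids.

    Features are grouped by gene into contiguous blocks; each block shares a
    core background sample set, and a feature's set takes a
    ``cooccurrence_strength`` fraction of the core (always the same core
    elements, so strength 1 means identical sets within a block) topped up
    with random samples.  Within-block Ochiai similarity therefore far
    exceeds the between-block chance level strength^2-fold.
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("feature_ids must be nonempty")
    rng = np.random.default_rng((cfg.seed, _BG_STREAM))
    N = cfg.n_background_samples
    universe = np.array([f"B{i:04d}" for i in range(N)], dtype=object)
    s = max(1, round(cfg.background_occurrence * N))
    k = round(cfg.cooccurrence_strength * s)

    cores: dict[int, np.ndarray] = {}
    sets: dict[str, frozenset[str]] = {}
    if cfg.holdout_fraction > 0:
        n_hold = int(round(cfg.holdout_fraction * len(feature_ids)))
        held = set(rng.choice(len(feature_ids), size=n_hold, replace=False).tolist())
    else:
        held = set()
    for fi, fid in enumerate(feature_ids):
        if fi in held:
            continue
        gene = ft.parse_feature_id(fid).gene
        block = gene_block(gene, cfg)
        if block not in cores:
            cores[block] = rng.permutation(N)[:s]
        core = cores[block]
        take = core[:k]
        rest_pool = np.setdiff1d(np.arange(N), take, assume_unique=False)
        extra = rng.choice(rest_pool, size=s - k, replace=False) if s - k > 0 else np.array([], dtype=int)
        sets[fid] = frozenset(universe[np.concatenate([take, extra]).astype(int)])
    return BackgroundCorpus(sets, universe=universe.tolist())


def cohort_feature_matrix(
    expr: pd.DataFrame,
    muts: pd.DataFrame,
    scheme: ft.LevelScheme | None = None,
) -> pd.DataFrame:
    """Convenience: derive and merge the full binary feature matrix."""
    parts = [ft.derive_expression_features(expr, scheme)]
    mfm = ft.derive_mutation_features(muts, expr.columns)
    if len(mfm):
        parts.append(mfm)
    return ft.merge_feature_matrices(parts)
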