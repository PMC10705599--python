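"""Resampling evaluation, AUROC, and the feature-error robustness simulation.

The robustness experiment mirrors the method's central engineering claim:
because the signature keeps many redundant predictive features, randomly
flipping feature calls (false positives / false negatives, as sequencing
bias would) should barely move the held-out AUROC, whereas a model resting
on a single feature degrades steadily with the error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .redundancy import BackgroundCorpus
from .scoring import TrainConfig, predict, train
from .weighting import phi_profile

logger = logging.getLogger(__name__)

DEFAULT_ERROR_RATES = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)


def auroc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def make_splits(
    y: pd.Series, n_reps: int = 10, train_frac: float = 0.9, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Label-stratified random train/test splits, reproducible given seed."""
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 members for stratified splits")
    sss = StratifiedShuffleSplit(n_splits=n_reps, train_size=train_frac, random_state=seed)
    ids = np.asarray(y.index, dtype=object)
    plans = []
    for tr, te in sss.split(np.zeros(len(y)), y.to_numpy()):
        plans.append((list(ids[tr]), list(ids[te])))
    return plans


@dataclass(frozen=True)
class ErrorSpec:
    """Specification of a simulated feature-error corruption."""

    rate: float
    mode: str = "both"  # 'false_positive' | 'false_negative' | 'both'
    target: str = "validation"  # 'train' | 'validation'
    seed: int = 0
    whole_feature: bool = False  # corrupt entire feature rows instead of cells

    def __post_init__(self):
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("error rate must lie in [0, 1]")
        if self.mode not in ("false_positive", "false_negative", "both"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.target not in ("train", "validation"):
            raise ValueError(f"unknown error target {self.target!r}")


def simulate_feature_errors(fm: pd.DataFrame, spec: ErrorSpec) -> pd.DataFrame:
    """Flip feature calls at the given rate (seeded, reproducible).

    In 'false_positive' mode each 0 flips to 1 independently with
    probability ``rate``; 'false_negative' flips 1 -> 0; 'both' applies each
    rule to its stratum.  With ``whole_feature`` set, whole feature rows are
    corrupted instead of single cells.
    """
    rng = np.random.default_rng(spec.seed)
    V = fm.to_numpy().astype(bool)
    out = V.copy()
    if spec.whole_feature:
        rows = rng.random(V.shape[0]) < spec.rate
        if spec.mode in ("false_positive", "both"):
            out[rows & ~V.any(axis=1)] = True
        if spec.mode in ("false_negative", "both"):
            out[rows & V.any(axis=1)] = False
    else:
        U = rng.random(V.shape)
        if spec.mode == "false_positive":
            out = np.where(~V & (U < spec.rate), True, V)
        elif spec.mode == "false_negative":
            out = np.where(V & (U < spec.rate), False, V)
        else:
            out = np.where(V, U >= spec.rate, U < spec.rate)
    return pd.DataFrame(out.astype(np.uint8), index=fm.index, columns=fm.columns)


def best_single_feature(fm: pd.DataFrame, y: pd.Series) -> tuple[str, float]:
    """The single feature with the largest phi against the response.

    Serves as the no-redundancy contrast scorer in robustness experiments:
    its prediction for a patient is just the (possibly corrupted) presence
    call of that one feature.
    """
    yv = y.loc[fm.columns].to_numpy(dtype=np.int64)
    phi = phi_profile(fm.to_numpy(), yv)
    phi = np.where(np.isnan(phi), -np.inf, phi)
    i = int(np.argmax(phi))
    return str(fm.index[i]), float(phi[i])


def robustness_curve(
    train_fm: pd.DataFrame,
    train_y: pd.Series,
    valid_fm: pd.DataFrame,
    valid_y: pd.Series,
    corpus: BackgroundCorpus,
    rates: Sequence[float] = DEFAULT_ERROR_RATES,
    mode: str = "both",
    target: str = "validation",
    n_reps: int = 5,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Held-out AUROC under simulated feature errors.

    For each rate and repetition the targeted matrix is corrupted; with
    ``target='train'`` the model is retrained on the corrupted features,
    with ``target='validation'`` the clean model rescoring corrupted
    validation features.  Randomness flows from one seed via a hierarchical
    scheme (one child stream per rate x repetition).

    Returns a tidy table with one row per (rate, rep) plus columns for the
    validation AUROC.
    """
    if config is None:
        config = TrainConfig()
    base_model = train(train_fm, train_y, corpus, config)
    rows = []
    for ri, rate in enumerate(rates):
        for rep in range(n_reps):
            child_seed = int(np.random.SeedSequence((seed, ri, rep)).generate_state(1)[0] % (2**31))
            spec = ErrorSpec(rate=rate, mode=mode, target=target, seed=child_seed)
            if rate == 0.0:
                model, vfm = base_model, valid_fm
            elif target == "train":
                model = train(simulate_feature_errors(train_fm, spec), train_y, corpus, config)
                vfm = valid_fm
            else:
                model, vfm = base_model, simulate_feature_errors(valid_fm, spec)
            st = predict(model, vfm)
            a = auroc(st.scores["final_score"].loc[valid_y.index], valid_y)
            rows.append((rate, rep, a))
    table = pd.DataFrame(rows, columns=["rate", "rep", "auroc"])
    return table


def summarize_robustness(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-rep robustness table to (rate, mean, sd)."""
    g = table.groupby("rate")["auroc"]
    return pd.DataFrame({"mean_auroc": g.mean(), "sd_auroc": g.std(ddof=1).fillna(0.0)}).reset_index()
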