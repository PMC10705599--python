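"""Redundancy-penalized class scores, D-line fitting, and the trained model.

A patient's *sensitive score* is a weighted mean of the phi weights omega of
the sensitive-class features present in that patient, where each feature is
shrunk by the square root of its redundancy penalty eps:

    EW_i  = omega_i / sqrt(eps_i)          (effective weight)
    EFN   = sum_i 1 / sqrt(eps_i)          (effective feature number)
    score = sum_i EW_i / EFN

The resistant score is the analog over resistant-class features.  Patients
are points in the (resistant, sensitive) plane; the dividing line (D-line)
through the origin whose slope maximizes the Youden index J = TPR + TNR - 1
on the training cohort separates predicted responders from non-responders,
and the signed perpendicular distance to it — positive on the sensitive
side — is the final score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .features import LevelScheme, drop_weak_level_features
from .io import sha256_of_frames
from .redundancy import (
    BackgroundCorpus,
    DEFAULT_CLUSTER_HEIGHT,
    cluster_features,
    ochiai_similarity,
    penalization_factors,
)
from .weighting import (
    DEFAULT_PHI_CUTOFF,
    RESISTANT,
    SENSITIVE,
    filter_same_trend_genes,
    select_predictive_features,
)

logger = logging.getLogger(__name__)

CLASSES = (SENSITIVE, RESISTANT)


# ---------------------------------------------------------------------------
# Class score


def class_score(omegas: Sequence[float], eps: Sequence[float]) -> tuple[float, int]:
    """(1/sqrt(eps))-weighted mean of omega over a patient's present features.

    Returns (score, n_features); an empty present set scores 0.0 with
    count 0 (the caller flags the patient as uninformative).
    """
    omegas = np.asarray(omegas, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if omegas.size == 0:
        return 0.0, 0
    if omegas.shape != eps.shape:
        raise ValueError("omega and eps must align")
    if np.any(eps < 1.0 - 1e-9):
        raise ValueError("penalization factors must be >= 1")
    inv = 1.0 / np.sqrt(eps)
    return float(np.sum(omegas * inv) / np.sum(inv)), int(omegas.size)


# ---------------------------------------------------------------------------
# D-line


@dataclass(frozen=True)
class DLine:
    """Dividing line through the origin of the (resistant, sensitive) plane.

    ``angle`` is its inclination in radians (0 = resistant axis); ``slope``
    = tan(angle) is the sensitive/resistant ratio.  Points above the line
    (sensitive side) get positive signed distances.
    """

    slope: float
    angle: float
    fallback: bool = False


def _youden(pred: np.ndarray, y: np.ndarray) -> float:
    pos = y == 1
    neg = ~pos
    tpr = pred[pos].mean() if pos.any() else 0.0
    tnr = (~pred[neg]).mean() if neg.any() else 0.0
    return float(tpr + tnr - 1.0)


def fit_dline(sensitive: Sequence[float], resistant: Sequence[float], y: Sequence[int]) -> DLine:
    """Youden-optimal dividing line through the origin.

    Candidate lines are the midpoints of consecutive sorted point angles
    plus the two extremes (below the smallest and above the largest angle).
    A point lying exactly on a candidate line counts as resistant-side, as
    does the origin.  Ties in J are broken by the midpoint of the widest
    optimal angle interval, then by the smaller slope.  If no line achieves
    J > 0 the fallback slope 1 (45 degrees) is returned with a warning.
    """
    s = np.asarray(sensitive, dtype=float)
    r = np.asarray(resistant, dtype=float)
    y = np.asarray(y, dtype=int)
    if s.shape != r.shape or s.shape != y.shape:
        raise ValueError("score pairs and labels must align")
    if not np.isfinite(s).all() or not np.isfinite(r).all():
        raise ValueError("score pairs must be finite")
    if y.min() == y.max():
        raise ValueError("both labels are required to fit the D-line")

    nonzero = (s != 0) | (r != 0)
    ang = np.arctan2(s, r)  # in [0, pi/2] for non-negative scores
    boundaries = np.unique(ang[nonzero])
    if boundaries.size == 0:
        logger.warning("all score pairs at the origin; falling back to slope 1")
        return DLine(slope=1.0, angle=math.atan(1.0), fallback=True)

    edges = np.concatenate(([0.0], boundaries, [math.pi / 2]))
    best = None  # (J, width, -angle) ordering
    js = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        theta = 0.5 * (lo + hi)
        pred = nonzero & (ang > theta)
        J = _youden(pred, y)
        js.append(J)
        width = hi - lo
        cand = (J, width, -theta)
        if best is None or cand > best:
            best = cand
    J, width, neg_theta = best
    if max(js) == min(js):
        # every candidate is equally (un)informative: nothing to optimize
        logger.warning("Youden index is flat across all candidate slopes; falling back to slope 1")
        return DLine(slope=1.0, angle=math.atan(1.0), fallback=True)
    if J <= 0:
        logger.warning("no dividing line beats chance (best J <= 0)")
    theta = -neg_theta
    return DLine(slope=math.tan(theta), angle=theta)


def signed_distance(sensitive, resistant, d: DLine):
    """Signed perpendicular distance of (resistant, sensitive) points to the D-line.

    Positive above the line (sensitive side), negative below; a point on the
    line scores exactly 0.
    """
    s = np.asarray(sensitive, dtype=float)
    r = np.asarray(resistant, dtype=float)
    out = s * math.cos(d.angle) - r * math.sin(d.angle)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Training configuration and model artifact


@dataclass(frozen=True)
class TrainConfig:
    cutoff: float = DEFAULT_PHI_CUTOFF
    cluster_height: float = DEFAULT_CLUSTER_HEIGHT
    cluster_metric: str = "profile"
    scheme: LevelScheme = field(default_factory=LevelScheme)
    loo_adjust: bool = True  # leave-one-out weight adjustment for training scores
    drop_level1: bool = True
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = list(self.scheme.fractions)
        return d


@dataclass
class ClassModel:
    """Per-class frozen state: selected features, weights, K, clusters."""

    features: list[str]
    omega: np.ndarray
    K: pd.DataFrame
    clusters: pd.Series


@dataclass
class IGenSigModel:
    """Frozen training artifact; self-contained for prediction."""

    classes: dict[str, ClassModel]
    dline: DLine
    config: TrainConfig
    provenance: dict

    @property
    def feature_ids(self) -> list[str]:
        out: list[str] = []
        for cls in CLASSES:
            out.extend(self.classes[cls].features)
        return out

    def weight_table(self) -> pd.DataFrame:
        frames = []
        for cls in CLASSES:
            cm = self.classes[cls]
            frames.append(
                pd.DataFrame(
                    {"class": cls, "omega": cm.omega},
                    index=pd.Index(cm.features, name="feature_id"),
                )
            )
        return pd.concat(frames)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        classes = {}
        for cls in CLASSES:
            cm = self.classes[cls]
            K = cm.K.to_numpy()
            triplets = []
            n = K.shape[0]
            iu, ju = np.triu_indices(n, k=1)
            nz = K[iu, ju] != 0.0
            for i, j in zip(iu[nz], ju[nz]):
                triplets.append([int(i), int(j), float(K[i, j])])
            classes[cls] = {
                "features": list(cm.features),
                "omega": [float(w) for w in cm.omega],
                "clusters": [int(c) for c in cm.clusters.to_numpy()] if len(cm.clusters) else [],
                "K_triplets": triplets,
            }
        return {
            "format_version": 1,
            "package_version": __version__,
            "config": self.config.to_dict(),
            "dline": {"slope": self.dline.slope, "angle": self.dline.angle, "fallback": self.dline.fallback},
            "classes": classes,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IGenSigModel":
        if d.get("format_version") != 1:
            raise ValueError("unrecognized model format")
        cfg_d = dict(d["config"])
        cfg_d["scheme"] = LevelScheme(tuple(cfg_d.pop("scheme")))
        config = TrainConfig(**cfg_d)
        classes = {}
        for name in CLASSES:
            cd = d["classes"][name]
            feats = list(cd["features"])
            n = len(feats)
            K = np.eye(n)
            for i, j, v in cd["K_triplets"]:
                K[i, j] = v
                K[j, i] = v
            idx = pd.Index(feats, name="feature_id")
            classes[name] = ClassModel(
                features=feats,
                omega=np.asarray(cd["omega"], dtype=float),
                K=pd.DataFrame(K, index=idx, columns=idx),
                clusters=pd.Series(np.asarray(cd["clusters"], dtype=int), index=idx, name="cluster"),
            )
        dl = d["dline"]
        return cls(
            classes=classes,
            dline=DLine(slope=dl["slope"], angle=dl["angle"], fallback=dl["fallback"]),
            config=config,
            provenance=dict(d["provenance"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path) -> "IGenSigModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScoreTable:
    """Per-patient scores plus the white-box per-feature breakdown."""

    scores: pd.DataFrame
    contributions: pd.DataFrame


# ---------------------------------------------------------------------------
# Training


def _loo_phi(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """phi of each feature (row) vs y with each sample left out in turn.

    Returns an (n_features, n_samples) array: column s holds the weights the
    cohort would assign had sample s not been observed.  Undefined entries
    become 0 (the feature then contributes nothing for that subject).
    """
    X = np.asarray(X, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    n11 = (X @ y)[:, None] - X * y[None, :]
    r1 = X.sum(axis=1)[:, None] - X
    c1 = int(y.sum()) - y[None, :]
    m = n - 1
    n10 = r1 - n11
    n01 = c1 - n11
    n00 = m - r1 - c1 + n11
    denom = (r1 * (m - r1) * c1 * (m - c1)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n11 * n00 - n10 * n01) / np.sqrt(denom)
    phi[denom == 0] = 0.0
    return phi


def train(
    fm: pd.DataFrame,
    y: pd.Series,
    corpus: BackgroundCorpus,
    config: TrainConfig | None = None,
) -> IGenSigModel:
    """Fit the full white-box model on a labeled training cohort.

    Pipeline: drop level-1 expression features -> phi selection at the
    cutoff -> same-trend consistency filter -> per-class Ochiai similarity
    and complete-linkage clustering on the background corpus -> per-patient
    redundancy penalties and class scores -> Youden-optimal D-line.

    When ``config.loo_adjust`` is on (default), the training score pairs
    used to fit the D-line recompute each subject's weights with that
    subject excluded, so a subject's own label cannot inflate its score.
    The frozen model always carries full-cohort weights for prediction.
    """
    if config is None:
        config = TrainConfig()
    if set(fm.columns) != set(y.index):
        raise ValueError("feature matrix and response cover different samples")
    y = y.loc[fm.columns]

    if config.drop_level1:
        fm = drop_weak_level_features(fm)

    wt = select_predictive_features(fm, y, cutoff=config.cutoff)
    wt = filter_same_trend_genes(wt)
    if wt.empty:
        raise ValueError(f"no predictive features at cutoff {config.cutoff}")

    yv = y.to_numpy(dtype=np.int64)
    classes: dict[str, ClassModel] = {}
    eps_by_class: dict[str, list[pd.Series]] = {}
    present_by_class: dict[str, list[np.ndarray]] = {}
    for cls in CLASSES:
        feats = wt.index[wt["class"] == cls].tolist()
        K = ochiai_similarity(corpus, feats)
        clusters = cluster_features(K, height=config.cluster_height, metric=config.cluster_metric)
        omega = wt.loc[feats, "omega"].to_numpy(dtype=float)
        classes[cls] = ClassModel(features=feats, omega=omega, K=K, clusters=clusters)

        X = fm.loc[feats].to_numpy() if feats else np.zeros((0, len(y)), dtype=np.uint8)
        Kv = K.to_numpy()
        lab = clusters.to_numpy() if len(clusters) else np.zeros(0, dtype=int)
        eps_list, present_list = [], []
        for sj in range(len(y)):
            pres = np.flatnonzero(X[:, sj] > 0)
            if pres.size:
                sub = Kv[np.ix_(pres, pres)]
                same = lab[pres][:, None] == lab[pres][None, :]
                eps = (sub * same).sum(axis=1)
            else:
                eps = np.zeros(0)
            eps_list.append(pd.Series(eps, index=[feats[i] for i in pres]))
            present_list.append(pres)
        eps_by_class[cls] = eps_list
        present_by_class[cls] = present_list

    # training score pairs for the D-line (optionally leave-one-out weights)
    pair_scores = {cls: np.zeros(len(y)) for cls in CLASSES}
    for cls in CLASSES:
        feats = classes[cls].features
        if not feats:
            continue
        X = fm.loc[feats].to_numpy()
        target = yv if cls == SENSITIVE else 1 - yv
        w_loo = _loo_phi(X, target) if config.loo_adjust else None
        omega = classes[cls].omega
        for sj in range(len(y)):
            pres = present_by_class[cls][sj]
            eps = eps_by_class[cls][sj].to_numpy()
            w = w_loo[pres, sj] if w_loo is not None else omega[pres]
            pair_scores[cls][sj], _ = class_score(w, eps)

    dline = fit_dline(pair_scores[SENSITIVE], pair_scores[RESISTANT], yv)

    provenance = {
        "training_hash": sha256_of_frames(fm.astype(int), y),
        "n_training_samples": int(len(y)),
        "seed": config.seed,
        "package_version": __version__,
    }
    return IGenSigModel(classes=classes, dline=dline, config=config, provenance=provenance)


# ---------------------------------------------------------------------------
# Prediction


def predict(model: IGenSigModel, fm_new: pd.DataFrame) -> ScoreTable:
    """Score a cohort with a frozen model.

    Present features are intersected with the model's selected sets; the
    redundancy penalties are recomputed per patient from the model's stored
    similarity matrix and clusters over that intersection.  Patients with no
    selected feature present score (0, 0) and are flagged uninformative.
    """
    model_feats = set(model.feature_ids)
    if not model_feats:
        raise ValueError("model has no features")
    overlap = model_feats & set(fm_new.index)
    frac = len(overlap) / len(model_feats)
    if not overlap:
        raise ValueError("no overlap between model features and the new feature matrix")
    if frac < 1.0:
        logger.warning("feature overlap with model: %.1f%%", 100 * frac)

    samples = fm_new.columns
    cols = {
        "sensitive_score": np.zeros(len(samples)),
        "resistant_score": np.zeros(len(samples)),
        "n_features_sensitive": np.zeros(len(samples), dtype=int),
        "n_features_resistant": np.zeros(len(samples), dtype=int),
    }
    contribs: list[tuple] = []
    for cls in CLASSES:
        cm = model.classes[cls]
        avail = [f for f in cm.features if f in fm_new.index]
        if not avail:
            continue
        omega = pd.Series(cm.omega, index=cm.features)
        X = (fm_new.loc[avail].to_numpy() > 0)
        Kv = cm.K.loc[avail, avail].to_numpy()
        lab = cm.clusters.loc[avail].to_numpy()
        score_key = f"{cls}_score"
        n_key = f"n_features_{cls}"
        for sj in range(len(samples)):
            pres = np.flatnonzero(X[:, sj])
            if pres.size:
                sub = Kv[np.ix_(pres, pres)]
                same = lab[pres][:, None] == lab[pres][None, :]
                eps = (sub * same).sum(axis=1)
                w = omega.loc[[avail[i] for i in pres]].to_numpy()
                score, n_f = class_score(w, eps)
                for k, i in enumerate(pres):
                    contribs.append(
                        (samples[sj], avail[i], cls, float(w[k]), float(eps[k]), float(w[k] / np.sqrt(eps[k])))
                    )
            else:
                score, n_f = 0.0, 0
            cols[score_key][sj] = score
            cols[n_key][sj] = n_f

    final = signed_distance(cols["sensitive_score"], cols["resistant_score"], model.dline)
    scores = pd.DataFrame(
        {
            "sensitive_score": cols["sensitive_score"],
            "resistant_score": cols["resistant_score"],
            "n_features_sensitive": cols["n_features_sensitive"],
            "n_features_resistant": cols["n_features_resistant"],
            "final_score": final,
            "predicted_label": (np.asarray(final) > 0).astype(int),
            "uninformative": (
                (cols["n_features_sensitive"] + cols["n_features_resistant"]) == 0
            ).astype(int),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    contributions = pd.DataFrame(
        contribs,
        columns=["sample_id", "feature_id", "class", "omega", "epsilon", "effective_weight"],
    )
    return ScoreTable(scores=scores, contributions=contributions)
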