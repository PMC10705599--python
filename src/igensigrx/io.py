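"""Readers and writers for the plain-text formats the pipeline speaks.

Formats: expression TSV (genes x samples), MAF-lite mutation TSV, phenotype
(response) TSV, GMT-style feature/corpus files, dense feature-matrix TSV and
the weight-table TSV.  Readers validate and reject malformed rows rather
than silently coercing them.

The GMT dialect used here is standard (feature id, description, then the
identifiers of the samples in which the feature is present) with one
extension: an optional leading ``#samples`` line enumerating the full sample
universe, so that all-zero columns survive a round trip.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _strip(s: str) -> str:
    return s.strip()


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-as-rows expression TSV (first column gene id)."""
    path = Path(path)
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split("\t")][1:]
    seen: set[str] = set()
    dups = sorted({h for h in header if h in seen or seen.add(h)})
    if dups:  # pandas would silently mangle duplicate column names
        raise FormatError(f"{path}: duplicate sample columns {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).map(_strip)
    df.columns = df.columns.astype(str).map(_strip)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values ({exc})") from exc
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_mutations_tsv(path: str | Path) -> pd.DataFrame:
    """Read a MAF-lite TSV with columns sample_id, gene_id, variant_class."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "gene_id", "variant_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df[required].isna().any().any():
        bad = df.index[df[required].isna().any(axis=1)].tolist()
        raise FormatError(f"{path}: empty fields in rows {bad}")
    for c in required:
        df[c] = df[c].map(_strip)
    return df[required]


def write_mutations_tsv(muts: pd.DataFrame, path: str | Path) -> None:
    muts.to_csv(path, sep="\t", index=False)


def read_response_tsv(path: str | Path) -> pd.Series:
    """Read sample_id/response TSV; response must be 0 or 1."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "response" not in df.columns:
        raise FormatError(f"{path}: needs columns sample_id, response")
    ids = df["sample_id"].map(_strip)
    if ids.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids {ids[ids.duplicated()].tolist()}")
    vals = df["response"].map(_strip)
    if not set(vals) <= {"0", "1"}:
        raise FormatError(f"{path}: response values must be 0/1, got {sorted(set(vals))}")
    y = pd.Series(vals.astype(int).to_numpy(), index=pd.Index(ids, name="sample_id"), name="response")
    return y


def write_response_tsv(y: pd.Series, path: str | Path) -> None:
    y.rename("response").to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT-style binary matrices


def write_feature_gmt(fm: pd.DataFrame, path: str | Path, description: str = "na") -> None:
    """Write a binary feature matrix as GMT with a #samples universe line."""
    with open(path, "w") as fh:
        fh.write("#samples\t" + "\t".join(map(str, fm.columns)) + "\n")
        arr = fm.to_numpy()
        cols = np.asarray(fm.columns, dtype=object)
        for i, fid in enumerate(fm.index):
            present = cols[arr[i] > 0]
            fh.write("\t".join([str(fid), description, *map(str, present)]) + "\n")


def read_feature_gmt(path: str | Path) -> pd.DataFrame:
    """Read a GMT-style feature file back into a 0/1 matrix."""
    path = Path(path)
    universe: list[str] | None = None
    feats: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = [p.strip() for p in line.split("\t")]
            if ln == 1 and parts[0] == "#samples":
                universe = parts[1:]
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: GMT rows need id and description")
            feats.append((parts[0], [p for p in parts[2:] if p]))
    ids = [f for f, _ in feats]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate feature ids")
    if universe is None:
        seen: dict[str, None] = {}
        for _, ss in feats:
            for s in ss:
                seen.setdefault(s)
        universe = list(seen)
    cols = pd.Index(universe, name="sample_id")
    if cols.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in universe")
    data = np.zeros((len(ids), len(cols)), dtype=np.uint8)
    col = {s: j for j, s in enumerate(cols)}
    for i, (_, ss) in enumerate(feats):
        for s in ss:
            if s not in col:
                raise FormatError(f"{path}: sample {s!r} outside declared universe")
            data[i, col[s]] = 1
    return pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=cols)


def write_feature_tsv(fm: pd.DataFrame, path: str | Path) -> None:
    fm.astype(int).to_csv(path, sep="\t", index_label="feature_id")


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(f"{path}: feature matrix entries must be 0/1")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(np.uint8)


# ---------------------------------------------------------------------------
# Weight table


def write_weight_table_tsv(wt: pd.DataFrame, path: str | Path) -> None:
    wt.to_csv(path, sep="\t", index_label="feature_id")


def read_weight_table_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"class", "omega"} <= set(df.columns):
        raise FormatError(f"{path}: weight table needs columns class, omega")
    df.index = df.index.astype(str)
    return df[["class", "omega"]]


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of_frames(*frames) -> str:
    """Stable content hash of DataFrames/Series (provenance stamping)."""
    h = hashlib.sha256()
    for fr in frames:
        h.update(fr.to_csv(sep="\t").encode())
    return h.hexdigest()
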