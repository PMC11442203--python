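"""Pathway-fingerprint (PathSim) similarity between compounds.

A compound's *cellular function fingerprint* is its row of the
compound × term path-count matrix M, where M[c, p] counts the distinct
targets t with both a compound–target edge (c, t) and an annotation
(t, p).  PathSim along the symmetric meta-path
compound→target→term→target→compound is then

    s(x, y) = 2·P[x, y] / (P[x, x] + P[y, y]),      P = M·Mᵀ

which lies in [0, 1], equals 1 on the diagonal for any compound with at
least one compound–target–term path, and is defined as 0 (including on
the diagonal) for path-less compounds to avoid 0/0.  Distance is
d = 1 − s.

Matrices are plain :class:`pandas.DataFrame` objects indexed by compound
id (rows and columns sorted), so they slice, join and serialise with the
ordinary pandas API.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, TermSource

logger = logging.getLogger(__name__)


def path_count_matrix(
    net: HeteroNetwork,
    mode: str = "count",
    source_filter: TermSource | None = None,
) -> pd.DataFrame:
    """Compound × term matrix of meta-path counts (or binary incidence).

    ``mode="count"`` gives M[c, p] = number of distinct targets linking c
    to p; ``mode="binary"`` the 0/1 indicator of M[c, p] > 0.  With
    ``source_filter`` only terms from that annotation source contribute
    (per-source fingerprints).
    """
    if mode not in ("count", "binary"):
        raise ValueError(f"mode must be 'count' or 'binary', got {mode!r}")
    cids = net.compound_ids()
    tids = sorted(t.id for t in net.targets)
    if source_filter is None:
        pids = sorted(t.id for t in net.terms)
    else:
        pids = sorted(t.id for t in net.terms if t.source == source_filter)
    crow = {c: i for i, c in enumerate(cids)}
    trow = {t: i for i, t in enumerate(tids)}
    prow = {p: i for i, p in enumerate(pids)}

    C = np.zeros((len(cids), len(tids)), dtype=np.int64)
    for e in net.ct_edges:
        C[crow[e.compound_id], trow[e.target_id]] = 1
    A = np.zeros((len(tids), len(pids)), dtype=np.int64)
    for t, p in net.tp_edges:
        if p in prow:
            A[trow[t], prow[p]] = 1
    M = C @ A
    if mode == "binary":
        M = (M > 0).astype(np.int64)
    return pd.DataFrame(M, index=cids, columns=pids)


def pathsim(M: pd.DataFrame) -> pd.DataFrame:
    """PathSim similarity matrix from a path-count matrix.

    Integer arithmetic throughout the path-count product; the single
    division at the end is the only floating-point step.  Compounds whose
    fingerprint row is all zero (no compound–target–term path) get
    similarity 0 to everything, themselves included, and are logged.
    """
    counts = M.to_numpy(dtype=np.int64)
    P = counts @ counts.T
    diag = np.diag(P)
    pathless = M.index[diag == 0]
    if len(pathless):
        logger.warning(
            "%d compound(s) have no compound-target-term path: %s",
            len(pathless),
            ", ".join(pathless[:10]),
        )
    denom = diag[:, None] + diag[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, 2.0 * P / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame(S, index=M.index, columns=M.index)


def to_distance(S: pd.DataFrame) -> pd.DataFrame:
    """Elementwise distance d = 1 − s; validates s ∈ [0, 1] first."""
    values = S.to_numpy(dtype=float)
    if values.min() < 0 or values.max() > 1:
        raise ValueError(
            f"similarity values outside [0, 1]: min={values.min()}, max={values.max()}"
        )
    return 1.0 - S


def validate_similarity(S: pd.DataFrame, atol: float = 1e-12) -> None:
    """Raise ValueError unless S is square, symmetric and in [0, 1]."""
    if list(S.index) != list(S.columns):
        raise ValueError("similarity matrix index and columns differ")
    V = S.to_numpy(dtype=float)
    if not np.allclose(V, V.T, atol=atol):
        raise ValueError("similarity matrix is not symmetric")
    if V.min() < -atol or V.max() > 1 + atol:
        raise ValueError("similarity values outside [0, 1]")


def write_matrix_csv(M: pd.DataFrame, path: str | Path) -> None:
    """Square CSV with the compound-id header row/column."""
    M.to_csv(path, index_label="id", float_format="%.12g")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_matrix_long(M: pd.DataFrame, path: str | Path, value_name: str = "value") -> None:
    """Long-format TSV (x, y, value), one row per ordered pair."""
    long = M.stack().rename(value_name).rename_axis(["x", "y"]).reset_index()
    long.to_csv(path, sep="\t", index=False, float_format="%.12g")
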