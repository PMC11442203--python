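"""Mechanism transfer from most-similar drugs and signature direction calls.

Each herbal component is paired with its most similar western drug on the
fingerprint similarity matrix; the drug's ATC codes and the function
terms the pair reaches in common become the component's predicted
pharmacology.  *Common biological processes* are the terms reachable from
both the similar-drug set and the component set; per-drug perturbation
signatures (gene-level z-scores, LINCS-style) are then scored on those
terms as the mean z over the term's genes and thresholded at ±tau into
up / down / flat regulation calls.  Insufficient gene overlap is a
distinct *no-call*, never conflated with flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, TermSource, atc_truncate

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.5
DEFAULT_MIN_OVERLAP = 3


@dataclass
class ExpressionSignature:
    """Gene-level z-score profile of one drug perturbation."""

    drug_id: str
    zscores: dict[str, float]

    def __post_init__(self) -> None:
        if not self.zscores:
            raise ValueError(f"signature for {self.drug_id!r} has no genes")
        bad = [g for g, z in self.zscores.items() if not np.isfinite(z)]
        if bad:
            raise ValueError(f"non-finite z-scores for genes {bad[:5]}")


@dataclass
class RegulationCall:
    drug_id: str
    term_id: str
    score: float
    direction: str  # "up" | "down" | "flat"


def nearest_wm(
    S: pd.DataFrame,
    tcm_ids: Iterable[str],
    wm_ids: Iterable[str],
    floor: float = 0.0,
) -> dict[str, tuple[str, float]]:
    """Most-similar western drug per component.

    Ties go to the lexicographically smallest drug id; components whose
    best similarity falls below ``floor`` are omitted.
    """
    tcm = sorted(tcm_ids)
    wm = sorted(wm_ids)
    if not tcm or not wm:
        raise ValueError("both id sets must be non-empty")
    if set(tcm) & set(wm):
        raise ValueError("component and drug id sets overlap")
    block = S.loc[tcm, wm]
    out: dict[str, tuple[str, float]] = {}
    for c in tcm:
        row = block.loc[c]
        best_wm = row.idxmax()  # columns sorted -> first max = smallest id
        best = float(row[best_wm])
        if best >= floor:
            out[c] = (best_wm, best)
    return out


def transfer_atc(
    nmap: Mapping[str, tuple[str, float]],
    wm_atc: Mapping[str, Iterable[str]],
    level: int = 3,
) -> dict[str, set[str]]:
    """Each component inherits its nearest drug's ATC codes, truncated."""
    out: dict[str, set[str]] = {}
    for cid, (wm, _) in nmap.items():
        codes = {atc_truncate(c, level) for c in wm_atc.get(wm, ())}
        if not codes:
            logger.warning("nearest drug %s of %s carries no ATC codes", wm, cid)
        out[cid] = codes
    return out


def transfer_go_terms(compound_id: str, wm_id: str, net: HeteroNetwork) -> set[str]:
    """Terms reachable (via any target) from *both* the component and the
    drug: the intersection of their fingerprint supports.  Symmetric in
    its two compound arguments."""
    return net.term_support(compound_id) & net.term_support(wm_id)


def common_processes(
    similar_wm_ids: Iterable[str],
    tcm_ids: Iterable[str],
    net: HeteroNetwork,
    source_filter: TermSource | None = TermSource.GO_BP,
) -> set[str]:
    """Terms reachable from ≥1 similar drug AND ≥1 component (default:
    GO biological processes only)."""
    wm = list(similar_wm_ids)
    tcm = list(tcm_ids)
    if not wm or not tcm:
        raise ValueError("both id sets must be non-empty")
    reach_wm: set[str] = set()
    for w in wm:
        reach_wm |= net.term_support(w)
    reach_tcm: set[str] = set()
    for c in tcm:
        reach_tcm |= net.term_support(c)
    shared = reach_wm & reach_tcm
    if source_filter is not None:
        src = net.term_source
        shared = {p for p in shared if src.get(p) == source_filter}
    return shared


def regulation_score(
    sig: ExpressionSignature,
    term_genes: Iterable[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float | None:
    """Mean signature z-score over the term's genes, or ``None`` (no-call)
    when fewer than ``min_overlap`` term genes are in the signature."""
    overlap = [g for g in set(term_genes) if g in sig.zscores]
    if len(overlap) < min_overlap:
        return None
    return float(np.mean([sig.zscores[g] for g in overlap]))


def regulation_call(score: float, tau: float = DEFAULT_TAU) -> str:
    """Threshold a regulation score into up / down / flat."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if score > tau:
        return "up"
    if score < -tau:
        return "down"
    return "flat"


def make_call(
    sig: ExpressionSignature,
    term_id: str,
    term_genes: Iterable[str],
    tau: float = DEFAULT_TAU,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RegulationCall | None:
    """Score + threshold in one step; ``None`` on insufficient overlap."""
    score = regulation_score(sig, term_genes, min_overlap=min_overlap)
    if score is None:
        return None
    return RegulationCall(sig.drug_id, term_id, score, regulation_call(score, tau))


def group_direction(
    calls: Sequence[RegulationCall], tau: float = DEFAULT_TAU
) -> str:
    """Overall direction of one drug group on one term: the mean of the
    member scores, thresholded at the same tau (|mean| ≤ tau → flat)."""
    if not calls:
        raise ValueError("need at least one regulation call")
    mean = float(np.mean([c.score for c in calls]))
    return regulation_call(mean, tau)


def direction_report(
    grouped_calls: Mapping[tuple[int, str], Sequence[RegulationCall]],
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Summary table (group, term, n_drugs, mean_score, direction), one
    row per cluster-group × term with at least one call."""
    rows = []
    for (group, term), calls in sorted(grouped_calls.items()):
        if not calls:
            continue
        mean = float(np.mean([c.score for c in calls]))
        rows.append(
            {
                "group": group,
                "term": term,
                "n_drugs": len(calls),
                "mean_score": mean,
                "direction": regulation_call(mean, tau),
            }
        )
    return pd.DataFrame(rows, columns=["group", "term", "n_drugs", "mean_score", "direction"])


# ---------------------------------------------------------------------------
# signature I/O: long TSV (drug_id, gene, z)


def read_signatures(path: str | Path) -> dict[str, ExpressionSignature]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene": str, "z": float})
    out: dict[str, ExpressionSignature] = {}
    for drug, sub in df.groupby("drug_id", sort=True):
        out[str(drug)] = ExpressionSignature(
            drug_id=str(drug), zscores=dict(zip(sub["gene"], sub["z"]))
        )
    return out


def write_signatures(sigs: Mapping[str, ExpressionSignature], path: str | Path) -> None:
    rows = [
        {"drug_id": d, "gene": g, "z": z}
        for d in sorted(sigs)
        for g, z in sorted(sigs[d].zscores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
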