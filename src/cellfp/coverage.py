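"""Similar-drug screening and per-indication pharmacological-effect coverage.

For each candidate indication the pipeline asks how much of the
indication's marketed-drug pharmacology the herbal components span:

* ATC code coverage      n/N — predicted vs indication ATC codes
  (compared at a configurable classification level, default 3);
* GO term coverage       m/M — predicted vs indication function terms;
* drug coverage          d/D — indication drugs similar to ≥1 component;
* cluster-group coverage g/G — indication cluster-tree groups containing
  ≥1 similar drug;
* CombinedRatio — the arithmetic mean of the first three.

A western drug counts as *similar* when its distance to at least one
herbal component is strictly below the screening threshold (by default
the global median of all component × drug cross distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .hetnet import atc_truncate


@dataclass
class SimilarDrugScreen:
    """Result of the median-threshold similarity screen."""

    threshold: float
    pairs_considered: int
    similar_wm_ids: dict[str, set[str]]  # indication -> similar drug set
    min_cross_distance: dict[str, float] = field(default_factory=dict)

    def all_similar(self) -> set[str]:
        out: set[str] = set()
        for s in self.similar_wm_ids.values():
            out |= s
        return out


@dataclass
class CoverageReport:
    indication_id: str
    n: int
    N: int
    m: int
    M: int
    d: int
    D: int
    g: int
    G: int

    @property
    def atc_coverage(self) -> float:
        return self.n / self.N

    @property
    def go_term_coverage(self) -> float:
        return self.m / self.M

    @property
    def drug_coverage(self) -> float:
        return self.d / self.D

    @property
    def group_coverage(self) -> float:
        return self.g / self.G

    @property
    def combined_ratio(self) -> float:
        return combined_ratio(self.atc_coverage, self.go_term_coverage, self.drug_coverage)

    def as_dict(self) -> dict:
        return {
            "indication": self.indication_id,
            "n": self.n,
            "N": self.N,
            "m": self.m,
            "M": self.M,
            "d": self.d,
            "D": self.D,
            "g": self.g,
            "G": self.G,
            "atc_coverage": self.atc_coverage,
            "go_term_coverage": self.go_term_coverage,
            "drug_coverage": self.drug_coverage,
            "group_coverage": self.group_coverage,
            "combined_ratio": self.combined_ratio,
        }


def cross_distances(
    D: pd.DataFrame, tcm_ids: Iterable[str], wm_ids: Iterable[str]
) -> pd.DataFrame:
    """Component × drug block of the distance matrix (sorted ids)."""
    tcm = sorted(tcm_ids)
    wm = sorted(wm_ids)
    if not tcm or not wm:
        raise ValueError("both the component and drug id sets must be non-empty")
    if set(tcm) & set(wm):
        raise ValueError("component and drug id sets overlap")
    return D.loc[tcm, wm]


def global_median_threshold(
    D: pd.DataFrame, tcm_ids: Iterable[str], wm_ids: Iterable[str]
) -> float:
    """Median of all component × drug cross distances (even count → mean
    of the central pair)."""
    block = cross_distances(D, tcm_ids, wm_ids)
    return float(np.median(block.to_numpy(dtype=float)))


def screen_similar_drugs(
    D: pd.DataFrame,
    tcm_ids: Iterable[str],
    indications: Mapping[str, Iterable[str]],
    threshold: float,
) -> SimilarDrugScreen:
    """Flag drugs whose minimal distance to any component is strictly
    below ``threshold``, grouped per indication.

    Similarity is a property of the drug, not of the indication: a drug
    similar in one indication is similar wherever it appears.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    wm_all = sorted({w for wms in indications.values() for w in wms})
    block = cross_distances(D, tcm_ids, wm_all)
    min_cross = block.min(axis=0)
    similar_global = {w for w in wm_all if min_cross[w] < threshold}
    per_ind = {
        ind: set(wms) & similar_global for ind, wms in sorted(indications.items())
    }
    return SimilarDrugScreen(
        threshold=threshold,
        pairs_considered=block.size,
        similar_wm_ids=per_ind,
        min_cross_distance={w: float(min_cross[w]) for w in wm_all},
    )


def atc_coverage(
    predicted_atc: set[str], indication_atc: set[str], level: int = 3
) -> tuple[int, int, float]:
    """ATC-code coverage n/N after truncating both sides to ``level``."""
    if not indication_atc:
        raise ValueError("indication ATC code set is empty")
    pred = {atc_truncate(c, level) for c in predicted_atc}
    ind = {atc_truncate(c, level) for c in indication_atc}
    n, N = len(pred & ind), len(ind)
    return n, N, n / N


def go_term_coverage(
    predicted_terms: set[str], indication_terms: set[str]
) -> tuple[int, int, float]:
    """Function-term coverage m/M."""
    if not indication_terms:
        raise ValueError("indication term set is empty")
    m, M = len(predicted_terms & indication_terms), len(indication_terms)
    return m, M, m / M


def drug_coverage(
    similar_for_indication: set[str], all_for_indication: set[str]
) -> tuple[int, int, float]:
    """Similar-drug coverage d/D."""
    if not all_for_indication:
        raise ValueError("indication drug set is empty")
    if not similar_for_indication <= all_for_indication:
        raise ValueError("similar drug set is not a subset of the indication's drugs")
    d, D = len(similar_for_indication), len(all_for_indication)
    return d, D, d / D


def group_coverage(
    assignment: ClusterAssignment | Mapping[str, int],
    indication_wm_ids: set[str],
    similar_set: set[str],
) -> tuple[int, int, float]:
    """Cluster-group coverage g/G over the indication's drugs.

    G counts the distinct cluster groups the indication's drugs occupy; g
    those containing at least one similar drug.  Every indication drug
    must carry a group label.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    missing = indication_wm_ids - set(labels)
    if missing:
        raise ValueError(f"unlabeled drugs in indication: {sorted(missing)[:5]}")
    groups_all = {labels[w] for w in indication_wm_ids}
    groups_sim = {labels[w] for w in indication_wm_ids & similar_set}
    g, G = len(groups_sim), len(groups_all)
    return g, G, g / G if G else 0.0


def combined_ratio(atc: float, go: float, drug: float) -> float:
    """Arithmetic mean of the ATC, GO-term and drug coverage ratios."""
    for name, v in (("atc", atc), ("go", go), ("drug", drug)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} coverage {v} outside [0, 1]")
    return (atc + go + drug) / 3.0


def indication_coverage(
    indication_id: str,
    predicted_atc: set[str],
    indication_atc: set[str],
    predicted_terms: set[str],
    indication_terms: set[str],
    similar_set: set[str],
    indication_wm_ids: set[str],
    assignment: ClusterAssignment | Mapping[str, int],
    atc_level: int = 3,
) -> CoverageReport:
    """Assemble the full per-indication :class:`CoverageReport`."""
    n, N, _ = atc_coverage(predicted_atc, indication_atc, level=atc_level)
    m, M, _ = go_term_coverage(predicted_terms, indication_terms)
    sim_here = similar_set & indication_wm_ids
    d, D, _ = drug_coverage(sim_here, indication_wm_ids)
    g, G, _ = group_coverage(assignment, indication_wm_ids, sim_here)
    return CoverageReport(indication_id, n, N, m, M, d, D, g, G)


def write_reports_tsv(reports: Iterable[CoverageReport], path: str | Path) -> None:
    df = pd.DataFrame([r.as_dict() for r in reports])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_indication_table(path: str | Path) -> dict[str, set[str]]:
    """TSV (indication_id, wm_id) → mapping indication → drug id set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for ind, wm in zip(df["indication_id"], df["wm_id"]):
        out.setdefault(ind, set()).add(wm)
    return out


def write_indication_table(indications: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"indication_id": ind, "wm_id": w}
        for ind in sorted(indications)
        for w in sorted(indications[ind])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
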