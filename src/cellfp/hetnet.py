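"""Compound–target–pathway heterogeneous network: data model and I/O.

The network is tripartite: compound nodes (traditional-medicine components
and marketed western drugs), protein-target nodes (gene symbols), and
biological-function terms (GO-BP / Reactome / KEGG / WikiPathways
accessions).  Two edge layers connect them: scored compound→target
predictions (confidence scores from structure-based target prediction)
and unscored target→term annotations extracted from gene-set (GMT) files.

File formats consumed/emitted:

* compound–target table: TSV ``compound_id  target_id  score``; ``#``
  comment lines ignored; header row auto-detected.
* term annotations: standard GMT (``term_id <TAB> description <TAB> gene…``).
* compound metadata: TSV with columns ``id, name, role, atc_codes,
  indications`` (the last two semicolon-separated).
* network dump: a single JSON document with stable key order.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: WHO ATC code grammar: anatomical letter, 2-digit therapeutic subgroup,
#: then optional pharmacological letter, chemical letter, 2-digit substance.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}(?:[A-Z](?:[A-Z](?:\d{2})?)?)?$")

#: Character length of an ATC code truncated to each of the 5 levels.
ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

#: Default confidence-score cutoff for retaining predicted compound–target
#: edges (strictly greater-than).  Configurable everywhere it is used.
DEFAULT_SCORE_THRESHOLD = 20.0


class Role(str, Enum):
    """Whether a compound is a herbal component or a marketed drug."""

    TCM_COMPONENT = "tcm_component"
    WESTERN_DRUG = "western_drug"


class TermSource(str, Enum):
    """Annotation database a function term was taken from."""

    GO_BP = "GO_BP"
    REACTOME = "Reactome"
    KEGG = "KEGG"
    WIKI = "Wiki"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def atc_truncate(code: str, level: int) -> str:
    """Truncate an ATC code to the given classification level (1–5)."""
    if level not in ATC_LEVEL_LENGTH:
        raise ValueError(f"ATC level must be 1..5, got {level}")
    return code[: ATC_LEVEL_LENGTH[level]]


@dataclass(frozen=True)
class CompoundNode:
    id: str
    name: str = ""
    role: Role = Role.TCM_COMPONENT
    atc_codes: frozenset[str] = frozenset()
    indication_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for code in self.atc_codes:
            if not ATC_PATTERN.match(code):
                raise ValueError(f"invalid ATC code {code!r} on compound {self.id!r}")


@dataclass(frozen=True)
class TargetGene:
    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("target gene id must be non-empty")


@dataclass(frozen=True)
class FunctionTerm:
    id: str
    source: TermSource
    name: str = ""


@dataclass(frozen=True)
class CompoundTargetEdge:
    compound_id: str
    target_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(
                f"negative confidence score {self.score} on edge "
                f"({self.compound_id!r}, {self.target_id!r})"
            )


@dataclass
class TermAnnotations:
    """Target→term pairs parsed from one GMT file, with term registry."""

    pairs: list[tuple[str, str]]
    terms: list[FunctionTerm]
    source: TermSource


@dataclass
class HeteroNetwork:
    """Tripartite compound / target / function-term network."""

    compounds: list[CompoundNode]
    targets: list[TargetGene]
    terms: list[FunctionTerm]
    ct_edges: list[CompoundTargetEdge]
    tp_edges: list[tuple[str, str]]
    score_threshold_applied: float = DEFAULT_SCORE_THRESHOLD

    # -- lookups -------------------------------------------------------

    def compound_ids(self, role: Role | None = None) -> list[str]:
        """Sorted compound ids, optionally restricted to one role."""
        return sorted(c.id for c in self.compounds if role is None or c.role == role)

    @property
    def term_source(self) -> dict[str, TermSource]:
        return {t.id: t.source for t in self.terms}

    def targets_of(self, compound_id: str) -> set[str]:
        self._require_compound(compound_id)
        return {e.target_id for e in self.ct_edges if e.compound_id == compound_id}

    def terms_of_target(self, target_id: str) -> set[str]:
        return {p for t, p in self.tp_edges if t == target_id}

    def term_support(self, compound_id: str) -> set[str]:
        """All function terms reachable from a compound via any of its targets."""
        targets = self.targets_of(compound_id)
        return {p for t, p in self.tp_edges if t in targets}

    def compound(self, compound_id: str) -> CompoundNode:
        self._require_compound(compound_id)
        return next(c for c in self.compounds if c.id == compound_id)

    def _require_compound(self, compound_id: str) -> None:
        if compound_id not in {c.id for c in self.compounds}:
            raise KeyError(f"unknown compound id {compound_id!r}")

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        """Raise ValueError on any referential-integrity violation."""
        cids = [c.id for c in self.compounds]
        if len(cids) != len(set(cids)):
            raise ValueError("duplicate compound ids")
        tids = {t.id for t in self.targets}
        if len(tids) != len(self.targets):
            raise ValueError("duplicate target ids")
        pids = {p.id for p in self.terms}
        if len(pids) != len(self.terms):
            raise ValueError("duplicate term ids")
        cset = set(cids)
        seen_ct: set[tuple[str, str]] = set()
        edges_per_compound: dict[str, int] = {}
        for e in self.ct_edges:
            if e.compound_id not in cset or e.target_id not in tids:
                raise ValueError(f"dangling compound-target edge {e}")
            if e.score <= self.score_threshold_applied:
                raise ValueError(
                    f"edge {e} at or below applied score threshold "
                    f"{self.score_threshold_applied}"
                )
            key = (e.compound_id, e.target_id)
            if key in seen_ct:
                raise ValueError(f"duplicate compound-target pair {key}")
            seen_ct.add(key)
            edges_per_compound[e.compound_id] = edges_per_compound.get(e.compound_id, 0) + 1
        for cid in cids:
            if edges_per_compound.get(cid, 0) == 0:
                raise ValueError(f"compound {cid!r} retained with no surviving edges")
        if len(set(self.tp_edges)) != len(self.tp_edges):
            raise ValueError("duplicate target-term pairs")
        for t, p in self.tp_edges:
            if t not in tids or p not in pids:
                raise ValueError(f"dangling target-term pair ({t!r}, {p!r})")

    # -- serialisation -------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "compounds": [
                {
                    "id": c.id,
                    "name": c.name,
                    "role": c.role.value,
                    "atc_codes": sorted(c.atc_codes),
                    "indication_ids": sorted(c.indication_ids),
                }
                for c in sorted(self.compounds, key=lambda c: c.id)
            ],
            "targets": sorted(t.id for t in self.targets),
            "terms": [
                {"id": t.id, "source": t.source.value, "name": t.name}
                for t in sorted(self.terms, key=lambda t: t.id)
            ],
            "ct_edges": [
                {"compound_id": e.compound_id, "target_id": e.target_id, "score": e.score}
                for e in sorted(self.ct_edges, key=lambda e: (e.compound_id, e.target_id))
            ],
            "tp_edges": sorted(self.tp_edges),
            "score_threshold_applied": self.score_threshold_applied,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HeteroNetwork":
        doc = json.loads(text)
        return cls(
            compounds=[
                CompoundNode(
                    id=c["id"],
                    name=c["name"],
                    role=Role(c["role"]),
                    atc_codes=frozenset(c["atc_codes"]),
                    indication_ids=frozenset(c["indication_ids"]),
                )
                for c in doc["compounds"]
            ],
            targets=[TargetGene(t) for t in doc["targets"]],
            terms=[
                FunctionTerm(id=t["id"], source=TermSource(t["source"]), name=t["name"])
                for t in doc["terms"]
            ],
            ct_edges=[
                CompoundTargetEdge(e["compound_id"], e["target_id"], e["score"])
                for e in doc["ct_edges"]
            ],
            tp_edges=[tuple(p) for p in doc["tp_edges"]],
            score_threshold_applied=doc["score_threshold_applied"],
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "HeteroNetwork":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# readers


def read_compound_target_table(
    path: str | Path,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[CompoundTargetEdge]:
    """Read a scored compound–target TSV, keeping rows with score strictly
    above ``score_threshold``.

    Duplicate (compound, target) rows are collapsed keeping the maximum
    score (the most confident prediction).  ``#`` comment lines and blank
    lines are skipped; a header row (non-numeric third column on the first
    data row) is auto-detected.  A non-numeric score elsewhere raises
    :class:`ParseError` naming the 1-based line number.
    """
    best: dict[tuple[str, str], float] = {}
    first_data_row = True
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(row)}")
            cid, tid, raw = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                score = float(raw)
            except ValueError:
                if first_data_row:  # header
                    first_data_row = False
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from None
            first_data_row = False
            if score > score_threshold:
                key = (cid, tid)
                if score > best.get(key, float("-inf")):
                    best[key] = score
    if not best:
        logger.warning("no compound-target edges above score %s in %s", score_threshold, path)
    return [
        CompoundTargetEdge(c, t, s) for (c, t), s in sorted(best.items())
    ]


def read_term_annotations_gmt(path: str | Path, source: TermSource) -> TermAnnotations:
    """Parse a GMT gene-set file into deduplicated (target, term) pairs.

    Each line is ``term_id <TAB> description <TAB> gene1 <TAB> gene2 …``.
    Lines with fewer than three fields raise :class:`ParseError`; a term
    whose gene list is empty after deduplication is skipped with a warning.
    """
    pairs: list[tuple[str, str]] = []
    terms: list[FunctionTerm] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_terms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            term_id, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                logger.warning("%s:%d: term %s has no genes, skipped", path, lineno, term_id)
                continue
            if term_id not in seen_terms:
                seen_terms.add(term_id)
                terms.append(FunctionTerm(id=term_id, source=source, name=desc))
            for g in genes:
                pair = (g, term_id)
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    pairs.append(pair)
    return TermAnnotations(pairs=pairs, terms=terms, source=source)


def read_compound_metadata(path: str | Path) -> list[CompoundNode]:
    """Read the compound metadata TSV (id, name, role, atc_codes, indications)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"id", "name", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    nodes = []
    for rec in df.to_dict("records"):
        nodes.append(
            CompoundNode(
                id=rec["id"],
                name=rec["name"],
                role=Role(rec["role"]),
                atc_codes=frozenset(c for c in rec.get("atc_codes", "").split(";") if c),
                indication_ids=frozenset(
                    i for i in rec.get("indications", "").split(";") if i
                ),
            )
        )
    return nodes


def write_compound_metadata(nodes: Sequence[CompoundNode], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "role": c.role.value,
                "atc_codes": ";".join(sorted(c.atc_codes)),
                "indications": ";".join(sorted(c.indication_ids)),
            }
            for c in sorted(nodes, key=lambda c: c.id)
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# construction


def build_network(
    ct_edges: Iterable[CompoundTargetEdge],
    annotations: TermAnnotations | Sequence[TermAnnotations],
    compound_meta: Iterable[CompoundNode],
    score_threshold_applied: float = DEFAULT_SCORE_THRESHOLD,
    strict: bool = False,
) -> HeteroNetwork:
    """Assemble a validated :class:`HeteroNetwork`.

    Compounds from ``compound_meta`` with no surviving compound–target edge
    are dropped with a warning (they fall out of every downstream analysis,
    mirroring the screen on the target-prediction confidence score).
    Target–term pairs naming a target absent from the edge layer are an
    error when ``strict`` else dropped with a warning.  Terms sharing an id
    across sources are rejected: term ids key the tp edge layer.
    """
    if isinstance(annotations, TermAnnotations):
        annotations = [annotations]
    edges = list(ct_edges)
    meta = {c.id: c for c in compound_meta}
    with_edges = {e.compound_id for e in edges}
    for cid in sorted(set(meta) - with_edges):
        logger.warning("compound %s has no surviving targets; dropped from network", cid)
    compounds = [meta[c] for c in sorted(set(meta) & with_edges)]
    orphan_edges = [e for e in edges if e.compound_id not in meta]
    if orphan_edges:
        raise ValueError(
            f"{len(orphan_edges)} compound-target edges name compounds absent from "
            f"metadata (first: {orphan_edges[0].compound_id!r})"
        )
    edges = [e for e in edges if e.compound_id in {c.id for c in compounds}]
    targets = sorted({e.target_id for e in edges})

    terms: list[FunctionTerm] = []
    registered: dict[str, FunctionTerm] = {}
    tp_edges: list[tuple[str, str]] = []
    seen_tp: set[tuple[str, str]] = set()
    target_set = set(targets)
    for ann in annotations:
        for term in ann.terms:
            prev = registered.get(term.id)
            if prev is not None and prev.source != term.source:
                raise ValueError(
                    f"term id {term.id!r} registered under two sources "
                    f"({prev.source.value}, {term.source.value})"
                )
            if prev is None:
                registered[term.id] = term
                terms.append(term)
        for t, p in ann.pairs:
            if t not in target_set:
                if strict:
                    raise ValueError(f"annotation pair ({t!r}, {p!r}) names unknown target")
                logger.warning("annotation target %s not in network; pair dropped", t)
                continue
            if (t, p) not in seen_tp:
                seen_tp.add((t, p))
                tp_edges.append((t, p))

    used_terms = {p for _, p in tp_edges}
    terms = [t for t in terms if t.id in used_terms]
    net = HeteroNetwork(
        compounds=compounds,
        targets=[TargetGene(t) for t in targets],
        terms=terms,
        ct_edges=edges,
        tp_edges=tp_edges,
        score_threshold_applied=score_threshold_applied,
    )
    net.validate()
    return net
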