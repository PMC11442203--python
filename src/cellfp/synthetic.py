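"""Synthetic heterogeneous networks with planted mechanism groups.

The generator emulates the statistical structure the similarity pipeline
assumes: K latent mechanism groups of compounds (herbal components and
western drugs alike) whose targets annotate round-robin into a
group-specific pool of GO-BP terms, with a tunable fraction of noise
targets annotated to uniformly random out-of-group terms (other groups'
pools or a shared Reactome-flavoured background pool).  Western drugs
carry one level-3 ATC code family per group; indications are drug sets
spanning a configurable number of groups; drug signatures shift each
group term's gene set by ±delta (one planted direction per group × term)
on top of i.i.d. Gaussian noise, LINCS-style.

At ``noise_rate=0`` compounds of one group share term profiles exactly
and groups reach disjoint term sets, so every within-group distance is
strictly smaller than every between-group distance — clustering at the
true K recovers the planted groups perfectly.

Everything is deterministic given ``SyntheticConfig.seed``, and
:func:`write_bundle` emits exactly the text formats the package readers
consume, plus the ground truth and a ready-to-run pipeline config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hetnet import (
    CompoundNode,
    CompoundTargetEdge,
    FunctionTerm,
    HeteroNetwork,
    Role,
    TargetGene,
    TermSource,
)
from .moa import ExpressionSignature, write_signatures
from .coverage import write_indication_table
from .hetnet import write_compound_metadata

_ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic benchmark instance."""

    K: int = 4
    n_tcm_per_group: int = 3
    n_wm_per_group: int = 6
    n_targets_per_compound: int = 8
    terms_per_group: int = 8
    shared_term_pool: int = 12
    noise_rate: float = 0.1
    n_indications: int = 4
    groups_per_indication: int = 2
    signature_shift: float = 2.0
    signature_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "K",
            "n_tcm_per_group",
            "n_wm_per_group",
            "n_targets_per_compound",
            "terms_per_group",
            "n_indications",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.shared_term_pool < 0:
            raise ValueError("shared_term_pool must be >= 0")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if not 1 <= self.groups_per_indication <= self.K:
            raise ValueError("groups_per_indication must be in 1..K")
        if self.signature_noise_sd < 0:
            raise ValueError("signature_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure underlying one generated bundle."""

    compound_group: dict[str, int]
    group_terms: dict[int, list[str]]
    indication_groups: dict[str, list[int]]
    directions: dict[str, dict[str, int]]  # wm -> term -> +1/-1

    def to_json(self) -> str:
        doc = {
            "compound_group": self.compound_group,
            "group_terms": {str(g): terms for g, terms in self.group_terms.items()},
            "indication_groups": self.indication_groups,
            "directions": self.directions,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(
            compound_group=doc["compound_group"],
            group_terms={int(g): t for g, t in doc["group_terms"].items()},
            indication_groups=doc["indication_groups"],
            directions={
                w: {p: int(d) for p, d in terms.items()}
                for w, terms in doc["directions"].items()
            },
        )


@dataclass
class SyntheticBundle:
    network: HeteroNetwork
    indications: dict[str, set[str]]
    signatures: dict[str, ExpressionSignature] | None
    truth: GroundTruth | None
    screen_threshold: float | None = None
    k_main: int | None = None
    decoy_rows: list[tuple[str, str, float]] = field(default_factory=list)


def _group_atc_level3(g: int) -> str:
    return f"{_ATC_LETTERS[(g - 1) % len(_ATC_LETTERS)]}{g:02d}A"


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Draw one benchmark instance; byte-identical given the same seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    group_terms = {
        g: [f"GO:{g * 10000 + t:07d}" for t in range(cfg.terms_per_group)]
        for g in range(1, cfg.K + 1)
    }
    background = [f"R-SYN-{i:04d}" for i in range(cfg.shared_term_pool)]
    all_terms = [p for g in group_terms.values() for p in g] + background

    compounds: list[CompoundNode] = []
    compound_group: dict[str, int] = {}
    for g in range(1, cfg.K + 1):
        for i in range(cfg.n_tcm_per_group):
            cid = f"tcm{g}_{i:02d}"
            compounds.append(CompoundNode(id=cid, name=f"component {cid}", role=Role.TCM_COMPONENT))
            compound_group[cid] = g
        lvl3 = _group_atc_level3(g)
        for i in range(cfg.n_wm_per_group):
            cid = f"wm{g}_{i:02d}"
            compounds.append(
                CompoundNode(
                    id=cid,
                    name=f"drug {cid}",
                    role=Role.WESTERN_DRUG,
                    atc_codes=frozenset({f"{lvl3}A{(i % 9) + 1:02d}"}),
                )
            )
            compound_group[cid] = g

    ct_edges: list[CompoundTargetEdge] = []
    tp_edges: list[tuple[str, str]] = []
    decoys: list[tuple[str, str, float]] = []
    for c in compounds:
        g = compound_group[c.id]
        pool = group_terms[g]
        other = [p for p in all_terms if p not in pool]
        for j in range(cfg.n_targets_per_compound):
            tid = f"T_{c.id}_{j}"
            ct_edges.append(CompoundTargetEdge(c.id, tid, float(rng.uniform(21.0, 40.0))))
            if other and rng.random() < cfg.noise_rate:
                term = str(rng.choice(other))
            else:
                term = pool[j % cfg.terms_per_group]
            tp_edges.append((tid, term))
        # one sub-threshold decoy prediction per compound, dropped on read
        decoys.append((c.id, f"T_{c.id}_decoy", float(rng.uniform(0.0, 15.0))))

    used = {p for _, p in tp_edges}
    terms = [
        FunctionTerm(id=p, source=TermSource.GO_BP, name=f"synthetic process {p}")
        for g in sorted(group_terms)
        for p in group_terms[g]
        if p in used
    ] + [
        FunctionTerm(id=p, source=TermSource.REACTOME, name=f"synthetic pathway {p}")
        for p in background
        if p in used
    ]
    targets = sorted({e.target_id for e in ct_edges})
    net = HeteroNetwork(
        compounds=compounds,
        targets=[TargetGene(t) for t in targets],
        terms=terms,
        ct_edges=ct_edges,
        tp_edges=tp_edges,
        score_threshold_applied=20.0,
    )
    net.validate()

    indications: dict[str, list[int]] = {}
    ind_wm: dict[str, set[str]] = {}
    wm_by_group: dict[int, list[str]] = {g: [] for g in range(1, cfg.K + 1)}
    for c in compounds:
        if c.role == Role.WESTERN_DRUG:
            wm_by_group[compound_group[c.id]].append(c.id)
    for i in range(cfg.n_indications):
        ind = f"IND{i + 1}"
        groups = [((i + j) % cfg.K) + 1 for j in range(cfg.groups_per_indication)]
        indications[ind] = sorted(set(groups))
        ind_wm[ind] = {w for g in indications[ind] for w in wm_by_group[g]}

    # planted regulation direction per (group, term); shared by group members
    dir_by_group_term = {
        (g, p): int(rng.choice([-1, 1]))
        for g in sorted(group_terms)
        for p in group_terms[g]
    }
    genes_of_term: dict[str, list[str]] = {}
    for t, p in tp_edges:
        genes_of_term.setdefault(p, []).append(t)

    signatures: dict[str, ExpressionSignature] = {}
    directions: dict[str, dict[str, int]] = {}
    gene_index = {t: i for i, t in enumerate(targets)}
    for g in range(1, cfg.K + 1):
        for w in wm_by_group[g]:
            z = rng.normal(0.0, cfg.signature_noise_sd, size=len(targets))
            directions[w] = {}
            for p in group_terms[g]:
                d = dir_by_group_term[(g, p)]
                directions[w][p] = d
                for gene in genes_of_term.get(p, ()):
                    z[gene_index[gene]] += d * cfg.signature_shift
            signatures[w] = ExpressionSignature(
                drug_id=w, zscores={t: float(z[gene_index[t]]) for t in targets}
            )

    truth = GroundTruth(
        compound_group=compound_group,
        group_terms=group_terms,
        indication_groups=indications,
        directions=directions,
    )
    return SyntheticBundle(
        network=net,
        indications=ind_wm,
        signatures=signatures,
        truth=truth,
        k_main=cfg.K,
        decoy_rows=decoys,
    )


def worked_example_fixture() -> SyntheticBundle:
    """Deterministic fixture reproducing the lumbar-disc-herniation (LDH)
    screening arithmetic end to end.

    One indication with 32 drugs in 7 cluster-tree groups (sizes
    5,5,5,5,4,4,4).  Per group there is one herbal component covering 4
    of the group's 10 terms; *similar* drugs cover all 10 terms (PathSim
    distance to the component 3/7 ≈ 0.43 < 0.53) and the remaining drugs
    cover terms 2–9 only (distance 2/3 ≈ 0.67 ≥ 0.53).  With the fixed
    screen threshold 0.53 exactly 23 of the 32 drugs pass (4,4,4,3,3,3,2
    per group), hitting all 7 groups: drug coverage 23/32 = 0.72 and
    cluster-group coverage 7/7 = 1.
    """
    sizes = [5, 5, 5, 5, 4, 4, 4]
    n_similar = [4, 4, 4, 3, 3, 3, 2]
    n_pool = 10

    compounds: list[CompoundNode] = []
    ct_edges: list[CompoundTargetEdge] = []
    tp_edges: list[tuple[str, str]] = []
    group_terms: dict[int, list[str]] = {}
    compound_group: dict[str, int] = {}
    ldh_wm: set[str] = set()

    def add_compound(cid: str, term_idx: list[int], pool: list[str]) -> None:
        for j, ti in enumerate(term_idx):
            tid = f"T_{cid}_{j}"
            ct_edges.append(CompoundTargetEdge(cid, tid, 30.0))
            tp_edges.append((tid, pool[ti]))

    for g in range(1, 8):
        pool = [f"GO:{8000000 + g * 100 + t:07d}" for t in range(n_pool)]
        group_terms[g] = pool
        tcm_id = f"ldh_tcm{g}"
        compounds.append(
            CompoundNode(id=tcm_id, name=f"component {tcm_id}", role=Role.TCM_COMPONENT)
        )
        compound_group[tcm_id] = g
        add_compound(tcm_id, [0, 1, 2, 3], pool)
        code = f"{_ATC_LETTERS[g - 1]}{g:02d}AA01"
        for i in range(sizes[g - 1]):
            similar = i < n_similar[g - 1]
            wid = f"ldh_wm{g}_{i:02d}{'s' if similar else 'x'}"
            compounds.append(
                CompoundNode(
                    id=wid,
                    name=f"drug {wid}",
                    role=Role.WESTERN_DRUG,
                    atc_codes=frozenset({code}),
                    indication_ids=frozenset({"LDH"}),
                )
            )
            compound_group[wid] = g
            ldh_wm.add(wid)
            add_compound(wid, list(range(n_pool)) if similar else list(range(2, n_pool)), pool)

    used = {p for _, p in tp_edges}
    terms = [
        FunctionTerm(id=p, source=TermSource.GO_BP, name=f"process {p}")
        for g in sorted(group_terms)
        for p in group_terms[g]
        if p in used
    ]
    targets = sorted({e.target_id for e in ct_edges})
    net = HeteroNetwork(
        compounds=compounds,
        targets=[TargetGene(t) for t in targets],
        terms=terms,
        ct_edges=ct_edges,
        tp_edges=tp_edges,
        score_threshold_applied=20.0,
    )
    net.validate()
    truth = GroundTruth(
        compound_group=compound_group,
        group_terms=group_terms,
        indication_groups={"LDH": list(range(1, 8))},
        directions={},
    )
    return SyntheticBundle(
        network=net,
        indications={"LDH": ldh_wm},
        signatures=None,
        truth=truth,
        screen_threshold=0.53,
        k_main=7,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the bundle as the text files the package readers consume.

    Writes the scored compound–target TSV (including sub-threshold decoy
    rows), one GMT per annotation source, the metadata / indication
    tables, signatures and ground truth where present, and a pipeline
    ``config.yaml`` pointing at them all.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = bundle.network
    paths: dict[str, Path] = {}

    ct_path = outdir / "compound_targets.tsv"
    rows = [(e.compound_id, e.target_id, e.score) for e in net.ct_edges]
    rows += bundle.decoy_rows
    with open(ct_path, "w") as fh:
        fh.write("compound_id\ttarget_id\tscore\n")
        for c, t, s in sorted(rows):
            fh.write(f"{c}\t{t}\t{s:.6g}\n")
    paths["compound_targets"] = ct_path

    genes_by_term: dict[str, list[str]] = {}
    for t, p in net.tp_edges:
        genes_by_term.setdefault(p, []).append(t)
    gmt_paths: dict[str, str] = {}
    for source in TermSource:
        members = [t for t in net.terms if t.source == source]
        if not members:
            continue
        gpath = outdir / f"{source.value.lower()}.gmt"
        with open(gpath, "w") as fh:
            for term in sorted(members, key=lambda t: t.id):
                genes = "\t".join(sorted(genes_by_term.get(term.id, ())))
                fh.write(f"{term.id}\t{term.name}\t{genes}\n")
        paths[f"gmt_{source.value}"] = gpath
        gmt_paths[source.value] = gpath.name

    meta_path = outdir / "metadata.tsv"
    write_compound_metadata(net.compounds, meta_path)
    paths["metadata"] = meta_path

    ind_path = outdir / "indications.tsv"
    write_indication_table(bundle.indications, ind_path)
    paths["indications"] = ind_path

    if bundle.signatures is not None:
        sig_path = outdir / "signatures.tsv"
        write_signatures(bundle.signatures, sig_path)
        paths["signatures"] = sig_path

    if bundle.truth is not None:
        gt_path = outdir / "ground_truth.json"
        gt_path.write_text(bundle.truth.to_json() + "\n")
        paths["ground_truth"] = gt_path

    cfg = {
        "compound_target_path": ct_path.name,
        "gmt_paths": gmt_paths,
        "metadata_path": meta_path.name,
        "indications_path": ind_path.name,
        "signatures_path": paths["signatures"].name if "signatures" in paths else None,
        "score_threshold": net.score_threshold_applied,
        "threshold_mode": "fixed" if bundle.screen_threshold is not None else "global_median",
        "threshold_value": bundle.screen_threshold,
        "k_main": bundle.k_main,
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths["config"] = cfg_path
    return paths
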