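"""End-to-end orchestration: load → similarity → cluster → screen →
coverage → mechanism transfer → direction report.

Every stage is a pure function of (inputs, config), so a run is fully
reproducible from its manifest (config hash + seed + package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import clustering, coverage, moa, similarity
from .hetnet import (
    HeteroNetwork,
    Role,
    TermSource,
    build_network,
    read_compound_metadata,
    read_compound_target_table,
    read_term_annotations_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    ``threshold_mode`` is either ``global_median`` (the median of all
    component × drug cross distances) or ``fixed`` (use
    ``threshold_value``).  ``k_filter`` enables the drug-library
    consistency screen before the main clustering; ``None`` skips it.
    """

    compound_target_path: str = "compound_targets.tsv"
    gmt_paths: dict[str, str] = field(default_factory=dict)  # source -> path
    metadata_path: str = "metadata.tsv"
    indications_path: str = "indications.tsv"
    signatures_path: str | None = None
    score_threshold: float = 20.0
    fingerprint_mode: str = "count"
    linkage: str = "complete"
    k_main: int | None = None
    k_filter: int | None = None
    min_cosize: int = 2
    atc_level: int = 3
    threshold_mode: str = "global_median"
    threshold_value: float | None = None
    nearest_floor: float = 0.0
    go_source: str = "GO_BP"
    tau: float = 0.5
    min_overlap: int = 3
    seed: int = 0
    outdir: str = "cellfp_out"

    def validate(self) -> None:
        if self.fingerprint_mode not in ("count", "binary"):
            raise ValueError(f"bad fingerprint_mode {self.fingerprint_mode!r}")
        if self.linkage not in clustering.LINKAGES:
            raise ValueError(f"bad linkage {self.linkage!r}")
        if self.threshold_mode not in ("global_median", "fixed"):
            raise ValueError(f"bad threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("threshold_mode 'fixed' requires threshold_value")
        if not 1 <= self.atc_level <= 5:
            raise ValueError("atc_level must be 1..5")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("compound_target_path", "metadata_path", "indications_path"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} does not exist")
        for src, p in self.gmt_paths.items():
            TermSource(src)  # raises on unknown source
            if not Path(p).exists():
                raise FileNotFoundError(f"gmt_paths[{src}]: {p} does not exist")
        if self.signatures_path is not None and not Path(self.signatures_path).exists():
            raise FileNotFoundError(f"signatures_path: {self.signatures_path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        base = Path(path).parent
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc = {k: v for k, v in doc.items() if v is not None}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        # resolve paths relative to the config file
        for name in ("compound_target_path", "metadata_path", "indications_path",
                     "signatures_path"):
            v = getattr(cfg, name)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, name, str(base / v))
        cfg.gmt_paths = {
            s: (p if Path(p).is_absolute() else str(base / p))
            for s, p in cfg.gmt_paths.items()
        }
        return cfg


def _stage(name: str):
    """Decorator: re-raise stage failures naming the stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def load_network(cfg: RunConfig) -> HeteroNetwork:
    edges = read_compound_target_table(cfg.compound_target_path, cfg.score_threshold)
    annotations = [
        read_term_annotations_gmt(path, TermSource(src))
        for src, path in sorted(cfg.gmt_paths.items())
    ]
    meta = read_compound_metadata(cfg.metadata_path)
    net = build_network(edges, annotations, meta, score_threshold_applied=cfg.score_threshold)
    logger.info(
        "network: %d compounds, %d targets, %d terms, %d ct edges, %d tp edges",
        len(net.compounds), len(net.targets), len(net.terms),
        len(net.ct_edges), len(net.tp_edges),
    )
    return net


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle to
    ``cfg.outdir``.  Returns the in-memory results keyed by stage."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = _stage("load")(load_network)(cfg)
    tcm_ids = net.compound_ids(Role.TCM_COMPONENT)
    wm_ids = net.compound_ids(Role.WESTERN_DRUG)
    if not tcm_ids or not wm_ids:
        raise RuntimeError("pipeline needs both component and drug compounds")

    @_stage("similarity")
    def _sim():
        M = similarity.path_count_matrix(net, mode=cfg.fingerprint_mode)
        S = similarity.pathsim(M)
        similarity.validate_similarity(S)
        return S, similarity.to_distance(S)

    S, D = _sim()

    @_stage("consistency_filter")
    def _filter():
        if cfg.k_filter is None:
            return sorted(wm_ids)
        retained = clustering.consistency_filter(
            D.loc[wm_ids, wm_ids], cfg.k_filter, cfg.min_cosize
        )
        logger.info("consistency filter: %d of %d drugs retained", len(retained), len(wm_ids))
        return sorted(retained)

    wm_kept = _filter()
    keep = sorted(tcm_ids) + wm_kept
    S, D = S.loc[keep, keep], D.loc[keep, keep]

    @_stage("clustering")
    def _cluster():
        dend = clustering.hcluster(D, linkage=cfg.linkage)
        k = cfg.k_main if cfg.k_main is not None else max(2, int(round(len(keep) ** 0.5)))
        return dend, clustering.cut_tree(dend, k)

    dend, assignment = _cluster()

    @_stage("screen")
    def _screen():
        indications = coverage.read_indication_table(cfg.indications_path)
        indications = {
            ind: set(wms) & set(wm_kept) for ind, wms in indications.items()
        }
        indications = {ind: wms for ind, wms in indications.items() if wms}
        if cfg.threshold_mode == "fixed":
            thr = float(cfg.threshold_value)
        else:
            thr = coverage.global_median_threshold(D, tcm_ids, wm_kept)
        logger.info("screen threshold (%s): %.4f", cfg.threshold_mode, thr)
        screen = coverage.screen_similar_drugs(D, tcm_ids, indications, thr)
        logger.info(
            "screen: %d of %d drugs similar across %d indications",
            len(screen.all_similar()), len(wm_kept), len(indications),
        )
        return indications, screen

    indications, screen = _screen()

    @_stage("moa_transfer")
    def _transfer():
        nmap = moa.nearest_wm(S, tcm_ids, wm_kept, floor=cfg.nearest_floor)
        wm_atc = {c.id: set(c.atc_codes) for c in net.compounds}
        pred_atc_by_c = moa.transfer_atc(nmap, wm_atc, level=cfg.atc_level)
        predicted_atc = set().union(*pred_atc_by_c.values()) if pred_atc_by_c else set()
        go_src = TermSource(cfg.go_source) if cfg.go_source else None
        src_map = net.term_source
        predicted_terms: set[str] = set()
        for cid, (wid, _) in nmap.items():
            predicted_terms |= moa.transfer_go_terms(cid, wid, net)
        if go_src is not None:
            predicted_terms = {p for p in predicted_terms if src_map.get(p) == go_src}
        return nmap, pred_atc_by_c, predicted_atc, predicted_terms, go_src, src_map

    nmap, pred_atc_by_c, predicted_atc, predicted_terms, go_src, src_map = _transfer()

    @_stage("coverage")
    def _coverage():
        reports = []
        for ind in sorted(indications):
            wms = indications[ind]
            ind_atc: set[str] = set()
            ind_terms: set[str] = set()
            for w in wms:
                ind_atc |= set(net.compound(w).atc_codes)
                ind_terms |= net.term_support(w)
            if go_src is not None:
                ind_terms = {p for p in ind_terms if src_map.get(p) == go_src}
            reports.append(
                coverage.indication_coverage(
                    ind,
                    predicted_atc,
                    ind_atc,
                    predicted_terms,
                    ind_terms,
                    screen.similar_wm_ids[ind],
                    wms,
                    assignment,
                    atc_level=cfg.atc_level,
                )
            )
        return reports

    reports = _coverage()

    @_stage("direction")
    def _direction():
        if cfg.signatures_path is None:
            return None, None
        sigs = moa.read_signatures(cfg.signatures_path)
        similar = sorted(screen.all_similar() & set(sigs))
        if not similar:
            logger.warning("no similar drugs carry signatures; direction report empty")
            return moa.direction_report({}, cfg.tau), {}
        common = moa.common_processes(similar, tcm_ids, net, source_filter=go_src)
        genes_by_term: dict[str, set[str]] = {}
        for t, p in net.tp_edges:
            genes_by_term.setdefault(p, set()).add(t)
        grouped: dict[tuple[int, str], list[moa.RegulationCall]] = {}
        for w in similar:
            for p in sorted(common):
                call = moa.make_call(
                    sigs[w], p, genes_by_term.get(p, set()),
                    tau=cfg.tau, min_overlap=cfg.min_overlap,
                )
                if call is not None:
                    grouped.setdefault((assignment.labels[w], p), []).append(call)
        return moa.direction_report(grouped, cfg.tau), grouped

    direction_df, grouped_calls = _direction()

    # ---- report bundle ------------------------------------------------
    similarity.write_matrix_csv(S, outdir / "similarity.csv")
    similarity.write_matrix_csv(D, outdir / "distance.csv")
    (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    assignment.write_tsv(outdir / "assignment.tsv")
    net.write_json(outdir / "network.json")
    coverage.write_reports_tsv(reports, outdir / "coverage.tsv")
    (outdir / "coverage.json").write_text(
        json.dumps([r.as_dict() for r in reports], indent=1, sort_keys=True) + "\n"
    )
    transfer_rows = [
        {
            "compound_id": c,
            "nearest_wm": nmap[c][0],
            "similarity": round(nmap[c][1], 10),
            "atc_codes": ";".join(sorted(pred_atc_by_c.get(c, set()))),
        }
        for c in sorted(nmap)
    ]
    pd.DataFrame(
        transfer_rows, columns=["compound_id", "nearest_wm", "similarity", "atc_codes"]
    ).to_csv(outdir / "moa_transfer.tsv", sep="\t", index=False)
    if direction_df is not None:
        direction_df.to_csv(
            outdir / "direction_report.tsv", sep="\t", index=False, float_format="%.6g"
        )

    cfg_dict = asdict(cfg)
    cfg_dict.pop("outdir")  # output location is not a scientific parameter
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "cellfp_version": __version__,
        "n_compounds": len(net.compounds),
        "n_components": len(tcm_ids),
        "n_drugs_input": len(wm_ids),
        "n_drugs_retained": len(wm_kept),
        "screen_threshold": screen.threshold,
        "n_similar_drugs": len(screen.all_similar()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    return {
        "network": net,
        "similarity": S,
        "distance": D,
        "dendrogram": dend,
        "assignment": assignment,
        "screen": screen,
        "nearest": nmap,
        "reports": reports,
        "direction": direction_df,
        "manifest": manifest,
    }
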