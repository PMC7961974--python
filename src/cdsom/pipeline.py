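"""End-to-end orchestration of the portrayal pipeline and run provenance.

``run_pipeline`` executes simulate -> preprocess -> train -> portraits ->
spots -> stratify -> gsz -> markers -> deconvolve -> psf on a synthetic
cohort (or a user-supplied expression TSV), writes every stage's outputs
under one directory and records a manifest with SHA-256 digests sufficient
to verify a bit-identical re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .deconvolve import atrophy_trajectory, deconvolve_cohort
from .genesets import GeneSet, gsz_matrix, gsz_score, spot_enrichment
from .markers import auc_map, select_markers, volcano
from .matrix import ExpressionMatrix
from .preprocess import preprocess
from .psf import group_psf, read_pathway_tsv
from .render import render_portrait
from .som import portraits, train_som
from .spots import detect_spots, overexpression_summary_map, spot_activation_table
from .stratify import (
    choose_k,
    correlation_silhouette,
    hierarchical_clusters,
    sample_correlation_matrix,
)
from .synthetic import CohortConfig, simulate_cohort, write_cohort

DEFAULT_CONFIG = {
    "simulate": {},  # CohortConfig keyword overrides
    "som": {"grid_rows": 20, "grid_cols": 20, "epochs": 50},
    # 0.92 rather than the detect_spots default 0.95: on a 20x20 fixture map
    # the five planted modules' footprints span ~7% of nodes, which a 5% cut
    # cannot cover
    "spots": {"quantile_threshold": 0.92, "min_size": 5},
    "stratify": {"k": "auto"},
    "markers": {"auc_min": 0.9},
    "deconvolve": {"enabled": True},
    "psf": {"pathway": "chain"},
    "render": {"pixel_size": 8},
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    stages: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge_config(user: Optional[dict]) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def toy_pathway_path(name: str) -> Path:
    """Path of one of the shipped toy pathway fixtures."""
    p = resources.files("cdsom.data.pathways") / f"{name}.tsv"
    if not p.is_file():
        raise FileNotFoundError(f"no toy pathway named {name!r}")
    return Path(str(p))


def run_pipeline(config: Optional[dict] = None, outdir="cdsom_run", seed: int = 0) -> RunManifest:
    """Run the full synthetic-cohort pipeline; returns the manifest."""
    cfg = _merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg, seed=seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(stage: str, paths: dict) -> None:
        manifest.stages[stage] = {k: str(v) for k, v in paths.items()}
        for k, v in paths.items():
            manifest.digests[f"{stage}/{k}"] = _sha256(Path(v))

    # -- simulate ----------------------------------------------------------
    sim_cfg = CohortConfig(seed=seed, **cfg["simulate"])
    raw, phenotype, truth = simulate_cohort(sim_cfg)
    record("simulate", write_cohort(out / "simulate", raw, phenotype, truth))
    grouping = truth.group_labels

    # -- preprocess --------------------------------------------------------
    em = preprocess(raw)
    pre_path = out / "preprocess" / "expression_centralized.tsv"
    pre_path.parent.mkdir(exist_ok=True)
    em.to_tsv(pre_path)
    record("preprocess", {"expression": pre_path})

    # -- train -------------------------------------------------------------
    model = train_som(em, seed=seed, **cfg["som"])
    model.save(out / "som")
    record("train", {
        "prototypes": out / "som" / "prototypes.tsv",
        "gene_to_node": out / "som" / "gene_to_node.tsv",
        "meta": out / "som" / "training_meta.json",
    })

    # -- portraits ---------------------------------------------------------
    pdir = out / "portraits"
    pdir.mkdir(exist_ok=True)
    ppaths = {}
    for p in portraits(model, grouping=grouping):
        if p.kind == "sample":
            continue
        fname = f"{p.kind}_{p.label.replace('/', '_')}.png"
        render_portrait(p, pdir / fname, pixel_size=cfg["render"]["pixel_size"])
        ppaths[fname] = pdir / fname
    record("portraits", ppaths)

    # -- spots -------------------------------------------------------------
    summary = overexpression_summary_map(model)
    spots = detect_spots(summary, model, **cfg["spots"])
    activation = spot_activation_table(spots, model)
    sdir = out / "spots"
    sdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {"label": s.label, "n_nodes": len(s.member_nodes),
             "n_genes": len(s.member_genes), "peak_node": s.peak_node,
             "peak_height": s.peak_height}
            for s in spots
        ]
    ).to_csv(sdir / "spot_report.tsv", sep="\t", index=False)
    activation.to_csv(sdir / "activation.tsv", sep="\t")
    record("spots", {"report": sdir / "spot_report.tsv",
                     "activation": sdir / "activation.tsv"})

    # -- stratify ----------------------------------------------------------
    corr = sample_correlation_matrix(model)
    k = cfg["stratify"]["k"]
    k = choose_k(model, corr=corr) if k == "auto" else int(k)
    assignment = hierarchical_clusters(model, k)
    sil = correlation_silhouette(assignment, corr)
    stdir = out / "stratify"
    stdir.mkdir(exist_ok=True)
    corr.to_csv(stdir / "correlation.tsv", sep="\t")
    assignment.labels.to_csv(stdir / "clusters.csv")
    sil.scores.to_csv(stdir / "silhouette.csv")
    record("stratify", {"correlation": stdir / "correlation.tsv",
                        "clusters": stdir / "clusters.csv",
                        "silhouette": stdir / "silhouette.csv"})

    # -- gsz (planted modules as gene sets) --------------------------------
    module_sets = [
        GeneSet(f"module_{lab}", "planted co-expression module",
                truth.module_genes(lab))
        for lab in sim_cfg.module_labels
    ]
    gsz = gsz_matrix(module_sets, em)
    gdir = out / "gsz"
    gdir.mkdir(exist_ok=True)
    gsz.to_csv(gdir / "gsz.tsv", sep="\t")
    enr = spot_enrichment(spots, module_sets, em.gene_ids)
    enr.to_csv(gdir / "spot_enrichment.tsv", sep="\t")
    record("gsz", {"gsz": gdir / "gsz.tsv", "enrichment": gdir / "spot_enrichment.tsv"})

    # -- markers (CD groups vs rest) ---------------------------------------
    labels = grouping.isin(["CD-L", "CD-H"]).to_numpy()
    up, _down = auc_map(model, labels, phenotype="CD")
    markers = select_markers(up, model, em, labels, auc_min=cfg["markers"]["auc_min"])
    volc = volcano(em, labels, genes=markers["gene"]) if len(markers) else pd.DataFrame()
    mdir = out / "markers"
    mdir.mkdir(exist_ok=True)
    pd.DataFrame(up.values).to_csv(mdir / "auc_map.tsv", sep="\t",
                                   index=False, header=False)
    markers.to_csv(mdir / "markers.tsv", sep="\t", index=False)
    volc.to_csv(mdir / "volcano.tsv", sep="\t")
    record("markers", {"auc_map": mdir / "auc_map.tsv",
                       "markers": mdir / "markers.tsv",
                       "volcano": mdir / "volcano.tsv"})

    # -- deconvolve --------------------------------------------------------
    if cfg["deconvolve"]["enabled"] and truth.signature is not None:
        fractions = deconvolve_cohort(raw, truth.signature, grouping=grouping)
        lower_crypt = GeneSet("lower_crypt", "planted proliferative crypt block",
                              truth.crypt_genes["lower_crypt"])
        scores = gsz_score(lower_crypt, em).scores
        traj = atrophy_trajectory(fractions, scores)
        ddir = out / "deconvolve"
        ddir.mkdir(exist_ok=True)
        fractions.fractions.to_csv(ddir / "fractions.csv")
        traj.fitted.to_csv(ddir / "trajectory_fitted.csv")
        record("deconvolve", {"fractions": ddir / "fractions.csv",
                              "trajectory": ddir / "trajectory_fitted.csv"})

    # -- psf ---------------------------------------------------------------
    pathway = read_pathway_tsv(toy_pathway_path(cfg["psf"]["pathway"]))
    psf_results = group_psf(pathway, em, grouping)
    fdir = out / "psf"
    fdir.mkdir(exist_ok=True)
    rows = [
        {"group": grp, "node": node, "signal": sig}
        for grp, res in psf_results.items()
        for node, sig in res.node_signals.items()
    ]
    pd.DataFrame(rows).to_csv(fdir / "psf.tsv", sep="\t", index=False)
    record("psf", {"psf": fdir / "psf.tsv"})

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
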