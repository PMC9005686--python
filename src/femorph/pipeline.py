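"""End-to-end pipeline: registration -> shape space -> statistics -> prediction.

`run_pipeline` sequences the full analysis in the protocol's order —
surface-patch projection, five template relaxations, two consensus sliding
iterations, delimitation-curve removal, GPA, PCA, angle measurements,
allometric regressions, phylogenetic signal, PGLS, ancestral states, and
k-NN locomotor prediction — and returns a report bundle plus a manifest
recording the configuration, seed and stage list so any stage can be
reproduced in isolation. Stages that lack their inputs (no meshes: projection
skipped; no tree: comparative stages skipped) are recorded as skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import evaluate_against_inputs, knn_predict, loo_evaluate
from .landmarks import LandmarkConfiguration, SpecimenRecord, TriangleMesh
from .metrics import angle_group_test, groupwise_allometry, projected_axis_angle
from .phylo import Phylogeny, ancestral_continuous, kmult_test, pgls_fit
from .procrustes import gpa_align
from .shapespace import fit_pca, morphospace_report
from .sliding import (project_surface_patch, relax_to_reference,
                      slide_sample_to_consensus, strip_delimitation_curves)

log = logging.getLogger(__name__)

STAGES = ["project", "relax", "consensus_slide", "strip_delimitation", "gpa",
          "pca", "angles", "allometry", "kmult", "pgls", "ancestral", "knn"]


@dataclass
class PipelineConfig:
    """All pipeline knobs, with the protocol's published constants as defaults."""

    n_relax_iter: int = 5
    n_slide_iter: int = 2
    classification_axis: int = 1          # 0-based: PC2
    k_neighbors: int = 5
    n_perm: int = 999
    seed: int = 0
    clamp_fraction: float = 0.1
    slide_curves: bool = True
    tangent_projection: bool = False      # reserved flag; residual PCA default
    distance_mode: str = "axis"           # axis | full-shape
    denominator: str = "all"              # all | known
    angle_pairs: dict = field(default_factory=dict)
    template_id: str | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors % 2 == 0:
            raise ValueError("k_neighbors must be odd")
        if self.n_relax_iter < 0 or self.n_slide_iter < 0:
            raise ValueError("iteration counts must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(
    configs: list[LandmarkConfiguration],
    records: list[SpecimenRecord],
    config: PipelineConfig | None = None,
    meshes: dict[str, TriangleMesh] | None = None,
    tree: Phylogeny | None = None,
    template: LandmarkConfiguration | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis; returns the report bundle (JSON-friendly dict)."""
    cfg = config or PipelineConfig()
    meshes = meshes or {}
    rec_by_id = {r.specimen_id: r for r in records}
    missing = [c.specimen_id for c in configs if c.specimen_id not in rec_by_id]
    if missing:
        raise ValueError(f"configurations without metadata: {missing[:5]}")

    report: dict = {"stages": {}}
    manifest = {"version": __version__, "seed": cfg.seed, "config": cfg.to_dict(),
                "n_specimens": len(configs), "stages": []}

    def record_stage(name: str, status: str, **info) -> None:
        manifest["stages"].append({"stage": name, "status": status, **info})

    template = template or (next((c for c in configs
                                  if c.specimen_id == cfg.template_id), None))

    # 1. surface patch projection (template -> specimens with meshes)
    if template is not None and meshes:
        projected = []
        for c in configs:
            mesh = meshes.get(c.specimen_id)
            if mesh is not None and c.specimen_id != template.specimen_id:
                projected.append(project_surface_patch(template, c, mesh))
            else:
                projected.append(c)
        configs = projected
        record_stage("project", "done", n=len(configs))
    else:
        record_stage("project", "skipped",
                     reason="no template/meshes; surface landmarks taken as digitized")

    # 2. relaxation against the template
    if template is not None and cfg.n_relax_iter > 0:
        configs = [
            relax_to_reference(c, template.coords, mesh=meshes.get(c.specimen_id),
                               n_iter=cfg.n_relax_iter,
                               clamp_fraction=cfg.clamp_fraction,
                               slide_curves=cfg.slide_curves)
            if c.specimen_id != template.specimen_id else c
            for c in configs
        ]
        record_stage("relax", "done", n_iter=cfg.n_relax_iter)
    else:
        record_stage("relax", "skipped", reason="no template")

    # 3. consensus sliding
    if cfg.n_slide_iter > 0 and template is not None:
        configs = slide_sample_to_consensus(
            configs, [meshes.get(c.specimen_id) for c in configs],
            n_iter=cfg.n_slide_iter, clamp_fraction=cfg.clamp_fraction,
            slide_curves=cfg.slide_curves)
        record_stage("consensus_slide", "done", n_iter=cfg.n_slide_iter)
    else:
        record_stage("consensus_slide", "skipped", reason="no template")

    # 4. delimitation removal
    n_before = configs[0].k
    configs = [strip_delimitation_curves(c) for c in configs]
    record_stage("strip_delimitation", "done",
                 removed=n_before - configs[0].k)

    # 5. GPA
    aligned = gpa_align(configs)
    report["stages"]["gpa"] = {
        "converged": aligned.converged, "iterations": aligned.iterations_used,
        "centroid_sizes": dict(zip(aligned.specimen_ids,
                                   aligned.centroid_sizes.tolist())),
    }
    record_stage("gpa", "done", converged=bool(aligned.converged))

    # 6. PCA + morphospace
    space = fit_pca(aligned)
    groups = {r.specimen_id: r.input_mode for r in records}
    report["stages"]["pca"] = {
        "variance_fractions": space.variance_fractions.tolist(),
        "scores": {sid: space.scores[i].tolist()
                   for i, sid in enumerate(space.specimen_ids)},
    }
    report["stages"]["morphospace"] = morphospace_report(space, groups)
    record_stage("pca", "done",
                 pc1=float(space.variance_fractions[0]),
                 pc2=float(space.variance_fractions[1]) if len(space.variance_fractions) > 1 else None)

    # 7. angles
    scheme = configs[0].scheme
    anat = scheme.anatomical_indices
    pairs = cfg.angle_pairs or {
        "head_rotation": ((int(anat[0]), int(anat[1])), (int(anat[2]), int(anat[3]))),
    }
    angle_rows = []
    for c in configs:
        for name, (a1, a2) in pairs.items():
            try:
                m = projected_axis_angle(c, a1, a2, angle_type=name)
                angle_rows.append({"specimen_id": c.specimen_id,
                                   "angle_type": name, "degrees": m.degrees})
            except ValueError as exc:
                log.warning("angle %s on %s failed: %s", name, c.specimen_id, exc)
    angles_df = pd.DataFrame(angle_rows)
    report["stages"]["angles"] = angle_rows
    if len(angle_rows):
        tests = {}
        for name in pairs:
            sub = angles_df[angles_df.angle_type == name]
            b = sub[sub.specimen_id.map(lambda s: groups.get(s) == "B")].degrees.values
            q = sub[sub.specimen_id.map(lambda s: groups.get(s) == "Q")].degrees.values
            if len(b) >= 2 and len(q) >= 2:
                try:
                    tests[name] = angle_group_test(b, q)
                except ValueError as exc:
                    tests[name] = {"error": str(exc)}
        report["stages"]["angle_tests"] = tests
    record_stage("angles", "done", n=len(angle_rows))

    # 8. allometry along the leading axes
    log_cs = np.log(aligned.centroid_sizes)
    glabels = np.array([groups.get(s, "I") for s in aligned.specimen_ids])
    allom = {}
    for ax in (0, cfg.classification_axis):
        fits = groupwise_allometry(space.scores[:, ax], log_cs, glabels)
        allom[f"PC{ax+1}"] = {g: dataclasses.asdict(r) for g, r in fits.items()}
    report["stages"]["allometry"] = allom
    record_stage("allometry", "done")

    # 9-11. comparative statistics (need a tree)
    if tree is not None:
        tips = aligned.specimen_ids
        ksig = kmult_test(aligned.residuals(), tree, tips,
                          n_perm=cfg.n_perm, seed=cfg.seed)
        k_pc = {}
        for ax in (0, cfg.classification_axis):
            r = kmult_test(space.scores[:, [ax]], tree, tips,
                           n_perm=cfg.n_perm, seed=cfg.seed + 1 + ax)
            k_pc[f"PC{ax+1}"] = {"k_mult": r.k_mult, "p": r.p_value}
        report["stages"]["kmult"] = {
            "global": {"k_mult": ksig.k_mult, "p": ksig.p_value},
            "per_axis": k_pc, "n_perm": cfg.n_perm,
        }
        record_stage("kmult", "done", k=ksig.k_mult)

        # indeterminate specimens enter the design with k-NN-estimated modes
        pgls_modes = list(glabels)
        indet = [i for i, g in enumerate(pgls_modes) if g == "I"]
        if indet:
            ax = cfg.classification_axis
            s_axis = {sid: float(space.scores[i, ax]) for i, sid in enumerate(tips)}
            kn = {tips[i]: pgls_modes[i] for i in range(len(tips))
                  if pgls_modes[i] in ("B", "Q")}
            if len(kn) >= cfg.k_neighbors:
                for p in knn_predict(s_axis, kn, [tips[i] for i in indet],
                                     k=cfg.k_neighbors):
                    pgls_modes[tips.index(p.specimen_id)] = p.predicted_mode
        if all(m in ("B", "Q") for m in pgls_modes) and len(set(pgls_modes)) > 1:
            pg = pgls_fit(aligned.residuals(), log_cs, pgls_modes, tree,
                          tips, n_perm=cfg.n_perm, seed=cfg.seed + 7)
            report["stages"]["pgls"] = {
                t.name: {"r_squared": t.r_squared, "F": t.f_statistic,
                         "p": t.p_value} for t in pg.terms}
            record_stage("pgls", "done")
        else:
            record_stage("pgls", "skipped",
                         reason="locomotor modes unavailable or single-class")

        anc = ancestral_continuous(space.scores[:, :2], tree, tips)
        report["stages"]["ancestral"] = {
            lab: anc["nodes"][i].tolist() for i, lab in enumerate(anc["node_ids"])}
        record_stage("ancestral", "done", n_nodes=len(anc["node_ids"]))
    else:
        for name in ("kmult", "pgls", "ancestral"):
            record_stage(name, "skipped", reason="no tree provided")
        log.info("no tree provided; comparative stages skipped")

    # 12. k-NN along the classification axis
    ax = cfg.classification_axis
    scores_axis = {sid: float(space.scores[i, ax])
                   for i, sid in enumerate(space.specimen_ids)}
    known = {sid: groups[sid] for sid in scores_axis if groups.get(sid) in ("B", "Q")}
    unknown = [sid for sid in scores_axis if sid not in known]
    knn_report: dict = {"axis": f"PC{ax+1}", "k": cfg.k_neighbors}
    if len(known) > cfg.k_neighbors:
        loo = loo_evaluate(scores_axis, known, k=cfg.k_neighbors, axis=f"PC{ax+1}")
        predictions = {p.specimen_id: p.predicted_mode for p in loo["predictions"]}
        if unknown:
            for p in knn_predict(scores_axis, known, unknown, k=cfg.k_neighbors,
                                 axis=f"PC{ax+1}"):
                predictions[p.specimen_id] = p.predicted_mode
        table = pd.DataFrame({
            "name": list(predictions),
            "input_mode": [groups.get(s, "I") for s in predictions],
            "predicted_mode": [predictions[s] for s in predictions],
        })
        knn_report.update({
            "predictions": predictions,
            "loo_success_rate_known": loo["success_rate_known"],
            "loo_success_rate_all": loo["success_rate_all"],
            "agreement": evaluate_against_inputs(table),
        })
        record_stage("knn", "done",
                     success=loo["success_rate_all" if cfg.denominator == "all"
                                 else "success_rate_known"])
    else:
        record_stage("knn", "skipped", reason="not enough known-mode specimens")
    report["stages"]["knn"] = knn_report

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    report["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        if len(angle_rows):
            angles_df.to_csv(out / "angles.csv", index=False)
        pd.DataFrame(report["stages"]["pca"]["scores"]).T.rename(
            columns=lambda i: f"PC{i+1}").to_csv(out / "scores.csv")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)
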