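"""One configured, seeded run: synth → descriptors → surface → PCA →
DCCM/network → hub scoring → state classifier.

All randomness flows from a single root seed expanded per stage, so a rerun
with the same configuration produces byte-identical tabular outputs.  Every
stage writes CSV/JSON under the output directory and records its parameters
in the run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, collective, descriptors, network, surface, synth
from .io import DomainMap, Ensemble, StructureModel, SystemManifest

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

_STAGES = ("descriptors", "surface", "pca", "network", "hubs", "classify")


class StageError(RuntimeError):
    """A pipeline stage failed or its dependencies were disabled."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    With no manifest path the synthetic study set defined by ``study`` is
    generated in place.  ``align=False`` is the right default for generated
    ensembles, which already share a reference frame; set it for raw
    trajectory input.
    """

    out_dir: str | Path = "allonet_run"
    seed: int = 0
    study: synth.StudyConfig | None = None
    manifest_path: str | Path | None = None
    domain_map_path: str | Path | None = None
    edge_threshold: float = 0.8
    interface_threshold: float = 1.0      # Å²
    pocket_radius: float = 5.0            # Å
    align: bool = False
    mixing_mode: str = "own_module"
    length_transform: str = "neglog"
    replicate_mode: str = "mean"          # or "concat"
    max_cluster_frames: int = 100
    consistency_thresholds: tuple = (0.70, 0.75, 0.80, 0.85, 0.90)
    run_consistency: bool = True
    n_top_connectors: int = 25
    rf_estimators: int = 1000
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES})

    def __post_init__(self) -> None:
        if not 0 < self.edge_threshold < 1:
            raise ValueError("edge_threshold outside (0, 1)")
        if self.interface_threshold < 0 or self.pocket_radius < 0:
            raise ValueError("thresholds must be non-negative")
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for s in _STAGES:
            self.stages.setdefault(s, True)


@dataclass
class PipelineResult:
    manifest: SystemManifest
    domain_map: DomainMap
    reference: StructureModel | None
    dccms: dict[str, network.CorrelationMatrix]
    partitions: dict[str, network.CommunityPartition]
    betweenness: dict[str, np.ndarray]
    interfaces: dict[str, surface.InterfaceSet]
    hub_table: pd.DataFrame | None
    classifier_report: dict | None
    similarity: pd.DataFrame | None
    out_dir: Path
    log: dict


def _frame_structure(ens: Ensemble, idx: int) -> StructureModel:
    n = ens.n_residues
    return StructureModel(
        coords=ens.coords[idx],
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        res_id=ens.res_ids,
        res_name=np.full(n, "ALA"),
        chain_id=np.full(n, "A"),
        source=f"{ens.system} frame {idx}",
    )


def _concat(reps: list[Ensemble]) -> Ensemble:
    coords = np.concatenate([e.coords for e in reps], axis=0)
    return Ensemble(coords, reps[0].res_ids, reps[0].system)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every enabled stage and write its outputs.

    Raises :class:`StageError` with a stage-tagged message on failure;
    outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # ---- inputs -----------------------------------------------------------
    reference = None
    if config.manifest_path is not None:
        from .io import load_domain_map, load_manifest, read_ensemble
        manifest = load_manifest(config.manifest_path)
        if config.domain_map_path is None:
            raise StageError("input: a domain map path is required with a manifest")
        domain_map = load_domain_map(config.domain_map_path)
        ensembles = {
            name: [read_ensemble(p) for p in ent.ensembles]
            for name, ent in manifest.entries.items()
        }
    else:
        study = config.study or synth.StudyConfig()
        manifest, ensembles, reference = synth.generate_study_set(
            study, seed=config.seed)
        domain_map = study.domain_map
        log["stages"]["synth"] = {
            "systems": manifest.systems, "n_replicates": study.n_replicates,
            "n_frames": study.n_frames, "hub_residues": list(study.hub_residues),
            "rho": [study.rho_intra, study.rho_baseline,
                    study.rho_hub_active, study.rho_hub_inactive],
        }
    manifest.require_both_classes()
    systems = manifest.systems
    res_ids = next(iter(ensembles.values()))[0].res_ids
    regions = domain_map.labels_for(res_ids)

    medoids: dict[str, StructureModel] = {}
    interfaces: dict[str, surface.InterfaceSet] = {}
    dccms: dict[str, network.CorrelationMatrix] = {}
    partitions: dict[str, network.CommunityPartition] = {}
    B: dict[str, np.ndarray] = {}
    similarity = None
    hub_table = None
    clf_report = None

    # ---- descriptors ------------------------------------------------------
    if config.stages["descriptors"]:
        try:
            rows = []
            for name in systems:
                reps = ensembles[name]
                profs = [descriptors.rmsf_profile(e) for e in reps]
                rmsf = np.mean([p.rmsf for p in profs], axis=0)
                pd.DataFrame({"residue_id": res_ids, "region": regions,
                              "rmsf": rmsf}).to_csv(
                    out / f"rmsf_{name}.csv", index=False, float_format="%.6f")
                ref_coords = (reference.ca_only().coords if reference is not None
                              else reps[0].coords.mean(axis=0))
                series = descriptors.rmsd_series(reps[0], ref_coords)
                pd.DataFrame({"frame": np.arange(len(series.values)),
                              "rmsd": series.values}).to_csv(
                    out / f"rmsd_{name}.csv", index=False, float_format="%.6f")
                cat = _concat(reps)
                rep_res = descriptors.representative_structure(
                    cat, max_frames=config.max_cluster_frames)
                medoids[name] = _frame_structure(cat, rep_res.frame_index)
                rows.append({"system": name, "label": manifest.entries[name].label,
                             "mean_rmsf": float(rmsf.mean()),
                             "mean_rmsd": float(series.values.mean()),
                             "medoid_frame": rep_res.frame_index,
                             "k_clusters": rep_res.k,
                             "silhouette": rep_res.silhouette})
            pd.DataFrame(rows).to_csv(out / "descriptor_summary.csv",
                                      index=False, float_format="%.6f")
            log["stages"]["descriptors"] = {"systems": systems}
        except Exception as exc:
            raise StageError(f"descriptors: {exc}") from exc

    # ---- surface / interfaces --------------------------------------------
    if config.stages["surface"]:
        try:
            recs = []
            for name in systems:
                if name in medoids:
                    struct = medoids[name]
                else:   # descriptors disabled: use the first frame
                    struct = _frame_structure(ensembles[name][0], 0)
                iface = surface.interdomain_interfaces(
                    struct, domain_map, threshold=config.interface_threshold)
                interfaces[name] = iface
                for rid in sorted(iface.residues):
                    recs.append({"system": name, "residue_id": rid,
                                 "delta_sasa": iface.delta_sasa[rid]})
            pd.DataFrame(recs, columns=["system", "residue_id", "delta_sasa"]
                         ).to_csv(out / "interface_residues.csv",
                                  index=False, float_format="%.4f")
            log["stages"]["surface"] = {
                "threshold": config.interface_threshold,
                "counts": {n: len(interfaces[n].residues) for n in systems}}
        except Exception as exc:
            raise StageError(f"surface: {exc}") from exc

    # ---- PCA --------------------------------------------------------------
    if config.stages["pca"]:
        try:
            pca_out = {}
            for name in systems:
                cat = _concat(ensembles[name])
                pca = collective.covariance_and_modes(cat, align=config.align)
                pca_out[name] = {
                    "eigenvalues": pca.eigenvalues[:10].tolist(),
                    "fractions": pca.fractions[:10].tolist(),
                    "trace": pca.trace,
                }
            with open(out / "pca_summary.json", "w") as fh:
                json.dump(pca_out, fh, indent=1)
            log["stages"]["pca"] = {"align": config.align}
        except Exception as exc:
            raise StageError(f"pca: {exc}") from exc

    # ---- network ----------------------------------------------------------
    if config.stages["network"]:
        try:
            part_rows = []
            for idx, name in enumerate(systems):
                reps = ensembles[name]
                if config.replicate_mode == "concat":
                    mat = network.dccm(_concat(reps), align=config.align)
                else:
                    mat = network.average_dccm(
                        [network.dccm(e, align=config.align) for e in reps])
                mat.system = name
                dccms[name] = mat
                g = network.build_graph(mat, threshold=config.edge_threshold,
                                        length=config.length_transform)
                network.export_graphml(g, out / f"network_{name}.graphml")
                part = network.detect_communities(
                    g, domain_map, seed=config.seed + 1000 + idx)
                partitions[name] = part
                B[name] = network.betweenness(g).values
                for pos, mid in sorted(part.module_of.items()):
                    part_rows.append({
                        "system": name, "residue_id": int(res_ids[pos]),
                        "module": mid, "purity": part.purity[mid],
                        "dominant_region": part.dominant_region[mid],
                        "is_integration": mid == part.integration_module,
                    })
            pd.DataFrame(part_rows).to_csv(out / "communities.csv",
                                           index=False, float_format="%.6f")
            sim = np.eye(len(systems))
            for i in range(len(systems)):
                for j in range(i + 1, len(systems)):
                    r, _ = network.dccm_similarity(dccms[systems[i]],
                                                   dccms[systems[j]])
                    sim[i, j] = sim[j, i] = r
            similarity = pd.DataFrame(sim, index=systems, columns=systems)
            similarity.to_csv(out / "dccm_similarity.csv", float_format="%.6f")
            bdf = pd.DataFrame({"residue_id": res_ids, "region": regions})
            for name in systems:
                bdf[name] = B[name]
            bdf.to_csv(out / "betweenness.csv", index=False, float_format="%.8f")
            log["stages"]["network"] = {
                "threshold": config.edge_threshold,
                "length": config.length_transform,
                "modularity": {n: partitions[n].modularity for n in systems},
            }
        except Exception as exc:
            raise StageError(f"network: {exc}") from exc

    # ---- hubs --------------------------------------------------------------
    if config.stages["hubs"]:
        if not config.stages["network"]:
            raise StageError("hubs: requires the network stage to be enabled")
        if not config.stages["surface"]:
            raise StageError("hubs: requires the surface stage to be enabled")
        try:
            from .hubs import hub_score_table
            Bmat = np.column_stack([B[n] for n in systems])
            consistency = None
            if config.run_consistency:
                consistency = {}
                counts = {int(r): 0.0 for r in res_ids}
                for idx, name in enumerate(systems):
                    cons = network.threshold_consistency(
                        dccms[name], domain_map,
                        thresholds=config.consistency_thresholds,
                        n=config.n_top_connectors,
                        seed=config.seed + 2000 + idx)
                    for r, v in cons.items():
                        counts[r] += v / len(systems)
                consistency = counts
            hub_table = hub_score_table(
                Bmat, manifest.y,
                [partitions[n] for n in systems],
                [interfaces[n].residues for n in systems],
                res_ids, regions=regions, consistency=consistency,
                mixing_mode=config.mixing_mode)
            hub_table.to_csv(out / "hub_scores.csv", index=False,
                             float_format="%.6f")
            log["stages"]["hubs"] = {
                "mixing_mode": config.mixing_mode,
                "n_hubs": int(hub_table["is_hub"].sum()),
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"hubs: {exc}") from exc

    # ---- classifier --------------------------------------------------------
    if config.stages["classify"]:
        try:
            spec = classify.default_feature_spec(domain_map)
            table = classify.assemble_features(ensembles, manifest, spec,
                                               domain_map=domain_map)
            fitted = classify.train_classifier(
                table, seed=config.seed + 3000,
                n_estimators=config.rf_estimators)
            clf_report = fitted.report.to_dict()
            perm = classify.feature_importance(
                fitted, "permutation", seed=config.seed + 3001)
            clf_report["permutation_importance"] = {
                row.feature: [row.importance, row.sd]
                for row in perm.itertuples()}
            with open(out / "classifier_report.json", "w") as fh:
                json.dump(clf_report, fh, indent=1)
            log["stages"]["classify"] = {
                "n_frames": int(len(table)),
                "auc": clf_report["auc"],
                "accuracy": clf_report["accuracy"]}
        except Exception as exc:
            raise StageError(f"classify: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return PipelineResult(
        manifest=manifest, domain_map=domain_map, reference=reference,
        dccms=dccms, partitions=partitions, betweenness=B,
        interfaces=interfaces, hub_table=hub_table,
        classifier_report=clf_report, similarity=similarity,
        out_dir=out, log=log,
    )
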