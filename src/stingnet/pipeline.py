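"""End-to-end analysis pipeline.

Runs simulation, local sensitivity + PCA scoring, flux ranking, model
reduction, network construction with centralities and hub frequencies, and
crosstalk scoring on one model, writing every artifact as a data file plus
a single JSON manifest of headline numbers.  Given the same model, seed and
options the outputs are reproducible byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .core import ReactionModel, validate_model
from .crosstalk import annotation_to_frame, crosstalk_points, crosstalk_scores
from .flux import compute_fluxes, top_reactions
from .network import centrality_table, hub_frequency, model_to_network, topology_summary
from .nsclc import build_nsclc_model
from .pca import run_pca, select_key_species
from .reduction import ReductionCriteria, reduce_model
from .sensitivity import aggregate, local_sensitivities
from .simulate import simulate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    model: Optional[ReactionModel] = None  # default: curated NSCLC model
    out_dir: str = "stingnet_results"
    t_end: float = 100.0
    seed: int = 0
    flux_min: float = 500.0
    pca_band: tuple = (0.8, 1.2)
    top_k: int = 20
    epc_realizations: int = 1000
    sensitivity_inputs: str = "parameters"


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every analysis stage and return the manifest dict."""
    model = config.model or build_nsclc_model()
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ValueError(f"model does not validate: {[str(e) for e in errors]}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model.species_table().to_csv(out / "species.csv", index=False)
    model.reaction_table().to_csv(out / "reactions.csv", index=False)

    # simulation ------------------------------------------------------------
    traj = simulate(model, t_end=config.t_end)
    traj.to_frame().to_csv(out / "trajectory_wide.csv", index=False)
    traj.to_tidy().to_csv(out / "trajectory_tidy.csv", index=False)

    # sensitivity + PCA ------------------------------------------------------
    tensor = local_sensitivities(
        model, t_end=config.t_end, inputs=config.sensitivity_inputs
    )
    score = aggregate(tensor)
    score.to_frame().to_csv(out / "sensitivity_scores.csv")
    pca = run_pca(score)
    pca.scores_frame().to_csv(out / "pca_scores.csv")
    selected = select_key_species(pca, *config.pca_band)
    (out / "pca_selection.json").write_text(json.dumps(selected, indent=1))

    # flux -------------------------------------------------------------------
    flux = compute_fluxes(model, traj)
    flux.to_csv(out / "flux_table.csv")
    top = top_reactions(flux, min_flux=config.flux_min)
    top.to_csv(out / "flux_top.csv")

    # reduction ---------------------------------------------------------------
    red = reduce_model(
        model, ReductionCriteria(flux_min=config.flux_min),
        trajectory=traj, score_matrix=score, flux_table=flux,
    )
    red.landscape.to_csv(out / "quasi_potential_landscape.csv", index=False)
    (out / "reduction.json").write_text(
        json.dumps(
            {
                "retained": red.retained_reactions,
                "removed": red.removed_reactions,
                "reduction_percent": red.reduction_percent_rounded,
            },
            indent=1,
        )
    )

    # network -----------------------------------------------------------------
    net = model_to_network(model)
    net.to_edgelist().to_csv(out / "network_edges.csv", index=False)
    net.write_graphml(out / "network.graphml")
    summary = topology_summary(net)
    ctable = centrality_table(
        net, n_realizations=config.epc_realizations, seed=config.seed
    )
    ctable.to_csv(out / "centralities.csv")
    hubs = hub_frequency(ctable, k=config.top_k)
    (out / "hub_report.json").write_text(
        json.dumps(
            {
                "k": hubs.k,
                "frequency": dict(hubs.ranked()),
                "max_frequency_nodes": hubs.max_frequency_nodes(),
            },
            indent=1,
        )
    )

    # crosstalk ----------------------------------------------------------------
    manifest: Dict = {}
    if model.pathway_tags:
        scores = crosstalk_scores(net, model.pathway_tags)
        pd.Series(scores, name="crosstalk_score").rename_axis("node").to_csv(
            out / "crosstalk_scores.csv"
        )
        annotation_to_frame(model.pathway_tags).to_csv(
            out / "pathway_annotation.csv", index=False
        )
        points = crosstalk_points(net, model.pathway_tags)
        manifest["crosstalk_points"] = len(points)
        manifest["crosstalk_point_nodes"] = sorted(points)

    manifest.update(
        {
            "model": model.name,
            "compartments": model.n_compartments,
            "species": model.n_species,
            "boundary_species": model.n_boundary_species,
            "reactions": model.n_reactions,
            "t_end_s": config.t_end,
            "top_flux_count": len(top),
            "reduction_percent": red.reduction_percent_rounded,
            "retained_reactions": len(red.retained_reactions),
            "pca_selected": len(selected),
            "network_nodes": summary.n_nodes,
            "network_edges": summary.n_edges,
            "network_radius": summary.radius,
            "network_diameter": summary.diameter,
            "network_avg_clustering": round(summary.avg_clustering, 3),
            "network_avg_degree": round(summary.avg_degree, 3),
            "seed": config.seed,
        }
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
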