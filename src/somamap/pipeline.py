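"""End-to-end orchestration: generate/load → prune → morphology → connectivity
→ cosine clustering → partner graph → laterality → consolidated JSON report.

The cosine analysis runs in two passes by default: all types except the
configured large sparse type at the main per-edge threshold, and that type
alone at the low threshold (a joint single pass is available via config).
"""

from __future__ import annotations

import glob
import json
import logging
import os

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import connectivity as conn
from . import cosine_cluster as cc
from . import laterality as lat
from . import morphology as morph
from . import partner_graph as pg
from . import synthetic as syn
from .config import PipelineConfig
from .errors import EmptyResultError, SomamapError
from .skeletons import RegionBox, Skeleton, prune_to_region, read_swc, resample, write_swc

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "evaluate_recovery", "generate_inputs", "load_inputs"]


def generate_inputs(config: PipelineConfig, out_dir: str) -> None:
    """Write a full synthetic input set (SWC, synapses, annotations, truth)."""
    os.makedirs(out_dir, exist_ok=True)
    overrides = dict(config.synthetic)
    roster = overrides.pop("roster", None)
    if roster is not None:
        types = [syn.TypeSpec(**t) for t in roster]
    else:
        types = syn.default_roster(int(overrides.pop("inom_n", 60)))
    layout_kwargs = {
        k: overrides.pop(k)
        for k in ("zone_scale", "zone_offset", "bristle_spread", "n_neighbors")
        if k in overrides
    }
    skel_kwargs = {
        k: overrides.pop(k)
        for k in ("jitter", "n_points", "axon_nodes", "contra_points", "contra_x")
        if k in overrides
    }
    syn_kwargs = {
        k: overrides.pop(k)
        for k in ("p_same", "p_neighbor", "p_distant", "mean_syn",
                  "cleft_params", "p_bmn")
        if k in overrides
    }
    if "cleft_params" in syn_kwargs:
        syn_kwargs["cleft_params"] = tuple(syn_kwargs["cleft_params"])
    # default run uses a higher per-edge synapse count so the main-pass
    # per-edge threshold (7) thins edges without erasing block structure
    syn_kwargs.setdefault("mean_syn", 9.0)
    if overrides:
        logger.warning("unused synthetic overrides: %s", sorted(overrides))

    layout = syn.generate_layout(types, seed=config.seed, **layout_kwargs)
    skeletons, truth = syn.generate_skeletons(
        layout, seed=config.seed, midline_x=config.midline_x, **skel_kwargs
    )
    table, truth = syn.generate_synapses(
        layout, skeletons, seed=config.seed, truth=truth, **syn_kwargs
    )

    swc_dir = os.path.join(out_dir, "swc")
    os.makedirs(swc_dir, exist_ok=True)
    for sk in skeletons:
        write_swc(sk, os.path.join(swc_dir, f"{sk.neuron_id}.swc"))
    conn.write_synapse_table(table, os.path.join(out_dir, "synapses.csv"))
    layout.annotations().write_csv(os.path.join(out_dir, "annotations.csv"))
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    config.to_yaml(os.path.join(out_dir, "params.yaml"))


def load_inputs(input_dir: str, units_scale: float = 1.0
                ) -> tuple[list[Skeleton], pd.DataFrame, conn.AnnotationTable,
                           syn.GroundTruth | None]:
    swc_dir = os.path.join(input_dir, "swc")
    paths = sorted(glob.glob(os.path.join(swc_dir, "*.swc")))
    if not paths:
        paths = sorted(glob.glob(os.path.join(input_dir, "*.swc")))
    if not paths:
        raise SomamapError(f"no SWC files under {input_dir}")
    skeletons = [read_swc(p, units_scale=units_scale) for p in paths]
    table = conn.read_synapse_table(os.path.join(input_dir, "synapses.csv"))
    ann = conn.AnnotationTable.read_csv(os.path.join(input_dir, "annotations.csv"))
    gt_path = os.path.join(input_dir, "ground_truth.json")
    truth = syn.GroundTruth.from_json(gt_path) if os.path.exists(gt_path) else None
    return skeletons, table, ann, truth


def _prune_to_own_synapses(skeletons: list[Skeleton], table: pd.DataFrame,
                           config: PipelineConfig) -> list[Skeleton]:
    """Prune each skeleton to the padded bounding box of its own synapse
    positions (pre- or postsynaptic rows); neurons without synapses pass
    through unpruned."""
    out = []
    for sk in skeletons:
        mask = (table["pre_id"] == sk.neuron_id) | (table["post_id"] == sk.neuron_id)
        pts = table.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)
        if len(pts) == 0:
            logger.info("neuron %s: no synapses; skipped pruning", sk.neuron_id)
            out.append(sk)
            continue
        box = RegionBox.from_points(pts, pad=config.prune_pad_um)
        try:
            out.append(prune_to_region(sk, box, keep=config.prune_keep))
        except EmptyResultError:
            logger.warning("neuron %s: empty after pruning; kept unpruned",
                           sk.neuron_id)
            out.append(sk)
    return out


def _cosine_pass(edges: dict, ann: conn.AnnotationTable, focal_types: list[str],
                 edge_min: int, cut_k: int | None, cut_height: float | None,
                 threshold_mode: str, min_fraction: float) -> dict:
    """One cosine clustering pass; returns a JSON-ready summary."""
    profile = cc.build_profiles(edges, ann, focal_types, edge_min=edge_min,
                                threshold_mode=threshold_mode)
    result: dict = {
        "focal_types": sorted(focal_types),
        "edge_min": edge_min,
        "threshold_mode": threshold_mode,
        "n_rows": len(profile.focal_ids),
        "n_partners": len(profile.partner_ids),
        "excluded": sorted(profile.excluded),
        "labels": {},
    }
    if len(profile.focal_ids) < 2:
        result["skipped"] = "fewer than 2 non-excluded rows"
        return result
    sim = cc.cosine_matrix(profile)
    if cut_k is not None:
        cut_k = min(cut_k, len(profile.focal_ids))
    elif cut_height is None:
        cut_k = min(len(focal_types), len(profile.focal_ids))
    clustered = cc.cluster_connectivity(sim, height=cut_height, k=cut_k)
    result["labels"] = clustered.labels
    report = cc.composition(clustered.labels, ann, min_fraction=min_fraction)
    result["composition_by_type"] = report.by_type.to_dict(orient="records")
    result["composition_by_cluster"] = report.by_cluster.to_dict(orient="records")
    return result


def run_pipeline(config: PipelineConfig, input_dir: str | None,
                 output_dir: str, synthetic: bool = False) -> dict:
    """Run every stage and write artifacts plus ``report.json``."""
    os.makedirs(output_dir, exist_ok=True)
    if synthetic:
        input_dir = os.path.join(output_dir, "inputs")
        generate_inputs(config, input_dir)
    if input_dir is None:
        raise SomamapError("input_dir required unless synthetic=True")

    skeletons, table, ann, truth = load_inputs(input_dir, config.units_scale)
    report: dict = {"config": config.to_dict(), "stages": {}}
    report["stages"]["inputs"] = {
        "n_neurons": len(skeletons), "n_synapse_rows": int(len(table)),
        "n_types": len(ann.types),
    }

    # --- synapse filtering -------------------------------------------------
    filtered = conn.filter_synapses(table, config.cleft_min)
    report["stages"]["cleft_filter"] = {
        "cleft_min": config.cleft_min,
        "rows_before": int(len(table)), "rows_after": int(len(filtered)),
    }

    # --- skeleton pruning + morphology ------------------------------------
    pruned = (_prune_to_own_synapses(skeletons, filtered, config)
              if config.prune_enabled else skeletons)
    if config.resample_step_um:
        pruned = [resample(sk, config.resample_step_um) for sk in pruned]
    dotprops = [morph.make_dotprops(sk, k=config.dotprops_k) for sk in pruned]

    def score_fn(d, dp):
        return morph.default_score_fn(d, dp, sigma=config.sigma_um)

    sim = morph.nblast_matrix(dotprops, score_fn)
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        os.path.join(output_dir, "morphology_similarity.csv")
    )
    tree = morph.ward_cluster(sim)
    cut_k = config.morphology_cut_k
    if cut_k is None and config.morphology_cut_height is None:
        cut_k = min(len(ann.types), len(sim.ids))
    morph_labels = morph.cut_clusters(
        tree, height=config.morphology_cut_height, k=cut_k
    )
    with open(os.path.join(output_dir, "morphology_dendrogram.nwk"), "w") as fh:
        fh.write(morph.to_newick(tree) + "\n")
    report["stages"]["morphology"] = {
        "n_clusters": len(set(morph_labels.values())),
        "labels": morph_labels,
    }

    # --- connectivity ------------------------------------------------------
    counts = conn.connection_counts(filtered, ann.neuron_ids)
    counts.to_csv(os.path.join(output_dir, "connection_counts.csv"))
    edges = conn.aggregate_edges(filtered)
    type_matrix = conn.type_connectivity(
        {e: w for e, w in edges.items() if e[0] in ann and e[1] in ann}, ann
    )
    type_matrix.to_csv(os.path.join(output_dir, "type_connectivity.csv"))
    report["stages"]["connectivity"] = {
        "n_edges": len(edges),
        "total_synapses": int(sum(edges.values())),
        "connection_counts": {
            i: [int(r.pre_count), int(r.post_count)]
            for i, r in counts.iterrows()
        },
    }

    # --- cosine clustering (two passes by default) -------------------------
    all_types = ann.types
    if config.joint or config.large_type not in all_types:
        passes = {
            "joint": (_cosine_pass(
                edges, ann, all_types, config.edge_min_low,
                config.connectivity_cut_k, config.connectivity_cut_height,
                config.threshold_mode, config.composition_min_fraction))
        }
    else:
        main_types = [t for t in all_types if t != config.large_type]
        passes = {
            "main": _cosine_pass(
                edges, ann, main_types, config.edge_min_main,
                config.connectivity_cut_k, config.connectivity_cut_height,
                config.threshold_mode, config.composition_min_fraction),
            "low": _cosine_pass(
                edges, ann, [config.large_type], config.edge_min_low,
                config.low_pass_cut_k, None,
                config.threshold_mode, config.composition_min_fraction),
        }
    report["stages"]["cosine"] = passes

    # --- partner graph -----------------------------------------------------
    assignment = pg.assign_partners(edges, ann)
    graph = pg.build_graph(edges, assignment, ann,
                           fraction_min=config.fraction_min)
    graph.edges.to_csv(os.path.join(output_dir, "partner_graph.csv"), index=False)
    report["stages"]["partner_graph"] = {
        "n_partners_assigned": len(assignment.assigned),
        "n_ties": len(assignment.ties),
        "assignment": dict(sorted(assignment.assigned.items())),
        "edges": graph.edges.to_dict(orient="records"),
        "type_totals": dict(sorted(graph.type_totals.items())),
        "fraction_min": config.fraction_min,
    }

    # --- laterality (on full skeletons, before pruning) --------------------
    lat_report = lat.percent_crossing(skeletons, ann, midline_x=config.midline_x)
    lat_report.per_neuron.to_csv(
        os.path.join(output_dir, "laterality.csv"), index=False
    )
    report["stages"]["laterality"] = {
        "per_type": lat_report.per_type.to_dict(orient="records"),
        "per_neuron": {
            r.neuron_id: bool(r.crossing)
            for r in lat_report.per_neuron.itertuples(index=False)
        },
    }

    # --- ground-truth recovery ---------------------------------------------
    if truth is not None:
        report["recovery"] = evaluate_recovery(report, truth)

    with open(os.path.join(output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _safe_ari(truth_labels: list, pred_labels: list) -> float | None:
    if len(set(truth_labels)) < 2 or len(truth_labels) < 2:
        return None
    return float(adjusted_rand_score(truth_labels, pred_labels))


def evaluate_recovery(report: dict, truth: syn.GroundTruth) -> dict:
    """Compare pipeline outputs against generation ground truth.

    Returns ARI of morphology and connectivity clusterings vs true types,
    partner-assignment accuracy vs partner ownership, and laterality
    accuracy vs construction flags.
    """
    out: dict = {}

    morph_labels = report["stages"]["morphology"]["labels"]
    ids = sorted(morph_labels)
    missing = [i for i in ids if i not in truth.neurons]
    if missing:
        raise SomamapError(f"neurons missing from ground truth: {missing[:10]}")
    out["morphology_ari"] = _safe_ari(
        truth.type_labels(ids), [morph_labels[i] for i in ids]
    )

    cos = report["stages"]["cosine"]
    key = "main" if "main" in cos else "joint"
    labels = cos[key]["labels"]
    ids = sorted(labels)
    out["connectivity_ari"] = (
        _safe_ari(truth.type_labels(ids), [labels[i] for i in ids])
        if ids else None
    )

    assignment = report["stages"]["partner_graph"]["assignment"]
    known = {p: t for p, t in assignment.items() if p in truth.partners}
    out["partner_accuracy"] = (
        sum(truth.partners[p] == t for p, t in known.items()) / len(known)
        if known else None
    )

    flags = report["stages"]["laterality"]["per_neuron"]
    common = [i for i in flags if i in truth.neurons]
    out["laterality_accuracy"] = (
        sum(bool(flags[i]) == bool(truth.neurons[i]["crossing"]) for i in common)
        / len(common) if common else None
    )
    return out
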