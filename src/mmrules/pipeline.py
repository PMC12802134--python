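"""End-to-end wiring: files -> tables -> geometry -> fit -> rules.

`prepare_inputs` turns raw tables plus distance sources (tree / ID table /
precomputed matrices) into model-ready objects; `run` executes the whole
pipeline from a :class:`RunConfig` and writes its artifacts (held-out
prediction table, rule text and JSON, loss trace, config snapshot, log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, Embedding, FeatureTable, LogNormalPrior, SubjectLabels
from .fit import (
    CVResult,
    FitConfig,
    build_model_data,
    cross_validate,
    multi_seed_fit,
)
from .geometry import (
    calibrate_radius_prior,
    patristic_distances,
    pcoa,
    rescale_embedding,
    select_dims_metab,
    select_dims_taxa,
)
from .model import HyperParams, RuleNetwork
from .report import export_rules, extract_rules, render_rules
from .tables import (
    align_inputs,
    filter_metabolites,
    filter_taxa,
    read_labels,
    read_table,
    to_relative_abundance,
    transform_metabolites,
)

logger = logging.getLogger("mmrules")

__all__ = ["RunConfig", "PreparedInputs", "prepare_inputs", "prepare_synthetic", "run"]


@dataclass
class RunConfig:
    """Paths plus every knob of a full run (library defaults)."""

    taxa_path: str
    metab_path: str
    labels_path: str
    tree_path: str | None = None
    taxa_distance_path: str | None = None
    metab_ids_path: str | None = None
    metab_distance_path: str | None = None
    metab_distance_is_similarity: bool = False
    subclass_path: str | None = None  # feature_id,subclass CSV
    family_path: str | None = None  # feature_id,family CSV
    fingerprint: str = "cactvs"
    cache_path: str | None = None
    min_taxa_count: float = 10
    min_taxa_frac: float = 0.10
    min_metab_presence: float = 0.15
    hyper: HyperParams = field(default_factory=HyperParams)
    fit: FitConfig = field(default_factory=FitConfig)
    do_cv: bool = False
    out_dir: str = "mmrules_out"
    seed: int = 0
    case_label: str = "case"


@dataclass
class PreparedInputs:
    taxa_rel: FeatureTable
    metab_raw: FeatureTable  # filtered, raw levels
    labels: SubjectLabels
    emb_T: Embedding
    emb_M: Embedding
    prior_T: LogNormalPrior
    prior_M: LogNormalPrior


def _two_col_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _default_groups(emb: Embedding, n_groups: int) -> dict[str, str]:
    """Fallback grouping when no taxonomy table is supplied: complete-linkage
    clusters of the embedded coordinates."""
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(emb.coords, method="complete")
    labels = fcluster(Z, t=max(n_groups, 2), criterion="maxclust")
    return {lab: f"group_{c}" for lab, c in zip(emb.labels, labels)}


def _build_geometry(
    D: DistanceMatrix,
    modality: str,
    groups: dict[str, str] | None,
) -> tuple[Embedding, LogNormalPrior]:
    dims = select_dims_taxa(D) if modality == "taxa" else select_dims_metab(D)
    emb = rescale_embedding(pcoa(D, dims))
    emb.modality = modality
    if groups is None:
        groups = _default_groups(emb, max(3, emb.n // 10))
    prior = calibrate_radius_prior(emb, groups)
    return emb, prior


def prepare_inputs(config: RunConfig) -> PreparedInputs:
    """Read, filter, align and embed everything the model needs."""
    labels = read_labels(config.labels_path)
    taxa = read_table(config.taxa_path, "taxa", labels)
    metab = read_table(config.metab_path, "metabolite", labels)
    taxa, metab, labels = align_inputs(taxa, metab, labels)
    taxa = filter_taxa(taxa, config.min_taxa_count, config.min_taxa_frac)
    rowsums = taxa.matrix.sum(axis=1)
    if np.allclose(rowsums, 1.0, atol=1e-6):
        taxa_rel = FeatureTable(taxa.values, "taxa", "relative_abundance")
    else:
        taxa_rel = to_relative_abundance(taxa)
    metab = filter_metabolites(metab, config.min_metab_presence)

    # taxa distances: tree or precomputed table
    if config.taxa_distance_path:
        from .chem import read_distance_table

        D_T = read_distance_table(config.taxa_distance_path).subset(
            [f for f in taxa_rel.feature_ids]
        )
    elif config.tree_path:
        D_T = patristic_distances(config.tree_path, taxa_rel.feature_ids)
        kept = [f for f in taxa_rel.feature_ids if f in D_T.labels]
        taxa_rel = FeatureTable(
            taxa_rel.values[kept], "taxa", taxa_rel.transform_state
        )
    else:
        raise ValueError("either tree_path or taxa_distance_path is required")

    # metabolite distances: precomputed table or fingerprints from IDs
    if config.metab_distance_path:
        from .chem import read_distance_table

        D_M = read_distance_table(
            config.metab_distance_path,
            similarities=config.metab_distance_is_similarity,
        )
    elif config.metab_ids_path:
        from .chem import StructureCache, build_metabolite_distances, read_metabolite_ids

        ids = read_metabolite_ids(config.metab_ids_path)
        cache = StructureCache(config.cache_path) if config.cache_path else None
        D_M, _ = build_metabolite_distances(ids, config.fingerprint, cache)
    else:
        raise ValueError("either metab_ids_path or metab_distance_path is required")
    keep_M = [f for f in metab.feature_ids if f in set(D_M.labels)]
    dropped = set(metab.feature_ids) - set(keep_M)
    if dropped:
        logger.warning("metabolites without distances dropped: %s", sorted(dropped))
    metab = FeatureTable(metab.values[keep_M], "metabolite", metab.transform_state)
    D_M = D_M.subset(keep_M)

    groups_T = _two_col_map(config.family_path) if config.family_path else None
    groups_M = _two_col_map(config.subclass_path) if config.subclass_path else None
    emb_T, prior_T = _build_geometry(D_T.subset(taxa_rel.feature_ids), "taxa", groups_T)
    emb_M, prior_M = _build_geometry(D_M, "metabolite", groups_M)
    return PreparedInputs(taxa_rel, metab, labels, emb_T, emb_M, prior_T, prior_M)


def prepare_synthetic(ds) -> PreparedInputs:
    """Model-ready inputs from a :class:`~mmrules.simulate.SyntheticDataset`,
    using the fabricated tree, chemical distances and grouping labels."""
    taxa = filter_taxa(ds.taxa)
    taxa_rel = to_relative_abundance(taxa)
    metab = filter_metabolites(ds.metab)
    D_T = patristic_distances(ds.baseline.tree, taxa_rel.feature_ids)
    D_M = ds.baseline.metab_dist.subset(metab.feature_ids)
    emb_T, prior_T = _build_geometry(D_T, "taxa", ds.baseline.taxa_families)
    emb_M, prior_M = _build_geometry(D_M, "metabolite", ds.baseline.metab_subclasses)
    return PreparedInputs(taxa_rel, metab, ds.labels, emb_T, emb_M, prior_T, prior_M)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Artifacts: predictions.csv, rules.txt, rules.json, loss_trace.csv,
    config.json, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("preparing inputs")
        prep = prepare_inputs(config)
        metab_std = transform_metabolites(prep.metab_raw)
        data = build_model_data(
            prep.taxa_rel, metab_std, prep.emb_T, prep.emb_M, prep.labels,
            prep.prior_T, prep.prior_M,
        )
        net = RuleNetwork(data, config.hyper)
        logger.info("fitting (%d seeds x %d epochs)", config.fit.seeds,
                    config.fit.epochs)
        res = multi_seed_fit(net, config.fit, base_seed=config.seed)
        p_train = net.predict_proba(res.params, res.final_temps, hard=res.hard)
        if config.do_cv:
            cv = cross_validate(
                prep.taxa_rel, prep.metab_raw, prep.emb_T, prep.emb_M,
                prep.labels, prep.prior_T, prep.prior_M, config.hyper,
                config.fit, base_seed=config.seed,
                fold_seed=config.seed * 7919 + 12345,
            )
            preds = cv.predictions
            logger.info("cross-validated AUC (pooled): %.3f", cv.pooled_auc)
        else:
            preds = pd.DataFrame({
                "subject_id": prep.labels.subject_ids,
                "fold": -1,
                "p_case": p_train,
                "label": prep.labels.array,
            })
        preds.to_csv(out / "predictions.csv", index=False)
        rules = extract_rules(res, data, config.hyper)
        (out / "rules.txt").write_text(
            render_rules(rules, config.case_label) + "\n"
        )
        export_rules(rules, str(out / "rules.json"))
        pd.DataFrame({"epoch": np.arange(len(res.loss_trace)),
                      "loss": res.loss_trace}).to_csv(
            out / "loss_trace.csv", index=False
        )
        snapshot = dataclasses.asdict(config)
        (out / "config.json").write_text(json.dumps(snapshot, indent=1, default=str))
        res.params.save(str(out / "model_params.npz"))
        logger.info("run complete: %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
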