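"""Semi-synthetic benchmark generator with five perturbation scenarios.

Starting from a baseline cohort (real, or fabricated by
:func:`fabricate_baseline` so nothing needs downloading), subjects are
resampled and split into synthetic "cases" and "controls", a group of
metabolites (a ball in chemical embedding space) and/or a taxonomic clade
is chosen, and group-level differences are injected:

* metabolites: on the standardized log scale, perturbed metabolites are
  redrawn from Normal(mu0, 1.5) for controls and Normal(mu1, 1.5) for
  cases (mu0 = -0.203, mu1 = 0.724, effect sizes calibrated from rules
  learned on real data); everything then receives measurement noise
  (variance 0.024) and is mapped back to raw levels.
* taxa: the perturbed clade's total relative abundance is redrawn
  log-normally (log means -6 for controls, -3 for cases, sd 1.5),
  allocated within the clade proportionally to the baseline composition,
  jittered by a truncated normal (30% CV), and counts are regenerated
  from a Dirichlet-multinomial (concentration 286) at the subject's
  original sequencing depth.

Scenario 1 perturbs one metabolite group; scenario 2 two metabolite
groups with the control group split into two subgroups that each receive
a doubled perturbation in one group; scenarios 3 and 4 are the taxa
analogues; scenario 5 perturbs one clade and one metabolite group, with
control subgroups receiving one perturbation each and cases both.

Every sampled group records its ground truth so detection can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .containers import (
    DistanceMatrix,
    Embedding,
    FeatureTable,
    LogNormalPrior,
    SubjectLabels,
)
from .geometry import (
    calibrate_radius_prior,
    pcoa,
    patristic_distances,
    rescale_embedding,
    select_dims_metab,
)
from .tables import filter_metabolites, transform_metabolites

__all__ = [
    "ScenarioConfig",
    "BaselineCohort",
    "SyntheticDataset",
    "fabricate_baseline",
    "sample_subjects",
    "sample_metabolite_group",
    "sample_taxa_clade",
    "perturb_metabolites",
    "perturb_taxa",
    "generate_scenario",
    "fold_change_stat",
    "write_dataset",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the five perturbation scenarios (defaults as derived
    from real-data rules; see module docstring)."""

    scenario: int = 1
    n_subjects: int = 64
    seed: int = 0
    mu0_M: float = -0.203
    mu1_M: float = 0.724
    sigma0_M: float = 1.5
    sigma1_M: float = 1.5
    mu0_T: float = -6.0
    mu1_T: float = -3.0
    sigma_T: float = 1.5
    sigma_meas2: float = 0.024
    theta: float = 0.3
    dmd_alpha: float = 286.0
    max_metab_frac: float = 0.15
    clade_min: int = 5
    clade_max: int = 30

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError("scenario must be in 1..5")
        if self.n_subjects % 2:
            raise ValueError("n_subjects must be even")
        if self.clade_min > self.clade_max:
            raise ValueError("clade_min must be <= clade_max")


@dataclass
class BaselineCohort:
    """A baseline (all-control) cohort: measurement tables, tree, chemical
    embedding and grouping labels.  Fabricated cohorts are fully synthetic
    stand-ins for a real control population."""

    taxa_counts: FeatureTable
    metab_raw: FeatureTable
    tree: object  # dendropy.Tree
    newick: str
    metab_dist: DistanceMatrix
    metab_subclasses: dict[str, str]
    taxa_families: dict[str, str]

    @property
    def n_subjects(self) -> int:
        return self.taxa_counts.n_subjects

    @property
    def depths(self) -> np.ndarray:
        return self.taxa_counts.matrix.sum(axis=1)


@dataclass
class SyntheticDataset:
    taxa: FeatureTable  # counts
    metab: FeatureTable  # raw positive levels
    labels: SubjectLabels
    truth: dict
    config: ScenarioConfig
    baseline: BaselineCohort


# ---------------------------------------------------------------------------
# baseline fabrication
# ---------------------------------------------------------------------------


def _random_coalescent_tree(n_taxa: int, seed: int):
    """A Kingman-coalescent tree over n_taxa leaves (dendropy)."""
    import random

    import dendropy
    from dendropy.simulate import treesim

    tns = dendropy.TaxonNamespace([f"taxon_{i}" for i in range(n_taxa)])
    return treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )


def taxa_family_labels(dist: DistanceMatrix, n_families: int) -> dict[str, str]:
    """Synthetic taxonomic-family stand-in: complete-linkage clusters of
    the patristic distance matrix."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist.D, checks=False), method="complete")
    labels = fcluster(Z, t=n_families, criterion="maxclust")
    return {lab: f"family_{c}" for lab, c in zip(dist.labels, labels)}


def fabricate_baseline(
    n_subjects: int = 67,
    n_taxa: int = 120,
    n_metab: int = 200,
    seed: int = 0,
    depth: int = 10000,
    embed_dim: int = 5,
) -> BaselineCohort:
    """Fabricate a fully synthetic baseline cohort.

    Taxa counts come from a log-normal-composition + multinomial model on
    a random coalescent tree; metabolite levels are correlated log-normal
    intensities with partial detection (zeros), and metabolite chemistry
    is emulated by Gaussian sub-class clusters in a latent coordinate
    space whose pairwise distances play the role of fingerprint distances.
    Deterministic per seed.
    """
    if n_taxa < 30:
        raise ValueError("need n_taxa >= 30 so clades up to 30 leaves exist")
    if n_metab < 8 or n_subjects < 4:
        raise ValueError("cohort too small")
    rng = np.random.default_rng(seed)
    subjects = [f"subj_{i:03d}" for i in range(n_subjects)]

    # taxa: base composition + per-subject noise -> multinomial counts
    tree = _random_coalescent_tree(n_taxa, seed)
    taxa_ids = [f"taxon_{i}" for i in range(n_taxa)]
    base = rng.normal(0.0, 2.0, size=n_taxa)
    logits = base[None, :] + rng.normal(0.0, 1.0, size=(n_subjects, n_taxa))
    comp = np.exp(logits - logits.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, comp[s]) for s in range(n_subjects)])
    taxa_counts = FeatureTable(
        pd.DataFrame(counts, index=subjects, columns=taxa_ids), "taxa", "raw"
    )

    # metabolites: clustered latent chemistry + correlated log intensities
    metab_ids = [f"metab_{i:03d}" for i in range(n_metab)]
    n_clusters = max(4, n_metab // 15)
    centers = rng.normal(0.0, 3.0, size=(n_clusters, embed_dim))
    cluster_of = rng.integers(0, n_clusters, size=n_metab)
    coords = centers[cluster_of] + rng.normal(0.0, 0.5, size=(n_metab, embed_dim))
    from scipy.spatial.distance import pdist, squareform

    metab_dist = DistanceMatrix(squareform(pdist(coords)), metab_ids)
    subclasses = {m: f"subclass_{c}" for m, c in zip(metab_ids, cluster_of)}

    rank = max(2, n_metab // 20)
    G = rng.normal(0.0, 1.0, size=(n_subjects, rank))
    W = rng.normal(0.0, 0.6, size=(rank, n_metab))
    z = G @ W + rng.normal(0.0, 0.8, size=(n_subjects, n_metab))
    mu_m = rng.normal(7.0, 1.0, size=n_metab)
    sd_m = rng.uniform(0.5, 1.5, size=n_metab)
    levels = np.exp(mu_m[None, :] + sd_m[None, :] * z)
    # partial detection: most metabolites near-complete, a few sparse
    censor_p = rng.uniform(0.0, 0.2, size=n_metab)
    sparse = rng.random(n_metab) < 0.05
    censor_p[sparse] = rng.uniform(0.9, 1.0, size=int(sparse.sum()))
    detected = rng.random((n_subjects, n_metab)) >= censor_p[None, :]
    for m in range(n_metab):  # keep at least two detections per metabolite
        if detected[:, m].sum() < 2:
            detected[rng.choice(n_subjects, 2, replace=False), m] = True
    levels = np.where(detected, levels, 0.0)
    metab_raw = FeatureTable(
        pd.DataFrame(levels, index=subjects, columns=metab_ids), "metabolite", "raw"
    )

    taxa_dist = patristic_distances(tree, taxa_ids)
    families = taxa_family_labels(taxa_dist, max(5, n_taxa // 10))
    return BaselineCohort(
        taxa_counts=taxa_counts,
        metab_raw=metab_raw,
        tree=tree,
        newick=tree.as_string(schema="newick").strip(),
        metab_dist=metab_dist,
        metab_subclasses=subclasses,
        taxa_families=families,
    )


# ---------------------------------------------------------------------------
# sampling subjects and perturbation targets
# ---------------------------------------------------------------------------


def sample_subjects(
    baseline_size: int, n: int, seed: int, max_n: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n subjects (case indices, control indices) from the baseline.

    One index sequence of length max(max_n, n) is drawn per seed and
    prefixes are taken, so draws are nested across n: the first
    ``baseline_size`` entries are a permutation (sampling without
    replacement while n <= baseline size), continued with replacement.
    Cases are the even positions of the prefix, controls the odd ones.
    """
    if n % 2:
        raise ValueError("n must be even")
    length = max(max_n, n)
    rng = np.random.default_rng(seed)
    head = rng.permutation(baseline_size)
    tail = rng.integers(0, baseline_size, size=max(length - baseline_size, 0))
    seq = np.concatenate([head, tail])[:length]
    prefix = seq[:n]
    return prefix[0::2].copy(), prefix[1::2].copy()


def sample_metabolite_group(
    emb: Embedding,
    radius_prior: LogNormalPrior,
    max_frac: float,
    rng: np.random.Generator,
    max_rejections: int = 1000,
) -> set[str]:
    """Rejection-sample a metabolite group: a uniformly chosen center
    metabolite plus all metabolites within a Log-Normal-drawn radius,
    rejecting groups larger than ``max_frac`` of all metabolites."""
    n = emb.n
    cap = int(np.floor(max_frac * n))
    if cap < 1:
        raise ValueError("max_frac too small: no group size is allowed")
    for _ in range(max_rejections):
        p = int(rng.integers(0, n))
        kappa = float(
            np.exp(rng.normal(radius_prior.log_location,
                              np.sqrt(radius_prior.log_scale2)))
        )
        d = np.linalg.norm(emb.coords - emb.coords[p][None, :], axis=1)
        H = np.flatnonzero(d <= kappa)
        if 1 <= H.size <= cap:
            return {emb.labels[i] for i in H}
    raise RuntimeError(
        f"exceeded {max_rejections} rejections sampling a metabolite group; "
        "check the radius prior calibration"
    )


_CLADE_CACHE: dict[tuple[int, int, int], list[list[str]]] = {}


def eligible_clades(tree, clade_min: int = 5, clade_max: int = 30) -> list[list[str]]:
    """Leaf sets of the internal nodes with clade_min..clade_max leaves
    (memoized per tree object)."""
    key = (id(tree), clade_min, clade_max)
    if key not in _CLADE_CACHE:
        eligible = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if clade_min <= len(leaves) <= clade_max:
                eligible.append(leaves)
        _CLADE_CACHE[key] = eligible
    return _CLADE_CACHE[key]


def sample_taxa_clade(
    tree, rng: np.random.Generator, clade_min: int = 5, clade_max: int = 30
) -> set[str]:
    """Uniform draw over internal nodes with clade_min..clade_max leaves."""
    eligible = eligible_clades(tree, clade_min, clade_max)
    if not eligible:
        raise ValueError(
            f"tree has no clade with {clade_min}..{clade_max} leaves"
        )
    return set(eligible[int(rng.integers(0, len(eligible)))])


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def perturb_metabolites(
    z_std: pd.DataFrame,
    std_stats: pd.DataFrame,
    groups: list[tuple[set[str], dict[str, tuple[float, float]]]],
    assignment: pd.Series,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject metabolite perturbations and map back to raw levels.

    ``z_std`` holds the standardized log values of the (resampled)
    subjects; ``groups`` pairs each perturbed member set H with a map
    from assignment label (case / control / control1 / control2) to the
    (mean, sd) of the biological-layer normal draw.  Unperturbed
    metabolites keep their standardized values.  All entries then receive
    measurement noise (variance ``sigma_meas2``) and are un-transformed
    with the baseline statistics: y = exp(y' * sqrt(v_m) + u_m).

    Returns (raw level table, biological-layer p table).
    """
    p = z_std.copy()
    for H, mu_map in groups:
        members = [m for m in z_std.columns if m in H]
        if not members:
            raise ValueError("perturbation group has no member in the table")
        for label, (mu, sd) in mu_map.items():
            rows = assignment.index[assignment == label]
            if len(rows) == 0:
                continue
            p.loc[rows, members] = rng.normal(
                mu, sd, size=(len(rows), len(members))
            )
    noise = rng.normal(0.0, np.sqrt(cfg.sigma_meas2), size=p.shape)
    y_prime = p.to_numpy() + noise
    u = std_stats.loc[p.columns, "mean"].to_numpy()
    v = std_stats.loc[p.columns, "var"].to_numpy()
    raw = np.exp(y_prime * np.sqrt(v)[None, :] + u[None, :])
    return pd.DataFrame(raw, index=p.index, columns=p.columns), p


def _truncnorm01(mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-CDF sampling of Normal(mean, sd^2) truncated to
    [0, 1]; entries with mean <= 0 or sd <= 0 pass through unchanged."""
    out = np.array(mean, dtype=float)
    ok = (mean > 0) & (sd > 0)
    if np.any(ok):
        a = (0.0 - mean[ok]) / sd[ok]
        b = (1.0 - mean[ok]) / sd[ok]
        u = rng.uniform(size=int(ok.sum()))
        out[ok] = truncnorm.ppf(u, a, b, loc=mean[ok], scale=sd[ok])
    return out


def perturb_taxa(
    w: pd.DataFrame,
    depths: np.ndarray,
    groups: list[tuple[set[str], dict[str, tuple[float, float]]]],
    assignment: pd.Series,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Inject clade perturbations and regenerate counts.

    ``w`` holds baseline relative abundances of the resampled subjects.
    For each clade C the clade's total mass is redrawn log-normally per
    subject (parameters by assignment label), allocated within C
    proportionally to the subject's baseline within-clade composition
    (equal split when the clade is absent), the whole composition
    renormalized, jittered by TruncatedNormal(gamma, (theta*gamma)^2, 0, 1),
    renormalized again, and counts drawn Dirichlet-multinomial with
    concentration ``dmd_alpha`` at the subject's original depth.

    Returns (count table, diagnostics with the log-mass draws per clade).
    """
    gamma = w.to_numpy(dtype=float).copy()
    cols = {c: i for i, c in enumerate(w.columns)}
    diags: dict = {"log_mass_draws": []}
    for H, mu_map in groups:
        members = [m for m in w.columns if m in H]
        if not members:
            raise ValueError("clade has no member in the table")
        midx = np.array([cols[m] for m in members])
        p_prime = np.empty(len(w))
        for label, (mu, sd) in mu_map.items():
            rows = np.flatnonzero((assignment == label).to_numpy())
            p_prime[rows] = rng.normal(mu, sd, size=rows.size)
        p_cs = np.exp(p_prime)
        base = w.to_numpy()[:, midx]
        tot = base.sum(axis=1)
        frac = np.where(
            tot[:, None] > 0, base / np.where(tot == 0, 1.0, tot)[:, None],
            1.0 / len(midx),
        )
        gamma[:, midx] = p_cs[:, None] * frac
        diags["log_mass_draws"].append(
            pd.Series(p_prime, index=w.index, name="log_mass")
        )
    gamma /= gamma.sum(axis=1, keepdims=True)
    phi = _truncnorm01(gamma, cfg.theta * gamma, rng)
    row_sums = phi.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    phi /= row_sums
    # Dirichlet-multinomial via the gamma construction, vectorized over rows
    g = rng.gamma(np.clip(cfg.dmd_alpha * phi, 0.0, None))
    bad = g.sum(axis=1) <= 0
    if np.any(bad):
        g[bad] = 1.0
    probs = g / g.sum(axis=1, keepdims=True)
    counts = rng.multinomial(np.asarray(depths, dtype=np.int64), probs)
    return pd.DataFrame(counts, index=w.index, columns=w.columns), diags


# ---------------------------------------------------------------------------
# scenario composition
# ---------------------------------------------------------------------------


def _metab_geometry(
    baseline: BaselineCohort,
) -> tuple[pd.DataFrame, pd.DataFrame, Embedding, LogNormalPrior]:
    """Filtered + standardized metabolites, their embedding and the
    calibrated group-sampling radius prior."""
    filt = filter_metabolites(baseline.metab_raw)
    std = transform_metabolites(filt)
    D = baseline.metab_dist.subset(std.feature_ids)
    emb = rescale_embedding(pcoa(D, select_dims_metab(D)))
    prior = calibrate_radius_prior(emb, baseline.metab_subclasses)
    return std.values, std.standardization, emb, prior


def _assignment(case_ids, control_ids, split_controls: bool) -> pd.Series:
    labels = {}
    for sid in case_ids:
        labels[sid] = "case"
    for i, sid in enumerate(control_ids):
        if split_controls:
            labels[sid] = "control1" if i % 2 == 0 else "control2"
        else:
            labels[sid] = "control"
    return pd.Series(labels)


def generate_scenario(baseline: BaselineCohort, cfg: ScenarioConfig) -> SyntheticDataset:
    """Compose subject resampling, group sampling and perturbation into a
    labelled semi-synthetic dataset with recorded ground truth."""
    rng = np.random.default_rng(cfg.seed)
    case_idx, ctrl_idx = sample_subjects(baseline.n_subjects, cfg.n_subjects, cfg.seed)
    base_sub = baseline.taxa_counts.subject_ids
    order = np.empty(cfg.n_subjects, dtype=int)
    order[0::2], order[1::2] = case_idx, ctrl_idx
    new_ids = [f"sample_{i:04d}" for i in range(cfg.n_subjects)]
    case_ids = [new_ids[i] for i in range(0, cfg.n_subjects, 2)]
    ctrl_ids = [new_ids[i] for i in range(1, cfg.n_subjects, 2)]
    split = cfg.scenario in (2, 4, 5)
    assignment = _assignment(case_ids, ctrl_ids, split).loc[new_ids]

    truth: dict = {
        "scenario": cfg.scenario,
        "baseline_indices": order.tolist(),
        "assignment": assignment.to_dict(),
        "metab_groups": [],
        "taxa_clades": [],
    }

    # --- metabolites
    z_all, std_stats, emb_M, prior_M = _metab_geometry(baseline)
    z_rows = z_all.iloc[order].set_axis(new_ids, axis=0)
    metab_groups: list[tuple[set[str], dict]] = []
    if cfg.scenario == 1:
        H = sample_metabolite_group(emb_M, prior_M, cfg.max_metab_frac, rng)
        metab_groups = [(H, {
            "case": (cfg.mu1_M, cfg.sigma1_M),
            "control": (cfg.mu0_M, cfg.sigma0_M),
        })]
    elif cfg.scenario == 2:
        H1 = sample_metabolite_group(emb_M, prior_M, cfg.max_metab_frac, rng)
        H2 = H1
        for _ in range(1000):
            H2 = sample_metabolite_group(emb_M, prior_M, cfg.max_metab_frac, rng)
            if not (H2 & H1):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample a disjoint second group")
        metab_groups = [
            (H1, {"case": (cfg.mu1_M, cfg.sigma1_M),
                  "control1": (2 * cfg.mu1_M, cfg.sigma1_M),
                  "control2": (cfg.mu0_M, cfg.sigma0_M)}),
            (H2, {"case": (cfg.mu1_M, cfg.sigma1_M),
                  "control1": (cfg.mu0_M, cfg.sigma0_M),
                  "control2": (2 * cfg.mu1_M, cfg.sigma1_M)}),
        ]
    elif cfg.scenario == 5:
        H = sample_metabolite_group(emb_M, prior_M, cfg.max_metab_frac, rng)
        metab_groups = [(H, {
            "case": (cfg.mu1_M, cfg.sigma1_M),
            "control1": (cfg.mu0_M, cfg.sigma0_M),
            "control2": (cfg.mu1_M, cfg.sigma1_M),
        })]
    if metab_groups:
        metab_df, _ = perturb_metabolites(
            z_rows, std_stats, metab_groups, assignment, cfg, rng
        )
        truth["metab_groups"] = [sorted(H) for H, _ in metab_groups]
    else:
        # unperturbed scenarios still pass through the measurement model
        metab_df, _ = perturb_metabolites(z_rows, std_stats, [
            (set(z_rows.columns), {})], assignment, cfg, rng)
    metab = FeatureTable(metab_df, "metabolite", "raw")

    # --- taxa
    counts = baseline.taxa_counts.values.iloc[order].set_axis(new_ids, axis=0)
    depths = counts.sum(axis=1).to_numpy()
    taxa_clades: list[tuple[set[str], dict]] = []
    if cfg.scenario == 3:
        C = sample_taxa_clade(baseline.tree, rng, cfg.clade_min, cfg.clade_max)
        taxa_clades = [(C, {
            "case": (cfg.mu1_T, cfg.sigma_T),
            "control": (cfg.mu0_T, cfg.sigma_T),
        })]
    elif cfg.scenario == 4:
        C1 = sample_taxa_clade(baseline.tree, rng, cfg.clade_min, cfg.clade_max)
        C2 = C1
        for _ in range(1000):
            C2 = sample_taxa_clade(baseline.tree, rng, cfg.clade_min, cfg.clade_max)
            if not (C2 & C1):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample a disjoint second clade")
        taxa_clades = [
            (C1, {"case": (cfg.mu1_T, cfg.sigma_T),
                  "control1": (2 * cfg.mu1_T, cfg.sigma_T),
                  "control2": (cfg.mu0_T, cfg.sigma_T)}),
            (C2, {"case": (cfg.mu1_T, cfg.sigma_T),
                  "control1": (cfg.mu0_T, cfg.sigma_T),
                  "control2": (2 * cfg.mu1_T, cfg.sigma_T)}),
        ]
    elif cfg.scenario == 5:
        C = sample_taxa_clade(baseline.tree, rng, cfg.clade_min, cfg.clade_max)
        taxa_clades = [(C, {
            "case": (cfg.mu1_T, cfg.sigma_T),
            "control1": (cfg.mu1_T, cfg.sigma_T),
            "control2": (cfg.mu0_T, cfg.sigma_T),
        })]
    if taxa_clades:
        rel = counts.div(counts.sum(axis=1), axis=0)
        taxa_df, _ = perturb_taxa(rel, depths, taxa_clades, assignment, cfg, rng)
        truth["taxa_clades"] = [sorted(C) for C, _ in taxa_clades]
    else:
        taxa_df = counts
    taxa = FeatureTable(taxa_df, "taxa", "raw")

    y = pd.Series(
        [1 if assignment[sid] == "case" else 0 for sid in new_ids],
        index=pd.Index(new_ids, name="subject_id"),
    )
    return SyntheticDataset(
        taxa=taxa, metab=metab, labels=SubjectLabels(y), truth=truth,
        config=cfg, baseline=baseline,
    )


def fold_change_stat(g: np.ndarray, labels: np.ndarray) -> float:
    """Ratio of class-mean detector outputs: mean over controls divided by
    mean over cases (used to calibrate perturbation magnitudes)."""
    g = np.asarray(g, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    denom = g[labels == 1].mean()
    if denom == 0:
        raise ValueError("case-group mean is zero")
    return float(g[labels == 0].mean() / denom)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write taxa counts, metabolite levels, labels, truth and the tree."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.taxa.values.to_csv(out / "taxa_counts.csv")
    ds.metab.values.to_csv(out / "metabolite_levels.csv")
    ds.labels.y.rename("label").to_csv(out / "labels.csv")
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=1))
    (out / "tree.nwk").write_text(ds.baseline.newick + "\n")
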