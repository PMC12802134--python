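"""MAP inference: initialization, annealed Adam training, restarts, CV.

Training is full-batch first-order optimization of the negative log
posterior with Adam (learning rate 0.001 for all parameters except the
taxa detector thresholds at 0.0001), while the five relaxation
temperatures are annealed linearly over the epochs.  Optimization is
restarted from several seeds and the lowest-loss fit is reported.

Cross-validation is stratified; metabolite log-standardization statistics
are re-fit on each training fold and applied to the held-out subjects, so
no held-out information leaks into the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .containers import Embedding, FeatureTable, LogNormalPrior, SubjectLabels
from .model import (
    AnnealingState,
    HyperParams,
    ModelData,
    ModelParams,
    RuleNetwork,
    Temperatures,
)
from .tables import apply_standardization, transform_metabolites

__all__ = [
    "FitConfig",
    "FitResult",
    "CVResult",
    "initialize",
    "fit",
    "multi_seed_fit",
    "cross_validate",
    "ruleset_similarity",
    "build_model_data",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings (library defaults)."""

    epochs: int = 5000
    lr_default: float = 0.001
    lr_eta_T: float = 0.0001
    lr_eta_M: float | None = None  # metabolite thresholds (None -> default)
    lr_weights: float | None = None  # beta and bias (None -> default)
    seeds: int = 10
    convergence_window: int = 100
    convergence_delta: float = 0.01
    cv_folds: int = 5
    loo: bool = False
    early_stop: bool = False
    selector_noise: bool = False  # sampled BinaryConcrete relaxations
    straight_through: bool = False  # binarized selectors in the forward pass
    annealing: AnnealingState = field(default_factory=AnnealingState)

    def __post_init__(self) -> None:
        if self.epochs < self.convergence_window:
            raise ValueError("epochs must be >= convergence_window")
        if self.seeds < 1:
            raise ValueError("seeds must be >= 1")


@dataclass
class FitResult:
    params: ModelParams
    loss_trace: np.ndarray
    converged: bool
    seed: int
    final_loss: float
    final_temps: Temperatures
    hard: bool = False  # selectors binarized in the forward pass


@dataclass
class CVResult:
    predictions: pd.DataFrame  # columns: subject_id, fold, p_case, label
    fold_aucs: list[float]
    pooled_auc: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else self.pooled_auc


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _kmeans_init(E: np.ndarray, X: np.ndarray, n_detectors: int, aggregate: str,
                 seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detector centers, radii and thresholds from k-means on the embedding.

    Centers are the centroids; each radius is the maximum distance from the
    centroid to its assigned members (floored at 1e-3); each threshold is
    the cohort mean of the cluster's aggregate (mean of standardized levels
    for metabolites, sum of relative abundances for taxa).
    """
    n_features = E.shape[0]
    k = n_detectors
    if k > n_features:
        warnings.warn(
            f"{n_detectors} detectors but only {n_features} features; "
            f"reducing k-means clusters to {n_features}"
        )
        k = n_features
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed % 2**31)).fit(E)
    assign = km.labels_
    from scipy.spatial.distance import cdist

    full_dist = cdist(E, E)
    centers = np.empty((n_detectors, E.shape[1]))
    radii = np.empty(n_detectors)
    thresholds = np.empty(n_detectors)
    for j in range(n_detectors):
        c = j % k
        members = np.flatnonzero(assign == c)
        centers[j] = km.cluster_centers_[c]
        dists = np.linalg.norm(E[members] - centers[j], axis=1)
        if members.size > 1:
            # mean member distance covers the typical cluster extent
            radii[j] = max(float(dists.mean()), 1e-2)
        else:
            # singleton cluster: reach to the nearest other feature
            d = full_dist[members[0]]
            radii[j] = float(d[d > 0].min()) if np.any(d > 0) else 1e-2
        inside = members[np.linalg.norm(E[members] - centers[j], axis=1) <= radii[j]]
        group = inside if inside.size else members
        if aggregate == "mean":
            agg = X[:, group].mean(axis=1)
        else:
            agg = X[:, group].sum(axis=1)
        thresholds[j] = float(agg.mean())
    return centers, radii, thresholds


def initialize(
    data: ModelData, hp: HyperParams, seed: int
) -> ModelParams:
    """Deterministic (per seed) initialization of all model parameters.

    Each rule's detectors come from an independently seeded k-means run, so
    a single restart explores K different detector configurations; rule
    selection then favors the configurations that carry signal.
    """
    rng = np.random.default_rng(seed)
    K = hp.K
    c_M = np.empty((K, hp.J, data.E_M.shape[1]))
    r_M = np.empty((K, hp.J))
    t_M = np.empty((K, hp.J))
    c_T = np.empty((K, hp.L, data.E_T.shape[1]))
    r_T = np.empty((K, hp.L))
    t_T = np.empty((K, hp.L))
    for k in range(K):
        sk = (seed * 1009 + k) % 2**31
        c_M[k], r_M[k], t_M[k] = _kmeans_init(data.E_M, data.X_M, hp.J, "mean", sk)
        c_T[k], r_T[k], t_T[k] = _kmeans_init(data.E_T, data.X_T, hp.L, "sum", sk)
    params = ModelParams(
        centers_M=c_M,
        log_radii_M=np.log(r_M),
        thresholds_M=t_M,
        centers_T=c_T,
        log_radii_T=np.log(r_T),
        thresholds_T=np.clip(t_T, 0.0, 1.0),
        detector_logits=np.zeros((K, hp.J + hp.L)),  # selector value 0.5
        rule_logits=0.1 * rng.standard_normal(K),  # ~0.5 with tie-breaking
        beta=rng.standard_normal(K),
        beta0=np.array(0.0),
    )
    return params


# ---------------------------------------------------------------------------
# Adam + training loop
# ---------------------------------------------------------------------------


class _Adam:
    """Adam over a single flat parameter vector (one learning-rate entry
    per element, so the taxa-threshold group can differ)."""

    def __init__(self, params: ModelParams, lr_default: float, lr_eta_T: float,
                 lr_eta_M: float | None = None, lr_weights: float | None = None,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slices: dict[str, tuple[slice, tuple]] = {}
        off = 0
        for f in ModelParams.FIELDS:
            arr = np.atleast_1d(getattr(params, f))
            self.slices[f] = (slice(off, off + arr.size), getattr(params, f).shape)
            off += arr.size
        self.n = off
        self.lr = np.full(off, lr_default)
        self.lr[self.slices["thresholds_T"][0]] = lr_eta_T
        if lr_eta_M is not None:
            self.lr[self.slices["thresholds_M"][0]] = lr_eta_M
        if lr_weights is not None:
            self.lr[self.slices["beta"][0]] = lr_weights
            self.lr[self.slices["beta0"][0]] = lr_weights
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = np.zeros(off)
        self.v = np.zeros(off)
        self.t = 0
        self._g = np.empty(off)
        self._x = np.empty(off)
        self._pack_params(params)

    def _pack_params(self, params: ModelParams) -> None:
        for f, (sl, shape) in self.slices.items():
            self._x[sl] = np.atleast_1d(getattr(params, f)).ravel()

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        g, x = self._g, self._x
        for f, (sl, shape) in self.slices.items():
            g[sl] = np.atleast_1d(grads[f]).ravel()
        self.m *= self.b1
        self.m += (1 - self.b1) * g
        self.v *= self.b2
        self.v += (1 - self.b2) * g * g
        step = self.lr * (self.m / (1 - self.b1**self.t)) / (
            np.sqrt(self.v / (1 - self.b2**self.t)) + self.eps
        )
        x -= step
        for f, (sl, shape) in self.slices.items():
            np.atleast_1d(getattr(params, f)).ravel()[:] = x[sl]

    def sync(self, params: ModelParams) -> None:
        """Re-pack after an external projection clamped parameters."""
        self._pack_params(params)


def fit(
    net: RuleNetwork,
    config: FitConfig = FitConfig(),
    seed: int = 0,
    init_params: ModelParams | None = None,
) -> FitResult:
    """Run annealed full-batch Adam MAP optimization from one seed."""
    params = init_params.copy() if init_params is not None else initialize(
        net.data, net.hp, seed
    )
    opt = _Adam(params, config.lr_default, config.lr_eta_T,
                config.lr_eta_M, config.lr_weights)
    ann = config.annealing
    trace = np.empty(config.epochs)
    converged = False
    epochs_run = config.epochs
    # optional sampled-relaxation noise stream (off by default)
    noise_rng = np.random.default_rng([seed, 0xA5])
    for e in range(config.epochs):
        temps = ann.at(e, config.epochs)
        noise = None
        if config.selector_noise:
            noise = (
                noise_rng.logistic(size=params.detector_logits.shape),
                noise_rng.logistic(size=params.rule_logits.shape),
            )
        loss, grads = net.loss_and_grad(
            params, temps, noise, hard=config.straight_through
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {e}")
        trace[e] = loss
        opt.step(params, grads)
        net.project(params)
        opt.sync(params)
        w = config.convergence_window
        if e >= w and (trace[e - w] - trace[e]) < config.convergence_delta:
            converged = True
            if config.early_stop:
                epochs_run = e + 1
                break
    trace = trace[:epochs_run]
    final_temps = ann.final(config.epochs)
    final_loss = net.negative_log_posterior(
        params, final_temps, hard=config.straight_through
    )
    return FitResult(
        params=params,
        loss_trace=trace,
        converged=converged,
        seed=seed,
        final_loss=float(final_loss),
        final_temps=final_temps,
        hard=config.straight_through,
    )


def multi_seed_fit(
    net: RuleNetwork, config: FitConfig = FitConfig(), base_seed: int = 0
) -> FitResult:
    """Restart :func:`fit` over ``config.seeds`` seeds; return the lowest
    final loss (ties broken by the smaller seed)."""
    results: list[FitResult] = []
    errors: list[str] = []
    for i in range(config.seeds):
        try:
            results.append(fit(net, config, seed=base_seed + i))
        except FloatingPointError as exc:  # pragma: no cover - defensive
            errors.append(f"seed {base_seed + i}: {exc}")
    if not results:
        raise RuntimeError("all seeds aborted: " + "; ".join(errors))
    return min(results, key=lambda r: (r.final_loss, r.seed))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def build_model_data(
    taxa_rel: FeatureTable,
    metab_std: FeatureTable,
    emb_T: Embedding,
    emb_M: Embedding,
    labels: SubjectLabels,
    prior_T: LogNormalPrior,
    prior_M: LogNormalPrior,
) -> ModelData:
    """Assemble aligned arrays, ordering embedding rows by table columns."""
    if taxa_rel.subject_ids != metab_std.subject_ids:
        raise ValueError("taxa and metabolite tables are not subject-aligned")
    if taxa_rel.subject_ids != labels.subject_ids:
        raise ValueError("tables and labels are not subject-aligned")
    idx_T = {lab: i for i, lab in enumerate(emb_T.labels)}
    idx_M = {lab: i for i, lab in enumerate(emb_M.labels)}
    missing_T = [f for f in taxa_rel.feature_ids if f not in idx_T]
    missing_M = [f for f in metab_std.feature_ids if f not in idx_M]
    if missing_T or missing_M:
        raise ValueError(f"features missing from embeddings: {missing_T + missing_M}")
    E_T = emb_T.coords[[idx_T[f] for f in taxa_rel.feature_ids]]
    E_M = emb_M.coords[[idx_M[f] for f in metab_std.feature_ids]]
    return ModelData(
        X_M=metab_std.matrix,
        X_T=taxa_rel.matrix,
        E_M=E_M,
        E_T=E_T,
        y=labels.array,
        prior_M=prior_M,
        prior_T=prior_T,
        metab_ids=metab_std.feature_ids,
        taxa_ids=taxa_rel.feature_ids,
    )


def cross_validate(
    taxa_rel: FeatureTable,
    metab_raw: FeatureTable,
    emb_T: Embedding,
    emb_M: Embedding,
    labels: SubjectLabels,
    prior_T: LogNormalPrior,
    prior_M: LogNormalPrior,
    hp: HyperParams = HyperParams(),
    config: FitConfig = FitConfig(),
    base_seed: int = 0,
    fold_seed: int = 12345,
) -> CVResult:
    """Held-out predictions via stratified k-fold (or leave-one-out) CV.

    ``metab_raw`` must be the *raw* filtered metabolite table: its
    log-standardization is re-fit on each training fold.
    """
    y = labels.array
    sids = np.array(labels.subject_ids)
    if config.loo:
        splits = list(LeaveOneOut().split(sids, y))
    else:
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True,
            random_state=int(fold_seed % 2**31),
        )
        splits = list(skf.split(sids, y))
    rows = []
    fold_aucs: list[float] = []
    for fold, (tr, te) in enumerate(splits):
        if len(set(y[tr])) < 2:
            raise ValueError(f"fold {fold} lost a label class in training")
        metab_tr = FeatureTable(metab_raw.values.iloc[tr], "metabolite", "raw")
        metab_tr_std = transform_metabolites(metab_tr)
        metab_te_std = apply_standardization(
            FeatureTable(metab_raw.values.iloc[te], "metabolite", "raw"),
            metab_tr_std.standardization,
        )
        taxa_tr = FeatureTable(taxa_rel.values.iloc[tr], "taxa", "relative_abundance")
        lab_tr = SubjectLabels(labels.y.iloc[tr])
        data_tr = build_model_data(
            taxa_tr, metab_tr_std, emb_T, emb_M, lab_tr, prior_T, prior_M
        )
        net = RuleNetwork(data_tr, hp)
        res = multi_seed_fit(net, config, base_seed=base_seed + 1000 * fold)
        # held-out forward pass with the training fold's priors/bounds
        data_te = ModelData(
            X_M=metab_te_std.matrix,
            X_T=taxa_rel.matrix[te],
            E_M=data_tr.E_M,
            E_T=data_tr.E_T,
            y=y[te],
            prior_M=prior_M,
            prior_T=prior_T,
        )
        net_te = RuleNetwork(data_te, hp)
        net_te.eta_M_lo, net_te.eta_M_hi = net.eta_M_lo, net.eta_M_hi
        p = net_te.predict_proba(res.params, res.final_temps, hard=res.hard)
        for s, prob, lab in zip(sids[te], p, y[te]):
            rows.append({"subject_id": s, "fold": fold, "p_case": prob, "label": lab})
        if len(set(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], p)))
    preds = pd.DataFrame(rows)
    pooled = float(roc_auc_score(preds["label"], preds["p_case"]))
    return CVResult(predictions=preds, fold_aucs=fold_aucs, pooled_auc=pooled)


# ---------------------------------------------------------------------------
# rule stability
# ---------------------------------------------------------------------------


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def ruleset_similarity(a, b) -> float:
    """Mean Jaccard similarity over an optimal bipartite matching of the
    detectors of two rule sets; unmatched detectors contribute 0."""
    det_a = [set(d.member_ids) for r in a.rules for d in r.detectors]
    det_b = [set(d.member_ids) for r in b.rules for d in r.detectors]
    if not det_a and not det_b:
        return 1.0
    if not det_a or not det_b:
        return 0.0
    sim = np.array([[_jaccard(x, ys) for ys in det_b] for x in det_a])
    ri, ci = linear_sum_assignment(-sim)
    return float(sim[ri, ci].sum() / max(len(det_a), len(det_b)))
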