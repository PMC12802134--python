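"""Distance geometry: patristic distances, PCoA embeddings, radius priors.

Taxa distances are patristic (branch-length path sums) on a Newick tree.
Both taxa and metabolite distance matrices are embedded in Euclidean space
by classical multidimensional scaling (PCoA): eigendecompose -1/2 J D^2 J,
keep the top axes with positive eigenvalues, scale eigenvectors by
sqrt(eigenvalue).  Embedding dimensionality is data-driven:

* taxa: the smallest dimension at which a two-sample Kolmogorov-Smirnov
  test no longer distinguishes (p >= alpha) the pre- and post-embedding
  pairwise distance distributions;
* metabolites: the smallest dimension whose positive eigenvalues explain
  a target fraction (default 95%) of the total positive-eigenvalue mass.

The Log-Normal prior on detector radii is calibrated from biological
groupings (chemical sub-classes for metabolites, taxonomic families for
taxa): within each group of >= 3 members the median pairwise embedded
distance h_c is computed, and the prior parameters are the median and
variance of the h_c across groups.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

from .containers import DistanceMatrix, Embedding, LogNormalPrior

__all__ = [
    "patristic_distances",
    "pcoa",
    "rescale_embedding",
    "select_dims_taxa",
    "select_dims_metab",
    "calibrate_radius_prior",
    "read_newick",
]


def rescale_embedding(emb: Embedding, target_range: float = 0.7) -> Embedding:
    """Uniformly rescale coordinates so their overall range is fixed.

    Putting both modalities' embeddings on one standard coordinate range
    makes detector radii, their priors and the inclusion temperature
    operate on a common scale regardless of the input metric's units.
    """
    rng = float(emb.coords.max() - emb.coords.min())
    if rng <= 0:
        raise ValueError("degenerate embedding: zero coordinate range")
    s = target_range / rng
    return Embedding(
        list(emb.labels), emb.coords * s, emb.eigenvalues * s**2, emb.modality
    )


def read_newick(path_or_string: str):
    """Parse a Newick tree (file path or literal string) with dendropy."""
    import dendropy

    s = str(path_or_string)
    if "(" in s and ";" in s:
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def patristic_distances(tree, taxa_ids: list[str]) -> DistanceMatrix:
    """Sum of branch lengths along leaf-to-leaf paths, for the given taxa.

    ``tree`` is a dendropy Tree or a Newick string/path.  Taxa absent from
    the tree are dropped with a warning.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    matched = [t for t in taxa_ids if t in leaf_names]
    missing = [t for t in taxa_ids if t not in leaf_names]
    if missing:
        warnings.warn(f"taxa not found in tree, dropped: {missing}")
    if len(matched) < 2:
        raise ValueError("fewer than 2 taxa matched tree leaves")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(matched)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                taxon_by_label[matched[i]], taxon_by_label[matched[j]]
            )
    return DistanceMatrix(D, matched)


def _pcoa_spectrum(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors of the Gower-centered matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def pcoa(D: DistanceMatrix, dims: int) -> Embedding:
    """Classical MDS of a distance matrix into ``dims`` Euclidean axes.

    Axes with eigenvalue <= 0 (non-Euclidean structure) are discarded; if
    fewer than ``dims`` positive axes exist, the embedding is truncated
    with a warning.  Each axis's sign is fixed so its first nonzero
    coordinate is positive.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    w, V = _pcoa_spectrum(D.D)
    tol = max(1e-10, 1e-10 * max(abs(w[0]), 1.0))
    pos = np.flatnonzero(w > tol)
    if pos.size == 0:
        raise ValueError("distance matrix has no positive PCoA eigenvalues")
    if dims > pos.size:
        warnings.warn(
            f"requested {dims} dimensions but only {pos.size} positive "
            f"eigenvalues; reducing"
        )
        dims = pos.size
    idx = pos[:dims]
    coords = V[:, idx] * np.sqrt(w[idx])[None, :]
    for d in range(coords.shape[1]):
        col = coords[:, d]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, d] = -col
    return Embedding(list(D.labels), coords, w[idx])


def select_dims_taxa(D: DistanceMatrix, alpha: float = 0.05, max_dims: int = 30) -> int:
    """Smallest embedding dimension whose distances are KS-indistinguishable
    from the input distances (p >= alpha), searching upward from 1.

    The search is capped at ``max_dims``; if no dimension passes, the
    dimension with the largest p-value is returned with a warning (strongly
    non-Euclidean inputs, e.g. raw tree metrics, may never pass at the
    pair-count power of the test).
    """
    if D.n < 3:
        return 1
    target = D.condensed()
    w, _ = _pcoa_spectrum(D.D)
    avail = int(np.sum(w > max(1e-10, 1e-10 * max(abs(w[0]), 1.0))))
    cap = min(avail, max_dims)
    pvals = []
    for d in range(1, cap + 1):
        emb = pcoa(D, d)
        embd = pdist(emb.coords)
        p = ks_2samp(target, embd).pvalue
        if p >= alpha:
            return d
        pvals.append(p)
    warnings.warn(
        "no embedding dimension passed the KS test; using the dimension "
        "with the largest p-value"
    )
    return int(np.argmax(pvals)) + 1


def select_dims_metab(D: DistanceMatrix, var_frac: float = 0.95) -> int:
    """Smallest dimension explaining ``var_frac`` of positive eigenvalue mass."""
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must be in (0, 1]")
    w, _ = _pcoa_spectrum(D.D)
    pos = w[w > max(1e-10, 1e-10 * max(abs(w[0]), 1.0))]
    if pos.size == 0:
        raise ValueError("no positive PCoA eigenvalues")
    frac = np.cumsum(pos) / pos.sum()
    return int(np.searchsorted(frac, var_frac - 1e-12) + 1)


def calibrate_radius_prior(
    emb: Embedding,
    groups: dict[str, str],
    *,
    min_group_size: int = 3,
) -> LogNormalPrior:
    """Calibrate the Log-Normal radius prior from biological groupings.

    For each group c with >= ``min_group_size`` members present in the
    embedding, h_c is the median pairwise Euclidean distance within the
    group.  The prior on a radius kappa is
    log kappa ~ Normal(log(median_c h_c), var_c(h_c)): the location is the
    log of the median-of-medians (so the prior's median radius equals the
    typical group spread) and the variance of the group medians is used
    directly on the log scale (population convention; floored at 1e-4 when
    degenerate).
    """
    by_group: dict[str, list[int]] = {}
    label_idx = {lab: i for i, lab in enumerate(emb.labels)}
    for fid, g in groups.items():
        if fid in label_idx:
            by_group.setdefault(str(g), []).append(label_idx[fid])
    h = []
    for g, idx in sorted(by_group.items()):
        if len(idx) < min_group_size:
            continue
        d = pdist(emb.coords[idx])
        h.append(np.median(d))
    if not h:
        raise ValueError(
            f"no group with >= {min_group_size} members present in the embedding"
        )
    h = np.asarray(sorted(h), dtype=float)
    loc = float(np.median(h))
    if loc <= 0:
        raise ValueError("median within-group distance is not positive")
    var = float(np.var(h))
    if var <= 0:
        warnings.warn("degenerate variance across group medians; flooring at 1e-4")
        var = 1e-4
    return LogNormalPrior(float(np.log(loc)), var, source_groups_used=h.size)
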