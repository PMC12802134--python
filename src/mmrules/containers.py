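"""Core in-memory containers shared across the package.

The pipeline moves four kinds of objects around: subject-by-feature
measurement tables (:class:`FeatureTable`), per-subject binary outcomes
(:class:`SubjectLabels`), symmetric feature-by-feature distance matrices
(:class:`DistanceMatrix`), and their Euclidean embeddings
(:class:`Embedding`).  All wrap pandas/numpy structures and validate their
invariants at construction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SubjectLabels",
    "DistanceMatrix",
    "Embedding",
    "LogNormalPrior",
]

#: valid modality tags for a FeatureTable
MODALITIES = ("taxa", "metabolite")

#: valid transform states for a FeatureTable
TRANSFORM_STATES = ("raw", "relative_abundance", "log_standardized")


@dataclass
class FeatureTable:
    """A subjects x features numeric table with a modality tag.

    Parameters
    ----------
    values
        DataFrame with subjects as rows (index = subject ids) and features
        as columns (columns = feature ids).
    modality
        ``"taxa"`` (counts or relative abundances) or ``"metabolite"``
        (positive raw levels or standardized log levels).
    transform_state
        One of ``"raw"``, ``"relative_abundance"``, ``"log_standardized"``.
    standardization
        For metabolite tables in ``log_standardized`` state: a DataFrame
        indexed by feature id with columns ``mean`` (u_m) and ``var`` (v_m)
        of the per-feature log levels, plus ``pseudocount`` used for zero
        replacement.  Needed to un-transform back to raw levels.
    """

    values: pd.DataFrame
    modality: str
    transform_state: str = "raw"
    standardization: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("FeatureTable contains NaN or Inf")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature_ids: {dups}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject_ids: {dups}")
        if self.transform_state == "relative_abundance":
            sums = vals.sum(axis=1)
            if np.any(sums > 1 + 1e-9) or np.any(vals < -1e-12):
                raise ValueError("relative abundances must be in [0,1] with row sums <= 1")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        std = None if self.standardization is None else self.standardization.copy()
        return FeatureTable(self.values.copy(), self.modality, self.transform_state, std)


@dataclass
class SubjectLabels:
    """Binary host-status labels (0 = control, 1 = case), one per subject."""

    y: pd.Series  # index = subject ids, values in {0, 1}

    def __post_init__(self) -> None:
        if self.y.index.duplicated().any():
            raise ValueError("duplicate subject_ids in labels")
        vals = set(pd.unique(self.y))
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(vals)}")
        if len(vals) < 2:
            raise ValueError("both classes must be present in labels")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.y.index]

    @property
    def array(self) -> np.ndarray:
        return self.y.to_numpy(dtype=int)


class DistanceMatrix:
    """A symmetric, non-negative, zero-diagonal pairwise distance matrix."""

    def __init__(self, D: np.ndarray, labels: list[str], *, tol: float = 1e-8):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != D.shape[0]:
            raise ValueError("labels length must match matrix size")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix contains NaN or Inf")
        if np.max(np.abs(D - D.T)) > tol:
            raise ValueError("distance matrix is not symmetric")
        if np.max(np.abs(np.diag(D))) > tol:
            raise ValueError("distance matrix diagonal is not zero")
        if np.min(D) < -tol:
            raise ValueError("distance matrix has negative entries")
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        self.D = np.clip(D, 0.0, None)
        self.labels = [str(x) for x in labels]

    @property
    def n(self) -> int:
        return self.D.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.D[iu]

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(k) for k in keep]
        return DistanceMatrix(self.D[np.ix_(idx, idx)], [self.labels[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("distance table must have matching row/column labels")
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


@dataclass
class Embedding:
    """Euclidean coordinates of features produced by PCoA.

    ``coords`` is N x D with columns ordered by decreasing eigenvalue;
    ``eigenvalues`` holds the retained (non-negative) eigenvalues.
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    modality: str = "taxa"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("embedding must be N x D with D >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates not finite")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels length must match coords rows")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))


@dataclass
class LogNormalPrior:
    """Log-Normal prior on detector radii.

    ``log_location`` and ``log_scale2`` are the mean and variance of the
    underlying normal on log(radius) (the literal reading; see geometry
    module for the natural-scale alternative).
    """

    log_location: float
    log_scale2: float
    source_groups_used: int = 1

    def __post_init__(self) -> None:
        if not self.log_scale2 > 0:
            raise ValueError("log_scale2 must be positive")
        if self.source_groups_used < 1:
            raise ValueError("source_groups_used must be >= 1")

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        """Log density of LogNormal(log_location, log_scale2) at x > 0."""
        x = np.asarray(x, dtype=float)
        s2 = self.log_scale2
        return (
            -np.log(x)
            - 0.5 * np.log(2 * np.pi * s2)
            - (np.log(x) - self.log_location) ** 2 / (2 * s2)
        )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
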