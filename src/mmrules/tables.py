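"""Reading, validating, filtering and transforming the input tables.

Inputs are delimited text tables: a subjects x taxa count (or relative
abundance) table, a subjects x metabolites positive level table, and a
two-column (subject_id, label) file.  Orientation of the feature tables is
auto-detected against the label file's subject ids.

Filtering conventions (boundaries inclusive on the keep side):

* taxa: keep taxon i iff the fraction of subjects with count >= ``min_count``
  is >= ``min_frac`` (defaults 10 and 0.10);
* metabolites: keep metabolite i iff the fraction of subjects with a
  positive level is >= ``min_presence_frac`` (default 0.15).

Metabolite levels are log-transformed and standardized per feature; zeros
are replaced beforehand by half the smallest positive observed level of
that metabolite.  The standardization statistics (u_m, v_m) are stored on
the output table so levels can be un-transformed (x -> exp(x*sqrt(v_m)+u_m))
and so held-out subjects can be standardized with training statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FeatureTable, SubjectLabels

__all__ = [
    "read_labels",
    "read_table",
    "filter_taxa",
    "filter_metabolites",
    "transform_metabolites",
    "apply_standardization",
    "inverse_transform_metabolites",
    "to_relative_abundance",
    "align_inputs",
    "write_table",
]


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_labels(path: str, sep: str | None = None) -> SubjectLabels:
    """Read a two-column (subject_id, label) file; labels coerced to 0/1."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns (subject_id, label)")
    sid = df.iloc[:, 0].astype(str)
    raw = df.iloc[:, 1]
    try:
        y = raw.astype(int)
    except (TypeError, ValueError):
        uniq = sorted(raw.unique())
        if len(uniq) != 2:
            raise ValueError(f"cannot binarize labels with values {uniq}")
        y = raw.map({uniq[0]: 0, uniq[1]: 1}).astype(int)
        warnings.warn(f"mapped labels {uniq[0]!r}->0, {uniq[1]!r}->1")
    return SubjectLabels(pd.Series(y.to_numpy(), index=pd.Index(sid, name="subject_id")))


def read_table(
    path: str,
    modality: str,
    labels: SubjectLabels | None = None,
    sep: str | None = None,
) -> FeatureTable:
    """Read a subjects x features delimited table.

    When ``labels`` is given, orientation is auto-detected: the axis whose
    ids overlap the label subject ids is taken as subjects (rows preferred
    on ties).  Without labels, rows are assumed to be subjects.
    """
    use_sep = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(use_sep)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate feature_ids in header: {dups}")
    df = pd.read_csv(path, sep=use_sep, header=0, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if labels is not None:
        lab = set(labels.subject_ids)
        row_hits = len(lab & set(df.index.astype(str)))
        col_hits = len(lab & set(df.columns.astype(str)))
        if row_hits == 0 and col_hits == 0:
            raise ValueError("no axis of the table matches the label subject ids")
        if col_hits > row_hits:
            df = df.T
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing cells in {path}")
    return FeatureTable(df, modality=modality, transform_state="raw")


def filter_taxa(
    t: FeatureTable, min_count: float = 10, min_frac: float = 0.10
) -> FeatureTable:
    """Remove taxa not reaching ``min_count`` in >= ``min_frac`` of subjects."""
    if t.modality != "taxa":
        raise ValueError("filter_taxa requires a taxa table")
    frac = (t.values >= min_count).mean(axis=0)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError(
            f"all taxa removed by filter (min_count={min_count}, min_frac={min_frac})"
        )
    out = FeatureTable(t.values.loc[:, keep].copy(), "taxa", t.transform_state)
    return out


def filter_metabolites(t: FeatureTable, min_presence_frac: float = 0.15) -> FeatureTable:
    """Remove metabolites detected (level > 0) in < ``min_presence_frac`` of subjects."""
    if t.modality != "metabolite":
        raise ValueError("filter_metabolites requires a metabolite table")
    presence = (t.values > 0).mean(axis=0)
    keep = presence >= min_presence_frac
    if not keep.any():
        raise ValueError(
            f"all metabolites removed by filter (min_presence_frac={min_presence_frac})"
        )
    return FeatureTable(t.values.loc[:, keep].copy(), "metabolite", t.transform_state)


def _zero_handled(values: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros per metabolite by half its minimum positive level."""
    out = values.copy()
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValueError(f"negative metabolite level in {col!r}")
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError(f"metabolite {col!r} has no positive levels")
        v = np.where(v > 0, v, pos.min() / 2.0)
        out[col] = v
    return out


def transform_metabolites(t: FeatureTable) -> FeatureTable:
    """Log-transform and standardize metabolite levels (population sd).

    Output columns have mean 0 and sd 1; the per-feature (u_m, v_m) log
    statistics and pseudocounts are stored in ``standardization``.
    """
    if t.modality != "metabolite":
        raise ValueError("transform_metabolites requires a metabolite table")
    if t.transform_state == "log_standardized":
        raise ValueError("already transformed")
    if t.n_subjects < 2:
        raise ValueError("standard deviation undefined for a single subject")
    handled = _zero_handled(t.values)
    logs = np.log(handled.to_numpy(dtype=float))
    u = logs.mean(axis=0)
    v = logs.var(axis=0)  # population (n-denominator) convention
    if np.any(v <= 0):
        const = [c for c, vv in zip(handled.columns, v) if vv <= 0]
        raise ValueError(f"constant metabolite(s), sd = 0: {const}")
    z = (logs - u) / np.sqrt(v)
    pseudo = np.array(
        [handled[c][t.values[c] > 0].min() / 2.0 for c in handled.columns]
    )
    std = pd.DataFrame(
        {"mean": u, "var": v, "pseudocount": pseudo}, index=handled.columns
    )
    return FeatureTable(
        pd.DataFrame(z, index=t.values.index, columns=t.values.columns),
        "metabolite",
        "log_standardized",
        standardization=std,
    )


def apply_standardization(t: FeatureTable, std: pd.DataFrame) -> FeatureTable:
    """Standardize raw metabolite levels with pre-computed (train) statistics."""
    if t.transform_state == "log_standardized":
        raise ValueError("already transformed")
    missing = [c for c in t.values.columns if c not in std.index]
    if missing:
        raise ValueError(f"standardization statistics missing for {missing}")
    vals = t.values.to_numpy(dtype=float).copy()
    pseudo = std.loc[t.values.columns, "pseudocount"].to_numpy()
    vals = np.where(vals > 0, vals, pseudo[None, :])
    z = (np.log(vals) - std.loc[t.values.columns, "mean"].to_numpy()) / np.sqrt(
        std.loc[t.values.columns, "var"].to_numpy()
    )
    return FeatureTable(
        pd.DataFrame(z, index=t.values.index, columns=t.values.columns),
        "metabolite",
        "log_standardized",
        standardization=std.loc[t.values.columns].copy(),
    )


def inverse_transform_metabolites(t: FeatureTable) -> FeatureTable:
    """Invert log-standardization: x -> exp(x * sqrt(v_m) + u_m)."""
    if t.transform_state != "log_standardized" or t.standardization is None:
        raise ValueError("table is not in log_standardized state")
    std = t.standardization
    u = std.loc[t.values.columns, "mean"].to_numpy()
    v = std.loc[t.values.columns, "var"].to_numpy()
    raw = np.exp(t.values.to_numpy(dtype=float) * np.sqrt(v) + u)
    return FeatureTable(
        pd.DataFrame(raw, index=t.values.index, columns=t.values.columns),
        "metabolite",
        "raw",
    )


def to_relative_abundance(t: FeatureTable) -> FeatureTable:
    """Divide each subject's taxa counts by their sum."""
    if t.modality != "taxa":
        raise ValueError("to_relative_abundance requires a taxa table")
    vals = t.values.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative counts")
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        zero_rows = [s for s, tot in zip(t.subject_ids, sums) if tot <= 0]
        raise ValueError(f"all-zero subject rows: {zero_rows}")
    rel = vals / sums[:, None]
    return FeatureTable(
        pd.DataFrame(rel, index=t.values.index, columns=t.values.columns),
        "taxa",
        "relative_abundance",
    )


def align_inputs(
    taxa: FeatureTable, metab: FeatureTable, labels: SubjectLabels
) -> tuple[FeatureTable, FeatureTable, SubjectLabels]:
    """Restrict all three inputs to their common subjects, in a shared order.

    The order of the taxa table's surviving subjects is preserved.
    """
    common = [s for s in taxa.subject_ids if s in set(metab.subject_ids) and s in set(labels.subject_ids)]
    if not common:
        raise ValueError("no common subjects across taxa, metabolites and labels")
    dropped = (
        (set(taxa.subject_ids) | set(metab.subject_ids) | set(labels.subject_ids))
        - set(common)
    )
    if dropped:
        warnings.warn(f"dropping subjects absent from some input: {sorted(dropped)}")
    y = labels.y.loc[common]
    if len(set(y)) < 2:
        raise ValueError("a label class disappeared after subject intersection")
    t2 = FeatureTable(taxa.values.loc[common].copy(), "taxa", taxa.transform_state)
    m2 = FeatureTable(
        metab.values.loc[common].copy(),
        "metabolite",
        metab.transform_state,
        None if metab.standardization is None else metab.standardization.copy(),
    )
    return t2, m2, SubjectLabels(y)


def write_table(t: FeatureTable, path: str, sep: str | None = None) -> None:
    t.values.to_csv(path, sep=_sep_for(path, sep))
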