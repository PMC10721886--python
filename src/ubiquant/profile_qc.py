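"""Replicate quality control, enrichment-efficiency metrics, abundance
summaries, and robust-change clustering.

Covers the descriptive half of a pulldown experiment's analysis: pairwise
replicate correlations, within-group coefficients of variation, PCA of the
sample layout, the percent contribution of ubiquitin peptides to total
peptide signal (the enrichment-efficiency readout), the absolute-abundance
(iBAQ) distribution and dynamic range, and hierarchical clustering of
row-Z-scored abundances restricted to "robustly changing" proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .design import SampleDesign
from .preprocess import LogMatrix

__all__ = [
    "QcReport",
    "ClusterResult",
    "replicate_qc",
    "ubiquitin_fraction",
    "ibaq_summary",
    "robust_change_set",
    "zscore_hcluster",
    "DEFAULT_UBIQUITIN_GENES",
]

# Gene symbols of the ubiquitin precursor loci (polyubiquitin and the two
# ribosomal fusions); used to derive the ubiquitin accession set when the
# configuration does not list accessions explicitly.
DEFAULT_UBIQUITIN_GENES = frozenset({"ubb", "ubc", "uba52", "rps27a"})


@dataclass
class QcReport:
    """Replicate/enrichment QC statistics.

    pearson : sample x sample correlation matrix (NaN where fewer than 3
        jointly observed rows).
    cv : per-protein, per-group coefficient of variation (%) on
        linear-scale intensities.
    cv_group_medians : median CV% per group.
    pca_scores : sample coordinates on the leading principal components.
    pca_explained : fraction of variance per component.
    """

    pearson: pd.DataFrame
    cv: pd.DataFrame
    cv_group_medians: pd.Series
    pca_scores: pd.DataFrame
    pca_explained: pd.Series


def replicate_qc(m: LogMatrix, design: SampleDesign | None = None, n_components: int = 2) -> QcReport:
    """Pairwise Pearson correlations, CVs, and PCA of a log2 matrix.

    Correlations use jointly observed rows only (imputed cells are treated
    as unobserved for this purpose), so they reflect measured signal.
    CVs are computed on linear-scale intensities: CV% on log values is not
    meaningful. PCA is an SVD of the column-centred complete matrix
    (missing cells excluded row-wise).
    """
    if design is None:
        design = m.design
    samples = list(design.samples)
    vals = m.values[samples].to_numpy(dtype=float)
    obs = (m.mask[samples] == "observed").to_numpy()

    n = len(samples)
    pearson = np.full((n, n), np.nan)
    for i in range(n):
        pearson[i, i] = 1.0
        for j in range(i + 1, n):
            joint = obs[:, i] & obs[:, j]
            if joint.sum() < 3:
                continue
            r = np.corrcoef(vals[joint, i], vals[joint, j])[0, 1]
            pearson[i, j] = pearson[j, i] = r
    pearson_df = pd.DataFrame(pearson, index=samples, columns=samples)

    linear = np.where(obs, np.exp2(vals), np.nan)
    cv_cols = {}
    for g in design.groups:
        idx = [samples.index(s) for s in design.samples_of(g)]
        sub = linear[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
            n_obs = np.sum(~np.isnan(sub), axis=1)
        cv = np.where((n_obs >= 2) & (mean > 0), 100.0 * sd / mean, np.nan)
        cv_cols[g] = cv
    cv_df = pd.DataFrame(cv_cols, index=m.values.index)
    cv_medians = cv_df.median(skipna=True)

    complete_rows = ~np.isnan(vals).any(axis=1)
    X = vals[complete_rows]
    if X.shape[0] >= 2:
        # samples as observations: SVD of the protein-centred samples x proteins matrix
        Xt = X.T - X.T.mean(axis=0, keepdims=True)
        u2, s2, _ = np.linalg.svd(Xt, full_matrices=False)
        k = min(n_components, len(s2))
        scores = u2[:, :k] * s2[:k]
        total_var = (s2**2).sum()
        explained = (s2**2) / total_var if total_var > 0 else np.zeros_like(s2)
        pca_scores = pd.DataFrame(
            scores, index=samples, columns=[f"PC{i+1}" for i in range(k)]
        )
        pca_explained = pd.Series(explained[:k], index=pca_scores.columns)
    else:
        pca_scores = pd.DataFrame(index=samples)
        pca_explained = pd.Series(dtype=float)

    return QcReport(
        pearson=pearson_df,
        cv=cv_df,
        cv_group_medians=cv_medians,
        pca_scores=pca_scores,
        pca_explained=pca_explained,
    )


def ubiquitin_fraction(
    peptides,
    ubiquitin_accessions: Iterable[str],
    design: SampleDesign | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Percent of summed peptide intensity contributed by ubiquitin entries.

    A peptide counts as ubiquitin-derived when its protein assignment
    intersects ``ubiquitin_accessions``. Returns per-sample percentages and
    a per-group table of mean and SD. Samples with zero total intensity are
    reported NaN with a warning.
    """
    ub = set(ubiquitin_accessions)
    if not ub:
        raise ValueError("ubiquitin accession set is empty")
    if design is None:
        design = peptides.design
    df = peptides.df
    is_ub = df["protein_ids"].map(lambda ids: bool(set(str(ids).split(";")) & ub))
    total = df.groupby("sample")["intensity"].sum()
    ub_total = df[is_ub].groupby("sample")["intensity"].sum()
    pct = pd.Series(np.nan, index=list(design.samples), name="ubiquitin_pct")
    for s in design.samples:
        t = float(total.get(s, 0.0))
        if t == 0.0:
            warnings.warn(f"sample {s!r} has zero total peptide intensity", stacklevel=2)
            continue
        pct[s] = 100.0 * float(ub_total.get(s, 0.0)) / t
    rows = {}
    for g in design.groups:
        vals = pct[list(design.samples_of(g))]
        rows[g] = {"mean": vals.mean(), "sd": vals.std(ddof=1)}
    return pct, pd.DataFrame(rows).T


def ibaq_summary(table, subset: Sequence[str] | None = None, n_bins: int = 40) -> dict:
    """Median log10 iBAQ, dynamic range, and histogram of a protein set.

    Per-protein iBAQ is the mean of positive per-sample values; proteins
    with no positive value are dropped. Dynamic range is max/min (fold).
    """
    ibaq = table.ibaq if not isinstance(table, pd.DataFrame) else table
    if subset is not None:
        ibaq = ibaq.loc[list(subset)]
    arr = ibaq.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_protein = np.nanmean(np.where(arr > 0, arr, np.nan), axis=1)
    per_protein = per_protein[np.isfinite(per_protein)]
    if per_protein.size == 0:
        raise ValueError("no positive iBAQ values in subset")
    log10 = np.log10(per_protein)
    counts, edges = np.histogram(log10, bins=n_bins)
    return {
        "median_log10": float(np.median(log10)),
        "dynamic_range_fold": float(per_protein.max() / per_protein.min()),
        "histogram": (counts, edges),
        "per_protein_log10": pd.Series(log10),
    }


def robust_change_set(
    m: LogMatrix, design: SampleDesign | None = None, groups: Sequence[str] | None = None
) -> list[str]:
    """Proteins robustly changing across the selected groups.

    For each protein, take the median over all samples of the selected
    groups; include the protein iff every replicate of some group lies
    strictly above that median AND every replicate of another group lies
    strictly below it. Values tying the median count as neither. Invariant
    to any strictly increasing transform of a row's values.
    """
    if design is None:
        design = m.design
    if groups is None:
        groups = list(design.groups)
    if len(groups) < 2:
        raise ValueError("robust-change rule needs at least 2 groups")
    sample_lists = [list(design.samples_of(g)) for g in groups]
    all_samples = [s for cols in sample_lists for s in cols]
    vals = m.values[all_samples]
    if vals.isna().to_numpy().any():
        raise ValueError("robust-change rule requires a complete matrix on the selected groups")
    med = vals.median(axis=1)
    out = []
    above = [vals[cols].gt(med, axis=0).all(axis=1) for cols in sample_lists]
    below = [vals[cols].lt(med, axis=0).all(axis=1) for cols in sample_lists]
    any_above = np.column_stack([a.to_numpy() for a in above]).any(axis=1)
    any_below = np.column_stack([b.to_numpy() for b in below]).any(axis=1)
    keep = any_above & any_below
    return [str(i) for i in vals.index[keep]]


@dataclass
class ClusterResult:
    """Hierarchically clustered, row-Z-scored abundance matrix."""

    z_matrix: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    cluster_labels: pd.Series
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    @property
    def ordered(self) -> pd.DataFrame:
        return self.z_matrix.loc[self.row_order, self.col_order]


def zscore_hcluster(
    m: LogMatrix | pd.DataFrame,
    subset: Sequence[str] | None = None,
    n_clusters: int | None = None,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Z-score rows and cluster rows and columns agglomeratively.

    Rows are standardized to mean 0 / SD 1; zero-variance rows are excluded
    with a warning (their Z-score is undefined). Rows are pre-sorted
    lexicographically by identifier so the leaf order is deterministic under
    distance ties. ``n_clusters`` cuts the row dendrogram into flat labels.
    """
    values = m.values if isinstance(m, LogMatrix) else m
    if subset is not None:
        values = values.loc[list(subset)]
    if values.empty:
        raise ValueError("empty protein subset")
    if values.isna().to_numpy().any():
        raise ValueError("clustering requires complete rows")
    values = values.sort_index(kind="stable")  # lexicographic tie-break
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"excluding {int(zero_var.sum())} zero-variance row(s) from clustering",
            stacklevel=2,
        )
        values = values[~zero_var]
        arr = arr[~zero_var]
        sd = sd[~zero_var]
    if values.empty:
        raise ValueError("no rows with variance to cluster")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    z_df = pd.DataFrame(z, index=values.index, columns=values.columns)

    if len(z_df) >= 2:
        row_link = linkage(z, method=method, metric=metric)
        row_order = [str(z_df.index[i]) for i in leaves_list(row_link)]
    else:
        row_link = np.empty((0, 4))
        row_order = [str(i) for i in z_df.index]
    if z_df.shape[1] >= 2:
        col_link = linkage(z.T, method=method, metric=metric)
        col_order = [str(z_df.columns[i]) for i in leaves_list(col_link)]
    else:
        col_link = np.empty((0, 4))
        col_order = [str(c) for c in z_df.columns]

    if n_clusters is not None and len(z_df) >= 2:
        labels = fcluster(row_link, t=n_clusters, criterion="maxclust")
    else:
        labels = np.ones(len(z_df), dtype=int)
    return ClusterResult(
        z_matrix=z_df,
        row_order=row_order,
        col_order=col_order,
        cluster_labels=pd.Series(labels, index=z_df.index, name="cluster"),
        row_linkage=row_link,
        col_linkage=col_link,
    )
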