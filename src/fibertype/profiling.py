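"""Fiber-type characterization of protein expression profiles.

Covers MYH-isoform fiber calling from proteotypic peptides, slow/fast
marker tables, the filter -> impute -> group-median -> Z-score -> cluster
chain used for unsupervised profile discovery, per-cluster annotation
percentages, and PCA with loadings for separator inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix import FIBER_TYPES, PeptideMatrix
from .quant import ProteinQuant


# ---------------------------------------------------------------------------
# MYH fiber calling
# ---------------------------------------------------------------------------

@dataclass
class MYHCallTable:
    """Summed proteotypic-peptide intensity per isoform and fiber type.

    ``called_type[isoform]`` is the tuple of fiber types attaining the
    maximal sum — usually a single type, but ties are reported in full
    because hybrid fibers co-express multiple MYH isoforms.
    """

    summed_intensity: pd.DataFrame  # isoform x fiber type
    called_type: dict[str, tuple[str, ...]]

    def call(self, isoform: str) -> str:
        """The unique called type (raises on a tie)."""
        types = self.called_type[isoform]
        if len(types) != 1:
            raise ValueError(f"{isoform}: ambiguous call {types}")
        return types[0]


def myh_fiber_call(
    matrix: PeptideMatrix, isoform_map: dict[str, str] | pd.Series
) -> MYHCallTable:
    """Call each MYH isoform's characteristic fiber type.

    Proteotypic peptide intensities of each isoform are summed over all
    samples of a fiber type; the called type is the argmax over types.
    Isoforms with no observed proteotypic peptide are excluded with a
    warning.
    """
    if matrix.sample_labels is None:
        raise ValueError("sample fiber-type labels are required")
    iso = pd.Series(isoform_map)
    mapping = matrix.peptide_to_protein.loc[matrix.peptides]
    keep = mapping.isin(iso.index) & matrix.proteotypic.loc[matrix.peptides]
    sub = matrix.intensities.loc[keep]
    iso_of_pep = mapping.loc[keep].map(iso)

    by_type = sub.T.groupby(matrix.sample_labels).sum(min_count=1).T
    summed = by_type.groupby(iso_of_pep).sum(min_count=1)

    dropped = set(iso.unique()) - set(summed.index)
    for name in sorted(dropped):
        warnings.warn(f"isoform {name} has no observed proteotypic peptide; excluded")

    called: dict[str, tuple[str, ...]] = {}
    for isoform, row in summed.iterrows():
        obs = row.dropna()
        mx = obs.max()
        called[str(isoform)] = tuple(obs.index[obs == mx])
    # keep the canonical fiber-type column order where applicable
    cols = [t for t in FIBER_TYPES if t in summed.columns] + [
        c for c in summed.columns if c not in FIBER_TYPES
    ]
    return MYHCallTable(summed_intensity=summed[cols].fillna(0.0), called_type=called)


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

def marker_table(
    quant: ProteinQuant,
    markers: dict[str, str] | pd.Series,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-fiber-type percentage summary of slow/fast marker proteins.

    Returns one row per marker with its slow/fast indication and the mean
    (or median) percentage within each fiber type.  Markers absent from the
    data get an all-missing row.  No classification decision is made here.
    """
    if quant.sample_labels is None:
        raise ValueError("sample fiber-type labels are required")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    markers = pd.Series(markers)
    grouped = quant.percent.T.groupby(quant.sample_labels)
    per_type = (grouped.mean() if stat == "mean" else grouped.median()).T

    cols = [t for t in FIBER_TYPES if t in per_type.columns]
    out = pd.DataFrame(index=markers.index, columns=["indicative_for"] + cols,
                       dtype=object)
    out["indicative_for"] = markers
    for prot in markers.index:
        if prot in per_type.index:
            out.loc[prot, cols] = per_type.loc[prot, cols].to_numpy()
    out[cols] = out[cols].astype(float)
    return out


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def filter_valid(matrix: pd.DataFrame, min_valid_fraction: float = 0.5) -> pd.DataFrame:
    """Keep rows observed in at least ``min_valid_fraction`` of samples."""
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    frac = matrix.notna().sum(axis=1) / matrix.shape[1]
    return matrix.loc[frac >= min_valid_fraction]


def impute_downshift(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
    per_sample: bool = True,
) -> pd.DataFrame:
    """Replace missing log2 values with draws from a downshifted normal.

    For each sample column s with observed mean mu_s and standard deviation
    sigma_s, missing cells are drawn from
    Normal(mu_s - downshift * sigma_s, (width * sigma_s)^2) — the standard
    left-censored imputation for label-free proteomics.  With
    ``per_sample=False`` the moments come from the whole matrix instead.
    Observed cells are returned bit-identical.
    """
    if width <= 0 or downshift < 0:
        raise ValueError("width must be positive and downshift non-negative")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    if per_sample:
        for s in out.columns:
            col = out[s]
            obs = col.dropna()
            n_missing = int(col.isna().sum())
            if n_missing == 0:
                continue
            if len(obs) < 2:
                raise ValueError(
                    f"sample {s!r} has {len(obs)} observed values; "
                    "need >= 2 to estimate imputation moments"
                )
            mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
            draws = rng.normal(mu - downshift * sigma, width * sigma, size=n_missing)
            out.loc[col.isna(), s] = draws
    else:
        vals = out.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise ValueError("need >= 2 observed values to estimate moments")
        mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        mask = np.isnan(vals)
        vals[mask] = rng.normal(mu - downshift * sigma, width * sigma,
                                size=int(mask.sum()))
        out = pd.DataFrame(vals, index=out.index, columns=out.columns)
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Partition of proteins into expression-profile clusters."""

    assignment: pd.Series  # protein -> cluster id (1..n_final)
    profiles: pd.DataFrame  # cluster x fiber type, median Z-scores
    sizes: pd.Series  # cluster -> member count


def group_medians(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Median expression per fiber-type group (proteins x types)."""
    med = matrix.T.groupby(labels.loc[matrix.columns]).median().T
    cols = [t for t in FIBER_TYPES if t in med.columns] + [
        c for c in med.columns if c not in FIBER_TYPES
    ]
    return med[cols]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores (population sd); constant rows are dropped."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant row(s) before Z-scoring")
    m = matrix.loc[keep]
    return m.sub(mu[keep], axis=0).div(sd[keep], axis=0)


def cluster_profiles(
    matrix: pd.DataFrame,
    labels: pd.Series,
    k_pre: int = 300,
    max_iter: int = 10,
    n_final: int = 4,
    seed: int = 0,
) -> ClusterResult:
    """Two-stage profile clustering of a filtered + imputed log2 matrix.

    Rows are reduced to per-fiber-type medians and Z-scored, pre-clustered
    with k-means (k = min(k_pre, n_rows), at most ``max_iter`` iterations,
    deterministic k-means++ under ``seed``), and the pre-cluster centroids
    are merged by Euclidean average-linkage hierarchical clustering; the
    tree is cut into ``n_final`` clusters and the assignment propagated back
    to proteins.  When there are no more rows than ``k_pre`` the k-means
    stage degenerates to the identity.
    """
    z = zscore_rows(group_medians(matrix, labels))
    n_rows = z.shape[0]
    if n_final > n_rows:
        raise ValueError(f"n_final={n_final} exceeds number of rows ({n_rows})")

    if n_rows <= k_pre:
        centroids = z.to_numpy()
        membership = np.arange(n_rows)
    else:
        km = KMeans(
            n_clusters=k_pre,
            max_iter=max_iter,
            n_init=1,
            init="k-means++",
            random_state=seed,
        ).fit(z.to_numpy())
        centroids = km.cluster_centers_
        membership = km.labels_
        # retain only non-empty pre-clusters
        used = np.unique(membership)
        remap = {c: i for i, c in enumerate(used)}
        centroids = centroids[used]
        membership = np.array([remap[c] for c in membership])

    if centroids.shape[0] == 1:
        centroid_cluster = np.array([1])
    else:
        tree = linkage(centroids, method="average", metric="euclidean")
        centroid_cluster = fcluster(tree, t=min(n_final, centroids.shape[0]),
                                    criterion="maxclust")

    assignment = pd.Series(centroid_cluster[membership], index=z.index,
                           name="cluster")
    profiles = z.groupby(assignment).median()
    sizes = assignment.value_counts().sort_index()
    sizes.name = "size"
    return ClusterResult(assignment=assignment, profiles=profiles, sizes=sizes)


# ---------------------------------------------------------------------------
# Annotation percentages
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Per-cluster annotation-category composition."""

    counts: pd.DataFrame  # cluster x category, integers
    percent: pd.DataFrame  # cluster x category, % of cluster size (2 decimals)


def annotate_percentages(
    result: ClusterResult, categories: dict[str, str] | pd.Series
) -> AnnotationTable:
    """Category counts and percentages with respect to cluster size.

    Every clustered protein contributes exactly once; proteins without a
    category map to "Other".  Percentages are count / cluster size * 100,
    rounded to 2 decimals for reporting.
    """
    cats = result.assignment.index.to_series().map(pd.Series(categories))
    cats = cats.fillna("Other")
    counts = pd.crosstab(result.assignment, cats)
    counts.index.name = "cluster"
    counts.columns.name = "category"
    percent = counts.div(result.sizes.loc[counts.index], axis=0).mul(100).round(2)
    return AnnotationTable(counts=counts, percent=percent)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_loadings(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample scores and protein loadings of the top principal components.

    ``matrix`` is protein x sample; samples are the observations.  Returns
    (scores: sample x PC, loadings: protein x PC ordered by decreasing
    max |loading|, explained variance per PC).  Missing values must be
    imputed upstream; a matrix without variance raises.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    x = matrix.T.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("PCA input contains missing values; impute first")
    if np.allclose(x, x[0], atol=0):
        raise ValueError("constant matrix: no variance to decompose")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=matrix.columns, columns=pcs)
    loadings = pd.DataFrame(pca.components_.T, index=matrix.index, columns=pcs)
    order = loadings.abs().max(axis=1).sort_values(ascending=False).index
    return scores_df, loadings.loc[order], pca.explained_variance_
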