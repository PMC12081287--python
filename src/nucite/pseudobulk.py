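"""Donor-level pseudobulk aggregation and donor-profile correlation.

Pseudobulk units are donor x cell-type sums of raw gene counts; units
with fewer than 10 member nuclei or fewer than 800 total counts are
dropped (the filters under which donor-level differential testing is
stable). Differential testing itself is delegated to dedicated count
models (e.g. DESeq2); this module exports ready-to-use count tables
with a covariate sheet.

The donor correlation view of a cell type builds normalized-log
profiles, reduces them to principal components (50 by default, with
optional per-batch PC-mean centering standing in for dedicated batch
integration), averages PC coordinates per donor, computes pairwise
Pearson correlations and clusters donors by average linkage on 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import scipy.spatial.distance

from .core_data import NucleusDataset, logger
from .preprocess import center_by_batch, normalize_expression


@dataclass
class PseudobulkTable:
    """Summed raw counts per retained donor x cell-type unit."""

    counts: pd.DataFrame  # units x genes
    unit_meta: pd.DataFrame  # per retained unit: donor, cell type, n_cells, ...
    dropped: pd.DataFrame  # units failing a filter, with reasons


@dataclass
class DonorCorrelation:
    donors: list
    correlation: pd.DataFrame  # symmetric Pearson matrix, diagonal 1
    linkage: np.ndarray  # scipy linkage matrix (average, 1 - r)
    dendrogram_order: list  # donors in dendrogram leaf order


def aggregate_pseudobulk(
    ds: NucleusDataset,
    group_by=("donor_id", "cell_type"),
    min_cells: int = 10,
    min_counts: int = 800,
) -> PseudobulkTable:
    """Sum raw counts per donor x cell-type unit and apply the unit filters.

    Retained units have at least ``min_cells`` member nuclei and at
    least ``min_counts`` total counts; dropped units are reported with
    the failed filters. Unit sums conserve the member nuclei's counts
    exactly.
    """
    group_by = list(group_by)
    for col in group_by:
        if col not in ds.meta.columns:
            raise ValueError(f"grouping column {col!r} missing from metadata")
    keys = ds.meta[group_by].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(keys)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(len(uniques), len(codes)),
    )
    sums = np.asarray((ind @ ds.X).todense())
    n_cells = np.bincount(codes, minlength=len(uniques))
    totals = sums.sum(axis=1)

    meta_rows = pd.DataFrame(
        [u.split("|") for u in uniques], columns=group_by, index=uniques
    )
    meta_rows["n_cells"] = n_cells
    meta_rows["total_counts"] = totals.astype(int)
    ok = (n_cells >= min_cells) & (totals >= min_counts)
    meta_rows["fail_min_cells"] = n_cells < min_cells
    meta_rows["fail_min_counts"] = totals < min_counts

    if not ok.any():
        raise ValueError(
            f"no pseudobulk unit has >= {min_cells} cells and >= "
            f"{min_counts} counts"
        )
    counts = pd.DataFrame(sums, index=uniques, columns=ds.genes)
    retained = counts.loc[ok]
    dropped = meta_rows.loc[~ok]
    if len(dropped):
        logger.info("pseudobulk: dropped %d/%d units", len(dropped), len(uniques))
    return PseudobulkTable(
        counts=retained,
        unit_meta=meta_rows.loc[ok].drop(columns=["fail_min_cells",
                                                  "fail_min_counts"]),
        dropped=dropped,
    )


def deseq_covariates(pb: PseudobulkTable, ds: NucleusDataset) -> pd.DataFrame:
    """Per-unit covariate sheet (disease group, modal batch) for count models."""
    donor_group = ds.meta.groupby("donor_id")["disease_group"].first()
    donor_batch = ds.meta.groupby("donor_id")["batch"].agg(
        lambda s: s.mode().iloc[0]
    )
    cov = pb.unit_meta.copy()
    cov["disease_group"] = cov["donor_id"].map(donor_group)
    cov["batch"] = cov["donor_id"].map(donor_batch)
    return cov


def donor_correlation_matrix(
    ds: NucleusDataset,
    cell_type: str | None = None,
    n_pcs: int = 50,
    min_nuclei: int = 10,
    batch_centering: bool = False,
    target_sum: float = 1e4,
) -> DonorCorrelation:
    """Pearson correlation of donor mean profiles in PC space, with tree.

    Nuclei of the requested cell type are normalized and log-scaled, PCA
    is fit on nuclei (``n_pcs`` components, clamped to the data), PC
    coordinates are optionally centered per batch and averaged per
    donor; donors with fewer than ``min_nuclei`` nuclei are excluded.
    Average-linkage hierarchical clustering runs on the 1 - r distance.
    """
    from sklearn.decomposition import PCA

    if cell_type is not None:
        mask = (ds.meta["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"no nuclei of cell type {cell_type!r}")
        ds = ds.subset_nuclei(mask)
    donor_counts = ds.meta["donor_id"].value_counts()
    eligible = donor_counts[donor_counts >= min_nuclei].index
    if len(eligible) < 3:
        raise ValueError(
            f"only {len(eligible)} donors have >= {min_nuclei} nuclei; "
            "need at least 3"
        )
    ds = ds.subset_nuclei(ds.meta["donor_id"].isin(eligible).to_numpy())

    norm = normalize_expression(ds.X, target_sum=target_sum)
    dense = np.asarray(norm.todense())
    k = min(n_pcs, dense.shape[0] - 1, dense.shape[1])
    if k < n_pcs:
        logger.warning("clamping n_pcs from %d to %d", n_pcs, k)
    pcs = PCA(n_components=k, random_state=0).fit_transform(dense)
    if batch_centering:
        pcs = center_by_batch(pcs, ds.meta["batch"].to_numpy())

    donors = sorted(eligible)
    profiles = np.vstack([
        pcs[(ds.meta["donor_id"] == d).to_numpy()].mean(axis=0) for d in donors
    ])
    corr = np.corrcoef(profiles)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    dist = scipy.spatial.distance.squareform(1.0 - corr, checks=False)
    linkage = sch.linkage(dist, method="average")
    order = [donors[i] for i in sch.leaves_list(linkage)]
    return DonorCorrelation(
        donors=donors,
        correlation=pd.DataFrame(corr, index=donors, columns=donors),
        linkage=linkage,
        dendrogram_order=order,
    )


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(linkage)

    def walk(node):
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"


def cluster_proportions(meta: pd.DataFrame, cluster_labels=None) -> pd.DataFrame:
    """Per-donor proportions of nuclei in each cluster (rows sum to 1).

    ``cluster_labels`` defaults to the ``cluster`` metadata column.
    Donors with zero nuclei never appear (there is no row to form).
    """
    labels = (
        meta["cluster"] if cluster_labels is None else pd.Series(
            np.asarray(cluster_labels), index=meta.index)
    )
    if labels.isna().any():
        raise ValueError("every nucleus needs a cluster label")
    tab = pd.crosstab(meta["donor_id"], labels)
    return tab.div(tab.sum(axis=1), axis=0)
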