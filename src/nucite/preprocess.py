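"""Nucleus/gene QC, expression normalization, variable genes, clustering.

QC thresholds follow the analysis conventions of mixed protein+RNA
single-nucleus cohorts: nuclei must express at least 50 genes, carry at
most 5% mitochondrial counts, at most 4,000 hashtag counts and (when the
antibody modality is present) at most 3,000 TDP-43 antibody counts;
genes must be detected in at least 5 nuclei. Expression is depth-
normalized to a fixed target sum and ln(x+1)-scaled. Variable genes use
the Seurat-style binned normalized dispersion. Embedding/clustering is
PCA -> kNN graph -> Leiden, with optional per-batch PC-mean centering
standing in for dedicated batch integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import NucleusDataset, logger

MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    min_genes_per_nucleus: int = 50
    min_cells_per_gene: int = 5
    max_mito_fraction: float = 0.05
    max_hashtag_counts: int = 4000
    max_tdp43_ab_counts: int = 3000

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class HVGParams:
    min_mean: float = 0.0015
    max_mean: float = 0.18
    min_disp: float = 0.30
    n_bins: int = 20

    def __post_init__(self):
        if not self.min_mean < self.max_mean:
            raise ValueError("min_mean must be < max_mean")


def _nucleus_qc_mask(ds: NucleusDataset, thr: QCThresholds, tdp43_antibody: str):
    """Boolean keep-mask per nucleus plus per-rule removal tallies."""
    X = ds.X
    genes_detected = X.getnnz(axis=1)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_cols = [i for i, g in enumerate(ds.genes) if g.startswith(MITO_PREFIX)]
    if mito_cols:
        mito = np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
        mito_frac = np.divide(mito, total, out=np.zeros_like(mito, dtype=float),
                              where=total > 0)
    else:
        mito_frac = np.zeros(ds.n_nuclei)
    hashtag = ds.meta["hashtag_counts"].to_numpy()

    fails = {
        "min_genes": genes_detected < thr.min_genes_per_nucleus,
        "mito_fraction": mito_frac > thr.max_mito_fraction,
        "hashtag_counts": hashtag > thr.max_hashtag_counts,
    }
    if tdp43_antibody in ds.antibodies:
        tdp = ds.A[:, ds.antibodies.index(tdp43_antibody)]
        fails["tdp43_antibody"] = tdp > thr.max_tdp43_ab_counts
    keep = ~np.logical_or.reduce(list(fails.values()))
    tallies = {rule: int(m.sum()) for rule, m in fails.items()}
    return keep, tallies


def qc_filter(
    ds: NucleusDataset,
    thr: QCThresholds | None = None,
    tdp43_antibody: str = "TDP43",
):
    """Apply nucleus- and gene-level QC; return (filtered dataset, report).

    Nuclei failing any rule are removed; genes detected in fewer than
    ``min_cells_per_gene`` of the remaining nuclei are removed. Nucleus
    and gene filters are iterated to a fixed point so a second
    application removes nothing. The TDP-43 antibody rule applies only
    when that antibody is in the panel.
    """
    if thr is None:
        thr = QCThresholds()
    report: dict[str, int] = {}
    current = ds
    first = True
    while True:
        keep_n, tallies = _nucleus_qc_mask(current, thr, tdp43_antibody)
        if first:
            report.update(tallies)
        removed_nuclei = int((~keep_n).sum())
        if removed_nuclei:
            current = current.subset_nuclei(keep_n)
        if current.n_nuclei == 0:
            raise ValueError(
                f"all nuclei removed by QC; per-rule failure counts: {report}"
            )
        detected_in = current.X.getnnz(axis=0)
        keep_g = detected_in >= thr.min_cells_per_gene
        removed_genes = int((~keep_g).sum())
        if first:
            report["min_cells_per_gene"] = removed_genes
            first = False
        if removed_genes:
            current = current.subset_genes(keep_g)
        if current.X.shape[1] == 0:
            raise ValueError("all genes removed by QC")
        if not removed_nuclei and not removed_genes:
            break
    report["n_nuclei_kept"] = current.n_nuclei
    report["n_genes_kept"] = len(current.genes)
    logger.info("qc_filter: %s", report)
    report_df = pd.DataFrame(
        {"rule": list(report), "count": list(report.values())}
    )
    return current, report_df


def normalize_expression(X, target_sum: float = 1e4) -> sp.csr_matrix:
    """Depth-normalize each nucleus to ``target_sum`` counts, then ln(x+1).

    Zeros are preserved (ln(0+1) = 0) and each nucleus's pre-log values
    sum to ``target_sum``, making profiles comparable across depth.
    """
    X = sp.csr_matrix(X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} nuclei have zero total counts; run QC first")
    scaled = sp.diags(target_sum / totals) @ X
    return scaled.log1p().tocsr()


def select_variable_genes(norm_X, genes, params: HVGParams | None = None):
    """Select highly variable genes on log-normalized data.

    Seurat-flavor recipe: per-gene mean and dispersion on the expm1
    scale, dispersion z-scored within ``n_bins`` mean bins; keep genes
    with mean inside ``(min_mean, max_mean)`` and normalized dispersion
    above ``min_disp``. Delegated to scanpy's implementation of that
    recipe. Returns (boolean mask over genes, list of selected names).
    """
    import anndata as ad
    import scanpy as sc

    if params is None:
        params = HVGParams()
    adata = ad.AnnData(
        X=sp.csr_matrix(norm_X),
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata,
            flavor="seurat",
            min_mean=params.min_mean,
            max_mean=params.max_mean,
            min_disp=params.min_disp,
            n_bins=params.n_bins,
        )
    mask = adata.var["highly_variable"].to_numpy()
    if mask.sum() < 2:
        raise ValueError(
            f"only {int(mask.sum())} variable genes pass the thresholds"
        )
    return mask, [g for g, m in zip(genes, mask) if m]


def embed_and_cluster(
    norm_X,
    hvg_mask=None,
    n_pcs: int = 40,
    k: int = 10,
    resolution: float = 0.8,
    batch=None,
    batch_center: bool = False,
    random_state: int = 0,
):
    """PCA -> kNN graph -> Leiden clustering; first two PCs as 2-D embedding.

    ``n_pcs`` is clamped (with a warning) when it exceeds what the data
    supports. ``batch_center=True`` subtracts per-batch PC means, a
    simple stand-in for dedicated batch integration. Returns
    ``(embedding (n, 2), labels (n,), pcs (n, n_pcs))``.
    """
    import anndata as ad
    import scanpy as sc

    norm_X = sp.csr_matrix(norm_X)
    n = norm_X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nuclei ({n})")
    if hvg_mask is not None:
        norm_X = norm_X[:, np.asarray(hvg_mask, dtype=bool)]
    max_pcs = min(n - 1, norm_X.shape[1] - 1)
    if n_pcs > max_pcs:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds data rank bound; clamping to {max_pcs}"
        )
        n_pcs = max_pcs
    adata = ad.AnnData(X=norm_X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.pca(adata, n_comps=n_pcs, random_state=random_state)
        pcs = adata.obsm["X_pca"]
        if batch_center:
            if batch is None:
                raise ValueError("batch labels required for batch_center")
            pcs = center_by_batch(pcs, batch)
            adata.obsm["X_pca"] = pcs
        sc.pp.neighbors(adata, n_neighbors=k, n_pcs=n_pcs, random_state=random_state)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=random_state,
            flavor="leidenalg",
        )
    labels = adata.obs["leiden"].to_numpy()
    return pcs[:, :2].copy(), labels, pcs


def center_by_batch(pcs: np.ndarray, batch) -> np.ndarray:
    """Subtract per-batch means from PC coordinates."""
    pcs = np.asarray(pcs, dtype=float).copy()
    batch = np.asarray(batch)
    for b in np.unique(batch):
        m = batch == b
        pcs[m] -= pcs[m].mean(axis=0)
    return pcs
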