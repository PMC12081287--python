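"""Two-step residual regression linking nuclear protein to transcripts.

Step 1 regresses each gene's log-normalized expression on technical
covariates — gene ~ log_ncounts + log_hashtag_counts + C(batch) — by
ordinary least squares and keeps the residuals; genes expressed in
fewer than 25 nuclei are skipped. Step 2 regresses those residuals on
the nCLR protein values (all panel proteins jointly by default, or one
at a time), with a two-sided t-test per coefficient and
Benjamini-Hochberg adjustment across all gene x protein tests in one
family (FDR 0.05 by default).

By default the protein columns are themselves residualized on the
step-1 covariates first, so the two-step coefficients coincide with the
coefficients of a single joint regression (Frisch-Waugh-Lovell); a
``residualize_proteins=False`` mode reproduces the literal two-step
procedure.

Enrichment of an external gene set (e.g. CLIP-derived TDP-43 targets)
among the signed associations is assessed with a two-sided Fisher exact
test on the 2x2 overlap table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_data import GeneSet, logger

DEFAULT_COVARIATES = ("log_ncounts", "log_hashtag_counts", "batch")
MIN_NUCLEI_PER_GENE = 25


@dataclass
class EnrichmentResult:
    """2x2 overlap table with Fisher exact test."""

    odds_ratio: float
    p_value: float
    table: np.ndarray  # [[in-set & assoc, assoc only], [in-set only, neither]]


# ---------------------------------------------------------------------------
# design construction and step 1
# ---------------------------------------------------------------------------


def build_design(
    meta: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Intercept + numeric covariates + one-hot batch (first level dropped).

    Collinear columns are dropped with a warning (e.g. a batch indicator
    when only one batch is present).
    """
    cols = {"intercept": np.ones(len(meta))}
    for cov in covariates:
        if cov == "batch":
            dummies = pd.get_dummies(meta["batch"].astype(str), prefix="batch",
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            if cov not in meta.columns:
                raise ValueError(f"covariate {cov!r} missing from metadata")
            cols[cov] = meta[cov].to_numpy(dtype=float)
    D = pd.DataFrame(cols, index=meta.index)
    # drop collinear columns, keeping the earliest ones
    keep, rank = [], 0
    for j in range(D.shape[1]):
        r = np.linalg.matrix_rank(D.iloc[:, keep + [j]].to_numpy())
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < D.shape[1]:
        dropped = [c for i, c in enumerate(D.columns) if i not in keep]
        warnings.warn(f"dropping collinear design columns: {dropped}")
        D = D.iloc[:, keep]
    return D


def _ols_residuals(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on the design D (via thin QR)."""
    Q, _ = np.linalg.qr(D)
    return Y - Q @ (Q.T @ Y)


def add_model_covariates(meta: pd.DataFrame, total_counts=None) -> pd.DataFrame:
    """Attach log_ncounts and log_hashtag_counts columns to metadata."""
    meta = meta.copy()
    tc = meta["total_counts"].to_numpy(float) if total_counts is None else np.asarray(total_counts, float)
    if (tc <= 0).any():
        raise ValueError("log_ncounts undefined for nuclei with zero counts")
    meta["log_ncounts"] = np.log(tc)
    ht = meta["hashtag_counts"].to_numpy(float)
    meta["log_hashtag_counts"] = np.log(np.maximum(ht, 1.0))
    return meta


def residualize_expression(
    norm_X,
    meta: pd.DataFrame,
    genes,
    covariates=DEFAULT_COVARIATES,
    min_nuclei: int = MIN_NUCLEI_PER_GENE,
):
    """Step 1: per-gene OLS residuals against the technical covariates.

    Genes expressed (nonzero) in fewer than ``min_nuclei`` nuclei are
    skipped. Returns ``(residuals DataFrame nuclei x kept genes,
    n_expressed Series, design DataFrame)``.
    """
    norm_X = sp.csr_matrix(norm_X)
    n_expressed = pd.Series(norm_X.getnnz(axis=0), index=list(genes))
    keep = n_expressed >= min_nuclei
    if not keep.any():
        raise ValueError(f"no gene is expressed in >= {min_nuclei} nuclei")
    D = build_design(meta, covariates)
    Y = np.asarray(norm_X[:, np.flatnonzero(keep.to_numpy())].todense(), dtype=float)
    resid = _ols_residuals(D.to_numpy(), Y)
    logger.info(
        "residualize_expression: kept %d/%d genes (>= %d nuclei), "
        "%d design columns",
        int(keep.sum()), len(n_expressed), min_nuclei, D.shape[1],
    )
    residuals = pd.DataFrame(
        resid, index=meta.index, columns=n_expressed.index[keep]
    )
    return residuals, n_expressed[keep], D


# ---------------------------------------------------------------------------
# step 2: protein fit with BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _fit_block(R: np.ndarray, Z: np.ndarray, dof: int):
    """OLS of every residual column on Z; returns (beta, t) per column.

    Z includes an intercept column; only the non-intercept coefficients
    are returned. ``dof`` is the residual degrees of freedom of the full
    (covariates + proteins) model.
    """
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    beta = ZtZ_inv @ (Z.T @ R)  # (k, g)
    fitted = Z @ beta
    rss = ((R - fitted) ** 2).sum(axis=0)
    sigma2 = rss / dof
    se = np.sqrt(np.outer(np.diag(ZtZ_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return beta[1:], t[1:]


def fit_protein_associations(
    residuals: pd.DataFrame,
    nclr: pd.DataFrame,
    proteins=None,
    mode: str = "joint",
    residualize_proteins: bool = True,
    design: pd.DataFrame | None = None,
    n_expressed: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Step 2: regress step-1 residuals on nCLR protein levels.

    Parameters
    ----------
    residuals, nclr
        Nuclei-aligned outputs of step 1 and of the protein
        quantification (reference antibody excluded automatically if its
        nCLR column is constant-zero).
    proteins
        Subset of nCLR columns to model; default: all non-reference.
    mode
        ``"joint"`` fits all selected proteins in one regression per
        gene; ``"single"`` fits one protein at a time.
    residualize_proteins
        Project the protein columns off the step-1 covariates first so
        the Frisch-Waugh-Lovell identity with the joint regression
        holds; requires ``design``.
    n_expressed
        Per-gene nucleus counts from step 1, reported as
        ``n_nuclei_used``.

    Returns
    -------
    DataFrame with one row per gene x protein: coefficient, t_stat,
    p_value, q_value (BH across all rows), significant (q < fdr),
    n_nuclei_used.
    """
    if mode not in {"joint", "single"}:
        raise ValueError(f"mode must be 'joint' or 'single', got {mode!r}")
    if list(residuals.index) != list(nclr.index):
        raise ValueError("residuals and nclr are not aligned on nuclei")
    if proteins is None:
        proteins = [
            p for p in nclr.columns if not np.allclose(nclr[p].to_numpy(), 0)
        ]
    P = nclr[list(proteins)].to_numpy(dtype=float)
    if (P.std(axis=0) == 0).any():
        const = [p for p, s in zip(proteins, P.std(axis=0)) if s == 0]
        raise ValueError(f"constant protein columns: {const}")

    n = len(residuals)
    k_cov = 0
    if residualize_proteins:
        if design is None:
            raise ValueError("residualize_proteins=True requires the design")
        Dm = design.to_numpy(dtype=float)
        P = _ols_residuals(Dm, P)
        k_cov = np.linalg.matrix_rank(Dm)
    R = residuals.to_numpy(dtype=float)
    genes = list(residuals.columns)

    records = []
    if mode == "joint":
        groups = [list(range(len(proteins)))]
    else:
        groups = [[j] for j in range(len(proteins))]
    for cols in groups:
        Z = np.column_stack([np.ones(n), P[:, cols]])
        dof = n - k_cov - len(cols) - 1
        if dof <= 0:
            raise ValueError("not enough nuclei for the requested model")
        beta, t = _fit_block(R, Z, dof)
        pvals = 2 * scipy.stats.t.sf(np.abs(t), dof)
        for row, j in enumerate(cols):
            for gi, gene in enumerate(genes):
                records.append(
                    (gene, proteins[j], beta[row, gi], t[row, gi], pvals[row, gi])
                )
    table = pd.DataFrame(
        records, columns=["gene", "protein", "coefficient", "t_stat", "p_value"]
    )
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < fdr
    if n_expressed is not None:
        table["n_nuclei_used"] = table["gene"].map(n_expressed).astype(int)
    else:
        table["n_nuclei_used"] = n
    return table


def significant_genes(table: pd.DataFrame, protein: str, sign: int = 0) -> set:
    """Genes significantly associated with ``protein``; sign>0/<0 filters by
    coefficient sign."""
    sub = table[(table["protein"] == protein) & table["significant"]]
    if sign > 0:
        sub = sub[sub["coefficient"] > 0]
    elif sign < 0:
        sub = sub[sub["coefficient"] < 0]
    return set(sub["gene"])


def run_two_step_pipeline(
    ds,
    min_nuclei: int = MIN_NUCLEI_PER_GENE,
    mode: str = "joint",
    fdr: float = 0.05,
    qc: bool = True,
) -> pd.DataFrame:
    """QC -> normalize -> residualize -> nCLR -> protein fit, in one call.

    Convenience wrapper running the full association workflow on an
    assembled dataset; returns the gene x protein association table.
    """
    from .preprocess import normalize_expression, qc_filter
    from .protein_quant import quantify_proteins

    if qc:
        ds, _ = qc_filter(ds)
    norm = normalize_expression(ds.X)
    meta = add_model_covariates(ds.meta, ds.total_counts)
    residuals, n_expr, design = residualize_expression(
        norm, meta, ds.genes, min_nuclei=min_nuclei
    )
    levels = quantify_proteins(ds.antibody_frame(), ds.reference_antibody)
    nclr = levels.nclr.drop(columns=[ds.reference_antibody])
    return fit_protein_associations(
        residuals, nclr, mode=mode, design=design, n_expressed=n_expr, fdr=fdr
    )


# ---------------------------------------------------------------------------
# gene-set overlap
# ---------------------------------------------------------------------------


def overlap_enrichment(assoc_genes, target_set, universe) -> EnrichmentResult:
    """Fisher exact test for overlap of associated genes with a target set.

    Builds the 2x2 table (associated vs rest) x (in target set vs not)
    over ``universe`` (the tested genes) and returns the sample odds
    ratio a*d/(b*c) with the two-sided exact p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    members = target_set.members if isinstance(target_set, GeneSet) else set(target_set)
    assoc = set(assoc_genes) & universe
    target = members & universe
    a = len(assoc & target)
    b = len(assoc - target)
    c = len(target - assoc)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return EnrichmentResult(odds_ratio=float(odds), p_value=float(p), table=table)


def gene_set_overlap_pct(set_a, set_b) -> float:
    """Percent overlap: 100 * |A n B| / |A u B| (Jaccard index x 100)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return 100.0 * len(a & b) / len(a | b)
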