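"""Core data model for joint nuclear protein + snRNA-seq analysis.

A :class:`NucleusDataset` holds three aligned pieces keyed by nucleus
barcode: a sparse gene-count matrix, a (small, dense) antibody-capture
count matrix whose panel must contain exactly one designated reference
antibody (histone H3 by default), and a per-nucleus metadata table
(donor, disease group, 10x-well batch, hashtag counts, ...).

Orientation convention: **nuclei are rows** in every in-memory matrix.
On disk the bundles follow the 10x convention (features as MatrixMarket
rows, barcodes as columns).
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("nucite")

#: disease groups recognised in nucleus metadata
DISEASE_GROUPS = ("young", "aged", "AD", "ALS", "FTD")

#: metadata columns every assembled dataset must provide
REQUIRED_META_COLUMNS = ("donor_id", "disease_group", "batch", "hashtag_counts")

#: default name of the reference antibody used as per-nucleus denominator
DEFAULT_REFERENCE_ANTIBODY = "H3"


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named set of gene symbols."""

    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        self.members = frozenset(self.members)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a tab-separated file, one set per line.

    The first field is the set name; the remaining fields are members.
    Empty fields (as produced by trailing tabs) are ignored.
    """
    sets = []
    for line in Path(path).read_text().splitlines():
        fields = [f for f in line.rstrip("\n").split("\t") if f]
        if not fields:
            continue
        if len(fields) < 2:
            raise ValueError(f"gene set line {fields[0]!r} has no members")
        sets.append(GeneSet(fields[0], frozenset(fields[1:])))
    return sets


@dataclass
class NucleusDataset:
    """Aligned gene counts, antibody counts and metadata for a set of nuclei.

    Attributes
    ----------
    barcodes
        Unique nucleus identifiers; the row order of ``X``, ``A`` and ``meta``.
    genes
        Gene symbols (columns of ``X``).
    antibodies
        Antibody names (columns of ``A``); must contain ``reference_antibody``.
    X
        Sparse non-negative integer count matrix, nuclei x genes.
    A
        Dense non-negative integer count matrix, nuclei x antibodies.
    meta
        Per-nucleus metadata indexed by barcode, with at least the columns in
        :data:`REQUIRED_META_COLUMNS`.
    """

    barcodes: list
    genes: list
    antibodies: list
    X: sp.csr_matrix
    A: np.ndarray
    meta: pd.DataFrame
    reference_antibody: str = DEFAULT_REFERENCE_ANTIBODY

    def __post_init__(self):
        self.validate()

    # -- consistency -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.barcodes)
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes are not unique")
        if self.X.shape != (n, len(self.genes)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"{n} barcodes x {len(self.genes)} genes"
            )
        if self.A.shape != (n, len(self.antibodies)):
            raise ValueError(
                f"A shape {self.A.shape} does not match "
                f"{n} barcodes x {len(self.antibodies)} antibodies"
            )
        if list(self.meta.index) != list(self.barcodes):
            raise ValueError("meta index does not match barcodes")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing required columns: {missing}")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("gene counts must be non-negative")
        if self.A.size and self.A.min() < 0:
            raise ValueError("antibody counts must be non-negative")
        if self.antibodies.count(self.reference_antibody) != 1:
            raise ValueError(
                f"antibody panel must contain exactly one reference antibody "
                f"{self.reference_antibody!r}; panel is {self.antibodies}"
            )
        bad = set(self.meta["disease_group"]) - set(DISEASE_GROUPS)
        if bad:
            raise ValueError(f"unknown disease_group values: {sorted(bad)}")

    # -- derived views -----------------------------------------------------
    @property
    def n_nuclei(self) -> int:
        return len(self.barcodes)

    @property
    def total_counts(self) -> np.ndarray:
        """Per-nucleus gene-count sum."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def antibody_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.barcodes, columns=self.antibodies)

    def log_ncounts(self) -> np.ndarray:
        """ln(total gene counts); defined only for nuclei with counts > 0."""
        tc = self.total_counts
        if (tc <= 0).any():
            raise ValueError("log_ncounts undefined for nuclei with zero counts")
        return np.log(tc)

    def subset_nuclei(self, mask_or_index) -> "NucleusDataset":
        """Return a new dataset restricted to the given nuclei (mask or positions)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        barcodes = [self.barcodes[i] for i in idx]
        return NucleusDataset(
            barcodes=barcodes,
            genes=list(self.genes),
            antibodies=list(self.antibodies),
            X=self.X[idx],
            A=self.A[idx],
            meta=self.meta.iloc[idx],
            reference_antibody=self.reference_antibody,
        )

    def subset_genes(self, mask_or_index) -> "NucleusDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NucleusDataset(
            barcodes=list(self.barcodes),
            genes=[self.genes[i] for i in idx],
            antibodies=list(self.antibodies),
            X=self.X[:, idx].tocsr(),
            A=self.A,
            meta=self.meta,
            reference_antibody=self.reference_antibody,
        )


# ---------------------------------------------------------------------------
# bundle I/O (MatrixMarket + TSV, 10x convention on disk)
# ---------------------------------------------------------------------------


def _find_bundle_file(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"bundle file {stem}(.gz) not found in {dir_path}"
    )


def _read_tsv_column(path: Path) -> list:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_matrix_bundle(dir_path: str | Path, modality: str = "expression"):
    """Read a matrix.mtx / barcodes.tsv / features.tsv bundle.

    Parameters
    ----------
    dir_path
        Directory containing ``matrix.mtx(.gz)``, ``barcodes.tsv(.gz)`` and
        ``features.tsv(.gz)``. On disk the matrix is features x barcodes.
    modality
        ``"expression"`` or ``"antibody"``; recorded for error messages only.

    Returns
    -------
    matrix : scipy.sparse.csr_matrix
        Counts with **nuclei as rows** and features as columns.
    barcodes, features : list of str
    """
    if modality not in {"expression", "antibody"}:
        raise ValueError(f"unknown modality {modality!r}")
    dir_path = Path(dir_path)
    mtx_path = _find_bundle_file(dir_path, "matrix.mtx")
    barcodes = _read_tsv_column(_find_bundle_file(dir_path, "barcodes.tsv"))
    features = _read_tsv_column(_find_bundle_file(dir_path, "features.tsv"))
    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
    else:
        mat = scipy.io.mmread(mtx_path)
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{modality} bundle in {dir_path}: matrix is {mat.shape} but "
            f"features/barcodes declare {(len(features), len(barcodes))}"
        )
    return mat.T.tocsr(), barcodes, features


def write_matrix_bundle(matrix, barcodes, features, dir_path: str | Path) -> None:
    """Write a nuclei x features matrix as a 10x-style bundle.

    The matrix is transposed to features x barcodes on disk so that the
    bundle round-trips through :func:`read_matrix_bundle`.
    """
    matrix = sp.csr_matrix(matrix)
    if matrix.nnz and matrix.data.min() < 0:
        raise ValueError("matrix must be non-negative")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode labels")
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature labels")
    if matrix.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match label lengths "
            f"{(len(barcodes), len(features))}"
        )
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dir_path / "matrix.mtx", sp.coo_matrix(matrix.T))
    (dir_path / "barcodes.tsv").write_text(
        "".join(b + "\n" for b in barcodes)
    )
    (dir_path / "features.tsv").write_text(
        "".join(f + "\n" for f in features)
    )


def read_meta_csv(path: str | Path) -> pd.DataFrame:
    """Read per-nucleus metadata; the first column must be the barcode."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def assemble_dataset(
    expr_bundle: str | Path,
    ab_bundle: str | Path,
    meta_csv: str | Path,
    reference_antibody: str = DEFAULT_REFERENCE_ANTIBODY,
) -> NucleusDataset:
    """Join expression, antibody and metadata sources on their common barcodes.

    The dataset is restricted to the barcode intersection (order taken from
    the expression bundle); the intersection size is logged. Barcode joins
    are exact string matches.
    """
    X, expr_bc, genes = read_matrix_bundle(expr_bundle, "expression")
    A, ab_bc, antibodies = read_matrix_bundle(ab_bundle, "antibody")
    meta = read_meta_csv(meta_csv)

    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV is missing required columns: {missing}")
    if reference_antibody not in antibodies:
        raise ValueError(
            f"reference antibody {reference_antibody!r} absent from panel "
            f"{antibodies}"
        )

    common = set(expr_bc) & set(ab_bc) & set(meta.index)
    if not common:
        raise ValueError("no barcode shared by expression, antibody and metadata")
    order = [b for b in expr_bc if b in common]
    logger.info(
        "assemble: %d/%d expression, %d antibody, %d metadata barcodes -> "
        "%d in intersection",
        len(order), len(expr_bc), len(ab_bc), len(meta), len(order),
    )

    expr_pos = {b: i for i, b in enumerate(expr_bc)}
    ab_pos = {b: i for i, b in enumerate(ab_bc)}
    xi = [expr_pos[b] for b in order]
    ai = [ab_pos[b] for b in order]

    meta = meta.loc[order].copy()
    X = X[xi]
    if "total_counts" not in meta.columns:
        meta["total_counts"] = np.asarray(X.sum(axis=1)).ravel().astype(int)

    return NucleusDataset(
        barcodes=order,
        genes=genes,
        antibodies=antibodies,
        X=X,
        A=np.asarray(A[ai].todense()).astype(np.int64),
        meta=meta,
        reference_antibody=reference_antibody,
    )


def write_dataset_bundle(ds: NucleusDataset, out_dir: str | Path) -> None:
    """Write a dataset as expr/ and adt/ bundles plus meta.csv."""
    out_dir = Path(out_dir)
    write_matrix_bundle(ds.X, ds.barcodes, ds.genes, out_dir / "expr")
    write_matrix_bundle(
        sp.csr_matrix(ds.A), ds.barcodes, ds.antibodies, out_dir / "adt"
    )
    ds.meta.to_csv(out_dir / "meta.csv", index_label="barcode")
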