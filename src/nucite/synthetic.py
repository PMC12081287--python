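"""Synthetic multi-donor cohort generator with ground truth.

Emulates the statistical structure of an intranuclear CITE-seq cohort:
donors spanning young/aged/AD/ALS/FTD groups pooled across 10x-well
batches; latent nuclear protein levels (log scale) with disease-dependent
shifts in a reactive capillary cluster; antibody capture counts subject to
a per-nucleus capture-efficiency scalar shared across the whole panel
(including the histone H3 reference, which is what reference
normalization cancels); and gene counts whose log-mean depends linearly
on latent protein through a sparse effect table, on sequencing depth and
on batch.

Both modalities are drawn negative-binomially (gamma-Poisson). The
emitted :class:`~nucite.core_data.NucleusDataset` is accompanied by a
:class:`SyntheticTruth` carrying the latent protein matrix and the true
gene-protein effect sizes for recovery and calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import DEFAULT_REFERENCE_ANTIBODY, NucleusDataset, logger

DISEASE = ("AD", "ALS", "FTD")

_AGE_RANGES = {
    "young": (15, 29),
    "aged": (67, 95),
    "AD": (65, 95),
    "ALS": (45, 75),
    "FTD": (45, 70),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are a desk-scale mirror of a multi-donor brain cohort: five
    disease groups, donors pooled so every batch mixes groups, negative-
    binomial nuclei counts per donor, ~2,000 gene counts per nucleus and
    a four-antibody panel including the H3 reference.
    """

    n_donors_per_group: int = 4
    groups: tuple = ("young", "aged", "AD", "ALS", "FTD")
    nuclei_per_donor_mean: float = 250.0
    nuclei_per_donor_shape: float = 5.0  # NB shape; var = mu + mu^2/shape
    n_genes: int = 500
    n_batches: int = 4
    panel: tuple = (DEFAULT_REFERENCE_ANTIBODY, "TDP43", "p65", "beta-catenin")
    reference_antibody: str = DEFAULT_REFERENCE_ANTIBODY
    #: gene -> (protein, beta_true); log-mean expression shifts by beta per
    #: unit of latent protein
    effect_table: dict = field(default_factory=dict)
    #: fixed baseline log relative expression for planted-effect genes
    #: (other genes draw theirs at random); a fixed, well-expressed
    #: baseline keeps the planted effect measurable and the recovery
    #: estimand stable across simulation replicates. None: draw at random.
    effect_gene_alpha: float | None = 2.0
    capture_efficiency_sd: float = 0.35  # log-normal sigma of per-nucleus scalar
    depth_mean: float = 2000.0
    depth_sd: float = 0.30  # log-normal sigma of per-nucleus depth factor
    nb_shape: float = 10.0  # gene-count NB shape (inverse overdispersion)
    ab_nb_shape: float = 10.0  # antibody-count NB shape
    ab_ref_mean: float = 200.0  # expected H3 counts at capture efficiency 1
    ab_protein_mean: float = 100.0  # baseline expected counts, other antibodies
    protein_lsd: float = 1.0  # SD of latent protein (log scale) across nuclei
    h3_lsd: float = 0.05  # residual variation of the H3 latent level
    #: latent shift (log scale) applied to reactive-cluster nuclei of
    #: disease donors, per protein
    reactive_protein_shifts: dict = field(
        default_factory=lambda: {"TDP43": -1.0, "beta-catenin": -0.5, "p65": 0.25}
    )
    reactive_fraction_disease: float = 0.6
    reactive_fraction_healthy: float = 0.15
    batch_gene_sd: float = 0.10  # SD of per-(batch, gene) log-mean offsets
    n_mito_genes: int = 10
    mito_mean_fraction: float = 0.02
    high_mito_fraction: float = 0.02  # nuclei drawn from a >5% mito regime
    hashtag_median: float = 800.0
    hashtag_sd: float = 0.5  # log-normal sigma
    high_hashtag_fraction: float = 0.02  # nuclei exceeding the 4,000 QC bound
    shallow_fraction: float = 0.01  # nuclei with too few detected genes
    shallow_depth: float = 30.0
    count_noise: bool = True  # False: emit rounded NB means (limit case)
    seed: int = 0

    def __post_init__(self):
        if self.n_donors_per_group < 1 or self.n_genes < 1 or self.n_batches < 1:
            raise ValueError("all sizes must be >= 1")
        if not self.groups:
            raise ValueError("at least one disease group is required")
        if self.reference_antibody not in self.panel:
            raise ValueError("panel must include the reference antibody")
        if self.capture_efficiency_sd < 0:
            raise ValueError("capture_efficiency_sd must be non-negative")
        for gene, (protein, beta) in self.effect_table.items():
            if protein not in self.panel or protein == self.reference_antibody:
                raise ValueError(
                    f"effect for {gene} targets unknown/reference protein "
                    f"{protein!r}"
                )
            if not np.isfinite(beta):
                raise ValueError(f"beta_true for {gene} is not finite")

    def gene_names(self) -> list:
        n_reg = self.n_genes - self.n_mito_genes
        names = [f"G{i:04d}" for i in range(n_reg)]
        names += [f"MT-{j}" for j in range(1, self.n_mito_genes + 1)]
        return names


def default_effect_table() -> dict:
    """A small planted effect table: TDP43-, p65- and beta-catenin-driven genes."""
    table = {}
    for i, beta in enumerate([1.0, 1.0, 0.5, -0.5, -1.0, -1.0]):
        table[f"G{i:04d}"] = ("TDP43", beta)
    table["G0006"] = ("p65", 0.5)
    table["G0007"] = ("p65", -0.5)
    table["G0008"] = ("beta-catenin", 0.5)
    table["G0009"] = ("beta-catenin", -0.5)
    return table


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    L: pd.DataFrame  # nuclei x proteins, latent log levels
    beta_true: pd.DataFrame  # genes x proteins, mostly zero
    donor_table: pd.DataFrame
    meta: pd.DataFrame
    capture_efficiency: np.ndarray  # per-nucleus scalar c_i
    depth_factors: np.ndarray  # per-nucleus expected total counts


# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the donor table and per-nucleus metadata skeleton.

    Donors are interleaved across groups and assigned round-robin to
    batches so that every batch mixes disease groups, mirroring pooled
    10x reactions. Nuclei counts per donor are negative binomial.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    donors = []
    for d in range(config.n_donors_per_group):
        for g in config.groups:
            lo, hi = _AGE_RANGES[g]
            donors.append(
                {
                    "donor_id": f"{g}_{d:02d}",
                    "disease_group": g,
                    "age": int(rng.integers(lo, hi + 1)),
                }
            )
    donor_table = pd.DataFrame(donors)
    donor_table["batch"] = [
        f"batch{i % config.n_batches}" for i in range(len(donor_table))
    ]

    mu, shape = config.nuclei_per_donor_mean, config.nuclei_per_donor_shape
    n_nuclei = rng.negative_binomial(shape, shape / (shape + mu), len(donor_table))
    n_nuclei = np.maximum(n_nuclei, 1)

    rows = []
    for (_, donor), n in zip(donor_table.iterrows(), n_nuclei):
        frac = (
            config.reactive_fraction_disease
            if donor.disease_group in DISEASE
            else config.reactive_fraction_healthy
        )
        reactive = rng.random(n) < frac
        for j in range(n):
            rows.append(
                {
                    "donor_id": donor.donor_id,
                    "disease_group": donor.disease_group,
                    "batch": donor.batch,
                    "age": donor.age,
                    "cell_type": "capillary",
                    "cluster": "REV1" if reactive[j] else "HC",
                }
            )
    meta = pd.DataFrame(rows)
    meta.index = pd.Index([f"N{i:06d}" for i in range(len(meta))], name="barcode")
    return donor_table, meta


# ---------------------------------------------------------------------------
# latent protein and antibody counts
# ---------------------------------------------------------------------------


def simulate_latent_protein(
    meta: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent nuclear protein levels on the natural-log scale.

    The H3 reference is constant across nuclei up to small noise; other
    proteins vary across nuclei and receive configured shifts in
    reactive-cluster nuclei of disease donors.
    """
    n = len(meta)
    L = pd.DataFrame(index=meta.index, columns=list(config.panel), dtype=float)
    reactive_disease = (
        (meta["cluster"] == "REV1") & meta["disease_group"].isin(DISEASE)
    ).to_numpy()
    for p in config.panel:
        if p == config.reference_antibody:
            L[p] = np.log(config.ab_ref_mean) + rng.normal(0, config.h3_lsd, n)
        else:
            base = np.log(config.ab_protein_mean) - config.protein_lsd**2 / 2
            vals = base + rng.normal(0, config.protein_lsd, n)
            shift = config.reactive_protein_shifts.get(p, 0.0)
            vals = vals + shift * reactive_disease
            L[p] = vals
    return L


def _nb_draw(mean, shape, rng):
    lam = rng.gamma(shape, np.asarray(mean) / shape)
    return rng.poisson(lam)


def simulate_antibody_counts(
    L: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
):
    """Antibody counts A[i,p] ~ NB(mean = c_i * exp(L[i,p])).

    The capture-efficiency scalar ``c_i`` multiplies every antibody of
    nucleus i, including the reference, so it cancels after reference
    normalization. With ``count_noise=False`` the rounded means are
    returned (limit case).
    """
    n = len(L)
    if config.capture_efficiency_sd > 0:
        c = rng.lognormal(
            -config.capture_efficiency_sd**2 / 2, config.capture_efficiency_sd, n
        )
    else:
        c = np.ones(n)
    mean = c[:, None] * np.exp(L.to_numpy())
    if config.count_noise:
        A = _nb_draw(mean, config.ab_nb_shape, rng)
    else:
        A = np.round(mean).astype(np.int64)
    return A.astype(np.int64), c


# ---------------------------------------------------------------------------
# gene counts
# ---------------------------------------------------------------------------


def simulate_gene_counts(
    meta: pd.DataFrame,
    L: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Gene counts with depth, batch and latent-protein effects planted.

    X[i,g] ~ NB(mean = s_i * p_ig) where the relative expression
    p_ig follows exp(alpha_g + batch offset + sum_p beta[g,p] L[i,p]),
    renormalized per nucleus, with a Beta-distributed mitochondrial
    fraction spliced into the MT- genes. Returns the count matrix, the
    hashtag counts, the true effect matrix and the depth factors.
    """
    genes = config.gene_names()
    n, g = len(meta), len(genes)
    proteins = [p for p in config.panel if p != config.reference_antibody]

    beta = pd.DataFrame(0.0, index=genes, columns=proteins)
    for gene, (protein, b) in config.effect_table.items():
        if gene not in beta.index:
            raise ValueError(f"effect table names unknown gene {gene!r}")
        beta.loc[gene, protein] = b

    alpha = rng.normal(0, 1.0, g)
    if config.effect_gene_alpha is not None and config.effect_table:
        gene_pos = {name: i for i, name in enumerate(genes)}
        for gene in config.effect_table:
            alpha[gene_pos[gene]] = config.effect_gene_alpha
    batches = sorted(meta["batch"].unique())
    batch_idx = meta["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    batch_eff = rng.normal(0, config.batch_gene_sd, (len(batches), g))

    # center latent protein so planted effects move relative expression
    # around the baseline rather than shifting every effect gene's mean
    Lc = L[proteins].to_numpy() - L[proteins].to_numpy().mean(axis=0)
    eta = alpha[None, :] + batch_eff[batch_idx] + Lc @ beta.to_numpy().T
    w = np.exp(eta)

    # mitochondrial share: Beta-distributed, with a configurable fraction
    # of nuclei in a >5% regime to exercise QC
    is_mito = np.array([name.startswith("MT-") for name in genes])
    if is_mito.any():
        mf = config.mito_mean_fraction
        f = rng.beta(2.0, 2.0 * (1 - mf) / mf, n)
        high = rng.random(n) < config.high_mito_fraction
        f[high] = rng.beta(4.0, 36.0, high.sum())  # mean 10%
        sum_m = w[:, is_mito].sum(axis=1)
        sum_r = w[:, ~is_mito].sum(axis=1)
        scale = f / (1 - f) * sum_r / sum_m
        w[:, is_mito] *= scale[:, None]

    p = w / w.sum(axis=1, keepdims=True)

    s = config.depth_mean * rng.lognormal(-config.depth_sd**2 / 2, config.depth_sd, n)
    shallow = rng.random(n) < config.shallow_fraction
    s[shallow] = config.shallow_depth
    mean = s[:, None] * p

    if config.count_noise:
        X = _nb_draw(mean, config.nb_shape, rng)
    else:
        X = np.round(mean).astype(np.int64)

    hashtag = rng.lognormal(np.log(config.hashtag_median), config.hashtag_sd, n)
    high = rng.random(n) < config.high_hashtag_fraction
    hashtag[high] = rng.uniform(4001, 8000, high.sum())
    hashtag = np.maximum(np.round(hashtag), 1).astype(np.int64)

    return sp.csr_matrix(X), hashtag, beta, s


# ---------------------------------------------------------------------------
# top-level assembly
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig):
    """Simulate a full cohort and return ``(NucleusDataset, SyntheticTruth)``.

    Fully reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    donor_table, meta = simulate_cohort(config, rng)
    L = simulate_latent_protein(meta, config, rng)
    A, capture = simulate_antibody_counts(L, config, rng)
    X, hashtag, beta_true, depth = simulate_gene_counts(meta, L, config, rng)

    meta = meta.copy()
    meta["hashtag_counts"] = hashtag
    meta["total_counts"] = np.asarray(X.sum(axis=1)).ravel().astype(int)

    ds = NucleusDataset(
        barcodes=list(meta.index),
        genes=config.gene_names(),
        antibodies=list(config.panel),
        X=X,
        A=A,
        meta=meta,
        reference_antibody=config.reference_antibody,
    )
    truth = SyntheticTruth(
        L=L,
        beta_true=beta_true,
        donor_table=donor_table,
        meta=meta,
        capture_efficiency=capture,
        depth_factors=depth,
    )
    logger.info(
        "simulated cohort: %d donors, %d nuclei, %d genes, panel %s",
        len(donor_table), ds.n_nuclei, len(ds.genes), list(config.panel),
    )
    return ds, truth


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    """Write the nonzero planted effects as a gene/protein/beta_true table."""
    rows = []
    for gene in truth.beta_true.index:
        for protein in truth.beta_true.columns:
            b = truth.beta_true.loc[gene, protein]
            if b != 0:
                rows.append({"gene": gene, "protein": protein, "beta_true": b})
    pd.DataFrame(rows, columns=["gene", "protein", "beta_true"]).to_csv(
        path, index=False
    )
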