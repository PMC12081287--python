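import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucite import (
    HVGParams,
    QCThresholds,
    embed_and_cluster,
    normalize_expression,
    qc_filter,
    select_variable_genes,
)

from conftest import build_dataset


def _qc_fixture():
    """Hand-built dataset exercising every QC rule at its boundary.

    90 regular genes + 10 MT- genes. Ten 'base' nuclei express all regular
    genes so the gene-level filter keeps them; special nuclei sit exactly
    on either side of each nucleus-level threshold.
    """
    genes = [f"g{j:03d}" for j in range(90)] + [f"MT-{j}" for j in range(1, 11)]
    rows, hashtag, tdp = [], [], []
    names = []

    def add(name, reg_genes, mito_counts=0, ht=100, tdp_ab=100):
        v = np.zeros(100, dtype=int)
        v[:reg_genes] = 2
        if mito_counts:
            v[90] = mito_counts
        rows.append(v)
        hashtag.append(ht)
        tdp.append(tdp_ab)
        names.append(name)

    for i in range(10):
        add(f"base{i}", 90)
    add("genes49", 49)
    add("genes50", 50)
    # 5.7% mito (6/106): removed by the "more than 5%" rule
    add("mito6pct", 50, mito_counts=6)
    # exactly 5% mito (5/100): kept
    v = np.zeros(100, dtype=int); v[:90] = 1; v[0] = 6; v[90] = 5
    rows.append(v); hashtag.append(100); tdp.append(100); names.append("mito5pct")
    add("hashtag4001", 60, ht=4001)
    add("hashtag4000", 60, ht=4000)
    add("tdp3001", 60, tdp_ab=3001)
    add("tdp3000", 60, tdp_ab=3000)

    counts = np.vstack(rows)
    A = np.column_stack([np.full(len(rows), 150), np.array(tdp)])
    ds = build_dataset(counts, antibodies=("H3", "TDP43"), A=A,
                       hashtag=hashtag, genes=genes)
    return ds, dict(zip(ds.barcodes, names))


class TestQCFilter:
    def test_boundary_cases(self):
        ds, names = _qc_fixture()
        filtered, report = qc_filter(ds)
        kept = {names[b] for b in filtered.barcodes}
        assert "genes49" not in kept and "genes50" in kept
        assert "mito6pct" not in kept and "mito5pct" in kept
        assert "hashtag4001" not in kept and "hashtag4000" in kept
        assert "tdp3001" not in kept and "tdp3000" in kept
        tallies = dict(zip(report["rule"], report["count"]))
        assert tallies["min_genes"] == 1
        assert tallies["mito_fraction"] == 1
        assert tallies["hashtag_counts"] == 1
        assert tallies["tdp43_antibody"] == 1

    def test_tdp43_rule_skipped_without_antibody(self):
        ds, names = _qc_fixture()
        rna_only = build_dataset(
            np.asarray(ds.X.todense()), antibodies=("H3", "p65"),
            hashtag=ds.meta["hashtag_counts"].tolist(), genes=ds.genes,
        )
        filtered, report = qc_filter(rna_only)
        assert "tdp43_antibody" not in set(report["rule"])
        kept = {names[b] for b in filtered.barcodes}
        assert "tdp3001" in kept  # no antibody modality, rule not applied

    def test_idempotent(self, qc_cohort):
        ds = qc_cohort["ds"]
        again, report = qc_filter(ds)
        assert again.n_nuclei == ds.n_nuclei
        assert len(again.genes) == len(ds.genes)

    def test_all_removed_raises_with_tallies(self):
        ds = build_dataset(np.ones((3, 10), dtype=int))  # 10 genes < 50
        with pytest.raises(ValueError, match="min_genes"):
            qc_filter(ds)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            QCThresholds(min_genes_per_nucleus=0)


class TestNormalizeExpression:
    def test_zero_maps_to_zero_and_target_sum(self):
        X = np.array([[10, 30, 0], [5, 0, 5]])
        norm = normalize_expression(X, target_sum=40)
        dense = np.asarray(norm.todense())
        assert dense[0, 2] == 0.0
        # first nucleus already sums to 40: values are ln(x + 1) directly
        assert np.allclose(dense[0, :2], [np.log(11), np.log(31)])
        # pre-log values sum to the target for every nucleus
        assert np.allclose(np.expm1(dense).sum(axis=1), 40)

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 20, (1, 50))
        norm1 = normalize_expression(row)
        norm2 = normalize_expression(row * 2)
        assert np.allclose(norm1.todense(), norm2.todense())

    def test_zero_count_nucleus_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_expression(np.array([[0, 0], [1, 2]]))

    def test_zero_pattern_preserved(self):
        rng = np.random.default_rng(1)
        X = sp.random(30, 40, density=0.3, random_state=rng)
        X = sp.csr_matrix(np.round(X.todense() * 9) + 0)
        X = X[np.asarray(X.sum(axis=1)).ravel() > 0]
        norm = normalize_expression(X)
        assert np.array_equal(
            np.asarray(X.todense()) > 0, np.asarray(norm.todense()) > 0
        )


def _hvg_matrix(seed=0, n=400, g=300):
    """Poisson genes with means inside the selection window plus one
    overdispersed gene (index 0) and one constant gene (index 1)."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(0.005, 0.1, g)
    counts = rng.poisson(mu[None, :] * np.ones((n, 1)))
    counts[:, 0] = rng.negative_binomial(0.05, 0.5, n)  # overdispersed
    counts[:, 1] = 1  # constant
    counts[:, 2] = rng.poisson(0.5, n)  # mean above max_mean window
    keep = counts.sum(axis=1) > 0
    X = sp.csr_matrix(counts[keep])
    target = X.sum() / X.shape[0]
    return normalize_expression(X, target_sum=target)


class TestVariableGenes:
    def test_planted_dispersion_structure(self):
        norm = _hvg_matrix()
        genes = [f"g{i}" for i in range(norm.shape[1])]
        mask, selected = select_variable_genes(norm, genes)
        assert mask[0], "overdispersed gene inside the mean window selected"
        assert not mask[1], "constant gene excluded"
        assert not mask[2], "gene with mean above max_mean excluded"
        # direct dispersion computation confirms the planted gene
        dense = np.asarray(norm.todense())
        expm = np.expm1(dense)
        disp = expm.var(axis=0) / np.maximum(expm.mean(axis=0), 1e-12)
        assert disp[0] > np.median(disp[mask])

    def test_order_independence(self):
        norm = _hvg_matrix()
        genes = [f"g{i}" for i in range(norm.shape[1])]
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(genes))
        _, sel1 = select_variable_genes(norm, genes)
        _, sel2 = select_variable_genes(
            sp.csr_matrix(norm.todense()[:, perm]), [genes[i] for i in perm]
        )
        assert set(sel1) == set(sel2)

    def test_too_few_pass_raises(self):
        rng = np.random.default_rng(0)
        X = sp.csr_matrix(rng.poisson(50, (50, 20)) + 1.0)
        with pytest.raises(ValueError, match="variable genes"):
            select_variable_genes(X.log1p(), [f"g{i}" for i in range(20)])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            HVGParams(min_mean=0.5, max_mean=0.1)


class TestEmbedCluster:
    def _blobs(self, n_per=500, sep=10.0, dim=20, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n_per, dim))
        b = rng.normal(0, 1, (n_per, dim))
        b[:, 0] += sep
        X = np.vstack([a, b])
        labels = np.array([0] * n_per + [1] * n_per)
        return sp.csr_matrix(X - X.min()), labels

    def test_two_separated_blobs_recovered(self):
        X, truth = self._blobs()
        emb, labels, _ = embed_and_cluster(X, n_pcs=10, k=10, resolution=0.8)
        ct = pd.crosstab(pd.Series(labels), pd.Series(truth))
        # each found cluster is pure for one blob, and blob assignment
        # agrees with cluster majority >= 99%
        majority = ct.idxmax(axis=1)
        agree = sum(ct.loc[c, majority[c]] for c in ct.index) / len(truth)
        assert agree >= 0.99
        assert len(set(majority)) == 2  # both blobs found

    def test_duplicated_nuclei_share_labels(self):
        X, _ = self._blobs(n_per=100, dim=5, seed=1)
        dense = np.asarray(X.todense())
        dup = sp.csr_matrix(np.vstack([dense, dense[:1]]))
        _, labels, _ = embed_and_cluster(dup, n_pcs=4, k=5)
        assert labels[0] == labels[-1]

    def test_npcs_clamped_with_warning(self):
        X, _ = self._blobs(n_per=30, dim=5, seed=2)
        with pytest.warns(UserWarning, match="clamp"):
            embed_and_cluster(X, n_pcs=50, k=5)

    def test_k_too_large_rejected(self):
        X, _ = self._blobs(n_per=4, dim=3, seed=3)
        with pytest.raises(ValueError, match="k="):
            embed_and_cluster(X, k=10)
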