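import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from nucite import (
    GeneSet,
    bh_adjust,
    build_design,
    fit_protein_associations,
    gene_set_overlap_pct,
    overlap_enrichment,
    residualize_expression,
)

PROTEINS = ["TDP43", "p65", "beta-catenin"]


def _meta(n, seed=0, n_batches=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "log_ncounts": rng.normal(7.5, 0.3, n),
            "log_hashtag_counts": rng.normal(6.7, 0.5, n),
            "batch": rng.choice([f"b{i}" for i in range(n_batches)], n),
        },
        index=[f"N{i}" for i in range(n)],
    )


def _linear_data(n=300, g=20, seed=0, beta=None):
    """Expression = covariate effects + protein effects + Gaussian noise."""
    rng = np.random.default_rng(seed)
    meta = _meta(n, seed)
    D = build_design(meta)
    gamma = rng.normal(0, 0.5, (D.shape[1], g))
    P = rng.normal(0, 1, (n, len(PROTEINS)))
    B = np.zeros((g, len(PROTEINS)))
    if beta:
        for (gi, pj), b in beta.items():
            B[gi, pj] = b
    Y = D.to_numpy() @ gamma + P @ B.T + rng.normal(0, 1, (n, g))
    Y = Y - Y.min() + 0.1  # keep strictly positive so every entry counts as expressed
    nclr = pd.DataFrame(P, index=meta.index, columns=PROTEINS)
    genes = [f"g{i}" for i in range(g)]
    return Y, meta, nclr, genes


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self):
        Y, meta, _, genes = _linear_data()
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        dots = design.to_numpy().T @ resid.to_numpy()
        assert np.abs(dots).max() < 1e-8

    def test_intercept_only_equals_mean_centering(self):
        Y, meta, _, genes = _linear_data()
        resid, _, _ = residualize_expression(
            sp.csr_matrix(Y), meta, genes, covariates=()
        )
        assert np.allclose(resid.to_numpy(), Y - Y.mean(axis=0), atol=1e-10)

    def test_min_nuclei_gene_filter(self):
        rng = np.random.default_rng(0)
        n = 60
        Y = rng.lognormal(0, 1, (n, 3))
        Y[24:, 0] = 0.0  # gene 0 expressed in 24 nuclei
        Y[25:, 1] = 0.0  # gene 1 expressed in 25 nuclei
        resid, n_expr, _ = residualize_expression(
            sp.csr_matrix(Y), _meta(n), ["g24", "g25", "gAll"]
        )
        assert "g24" not in resid.columns
        assert "g25" in resid.columns
        assert n_expr["g25"] == 25

    def test_collinear_design_column_dropped(self):
        meta = _meta(50, n_batches=1)  # single batch: no dummy to encode
        meta["log_hashtag_counts"] = meta["log_ncounts"]  # duplicated covariate
        with pytest.warns(UserWarning, match="collinear"):
            D = build_design(meta)
        assert "log_hashtag_counts" not in D.columns
        assert np.linalg.matrix_rank(D.to_numpy()) == D.shape[1]


class TestBHAdjustment:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_stepup(self, seed):
        def stepup(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            return q

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 101) ** 2
        assert np.allclose(bh_adjust(p), stepup(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestProteinFit:
    def test_fwl_two_step_equals_joint_regression(self):
        """With protein residualization, the two-step coefficients equal
        those of one joint regression (Frisch-Waugh-Lovell)."""
        Y, meta, nclr, genes = _linear_data(n=200, g=15, seed=3,
                                            beta={(0, 0): 1.0, (5, 2): -0.7})
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        table = fit_protein_associations(resid, nclr, design=design)
        full = np.column_stack([design.to_numpy(), nclr.to_numpy()])
        joint, *_ = np.linalg.lstsq(full, Y, rcond=None)
        joint = joint[design.shape[1]:]  # protein rows
        for j, protein in enumerate(nclr.columns):
            got = (
                table[table["protein"] == protein]
                .set_index("gene")
                .loc[genes, "coefficient"]
                .to_numpy()
            )
            assert np.abs(got - joint[j]).max() < 1e-8

    def test_single_mode_matches_per_protein_ols(self):
        Y, meta, nclr, genes = _linear_data(n=150, g=8, seed=4)
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        table = fit_protein_associations(resid, nclr, mode="single",
                                         design=design)
        # oracle: per-protein simple regression on the residualized protein
        D = design.to_numpy()
        Q, _ = np.linalg.qr(D)
        P = nclr.to_numpy() - Q @ (Q.T @ nclr.to_numpy())
        for j, protein in enumerate(nclr.columns):
            x = P[:, j]
            got = (
                table[table["protein"] == protein]
                .set_index("gene")
                .loc[genes, "coefficient"]
                .to_numpy()
            )
            expect = x @ resid.to_numpy() / (x @ x)
            assert np.abs(got - expect).max() < 1e-10

    def test_intercept_absorbs_protein_shift(self):
        Y, meta, nclr, genes = _linear_data(n=120, g=6, seed=5)
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        t1 = fit_protein_associations(resid, nclr, design=design)
        t2 = fit_protein_associations(resid, nclr + 13.5, design=design)
        assert np.allclose(t1["coefficient"], t2["coefficient"], atol=1e-9)

    def test_constant_protein_rejected(self):
        Y, meta, nclr, genes = _linear_data(n=60, g=4)
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        nclr = nclr.copy()
        nclr["TDP43"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_protein_associations(resid, nclr, design=design,
                                     residualize_proteins=False)

    def test_planted_effect_detected(self):
        Y, meta, nclr, genes = _linear_data(n=500, g=25, seed=6,
                                            beta={(0, 0): 1.0})
        resid, _, design = residualize_expression(sp.csr_matrix(Y), meta, genes)
        table = fit_protein_associations(resid, nclr, design=design)
        hit = table[(table["gene"] == "g0") & (table["protein"] == "TDP43")]
        assert hit["significant"].iloc[0] and hit["coefficient"].iloc[0] > 0
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()


class TestOverlapEnrichment:
    @staticmethod
    def _fisher_two_sided_oracle(a, b, c, d):
        """Exhaustive two-sided Fisher p by hypergeometric enumeration."""
        N, K, n = a + b + c + d, a + c, a + b
        pmf = scipy.stats.hypergeom(N, K, n).pmf
        p_obs = pmf(a)
        ks = np.arange(max(0, n - (N - K)), min(K, n) + 1)
        return sum(pmf(k) for k in ks if pmf(k) <= p_obs * (1 + 1e-9))

    def test_worked_table_odds_ratio_4(self):
        universe = [f"g{i}" for i in range(30)]
        assoc = universe[:15]
        target = universe[:10] + universe[15:20]  # a=10, b=5, c=5, d=10
        res = overlap_enrichment(assoc, GeneSet("t", frozenset(target)), universe)
        assert res.odds_ratio == 4.0
        assert np.array_equal(res.table, [[10, 5], [5, 10]])
        assert np.isclose(res.p_value, self._fisher_two_sided_oracle(10, 5, 5, 10),
                          atol=1e-10)

    def test_zero_overlap_gives_zero_odds(self):
        universe = [f"g{i}" for i in range(20)]
        res = overlap_enrichment(universe[:8], set(universe[8:16]), universe)
        assert res.odds_ratio == 0.0
        assert 0 < res.p_value <= 1

    def test_perfect_overlap_matches_enumeration(self):
        universe = [f"g{i}" for i in range(8)]
        half = universe[:4]
        res = overlap_enrichment(half, set(half), universe)
        assert np.isclose(res.p_value, self._fisher_two_sided_oracle(4, 0, 0, 4),
                          atol=1e-12)
        # the observed table is the extreme one: its one-sided probability
        # is the hypergeometric point mass
        point = scipy.stats.hypergeom(8, 4, 4).pmf(4)
        assert scipy.stats.fisher_exact(res.table, "greater")[1] == pytest.approx(point)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment({"a"}, {"a"}, set())


class TestOverlapPct:
    @pytest.mark.parametrize(
        "a, b, expect",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 50.0),
            ({"x", "y"}, {"x", "y"}, 100.0),
            ({"x"}, {"y"}, 0.0),
        ],
    )
    def test_worked_examples(self, a, b, expect):
        assert gene_set_overlap_pct(a, b) == expect

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap_pct(set(), set())
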