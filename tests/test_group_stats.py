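import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from trsc.group_stats import (
    bh_fdr,
    build_design,
    difference_matrices,
    fit_all,
    fit_many,
    fit_pair_regression,
)
from trsc.io_core import CohortMetadata, ValidationError


def bh_oracle(p, alpha=0.05):
    """Brute-force Benjamini-Hochberg step-up: adjusted p and rejections."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    # step-up rejection: largest k with p_(k) <= alpha*k/m, reject all smaller
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return adj, reject


def _metadata(n_per_cell=2):
    rows = []
    for dx in ("HC", "SZ"):
        for sex in ("F", "M"):
            for k in range(n_per_cell):
                rows.append((f"{dx}{sex}{k}", dx, sex))
    return CohortMetadata(pd.DataFrame(rows, columns=["subject_id", "diagnosis", "sex"]))


class TestDesign:
    def test_columns_and_coding(self):
        d = build_design(_metadata())
        assert d.columns == ["intercept", "dx", "sex", "dx_sex"]
        np.testing.assert_array_equal(d.X[:, 1], [0, 0, 0, 0, 1, 1, 1, 1])  # SZ = 1
        np.testing.assert_array_equal(d.X[:, 2], [0, 0, 1, 1, 0, 0, 1, 1])  # M = 1
        np.testing.assert_array_equal(d.X[:, 3], d.X[:, 1] * d.X[:, 2])

    def test_empty_cell_identified(self):
        rows = [("a", "HC", "M"), ("b", "HC", "F"), ("c", "SZ", "M")]
        meta = CohortMetadata(pd.DataFrame(rows, columns=["subject_id", "diagnosis", "sex"]))
        with pytest.raises(ValidationError, match="diagnosis=SZ, sex=F"):
            build_design(meta)


class TestOls:
    def test_perfect_separation_by_diagnosis(self):
        meta = _metadata(4)
        d = build_design(meta)
        res = fit_pair_regression(d.X[:, 1], d)  # response IS the dx indicator
        dx = res[res.contrast == "diagnosis"].iloc[0]
        sex = res[res.contrast == "sex"].iloc[0]
        assert dx.p < 1e-12
        assert sex.beta == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_eight_subject_example(self, rng):
        """beta/t/p agree with normal equations and with statsmodels OLS."""
        meta = _metadata(2)
        d = build_design(meta)
        y = rng.normal(size=8) + d.X[:, 1] * 1.5
        res = fit_pair_regression(y, d)
        # independent route 1: normal equations + t distribution by hand
        beta_ne = np.linalg.solve(d.X.T @ d.X, d.X.T @ y)
        resid = y - d.X @ beta_ne
        s2 = resid @ resid / (8 - 4)
        cov = s2 * np.linalg.inv(d.X.T @ d.X)
        for contrast, col in (("diagnosis", 1), ("sex", 2), ("interaction", 3)):
            row = res[res.contrast == contrast].iloc[0]
            t_ne = beta_ne[col] / np.sqrt(cov[col, col])
            p_ne = 2 * sps.t.sf(abs(t_ne), 4)
            assert row.beta == pytest.approx(beta_ne[col], abs=1e-10)
            assert row.t == pytest.approx(t_ne, abs=1e-10)
            assert row.p == pytest.approx(p_ne, abs=1e-10)
        # independent route 2: statsmodels
        fit = sm.OLS(y, d.X).fit()
        for contrast, col in (("diagnosis", 1), ("sex", 2), ("interaction", 3)):
            row = res[res.contrast == contrast].iloc[0]
            assert row.t == pytest.approx(fit.tvalues[col], abs=1e-10)
            assert row.p == pytest.approx(fit.pvalues[col], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        """Diagnosis p-values are Uniform(0,1) under the null (KS at alpha=0.01)."""
        meta = _metadata(4)
        d = build_design(meta)
        Y = rng.normal(size=(16, 1000))
        _, _, p = fit_many(Y, d)
        ks = sps.kstest(p[1], "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_subjects(self):
        meta = _metadata(1)
        with pytest.raises(ValidationError, match="subjects"):
            fit_many(np.zeros((4, 1)), build_design(meta))


class TestBhFdr:
    def test_worked_example(self):
        adj, rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_all_ones_none_rejected(self):
        adj, rej = bh_fdr(np.ones(7))
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p_identity(self):
        adj, rej = bh_fdr(np.array([0.04]), alpha=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 1.5]))
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.0, 0.5]))

    def test_oracle_equivalence_random_vectors(self, rng):
        """Adjusted p-values match an independent step-up implementation."""
        for _ in range(300):
            m = int(rng.integers(1, 2000))
            p = rng.uniform(1e-12, 1, m) ** rng.uniform(0.3, 3)
            adj, rej = bh_fdr(p, alpha=0.05)
            adj_o, rej_o = bh_oracle(p, alpha=0.05)
            np.testing.assert_allclose(adj, adj_o, rtol=1e-12)
            np.testing.assert_array_equal(rej, rej_o)

    def test_monotonicity_enforced(self, rng):
        p = rng.uniform(size=50)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _summaries_for(meta, n_components, values_fn, rng):
    from trsc.coupling import component_pairs

    rows = []
    for sid in meta.table["subject_id"]:
        for i, j in component_pairs(n_components):
            for q in range(1, 5):
                v = values_fn(sid, i, j, q)
                rows.append((sid, i, j, q, v, v))
    return pd.DataFrame(
        rows, columns=["subject", "pair_i", "pair_j", "quartile", "cell_count", "avg_cluster_size"]
    )


class TestFitAllAndMatrices:
    def test_all_null_gives_zero_matrices(self, rng):
        meta = _metadata(3)
        summaries = _summaries_for(meta, 4, lambda s, i, j, q: rng.normal(), rng)
        res = fit_all(summaries, meta)
        mats = difference_matrices(res, alpha=1e-6, n_components=4)
        assert len(mats) == 4 * 2 * 3
        # with alpha tiny and null data, nothing should survive either mask
        assert all(np.count_nonzero(m) == 0 for m in mats.values())

    def test_single_strong_pair_upper_triangle(self, rng):
        meta = _metadata(5)
        dx = dict(zip(meta.table.subject_id, meta.diagnosis))

        def values(s, i, j, q):
            boost = 5.0 if (i, j, q) == (0, 1, 4) and dx[s] == "SZ" else 0.0
            return rng.normal() + boost

        summaries = _summaries_for(meta, 3, values, rng)
        res = fit_all(summaries, meta)
        mats = difference_matrices(res, alpha=0.05, n_components=3)
        m = mats[(4, "cell_count", "diagnosis")]
        assert m[0, 1] > 0  # SZ-dominant -> positive t -> positive signed logp
        row = res[
            (res.quartile == 4)
            & (res.measure == "cell_count")
            & (res.contrast == "diagnosis")
            & (res.pair_i == 0)
            & (res.pair_j == 1)
        ].iloc[0]
        # lower triangle mirrors the FDR decision for that pair
        assert (m[1, 0] != 0) == bool(row.reject_fdr)

    def test_sign_convention_hc_dominance_negative(self, rng):
        """Raising HC values for a pair makes the diagnosis t negative (SZ=1)."""
        meta = _metadata(5)
        dx = dict(zip(meta.table.subject_id, meta.diagnosis))

        def values(s, i, j, q):
            boost = 4.0 if (i, j) == (0, 2) and dx[s] == "HC" else 0.0
            return rng.normal() + boost

        summaries = _summaries_for(meta, 3, values, rng)
        res = fit_all(summaries, meta)
        sub = res[
            (res.pair_i == 0) & (res.pair_j == 2) & (res.contrast == "diagnosis")
        ]
        assert (sub.t < 0).all()
        assert (sub.signed_logp < 0).all()

    def test_fdr_family_is_per_matrix(self, rng):
        meta = _metadata(4)
        summaries = _summaries_for(meta, 4, lambda s, i, j, q: rng.normal(), rng)
        res = fit_all(summaries, meta)
        for _, sub in res.groupby(["quartile", "measure", "contrast"]):
            adj, _ = bh_fdr(sub["p"].to_numpy())
            np.testing.assert_allclose(sub["p_fdr"].to_numpy(), adj, rtol=1e-12)

    def test_missing_pairs_detected(self, rng):
        meta = _metadata(3)
        summaries = _summaries_for(meta, 4, lambda s, i, j, q: rng.normal(), rng)
        res = fit_all(summaries, meta)
        with pytest.raises(ValidationError, match="incomplete"):
            difference_matrices(res.iloc[:-3], alpha=0.05, n_components=4)

    def test_signed_logp_consistency(self, rng):
        meta = _metadata(3)
        summaries = _summaries_for(meta, 3, lambda s, i, j, q: rng.normal(), rng)
        res = fit_all(summaries, meta)
        np.testing.assert_allclose(
            res.signed_logp, -np.log10(res.p) * np.sign(res.t), rtol=1e-12
        )
        assert (res.p_fdr >= res.p - 1e-15).all()
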