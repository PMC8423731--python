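import numpy as np
import pandas as pd
import pytest

import stabgwas as sg
from stabgwas.io import ValidationError
from tests.test_popgen import panel


@pytest.fixture(scope="module")
def structured_panel():
    cfg = sg.SimConfig(n_genotypes=200, group_split=(134, 66), n_markers=1000,
                       n_chromosomes=5, seed=31, fst_like_divergence=0.3,
                       ld_block_len=1, qtls=[])
    return sg.simulate_genotypes(cfg)


class TestKinship:
    def test_duplicate_samples_are_self_similar(self):
        g = panel([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]])
        k = sg.kinship_vanraden(g)
        assert k[0, 1] == pytest.approx(k[0, 0], abs=1e-5)
        assert k[0, 1] == pytest.approx(k[1, 1], abs=1e-5)

    def test_orientation_invariance(self, small_panel):
        k1 = sg.kinship_vanraden(small_panel)
        flipped = small_panel.subset()
        flipped.dosage = np.where(flipped.dosage == sg.MISSING,
                                  sg.MISSING, 2 - flipped.dosage)
        k2 = sg.kinship_vanraden(flipped)
        np.testing.assert_allclose(k1, k2, atol=1e-10)

    def test_unrelated_panel_off_diagonal_near_zero(self):
        # centering forces the off-diagonal mean to -diag.mean/(n-1), which at
        # n=200 independent samples is within the 0.02 tolerance
        cfg = sg.SimConfig(n_genotypes=200, group_split=(100, 100), n_markers=5000,
                           n_chromosomes=5, seed=41, fst_like_divergence=0.0,
                           ld_block_len=1, qtls=[])
        g = sg.simulate_genotypes(cfg)
        k = sg.kinship_vanraden(g)
        off = k[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_symmetric_psd(self, structured_panel):
        k = sg.kinship_vanraden(structured_panel)
        np.testing.assert_allclose(k, k.T, atol=1e-10)
        assert np.linalg.eigvalsh(k).min() > -1e-8

    def test_monomorphic_only_rejected(self):
        g = panel([[0, 0, 0], [2, 2, 2]])
        with pytest.raises(ValidationError):
            sg.kinship_vanraden(g)


class TestStructurePca:
    def test_k_zero_rejected(self, small_panel):
        with pytest.raises(ValidationError):
            sg.structure_pca(small_panel, k=0)

    def test_columns_centered_orthogonal(self, structured_panel):
        pcs = sg.structure_pca(structured_panel, k=3)
        np.testing.assert_allclose(pcs.mean(axis=0), 0, atol=1e-8)
        gram = pcs.T @ pcs
        off = gram[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_pc1_tags_subpopulations(self, structured_panel):
        pcs = sg.structure_pca(structured_panel, k=1)
        grp = (structured_panel.groups == "cultivar").astype(float)
        assert abs(np.corrcoef(pcs[:, 0], grp)[0, 1]) > 0.9

    def test_deterministic_sign_convention(self, structured_panel):
        a = sg.structure_pca(structured_panel, k=3)
        b = sg.structure_pca(structured_panel, k=3)
        np.testing.assert_array_equal(a, b)


class TestGlmScan:
    def test_null_type_one_rate(self, structured_panel):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, structured_panel.n_samples)
        res = sg.glm_scan(y, structured_panel, sg.structure_pca(structured_panel, 3))
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_duplicated_marker_identical_p(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 40)
        g = panel([list(col), list(col), list(rng.integers(0, 3, 40))])
        y = rng.normal(0, 1, 40)
        res = sg.glm_scan(y, g, None)
        assert res.table["p"].iloc[0] == res.table["p"].iloc[1]

    def test_perfect_fit_underflows_to_sentinel(self):
        rng = np.random.default_rng(3)
        cols = [list(rng.integers(0, 3, 400)) for _ in range(3)]
        g = panel(cols)
        y = 2.0 * g.dosage[:, 0].astype(float)
        res = sg.glm_scan(y, g, None)
        assert res.table["p"].iloc[0] == pytest.approx(5e-324, abs=0)
        assert res.table["significant"].iloc[0]

    def test_monomorphic_marker_gets_p_one(self):
        g = panel([[1, 1, 1, 1, 1, 1], [0, 1, 2, 0, 1, 2]])
        rng = np.random.default_rng(4)
        res = sg.glm_scan(rng.normal(0, 1, 6), g, None)
        assert res.table["p"].iloc[0] == 1.0

    def test_constant_response_rejected(self, small_panel):
        with pytest.raises(ValidationError, match="constant"):
            sg.glm_scan(np.ones(small_panel.n_samples), small_panel, None)

    def test_series_alignment_by_sample_id(self, small_panel):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(0, 1, small_panel.n_samples),
                      index=small_panel.samples)
        shuffled = y.sample(frac=1.0, random_state=1)
        r1 = sg.glm_scan(y, small_panel, None)
        r2 = sg.glm_scan(shuffled, small_panel, None)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestMlmScan:
    def test_reduces_to_glm_under_identity_kinship(self, structured_panel):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, structured_panel.n_samples)
        q = sg.structure_pca(structured_panel, 3)
        k = np.eye(structured_panel.n_samples)
        glm = sg.glm_scan(y, structured_panel, q)
        mlm = sg.mlm_scan(y, structured_panel, q, k)
        np.testing.assert_allclose(mlm.table["neglog10p"], glm.table["neglog10p"],
                                   rtol=0.1)

    def test_controls_structure_inflation(self, structured_panel):
        # confounded null: group effect + polygenic background
        n = structured_panel.n_samples
        k = sg.kinship_vanraden(structured_panel)
        q = sg.structure_pca(structured_panel, 3)
        chol = np.linalg.cholesky(k + 1e-8 * np.eye(n))
        grp = (structured_panel.groups == "cultivar").astype(float)
        lam_mlm, lam_glm0 = [], []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            y = grp + chol @ rng.normal(0, 0.7, n) + rng.normal(0, 1, n)
            lam_mlm.append(sg.mlm_scan(y, structured_panel, q, k).lambda_gc)
            lam_glm0.append(sg.glm_scan(y, structured_panel, None).lambda_gc)
        assert np.median(lam_glm0) > np.median(lam_mlm)
        assert 0.85 <= np.median(lam_mlm) <= 1.15

    def test_power_at_planted_qtl(self, structured_panel):
        rng = np.random.default_rng(7)
        x = structured_panel.dosage[:, 10].astype(float)
        e = rng.normal(0, 1, structured_panel.n_samples)
        beta = np.sqrt(0.3 / 0.7 * e.var() / x.var())
        y = (x - x.mean()) * beta + e
        k = sg.kinship_vanraden(structured_panel)
        q = sg.structure_pca(structured_panel, 3)
        res = sg.mlm_scan(y, structured_panel, q, k)
        assert res.table["neglog10p"].iloc[10] > 3
        assert res.table["neglog10p"].idxmax() == 10

    def test_asymmetric_kinship_rejected(self, small_panel):
        n = small_panel.n_samples
        k = np.eye(n)
        k[0, 1] = 0.5
        rng = np.random.default_rng(8)
        with pytest.raises(ValidationError, match="symmetric"):
            sg.mlm_scan(rng.normal(0, 1, n), small_panel, None, k)


class TestMtaCalling:
    @staticmethod
    def result_from(neglog, chrom, pos):
        n = len(neglog)
        table = pd.DataFrame({
            "marker": [f"m{i}" for i in range(n)], "chrom": chrom, "pos_bp": pos,
            "beta": 1.0, "se": 1.0, "p": 10.0 ** (-np.asarray(neglog)),
            "neglog10p": neglog, "significant": np.asarray(neglog) > 3.0})
        return sg.GWASResult(response="y", table=table, lambda_gc=1.0, model="GLM")

    def test_no_hits_empty(self):
        res = self.result_from([1.0, 2.0], ["1A", "1A"], [100, 200])
        assert sg.call_mtas(res).empty

    def test_interval_merge_rule(self):
        # decay 100: hits 2*decay apart stay separate; 0.5*decay apart merge
        res = self.result_from([5.0, 5.0, 5.0], ["1A", "1A", "1A"], [1000, 1200, 1250])
        mta = sg.call_mtas(res, ld_decay_by_chrom={"1A": 100.0})
        assert mta["locus"].nunique() == 2
        assert len(mta) == 3
        merged = mta[mta["pos_bp"] >= 1200]
        assert merged["locus"].nunique() == 1

    def test_threshold_monotonicity(self):
        res = self.result_from([2.0, 4.0, 6.0], ["1A"] * 3, [1, 2, 3])
        at3 = set(sg.call_mtas(res, threshold=3)["marker"])
        at5 = set(sg.call_mtas(res, threshold=5)["marker"])
        assert at5 <= at3


class TestPleiotropy:
    def test_single_response_markers_excluded(self):
        r1 = TestMtaCalling.result_from([5.0, 1.0], ["1A", "1A"], [1, 2])
        r2 = TestMtaCalling.result_from([1.0, 1.0], ["1A", "1A"], [1, 2])
        out = sg.pleiotropy_overlap({"a": r1, "b": r2})
        assert out.empty

    def test_shared_marker_reported_with_responses(self):
        r1 = TestMtaCalling.result_from([5.0, 1.0], ["1A", "1A"], [1, 2])
        r2 = TestMtaCalling.result_from([4.0, 1.0], ["1A", "1A"], [1, 2])
        out = sg.pleiotropy_overlap({"a": r1, "b": r2})
        assert list(out["marker"]) == ["m0"]
        assert out["responses"].iloc[0] == "a,b"

    def test_order_invariance(self):
        r1 = TestMtaCalling.result_from([5.0, 4.0], ["1A", "1A"], [1, 2])
        r2 = TestMtaCalling.result_from([4.0, 5.0], ["1A", "1A"], [1, 2])
        out1 = sg.pleiotropy_overlap({"a": r1, "b": r2})
        out2 = sg.pleiotropy_overlap({"b": r2, "a": r1})
        pd.testing.assert_frame_equal(out1, out2)

    def test_mismatched_marker_sets_rejected(self):
        r1 = TestMtaCalling.result_from([5.0, 1.0], ["1A", "1A"], [1, 2])
        r2 = TestMtaCalling.result_from([5.0], ["1A"], [1])
        with pytest.raises(ValidationError, match="marker"):
            sg.pleiotropy_overlap({"a": r1, "b": r2})


def test_qq_and_manhattan_exports(structured_panel):
    rng = np.random.default_rng(9)
    y = rng.normal(0, 1, structured_panel.n_samples)
    res = sg.glm_scan(y, structured_panel, None)
    man = sg.manhattan_data(res)
    assert list(man.columns) == ["marker", "chrom", "pos_bp", "neglog10p"]
    qq = sg.qq_data(res)
    assert len(qq) == structured_panel.n_markers
    assert (qq["observed"].diff().dropna() <= 0).all()


class TestMlmOracle:
    def test_matches_dense_gls_oracle(self):
        # independent route: explicit V = delta*K + I, dense solves, REML
        # log-likelihood evaluated from slogdet formulas without rotation
        from scipy import optimize as sopt
        from scipy import stats as sstats

        cfg = sg.SimConfig(n_genotypes=60, group_split=(40, 20), n_markers=20,
                           n_chromosomes=2, seed=55, fst_like_divergence=0.2,
                           ld_block_len=1, qtls=[])
        g = sg.simulate_genotypes(cfg)
        k = sg.kinship_vanraden(g)
        rng = np.random.default_rng(3)
        chol = np.linalg.cholesky(k + 1e-8 * np.eye(60))
        y = chol @ rng.normal(0, 1, 60) + rng.normal(0, 1, 60)
        q = sg.structure_pca(g, 2)
        res = sg.mlm_scan(y, g, q, k)

        n = 60
        x0 = np.column_stack([np.ones(n), q])
        p = x0.shape[1]

        def neg_reml(log_delta):
            v = np.exp(log_delta) * k + np.eye(n)
            vinv = np.linalg.inv(v)
            xtvx = x0.T @ vinv @ x0
            beta = np.linalg.solve(xtvx, x0.T @ vinv @ y)
            r = y - x0 @ beta
            rss = float(r @ vinv @ r)
            _, ld_v = np.linalg.slogdet(v)
            _, ld_x = np.linalg.slogdet(xtvx)
            return 0.5 * ((n - p) * np.log(rss / (n - p)) + ld_v + ld_x + (n - p))

        grid = np.linspace(-10, 10, 41)
        kbest = int(np.argmin([neg_reml(v) for v in grid]))
        opt = sopt.minimize_scalar(neg_reml, bounds=(grid[max(0, kbest - 1)],
                                                     grid[min(40, kbest + 1)]),
                                   method="bounded")
        delta = float(np.exp(opt.x))
        assert delta == pytest.approx(res.variance_components["delta"], rel=1e-3)

        v = delta * k + np.eye(n)
        vinv = np.linalg.inv(v)
        d = g.dosage.astype(float)
        for j in range(g.n_markers):
            x = np.column_stack([x0, d[:, j]])
            xtvx = x.T @ vinv @ x
            beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
            r = y - x @ beta
            sigma2 = float(r @ vinv @ r) / (n - p - 1)
            se = np.sqrt(sigma2 * np.linalg.inv(xtvx)[-1, -1])
            pval = 2 * sstats.t.sf(abs(beta[-1] / se), n - p - 1)
            assert res.table["beta"].iloc[j] == pytest.approx(beta[-1], rel=1e-6, abs=1e-10)
            assert res.table["p"].iloc[j] == pytest.approx(pval, rel=1e-6, abs=1e-12)

    def test_wald_matches_lrt_ordering(self, structured_panel):
        # Wald and likelihood-ratio orderings agree at fixed variance ratio
        from scipy.stats import spearmanr

        g = structured_panel
        k = sg.kinship_vanraden(g)
        q = sg.structure_pca(g, 3)
        rng = np.random.default_rng(14)
        chol = np.linalg.cholesky(k + 1e-8 * np.eye(g.n_samples))
        y = chol @ rng.normal(0, 0.7, g.n_samples) + rng.normal(0, 1, g.n_samples)
        res = sg.mlm_scan(y, g, q, k)
        delta = res.variance_components["delta"]

        lam, u = np.linalg.eigh(k)
        w = 1.0 / (np.clip(lam, 0, None) * delta + 1.0)
        sw = np.sqrt(w)
        yr = (u.T @ y) * sw
        x0 = (u.T @ np.column_stack([np.ones(g.n_samples), q])) * sw[:, None]
        dr = (u.T @ g.dosage.astype(float)) * sw[:, None]
        q0, _ = np.linalg.qr(x0)
        ry = yr - q0 @ (q0.T @ yr)
        rd = dr - q0 @ (q0.T @ dr)
        sxx = (rd ** 2).sum(0)
        poly = sxx > 1e-8 * g.n_samples  # LRT undefined at monomorphic markers
        rss0 = float(ry @ ry)
        bj = (rd[:, poly] * ry[:, None]).sum(0) / sxx[poly]
        rss1 = rss0 - bj ** 2 * sxx[poly]
        lrt = g.n_samples * np.log(rss0 / rss1)
        rho = spearmanr(lrt, res.table["neglog10p"].to_numpy()[poly]).statistic
        assert rho > 0.99
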