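import numpy as np
import pandas as pd
import pytest

import cellprior as cp
from cellprior.annotation import BASELINE_COL
from cellprior.ldsc import (
    ReferencePanel,
    block_jackknife,
    default_n_blocks,
    ld_scores,
    ld_scores_bruteforce,
    make_blocks,
    read_panel,
    stratified_regression,
    write_panel,
)


def _panel_from_genotypes(g, spacing=10_000):
    m = g.shape[1]
    snp_map = pd.DataFrame(
        {"snp_id": [f"rs{j}" for j in range(m)], "chrom": "1",
         "pos_bp": spacing * (1 + np.arange(m))}
    )
    return ReferencePanel(np.asarray(g, dtype=float), snp_map)


def _baseline(m):
    return pd.DataFrame({BASELINE_COL: np.ones(m)})


class TestLdScores:
    def test_single_snp_self_score_is_one(self):
        rng = np.random.default_rng(0)
        panel = _panel_from_genotypes(rng.integers(0, 3, size=(50, 1)))
        ld = ld_scores(panel, _baseline(1))
        assert ld.iloc[0, 0] == pytest.approx(1.0)

    def test_perfect_ld_pair_scores_two(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=(60, 1))
        panel = _panel_from_genotypes(np.hstack([col, col]))
        ld = ld_scores(panel, _baseline(2))
        np.testing.assert_allclose(ld.to_numpy(), 2.0, rtol=1e-12)

    def test_monomorphic_snp_contributes_zero(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(50, 3)).astype(float)
        g[:, 1] = 2.0
        panel = _panel_from_genotypes(g)
        with pytest.warns(UserWarning, match="monomorphic"):
            ld = ld_scores(panel, _baseline(3))
        assert ld.iloc[1, 0] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_sweep_equals_bruteforce(self, seed):
        cfg = cp.SimConfig(seed=seed, n_blocks=2, snps_per_block=30, n_ref=80)
        panel = cp.simulate_panel(cfg)
        rng = np.random.default_rng(seed)
        annots = pd.DataFrame(
            {BASELINE_COL: np.ones(60), "ct": rng.random(60)}
        )
        fast = ld_scores(panel, annots, window_bp=150_000)
        slow = ld_scores_bruteforce(panel, annots, window_bp=150_000)
        np.testing.assert_allclose(fast.to_numpy(), slow.to_numpy(), atol=1e-10)

    def test_baseline_score_at_least_self(self, small_panel):
        ld = ld_scores(small_panel, _baseline(small_panel.n_snps))
        assert (ld[BASELINE_COL] >= 1.0 - 1e-9).all()


class TestStratifiedRegression:
    @staticmethod
    def _noise_free(seed=0, tau=(5e-8, 1e-8), n=100_000.0):
        cfg = cp.SimConfig(seed=seed, n_blocks=3, snps_per_block=40, n_ref=150)
        panel = cp.simulate_panel(cfg)
        rng = np.random.default_rng(seed)
        annots = pd.DataFrame(
            {BASELINE_COL: np.ones(120), "ct": rng.random(120) * (rng.random(120) < 0.4)}
        )
        ld = ld_scores(panel, annots)
        chi2 = 1.0 + n * (tau[0] * ld[BASELINE_COL] + tau[1] * ld["ct"])
        stats = pd.DataFrame(
            {"snp_id": panel.snp_map["snp_id"], "chi2": chi2, "n": n,
             "z": np.sqrt(chi2)}
        )
        return stats, ld

    def test_exact_recovery_noise_free(self):
        stats, ld = self._noise_free()
        res = stratified_regression(stats, ld, test_col="ct", n_blocks=10)
        assert res.tau == pytest.approx(1e-8, rel=1e-10)
        assert res.tau_all[BASELINE_COL] == pytest.approx(5e-8, rel=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-18)

    def test_scale_equivariance(self):
        stats, ld = self._noise_free(seed=3)
        res1 = stratified_regression(stats, ld, test_col="ct", n_blocks=10)
        ld2 = ld.copy()
        ld2["ct"] = ld2["ct"] * 2.0
        res2 = stratified_regression(stats, ld2, test_col="ct", n_blocks=10)
        assert res2.tau == pytest.approx(res1.tau / 2.0, rel=1e-8)

    def test_collinear_design_rejected(self):
        stats, ld = self._noise_free()
        ld2 = ld.copy()
        ld2["ct"] = 2.0 * ld2[BASELINE_COL]
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            stratified_regression(stats, ld2, test_col="ct")

    def test_test_col_not_in_baseline(self):
        stats, ld = self._noise_free()
        with pytest.raises(ValueError, match="baseline"):
            stratified_regression(stats, ld, baseline_cols=("ct",), test_col="ct")


class TestBlockJackknife:
    def test_zero_variance_gives_zero_se(self):
        se = block_jackknife(lambda keep: 1.23, n_snps=100, n_blocks=10)
        assert se == 0.0

    def test_two_block_closed_form(self):
        # delete-block estimates 1 and 3 -> SE = sqrt(1/2 * ((1-2)^2+(3-2)^2)) = 1
        vals = {0: 1.0, 50: 3.0}

        def fit(keep):
            return vals[int(np.flatnonzero(~keep)[0])]

        assert block_jackknife(fit, n_snps=100, n_blocks=2) == pytest.approx(1.0)

    def test_close_to_analytic_ols_se(self):
        """Jackknife SE tracks the analytic OLS SE on iid Gaussian data."""
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n, x = 400, rng.standard_normal(400)
            y = 0.5 * x + rng.standard_normal(n)
            X = np.column_stack([np.ones(n), x])

            def fit(keep):
                coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
                return coef[1]

            jk = block_jackknife(fit, n, n_blocks=40)
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            sigma2 = resid @ resid / (n - 2)
            analytic = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            ratios.append(jk / analytic)
        assert abs(np.median(ratios) - 1.0) < 0.3

    def test_bad_blocks_rejected(self):
        with pytest.raises(ValueError):
            make_blocks(10, 1)
        with pytest.raises(ValueError):
            make_blocks(5, 6)

    def test_default_n_blocks(self):
        assert default_n_blocks(5000) == 200
        assert default_n_blocks(500) == 50
        assert default_n_blocks(500, 17) == 17


class TestPrioritizeAll:
    def test_threshold_and_sorting(self):
        cfg = cp.SimConfig(seed=9, n_blocks=4, snps_per_block=50, n_ref=200)
        panel = cp.simulate_panel(cfg)
        rng = np.random.default_rng(9)
        m = cfg.n_snps
        annots = pd.DataFrame(
            {BASELINE_COL: np.ones(m),
             "ct_a": rng.random(m) * (rng.random(m) < 0.3),
             "ct_b": rng.random(m) * (rng.random(m) < 0.3)}
        )
        ld = ld_scores(panel, annots)
        stats, _ = cp.simulate_gwas(cfg, panel, annots["ct_a"].to_numpy())
        results = cp.prioritize_all(stats, ld, ["ct_a", "ct_b"], alpha=0.05, n_blocks=20)
        ps = [r.p_one_tailed for r in results]
        assert ps == sorted(ps)
        for r in results:
            assert r.significant_bonferroni == (r.p_one_tailed < 0.05 / 2)


def test_panel_roundtrip(tmp_path, small_panel):
    write_panel(small_panel, tmp_path / "d.tsv", tmp_path / "m.tsv")
    back = read_panel(tmp_path / "d.tsv", tmp_path / "m.tsv")
    np.testing.assert_array_equal(back.genotypes, small_panel.genotypes)
    assert list(back.snp_map["snp_id"]) == list(small_panel.snp_map["snp_id"])


def test_small_panel_rejected():
    g = np.random.default_rng(0).integers(0, 3, size=(10, 5))
    snp_map = pd.DataFrame(
        {"snp_id": [f"rs{j}" for j in range(5)], "chrom": "1", "pos_bp": range(1, 6)}
    )
    with pytest.raises(ValueError, match="25"):
        ReferencePanel(g, snp_map)
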