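import numpy as np
import pytest
from scipy import stats

from denseior.anova import (posthoc_bonferroni, rm_anova_validity_by_ctoa,
                            select_replication_ctoas, subset_cell_means)
from denseior.preprocess import CellMeans


def _cm(valid, invalid, ctoa=None):
    valid = np.asarray(valid, float)
    invalid = np.asarray(invalid, float)
    P, C = valid.shape
    if ctoa is None:
        ctoa = (np.arange(C) + 1) * 0.042
    return CellMeans(ctoa=np.asarray(ctoa, float),
                     participants=[f"P{i}" for i in range(P)],
                     valid=valid, invalid=invalid)


def _random_cm(seed, P=12, C=5):
    rng = np.random.default_rng(seed)
    subj = rng.normal(0, 0.6, (P, 1))
    return _cm(rng.normal(size=(P, C)) + subj,
               rng.normal(size=(P, C)) + subj + rng.normal(0, 0.4, (1, C)))


# ---------------------------------------------------------------- oracle ---

def _oracle_anova(Y):
    """Textbook two-way fully-within decomposition + Box epsilon,
    implemented independently of the package (and of pingouin)."""
    S, A, B = Y.shape
    m = Y.mean()
    ms, mi, mj = Y.mean(axis=(1, 2)), Y.mean(axis=(0, 2)), Y.mean(axis=(0, 1))
    msi, msj, mij = Y.mean(axis=2), Y.mean(axis=1), Y.mean(axis=0)
    SS_A = S * B * ((mi - m) ** 2).sum()
    SS_B = S * A * ((mj - m) ** 2).sum()
    SS_AB = S * ((mij - mi[:, None] - mj[None, :] + m) ** 2).sum()
    SS_s = A * B * ((ms - m) ** 2).sum()
    SS_sA = B * ((msi - ms[:, None] - mi[None, :] + m) ** 2).sum()
    SS_sB = A * ((msj - ms[:, None] - mj[None, :] + m) ** 2).sum()
    resid = (Y - msi[:, :, None] - msj[:, None, :] - mij[None, :, :]
             + ms[:, None, None] + mi[None, :, None] + mj[None, None, :] - m)
    SS_sAB = (resid ** 2).sum()
    F = {"validity": (SS_A / (A - 1)) / (SS_sA / ((S - 1) * (A - 1))),
         "ctoa": (SS_B / (B - 1)) / (SS_sB / ((S - 1) * (B - 1))),
         "validity*ctoa": (SS_AB / ((A - 1) * (B - 1)))
         / (SS_sAB / ((S - 1) * (A - 1) * (B - 1)))}
    den = SS_s + SS_sA + SS_sB + SS_sAB
    ng2 = {"validity": SS_A / (SS_A + den), "ctoa": SS_B / (SS_B + den),
           "validity*ctoa": SS_AB / (SS_AB + den)}

    def box_eps(M, df):
        d = M.shape[1]
        cov = np.cov(M.T)
        return (np.trace(cov) ** 2) / (df * np.trace(cov @ cov))

    CB = np.linalg.qr(np.eye(B) - 1 / B)[0][:, :B - 1]
    CA = np.linalg.qr(np.eye(A) - 1 / A)[0][:, :A - 1]
    eps = {"validity": 1.0,
           "ctoa": box_eps(Y.mean(axis=1) @ CB, B - 1),
           "validity*ctoa": box_eps(Y.reshape(S, A * B) @ np.kron(CA, CB),
                                    (A - 1) * (B - 1))}
    return F, ng2, eps


class TestRmAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_decomposition(self, seed):
        cm = _random_cm(seed)
        Y = np.stack([cm.valid, cm.invalid], axis=1)  # S x 2 x C
        F, ng2, eps = _oracle_anova(Y)
        for row in rm_anova_validity_by_ctoa(cm):
            assert row.F == pytest.approx(F[row.effect], abs=1e-8)
            assert row.eta_g_squared == pytest.approx(ng2[row.effect],
                                                      abs=1e-8)
            assert row.eps == pytest.approx(eps[row.effect], abs=1e-8)
            assert row.df1_gg == pytest.approx(row.df1 * row.eps)
            assert row.df2_gg == pytest.approx(row.df2 * row.eps)

    def test_compound_symmetric_covariance_gives_epsilon_one(self):
        # color random data so its sample covariance over the 5 CTOA
        # levels (collapsed over validity) is exactly compound symmetric
        rng = np.random.default_rng(4)
        P, C = 14, 5
        raw = rng.normal(size=(P, C))
        raw -= raw.mean(axis=0)
        white = raw @ np.linalg.inv(np.linalg.cholesky(np.cov(raw.T))).T
        cs = 0.3 + 0.7 * np.eye(C)  # compound-symmetric target
        colored = white @ np.linalg.cholesky(cs).T
        cm = _cm(colored, colored.copy())
        rows = {r.effect: r for r in rm_anova_validity_by_ctoa(cm)}
        assert rows["ctoa"].eps == pytest.approx(1.0, abs=1e-8)

    def test_eta_g_invariant_to_additive_constant(self):
        cm = _random_cm(5)
        shifted = _cm(cm.valid + 11.3, cm.invalid + 11.3, cm.ctoa)
        a = {r.effect: r.eta_g_squared for r in rm_anova_validity_by_ctoa(cm)}
        b = {r.effect: r.eta_g_squared
             for r in rm_anova_validity_by_ctoa(shifted)}
        for eff in a:
            assert a[eff] == pytest.approx(b[eff], abs=1e-10)

    def test_missing_cells_rejected(self):
        cm = _random_cm(6)
        cm.valid[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_validity_by_ctoa(cm)


class TestReplicationSubset:
    def test_default_grid_nearest_multiples(self, grid):
        chosen = select_replication_ctoas(grid)
        assert np.allclose(chosen * 1000, [42, 84, 210, 294, 504])

    def test_fifty_ms_grid_is_exact(self):
        grid = np.arange(1, 21) * 0.05
        chosen = select_replication_ctoas(grid)
        assert np.allclose(chosen * 1000, [50, 100, 200, 300, 500])

    def test_ties_break_toward_shorter_ctoa(self):
        grid = np.array([0.04, 0.06, 0.5])  # 50 ms is equidistant
        assert select_replication_ctoas(grid, targets_ms=(50,))[0] == 0.04

    def test_target_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside"):
            select_replication_ctoas(grid[:5])  # max 210 ms < 500 ms

    def test_subset_preserves_participants(self, grid):
        cm = _random_cm(7, P=6, C=25)
        cm = _cm(cm.valid, cm.invalid, grid)
        sub = subset_cell_means(cm, select_replication_ctoas(grid))
        assert sub.valid.shape == (6, 5)
        assert np.allclose(sub.ctoa * 1000, [42, 84, 210, 294, 504])


class TestPosthoc:
    def test_identical_conditions_degenerate(self):
        cm = _cm(np.ones((8, 5)), np.ones((8, 5)))
        for r in posthoc_bonferroni(cm):
            assert r.t == 0.0 and r.p_bonferroni == 1.0
            assert not r.significant

    def test_known_t_reproduces_published_adjustment(self):
        # engineered paired differences with t(38) = 1.82 at one CTOA:
        # the x5 Bonferroni rule gives the published ~.38 adjusted p
        n = 39
        base = np.linspace(-1, 1, n)
        unit = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
        d = 1.82 / np.sqrt(n) + unit  # mean/SE = 1.82
        valid = np.zeros((n, 5))
        invalid = np.tile(d[:, None], (1, 5))
        rows = posthoc_bonferroni(_cm(valid, invalid))
        expected_raw = 2 * stats.t.sf(1.82, 38)
        for r in rows:
            assert r.t == pytest.approx(1.82, abs=1e-10)
            assert r.df == 38
            assert r.p_raw == pytest.approx(expected_raw, abs=1e-10)
            assert r.p_bonferroni == pytest.approx(min(1, 5 * expected_raw))
            assert r.p_bonferroni == pytest.approx(0.383, abs=0.001)
            assert not r.significant

    def test_adjusted_p_never_below_raw(self):
        cm = _random_cm(8)
        for r in posthoc_bonferroni(cm):
            assert r.p_bonferroni >= r.p_raw
            assert r.p_bonferroni <= 1.0

    def test_sign_convention_facilitation_is_positive(self):
        # faster valid responses (facilitation) -> invalid - valid > 0
        rng = np.random.default_rng(9)
        valid = rng.normal(-0.3, 0.05, (20, 1))
        invalid = rng.normal(0.3, 0.05, (20, 1))
        r, = posthoc_bonferroni(_cm(valid, invalid))
        assert r.t > 0
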