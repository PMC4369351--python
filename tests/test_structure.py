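import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import spearmanr

from multiway3c.genome import GenomeLayout, build_bead_map, make_bins
from multiway3c.structure import (
    ContactGroups,
    ModelConfig,
    _mu_lattice,
    _penalized_loglik,
    build_groups,
    estimate_dmax,
    infer,
    log_likelihood,
    mu_step,
    structure_step,
    superpose_rmsd,
)


@pytest.fixture
def hap5():
    layout = GenomeLayout([("chr1", 5000)])
    bins = make_bins(layout, 1000)
    return layout, bins, build_bead_map(bins, layout)


def _hap_counts_from(X, alpha=-3.0):
    n = X.shape[0]
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2) + np.eye(n)
    return np.where(np.eye(n) == 0, d ** alpha, 0.0)


class TestLogLikelihood:
    def test_hand_evaluated_unit_case(self, hap5):
        """Two beads, c = 1, mu = 1, d = 1: the term is
        0 - 1 - log Gamma(2) = -1."""
        layout = GenomeLayout([("chr1", 2000)])
        bins = make_bins(layout, 1000)
        bm = build_bead_map(bins, layout)
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        groups = build_groups(C, bm, bins)
        X = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert log_likelihood(X, np.ones(1), groups) == pytest.approx(-1.0)

    def test_term_maximized_at_mle_distance(self):
        """For a single pair the term mu*c*a*log d - d^a peaks at
        d = (mu c)^(1/a); checked against a dense 1-D grid."""
        alpha, muc = -3.0, 7.0
        d_grid = np.linspace(0.2, 3.0, 20_000)
        term = muc * alpha * np.log(d_grid) - d_grid ** alpha
        d_star = d_grid[np.argmax(term)]
        assert d_star == pytest.approx(muc ** (1 / alpha), rel=1e-3)

    def test_zero_count_pairs_excluded(self, hap5):
        _, bins, bm = hap5
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 2.0
        groups = build_groups(C, bm, bins)
        assert groups.n_pairs == 1


class TestEstimateDmax:
    def test_constant_adjacent_counts(self, hap5):
        _, bins, bm = hap5
        C = np.zeros((5, 5))
        for k in range(4):
            C[k, k + 1] = C[k + 1, k] = 8.0
        assert estimate_dmax(C, bm, bins) == pytest.approx(8.0 ** (-1 / 3))

    def test_two_values_match_quantile_oracle(self):
        layout = GenomeLayout([("chr1", 3000)])
        bins = make_bins(layout, 1000)
        bm = build_bead_map(bins, layout)
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 1.0   # distance 1.0
        C[1, 2] = C[2, 1] = 8.0   # distance 0.5
        expect = np.quantile([1.0, 0.5], 0.97)
        assert estimate_dmax(C, bm, bins) == pytest.approx(expect)

    def test_monotone_in_counts(self, hap5):
        _, bins, bm = hap5
        C = np.zeros((5, 5))
        for k in range(4):
            C[k, k + 1] = C[k + 1, k] = 5.0
        low = estimate_dmax(C, bm, bins)
        high = estimate_dmax(4 * C, bm, bins)
        assert high < low

    def test_diploid_adjacent_pairs_excluded(self, diploid_layout,
                                             diploid_bins, diploid_beadmap):
        C = np.zeros((20, 20))
        for k in range(9):
            C[k, k + 1] = C[k + 1, k] = 8.0          # haploid chr1
            C[10 + k, 11 + k] = C[11 + k, 10 + k] = 1000.0  # diploid chr2
        # diploid adjacency must not drag the quantile down
        assert estimate_dmax(C, diploid_beadmap, diploid_bins) == \
            pytest.approx(8.0 ** (-1 / 3))


class TestMuStep:
    def _groups(self, diploid_beadmap, diploid_bins, c=10.0, pairs=((0, 10),)):
        C = np.zeros((20, 20))
        for k, l in pairs:
            C[k, l] = C[l, k] = c
        return build_groups(C, diploid_beadmap, diploid_bins)

    def test_haploid_pair_forced_to_one(self, diploid_beadmap, diploid_bins):
        groups = self._groups(diploid_beadmap, diploid_bins, pairs=((0, 1),))
        X = np.random.default_rng(0).normal(size=(30, 3))
        assert mu_step(X, groups, ModelConfig()).tolist() == [1.0]

    def test_symmetric_haploid_diploid_split(self, diploid_beadmap,
                                             diploid_bins):
        groups = self._groups(diploid_beadmap, diploid_bins)
        X = np.zeros((30, 3))
        X[0] = [0, 0, 0]
        bA, bB = diploid_beadmap.beads_for_locus(10)
        X[bA] = [1, 0, 0]
        X[bB] = [0, 1, 0]  # equidistant from bead 0
        mu = mu_step(X, groups, ModelConfig())
        assert mu.tolist() == [0.5, 0.5]

    def test_closer_bead_hits_box_bound(self, diploid_beadmap, diploid_bins):
        groups = self._groups(diploid_beadmap, diploid_bins)
        X = np.zeros((30, 3))
        bA, bB = diploid_beadmap.beads_for_locus(10)
        X[bA] = [0.3, 0, 0]
        X[bB] = [3.0, 0, 0]
        mu = mu_step(X, groups, ModelConfig())
        assert mu.tolist() == [0.7, 0.3]

    def test_matches_exhaustive_lattice_oracle(self, diploid_beadmap,
                                               diploid_bins):
        """Grid search equals brute-force evaluation of the full objective
        over the 0.01 lattice."""
        rng = np.random.default_rng(1)
        groups = self._groups(diploid_beadmap, diploid_bins, c=13.0)
        X = rng.normal(size=(30, 3))
        cfg = ModelConfig()
        mu = mu_step(X, groups, cfg)
        sl = groups.group_slices[0]
        i, j = groups.pair_i[sl], groups.pair_j[sl]
        d = np.linalg.norm(X[i] - X[j], axis=1)
        best, best_val = None, -np.inf
        for lat in _mu_lattice(2, 0.01, (0.3, 0.7)):
            muc = np.asarray(lat) * 13.0
            val = float(np.sum(muc * -3.0 * np.log(d) - d ** -3.0
                               - gammaln(muc + 1)))
            if val > best_val:
                best, best_val = lat, val
        assert mu[sl].tolist() == list(best)

    def test_group_sums_exactly_one(self, diploid_beadmap, diploid_bins):
        rng = np.random.default_rng(2)
        C = rng.poisson(6, size=(20, 20)).astype(float)
        C = C + C.T
        np.fill_diagonal(C, 0)
        groups = build_groups(C, diploid_beadmap, diploid_bins)
        mu = mu_step(rng.normal(size=(30, 3)), groups, ModelConfig())
        for sl in groups.group_slices:
            assert mu[sl].sum() == pytest.approx(1.0, abs=1e-12)
            assert (mu[sl] >= 0).all() and (mu[sl] <= 1).all()


class TestStructureStep:
    def test_three_bead_generative_distances(self):
        """Counts computed from exact d**-3 means on a 3-bead chain:
        recovered pairwise distances match the generative ones within 1%."""
        layout = GenomeLayout([("chr1", 3000)])
        bins = make_bins(layout, 1000)
        bm = build_bead_map(bins, layout)
        X_true = np.array([[0.0, 0, 0], [0.6, 0, 0], [0.9, 0.5, 0.0]])
        C = _hap_counts_from(X_true)
        models = infer(C, bm, bins, ModelConfig(restarts=3, seed=0))
        d_true = np.linalg.norm(X_true[:, None] - X_true[None, :], axis=2)
        d_fit = np.linalg.norm(
            models[0].X[:, None] - models[0].X[None, :], axis=2
        )
        iu = np.triu_indices(3, 1)
        assert np.allclose(d_fit[iu], d_true[iu], rtol=0.01)

    def test_likelihood_invariant_under_rigid_motion(self, hap5):
        _, bins, bm = hap5
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3))
        C = _hap_counts_from(X)
        groups = build_groups(C, bm, bins)
        mu = np.ones(groups.n_pairs)
        base = log_likelihood(X, mu, groups)
        # rotation + translation + reflection
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, -1.0]]
        )
        moved = X @ R.T + np.array([3.0, -2.0, 1.0])
        assert log_likelihood(moved, mu, groups) == pytest.approx(base)

    def test_alternation_monotone_ascent(self, diploid_beadmap, diploid_bins):
        """Each accepted alternation step never lowers the penalized
        objective."""
        rng = np.random.default_rng(4)
        C = rng.poisson(10, size=(20, 20)).astype(float)
        C = C + C.T
        np.fill_diagonal(C, 0)
        groups = build_groups(C, diploid_beadmap, diploid_bins)
        cfg = ModelConfig(seed=0)
        dmax = estimate_dmax(C, diploid_beadmap, diploid_bins)
        X = rng.normal(size=(30, 3)) * dmax
        mu = np.empty(groups.n_pairs)
        for sl in groups.group_slices:
            mu[sl] = 1.0 / (sl.stop - sl.start)
        prev = _penalized_loglik(X, mu, groups, cfg, dmax)
        for _ in range(5):
            mu = mu_step(X, groups, cfg)
            after_mu = _penalized_loglik(X, mu, groups, cfg, dmax)
            assert after_mu >= prev - 1e-8
            X_new = structure_step(X, mu, groups, cfg, dmax)
            after_x = _penalized_loglik(X_new, mu, groups, cfg, dmax)
            if after_x >= after_mu:
                X = X_new
                prev = after_x
            else:
                prev = after_mu


class TestInfer:
    def test_seed_determinism(self, hap5):
        _, bins, bm = hap5
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3)) * 0.4  # compact: keeps counts nonzero
        C = np.round(_hap_counts_from(X) * 3)
        cfg = ModelConfig(restarts=3, seed=11)
        a = infer(C, bm, bins, cfg)
        b = infer(C, bm, bins, cfg)
        assert np.array_equal(a[0].X, b[0].X)
        assert a[0].log_lik == b[0].log_lik

    def test_haploid_genome_mu_degenerate(self, hap5):
        _, bins, bm = hap5
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        C = _hap_counts_from(X)
        models = infer(C, bm, bins, ModelConfig(restarts=2, seed=0))
        assert (models[0].mu == 1.0).all()

    def test_distance_rank_recovery_on_toy_counts(self, hap5):
        """alpha = -3 with rounded d**alpha * scale counts: inferred
        distances rank-correlate > 0.95 with truth."""
        layout = GenomeLayout([("chr1", 8000)])
        bins = make_bins(layout, 1000)
        bm = build_bead_map(bins, layout)
        rng = np.random.default_rng(7)
        t = np.arange(8) * 0.8
        X_true = np.c_[np.cos(t), np.sin(t), 0.2 * t] * 0.5
        d = np.linalg.norm(X_true[:, None] - X_true[None, :], axis=2)
        C = np.round(_hap_counts_from(X_true) * 5)
        models = infer(C, bm, bins, ModelConfig(restarts=4, seed=1))
        d_fit = np.linalg.norm(
            models[0].X[:, None] - models[0].X[None, :], axis=2
        )
        iu = np.triu_indices(8, 1)
        assert spearmanr(d[iu], d_fit[iu]).statistic > 0.95

    def test_top_fraction_selection(self, hap5):
        _, bins, bm = hap5
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 3))
        C = np.round(_hap_counts_from(X) * 2)
        models = infer(C, bm, bins,
                       ModelConfig(restarts=5, top_fraction=0.4, seed=0))
        assert len(models) == 2
        assert models[0].log_lik >= models[1].log_lik


class TestSuperpose:
    def test_rmsd_zero_under_rigid_motion_and_reflection(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(10, 3))
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        B = (A @ R.T) * np.array([1, 1, 1]) + 2.0
        assert superpose_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)
        mirrored = A * np.array([1, 1, -1])
        assert superpose_rmsd(A, mirrored) == pytest.approx(0.0, abs=1e-9)
        assert superpose_rmsd(A, A + rng.normal(size=(10, 3))) > 0.1
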