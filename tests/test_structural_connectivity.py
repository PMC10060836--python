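import numpy as np
import pytest
from scipy import stats

from awfc import LabeledMatrix, SCProbMatrix, fit_zip, second_order, symmetrize
from awfc.cohort_io import VoxelCountTable
from awfc.errors import ComputationError, DegenerateDataError, ValidationError
from awfc.structural_connectivity import (
    ZipFit,
    distance_adjust,
    fit_zip_from_matrices,
    process_subject_sc,
    sc_probability,
    zip_loglik,
)
from helpers import second_order_bruteforce, zip_grid_oracle, zip_sample


def prob_matrix(vals, labels=None):
    vals = np.asarray(vals, dtype=float)
    labels = labels or [f"R{i}" for i in range(vals.shape[0])]
    m = LabeledMatrix(labels=labels, values=vals, kind="sc_prob")
    return SCProbMatrix(matrix=m, provenance=np.full(vals.shape, "direct", dtype="<U8"))


class TestScProbability:
    def test_all_zero_counts(self):
        t = VoxelCountTable(
            counts={("A", "B"): np.zeros(8, dtype=int)}, total_leaving={"A": 100}
        )
        assert sc_probability(t)[("A", "B")] == 0.0

    def test_constant_counts(self):
        t = VoxelCountTable(
            counts={("A", "B"): np.full(6, 5)}, total_leaving={"A": 50}
        )
        assert sc_probability(t)[("A", "B")] == pytest.approx(0.1)

    def test_linear_interpolation_quantile(self):
        t = VoxelCountTable(
            counts={("A", "B"): np.arange(10)}, total_leaving={"A": 100}
        )
        # type-7: h = 9*0.9 = 8.1 -> 8 + 0.1*(9-8) = 8.1
        assert sc_probability(t)[("A", "B")] == pytest.approx(0.081)

    def test_zero_total_leaving_warns_and_zeroes(self, caplog):
        t = VoxelCountTable(
            counts={("A", "B"): np.full(4, 3)}, total_leaving={"A": 0}
        )
        with caplog.at_level("WARNING"):
            assert sc_probability(t)[("A", "B")] == 0.0
        assert "total_leaving" in caplog.text

    def test_clip_to_one(self):
        t = VoxelCountTable(
            counts={("A", "B"): np.full(4, 30)}, total_leaving={"A": 10}
        )
        assert sc_probability(t)[("A", "B")] == 1.0

    def test_bad_percentile(self):
        t = VoxelCountTable(counts={("A", "B"): np.ones(2, int)}, total_leaving={"A": 1})
        with pytest.raises(ValidationError):
            sc_probability(t, percentile=0)


class TestSymmetrize:
    def test_mean(self):
        d = {("A", "B"): 0.2, ("B", "A"): 0.4}
        m = symmetrize(d, ["A", "B"])
        assert m.values[0, 1] == pytest.approx(0.3)
        assert m.values[1, 0] == pytest.approx(0.3)
        assert m.values[0, 0] == 1.0

    def test_equal_passthrough(self):
        m = symmetrize({("A", "B"): 0.4, ("B", "A"): 0.4}, ["A", "B"])
        assert m.values[0, 1] == 0.4

    def test_max_mode(self):
        m = symmetrize({("A", "B"): 0.2, ("B", "A"): 0.4}, ["A", "B"], mode="max")
        assert m.values[0, 1] == 0.4

    def test_all_zero(self):
        d = {(a, b): 0.0 for a in "ABC" for b in "ABC" if a != b}
        m = symmetrize(d, list("ABC"))
        off = ~np.eye(3, dtype=bool)
        assert (m.values[off] == 0).all() and (np.diag(m.values) == 1).all()

    def test_missing_reverse_pair(self):
        with pytest.raises(ValidationError, match="reverse"):
            symmetrize({("A", "B"): 0.2}, ["A", "B"])


class TestFitZip:
    def test_constant_counts_poisson_limit(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(10, 120, 400)
        s = np.full(400, 7)
        f = fit_zip(s, g)
        assert f.alpha0 == pytest.approx(np.log(7), abs=0.05)
        assert f.alpha1 == pytest.approx(0.0, abs=1e-3)
        assert f.omega < 0.02

    def test_parameter_recovery_single_seed(self):
        s, g = zip_sample(1)
        f = fit_zip(s, g)
        assert f.alpha0 == pytest.approx(2.0, abs=0.1)
        assert f.alpha1 == pytest.approx(-0.02, abs=0.005)
        assert f.omega == pytest.approx(0.25, abs=0.05)
        assert f.n_pairs == 1000

    def test_loglik_matches_direct_evaluation(self):
        s, g = zip_sample(1, n=50)
        f = fit_zip(s, g)
        assert f.loglik == pytest.approx(zip_loglik(f.alpha0, f.alpha1, f.omega, s, g))

    def test_grid_oracle_agrees(self):
        s, g = zip_sample(2, n=400)
        f = fit_zip(s, g)
        ll_grid, _ = zip_grid_oracle(s, g)
        assert abs(f.loglik - ll_grid) < 1e-4

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_zip(np.zeros(20, dtype=int), np.linspace(10, 100, 20))

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError, match="at least 6"):
            fit_zip([1, 2, 3], [1.0, 2.0, 3.0])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            fit_zip([1] * 10, [-1.0] + [1.0] * 9)

    def test_median_error_over_replicates(self):
        errs = []
        for seed in range(20):
            s, g = zip_sample(seed)
            errs.append(abs(fit_zip(s, g).alpha1 + 0.02))
        assert np.median(errs) <= 0.003

    def test_from_matrices_uses_all_ordered_pairs(self, tiny_atlas):
        rng = np.random.default_rng(0)
        n = 3
        tot = rng.poisson(8.0, (n, n)).astype(float)
        np.fill_diagonal(tot, 0)
        totals = LabeledMatrix(labels=tiny_atlas.labels, values=tot, kind="tract_count")
        d = rng.uniform(5, 50, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dist = LabeledMatrix(labels=tiny_atlas.labels, values=d, kind="distance")
        f = fit_zip_from_matrices(totals, dist)
        assert f.n_pairs == n * (n - 1)


class TestDistanceAdjust:
    def mk_dist(self, labels, vals):
        return LabeledMatrix(labels=labels, values=np.asarray(vals, float), kind="distance")

    def test_alpha1_zero_identity(self):
        pi = prob_matrix([[1, 0.3], [0.3, 1]])
        fit = ZipFit(alpha0=1.0, alpha1=0.0, omega=0.1, converged=True, n_pairs=10, loglik=0)
        dist = self.mk_dist(pi.labels, [[0, 40], [40, 0]])
        out = distance_adjust(pi, fit, dist)
        assert np.array_equal(out.values, pi.values)

    def test_median_distance_factor(self):
        # pair at g=100 with g_med=50, alpha1=-0.02 -> factor e^1
        labels = ["A", "B", "C", "D"]
        vals = np.full((4, 4), 0.1)
        np.fill_diagonal(vals, 1.0)
        pi = prob_matrix(vals, labels)
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 100.0
        # remaining off-diagonal distances all 50 -> median 50
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            d[i, j] = d[j, i] = 50.0
        fit = ZipFit(alpha0=2.0, alpha1=-0.02, omega=0.2, converged=True, n_pairs=12, loglik=0)
        out = distance_adjust(pi, fit, self.mk_dist(labels, d))
        assert out.values[0, 1] == pytest.approx(0.1 * np.e)
        assert out.values[2, 3] == pytest.approx(0.1)

    def test_clipping_branch(self):
        labels = ["A", "B", "C", "D"]
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 1.0)
        pi = prob_matrix(vals, labels)
        d = np.full((4, 4), 50.0)
        d[0, 1] = d[1, 0] = 100.0
        np.fill_diagonal(d, 0.0)
        fit = ZipFit(alpha0=2.0, alpha1=-0.02, omega=0.2, converged=True, n_pairs=12, loglik=0)
        out = distance_adjust(pi, fit, self.mk_dist(labels, d))
        assert out.values[0, 1] == 1.0  # min(1, 0.5*e) clipped

    def test_longer_pairs_boosted_for_negative_alpha1(self, rng):
        n = 6
        labels = [f"R{i}" for i in range(n)]
        vals = np.full((n, n), 0.05)
        np.fill_diagonal(vals, 1.0)
        pi = prob_matrix(vals, labels)
        d = rng.uniform(10, 120, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        fit = ZipFit(alpha0=2.0, alpha1=-0.02, omega=0.2, converged=True, n_pairs=30, loglik=0)
        out = distance_adjust(pi, fit, self.mk_dist(labels, d))
        iu = np.triu_indices(n, 1)
        ratio = out.values[iu] / pi.values[iu]
        order = np.argsort(d[iu])
        assert (np.diff(ratio[order]) >= -1e-12).all()

    def test_unconverged_requires_force(self):
        pi = prob_matrix([[1, 0.3], [0.3, 1]])
        fit = ZipFit(alpha0=1.0, alpha1=-0.01, omega=0.1, converged=False, n_pairs=10, loglik=0)
        dist = self.mk_dist(pi.labels, [[0, 40], [40, 0]])
        with pytest.raises(ComputationError, match="converge"):
            distance_adjust(pi, fit, dist)
        distance_adjust(pi, fit, dist, force=True)  # no raise


class TestSecondOrder:
    def test_all_zero_unchanged(self):
        vals = np.eye(4)
        out = second_order(prob_matrix(vals))
        assert np.array_equal(out.values, vals)

    def test_three_roi_example(self):
        vals = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.8], [0.5, 0.8, 1.0]])
        out = second_order(prob_matrix(vals))
        assert out.values[0, 2] == pytest.approx(0.72)
        assert out.values[0, 1] == 0.9 and out.values[1, 2] == 0.8
        assert out.provenance[0, 2] == "indirect"
        assert out.provenance[0, 1] == "direct"

    def test_bruteforce_oracle_bitwise(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 1, (10, 10))
            vals = (x + x.T) / 2
            np.fill_diagonal(vals, 1.0)
            out = second_order(prob_matrix(vals))
            assert np.array_equal(out.values, second_order_bruteforce(vals))

    def test_monotone_and_symmetric(self, rng):
        x = rng.uniform(0, 1, (8, 8))
        vals = (x + x.T) / 2
        np.fill_diagonal(vals, 1.0)
        out = second_order(prob_matrix(vals))
        assert (out.values >= vals - 1e-15).all()
        assert np.array_equal(out.values, out.values.T)

    def test_permutation_equivariance(self, rng):
        x = rng.uniform(0, 1, (7, 7))
        vals = (x + x.T) / 2
        np.fill_diagonal(vals, 1.0)
        perm = rng.permutation(7)
        base = second_order(prob_matrix(vals)).values
        permuted = second_order(prob_matrix(vals[np.ix_(perm, perm)])).values
        assert np.array_equal(base[np.ix_(perm, perm)], permuted)

    def test_not_idempotent_in_general(self):
        # chain 0-1-2-3: one pass links 0-2 but 0-3 only via a second pass
        vals = np.eye(4)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            vals[i, j] = vals[j, i] = 0.9
        once = second_order(prob_matrix(vals))
        twice = second_order(once)
        assert twice.values[0, 3] > once.values[0, 3]


class TestFullScStage:
    def test_trend_removal_on_synthetic(self, small_cohort):
        subject = small_cohort.subjects[0]
        con = subject.connectome
        raw, _ = process_subject_sc(
            con.counts, con.distances, adjust="none", apply_second_order=False
        )
        adj, _ = process_subject_sc(
            con.counts, con.distances, adjust="median-distance", apply_second_order=False
        )
        iu = np.triu_indices(len(con.labels), 1)
        g = con.distances.values[iu]
        rho_raw = stats.spearmanr(raw.values[iu], g).statistic
        rho_adj = stats.spearmanr(adj.values[iu], g).statistic
        assert abs(rho_adj) < abs(rho_raw)
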