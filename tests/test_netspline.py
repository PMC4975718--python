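"""Incidence, penalty, smoothing selection and intervals of the network spline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import eigh

from streamnet.netspline import (NetworkSplineModel, OdSpec, aicc,
                                 build_incidence, build_penalty,
                                 build_surface_basis, fit_od_at_lambda,
                                 od_predict, select_lambda)
from streamnet.network import (NetworkPointSet, Segment, StreamNetwork,
                               generate_network)
from streamnet.simulate import ScenarioConfig, ScenarioSimulator, StudyGeometry


@pytest.fixture(scope="module")
def geo():
    return StudyGeometry.build(31, seed=3, n_obs_levels=(60,), n_pred=40)


@pytest.fixture(scope="module")
def dataset(geo):
    cfg = ScenarioConfig(k1=1.0, k2=0, r_phi_factor=0.3, n=60, n_seg=31)
    return ScenarioSimulator(geo, cfg, base_seed=11).replicate(0)


def dense_points(net, per_seg, seed=0):
    """per_seg points on every segment (so B has full column support)."""
    rng = np.random.default_rng(seed)
    seg, upd = [], []
    for i in range(1, net.n_seg + 1):
        for _ in range(per_seg):
            seg.append(i)
            upd.append(net.base_updist[i - 1]
                       + rng.uniform(0, net.lengths[i - 1]))
    return NetworkPointSet(seg, upd, np.zeros(len(seg)), np.zeros(len(seg)))


class TestIncidence:
    def test_column_sums_count_observations(self):
        net = generate_network(5, seed=0)
        pts = NetworkPointSet([2, 2, 5], [0.1, 0.2, 0.1], [0] * 3, [0] * 3)
        B = build_incidence(pts, 5).B.toarray()
        assert list(B.sum(axis=0)) == [0, 2, 0, 0, 1]
        assert (B.sum(axis=1) == 1).all()

    def test_selection_property(self, rand_net, rand_points):
        B = build_incidence(rand_points, rand_net.n_seg).B
        beta = np.random.default_rng(0).normal(size=rand_net.n_seg)
        assert np.allclose(B @ beta, beta[rand_points.segment_ids - 1])

    def test_out_of_range_segment_rejected(self):
        pts = NetworkPointSet([7], [0.0], [0], [0])
        with pytest.raises(ValueError):
            build_incidence(pts, 5)


class TestPenalty:
    def test_constant_vector_in_null_space(self, rand_net):
        pen = build_penalty(rand_net)
        one = np.ones(rand_net.n_seg)
        assert np.abs(pen.D @ one).max() == 0.0
        assert abs(one @ (pen.P @ one)) < 1e-12

    def test_single_confluence_value_and_minimizer(self, small_net):
        # flows 1,1 into 2; beta_a=1, beta_b=0: penalty at the mass-balance
        # value beta_c=0.5 is (1/4)(0.25)+(1/4)(0.25) = 0.125 and minimal
        pen = build_penalty(small_net)

        def quad(bc):
            order = {sid: i for i, sid in enumerate(sorted(small_net.segments))}
            beta = np.zeros(3)
            beta[order[2]] = 1.0
            beta[order[3]] = 0.0
            beta[order[1]] = bc
            return float(beta @ (pen.P @ beta))

        assert quad(0.5) == pytest.approx(0.125)
        grid = np.linspace(-1, 2, 301)
        assert min(grid, key=quad) == pytest.approx(0.5, abs=0.01)

    def test_quadratic_form_matches_explicit_loop(self, rand_net):
        pen = build_penalty(rand_net)
        rng = np.random.default_rng(2)
        for _ in range(5):
            b = rng.normal(size=rand_net.n_seg)
            loop = 0.0
            for a, bb, c in rand_net.confluence_triplets():
                fa, fb, fc = (rand_net.flows[i - 1] for i in (a, bb, c))
                loop += ((fa / fc) ** 2 * (b[a - 1] - b[c - 1]) ** 2
                         + (fb / fc) ** 2 * (b[bb - 1] - b[c - 1]) ** 2)
            assert float(b @ (pen.P @ b)) == pytest.approx(loop, abs=1e-12)

    def test_two_rows_per_confluence_each_with_two_entries(self, rand_net):
        pen = build_penalty(rand_net)
        assert pen.D.shape == (2 * rand_net.n_confluences(), rand_net.n_seg)
        counts = np.diff(pen.D.tocsr().indptr)
        assert (counts == 2).all()


class TestAicc:
    def test_printed_spot_values(self):
        assert aicc(1.0, 10, 100) == pytest.approx(0.25)
        assert aicc(np.e, 0, 4) == pytest.approx(2.0)

    def test_undefined_when_df_too_large(self):
        with pytest.raises(ValueError, match="AICC undefined"):
            aicc(1.0, 98, 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(df=st.floats(0, 50), inc=st.floats(0.1, 10))
    def test_monotone_increasing_in_df(self, df, inc):
        n = 100
        assert aicc(1.5, df + min(inc, n - df - 3), n) >= aicc(1.5, df, n)


class TestFitAtLambda:
    def test_unpenalized_fit_recovers_segment_means(self):
        net = generate_network(5, seed=1)
        pts = dense_points(net, 4)
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(pts))
        m = NetworkSplineModel(y, None, pts, net)
        f = m.fit_at(0.0)
        for i in range(1, 6):
            mask = pts.segment_ids == i
            assert f.beta_seg[i - 1] == pytest.approx(y[mask].mean(),
                                                      abs=1e-5)

    def test_infinite_smoothing_collapses_to_constant(self):
        net = generate_network(9, seed=1)
        pts = dense_points(net, 3)
        y = np.random.default_rng(4).normal(size=len(pts))
        f = NetworkSplineModel(y, None, pts, net).fit_at(1e12)
        assert np.ptp(f.beta_seg) < 1e-5  # null space of D is constant

    def test_df_matches_spectral_oracle(self):
        # df = sum_i 1/(1 + lambda mu_i) with mu_i the generalized
        # eigenvalues of (P, C'C) when C'C is invertible
        net = generate_network(7, seed=2)
        pts = dense_points(net, 5)
        y = np.random.default_rng(5).normal(size=len(pts))
        m = NetworkSplineModel(y, None, pts, net)
        lam = 3.7
        f = m.fit_at(lam)
        Pr = m.P_net_full + m.ridge_full / lam
        mu = eigh(Pr, m.CtC, eigvals_only=True)
        assert f.df == pytest.approx(np.sum(1.0 / (1.0 + lam * mu)),
                                     rel=1e-8)

    def test_negative_lambda_rejected(self, dataset):
        with pytest.raises(ValueError):
            fit_od_at_lambda(dataset, -1.0)


class TestSelection:
    def test_selected_fit_attains_grid_minimum(self, dataset):
        spec = OdSpec()
        best = select_lambda(dataset, spec)
        lo, hi, k = spec.lambda_grid
        for lam in np.geomspace(lo, hi, int(k)):
            f = fit_od_at_lambda(dataset, lam, spec=spec)
            assert best.aicc <= f.aicc + 1e-12

    def test_noise_prefers_heavy_smoothing_signal_prefers_light(self):
        net = generate_network(25, seed=6)
        pts = dense_points(net, 4, seed=1)
        rng = np.random.default_rng(7)
        # strong per-segment step signal vs pure noise
        step = 3.0 * (np.arange(net.n_seg) % 2)
        lam_noise, lam_signal = [], []
        for rep in range(30):
            y_noise = rng.normal(size=len(pts))
            y_signal = step[pts.segment_ids - 1] + 0.2 * rng.normal(
                size=len(pts))
            m1 = NetworkSplineModel(y_noise, None, pts, net)
            m2 = NetworkSplineModel(y_signal, None, pts, net)
            lam_noise.append(m1.fit().lambda_net)
            lam_signal.append(m2.fit().lambda_net)
        assert np.median(lam_noise) > np.median(lam_signal)
        # heavy smoothing dominates under pure noise
        assert np.mean(np.array(lam_noise) > 1.0) >= 0.8


class TestSurfaceBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-2, 3, size=(50, 2))
        basis, _ = build_surface_basis(coords, 8)
        assert np.allclose(basis.sum(axis=1), 1.0)

    def test_constant_coefficients_give_flat_surface_zero_penalty(self):
        coords = np.random.default_rng(9).uniform(0, 1, size=(20, 2))
        basis, P = build_surface_basis(coords, 6)
        g = np.ones(basis.shape[1])
        assert np.allclose(basis @ g, 1.0)
        assert g @ P @ g == pytest.approx(0.0, abs=1e-12)

    def test_tensor_rows_are_products_of_marginal_rows(self):
        coords = np.array([[0.3, 0.7], [0.9, 0.1], [0.5, 0.5]])
        nb = 5
        basis, _ = build_surface_basis(coords, nb, bbox=(0, 1, 0, 1))
        # recompute marginals directly via the 1-d formula
        from scipy.interpolate import BSpline
        t = np.concatenate([np.zeros(3), np.linspace(0, 1, nb - 2),
                            np.ones(3)])
        Bx = BSpline.design_matrix(coords[:, 0], t, 3).toarray()
        By = BSpline.design_matrix(coords[:, 1], t, 3).toarray()
        manual = np.einsum("ni,nj->nij", Bx, By).reshape(3, nb * nb)
        assert np.allclose(basis, manual)

    def test_degenerate_range_rejected(self):
        coords = np.ones((5, 2))
        with pytest.raises(ValueError):
            build_surface_basis(coords, 6)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            build_surface_basis(np.random.rand(5, 2), 3)


class TestIntervalsAndPrediction:
    def test_unpenalized_covariance_equals_ols_form(self):
        net = generate_network(5, seed=1)
        pts = dense_points(net, 6)
        rng = np.random.default_rng(10)
        X = rng.normal(size=(len(pts), 2))
        y = rng.normal(size=len(pts))
        m = NetworkSplineModel(y, X, pts, net, param_names=["X1", "X3"])
        f = m.fit_at(0.0)
        ols_cov = f.sigma_hat ** 2 * np.linalg.inv(m.CtC)
        assert np.allclose(f.cov_params,
                           ols_cov[net.n_seg:net.n_seg + 2,
                                   net.n_seg:net.n_seg + 2], atol=1e-6)

    def test_prediction_approaches_segment_mean_when_unpenalized(self):
        net = generate_network(5, seed=1)
        pts = dense_points(net, 10)
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(pts)) + 2.0 * (pts.segment_ids == 2)
        m = NetworkSplineModel(y, None, pts, net)
        f = m.fit_at(1e-8)
        pred = NetworkPointSet([2], [net.base_updist[1] + 0.01], [0], [0])
        ps = f.predict(pred, None)
        assert ps.mean[0] == pytest.approx(y[pts.segment_ids == 2].mean(),
                                           abs=1e-4)

    def test_prediction_intervals_include_observation_noise(self, dataset):
        f = select_lambda(dataset)
        ps = od_predict(f, dataset=dataset)
        assert (ps.se ** 2 >= f.sigma_hat ** 2 - 1e-12).all()
        assert np.allclose(ps.hi90 - ps.mean, ps.mean - ps.lo90)

    def test_fitted_values_invariant_to_segment_relabeling(self):
        net = generate_network(9, seed=12)
        pts = net.sample_points(40, seed=13)
        rng = np.random.default_rng(14)
        y = rng.normal(size=40)
        f1 = NetworkSplineModel(y, None, pts, net).fit_at(2.0)
        perm = rng.permutation(net.n_seg) + 1
        segs = [Segment(id=int(perm[s.id - 1]),
                        downstream_id=None if s.downstream_id is None
                        else int(perm[s.downstream_id - 1]),
                        length=s.length, flow=s.flow,
                        x0=s.x0, y0=s.y0, x1=s.x1, y1=s.y1)
                for s in net.segments.values()]
        net2 = StreamNetwork(segs)
        pts2 = NetworkPointSet(perm[pts.segment_ids - 1], pts.updist,
                               pts.cx, pts.cy)
        f2 = NetworkSplineModel(y, None, pts2, net2).fit_at(2.0)
        assert np.allclose(f1.fittedvalues, f2.fittedvalues, atol=1e-8)
        assert f1.df == pytest.approx(f2.df, abs=1e-8)

    def test_interval_coverage_on_self_generated_data(self):
        # data generated from the spline model's own class: per-segment
        # means plus iid noise; 90% PIs should cover near nominally
        net = generate_network(21, seed=15)
        rng = np.random.default_rng(16)
        beta_true = rng.normal(size=net.n_seg)
        cover = []
        for rep in range(30):
            obs = net.sample_points(150, seed=100 + rep)
            pred = net.sample_points(80, seed=500 + rep)
            y = beta_true[obs.segment_ids - 1] + 0.5 * rng.normal(size=150)
            yp = beta_true[pred.segment_ids - 1] + 0.5 * rng.normal(size=80)
            f = NetworkSplineModel(y, None, obs, net).fit()
            ps = f.predict(pred, None)
            cover.append(ps.covers(yp).mean())
        assert np.mean(cover) == pytest.approx(0.90, abs=0.05)


class TestSurfaceVariant:
    def test_surface_model_fits_and_predicts(self, geo):
        cfg = ScenarioConfig(k1=1.0, k2=1, r_phi_factor=0.3, n=60, n_seg=31)
        ds = ScenarioSimulator(geo, cfg, base_seed=21).replicate(0)
        spec = OdSpec(include_surface=True, n_knots=6,
                      lambda_surf_grid=(1e-2, 1e4, 4))
        f = select_lambda(ds, spec)
        assert f.lambda_surf is not None
        assert f.gamma is not None and len(f.gamma) == 36
        ps = od_predict(f, dataset=ds)
        assert np.isfinite(ps.mean).all() and (ps.se > 0).all()
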