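import numpy as np
import pytest

from wholeheart.errors import (ConfigurationError, GeometryError, RankError)
from wholeheart.conduction import simulate_activation
from wholeheart.forward_inverse import (BSPRecording, ConductorGeometry,
                                        ElectrodeSet, InverseSettings,
                                        TransferMatrix, add_noise,
                                        annulus_transfer_gain,
                                        build_transfer_matrix_bem,
                                        earliest_breakthrough,
                                        epicardial_surface,
                                        estimate_activation_from_potentials,
                                        forward_project,
                                        make_standard_electrodes,
                                        mean_reference, read_bsp_csv,
                                        read_transfer_matrix,
                                        tikhonov_inverse, write_bsp_csv,
                                        write_transfer_matrix)
from wholeheart.potentials import (PotentialMovie, assign_node_potentials,
                                   make_default_template)


def identity_transfer(n):
    el = ElectrodeSet(np.zeros((n, 3)), [f"E{i}" for i in range(n)],
                      np.arange(n))
    return TransferMatrix(np.eye(n), el, np.arange(n), "test", [0.2])


def random_transfer(rng, rows, cols):
    # well-conditioned by construction: singular values in [1, 2]
    u, _ = np.linalg.qr(rng.normal(size=(rows, rows)))
    v, _ = np.linalg.qr(rng.normal(size=(cols, cols)))
    k = min(rows, cols)
    s = np.linspace(1.0, 2.0, k)
    m = u[:, :k] @ np.diag(s) @ v[:k]
    el = ElectrodeSet(np.zeros((rows, 3)), [f"E{i}" for i in range(rows)],
                      np.arange(rows))
    return TransferMatrix(m, el, np.arange(cols), "test", [0.2])


@pytest.fixture(scope="module")
def small_bem(spheres_level1):
    geom = ConductorGeometry.from_phantom(spheres_level1)
    electrodes = make_standard_electrodes(geom, 20, 0)
    return build_transfer_matrix_bem(geom, electrodes)


class TestBEM:
    def test_rows_sum_to_one(self, small_bem):
        np.testing.assert_allclose(small_bem.matrix.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_constant_potential_transfers_unchanged(self, small_bem):
        c = 7.5
        out = small_bem.matrix @ np.full(small_bem.n_sources, c)
        np.testing.assert_allclose(out, c, atol=1e-5)

    def test_doubling_conductivities_leaves_T_unchanged(self,
                                                        spheres_level1):
        geom = ConductorGeometry.from_phantom(spheres_level1)
        el = make_standard_electrodes(geom, 12, 0)
        t1 = build_transfer_matrix_bem(geom, el)
        geom2 = ConductorGeometry(geom.vertices, geom.surfaces,
                                  [2 * c for c in geom.region_conductivities])
        t2 = build_transfer_matrix_bem(geom2, el)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)

    def test_annulus_gain_formula_against_radial_fd_oracle(self):
        """The closed-form per-degree gain matches a finite-difference
        solve of the radial Laplace equation with insulated outer
        boundary."""
        a, b = 50.0, 200.0
        r = np.linspace(a, b, 4001)
        h = r[1] - r[0]
        for l in range(5):
            n = len(r)
            A = np.zeros((n, n))
            rhs = np.zeros(n)
            A[0, 0] = 1.0
            rhs[0] = 1.0                      # V(a) = 1
            for i in range(1, n - 1):
                A[i, i - 1] = 1 / h ** 2 - 1 / (r[i] * h)
                A[i, i] = -2 / h ** 2 - l * (l + 1) / r[i] ** 2
                A[i, i + 1] = 1 / h ** 2 + 1 / (r[i] * h)
            # insulated: one-sided second-order dV/dr = 0 at r = b
            A[-1, -1] = 3.0
            A[-1, -2] = -4.0
            A[-1, -3] = 1.0
            v = np.linalg.solve(A, rhs)
            assert annulus_transfer_gain(l, a, b) == pytest.approx(
                v[-1], rel=1e-4)

    def test_constant_gain_is_exactly_one(self):
        assert annulus_transfer_gain(0, 50, 200) == 1.0

    def test_open_surface_rejected(self, spheres_level1):
        geom = ConductorGeometry.from_phantom(spheres_level1)
        broken = ConductorGeometry(geom.vertices,
                                   [geom.surfaces[0][:-1], geom.surfaces[1]],
                                   geom.region_conductivities)
        with pytest.raises(GeometryError, match="manifold"):
            broken.validate()

    def test_non_nested_surfaces_rejected(self, spheres_level1):
        geom = ConductorGeometry.from_phantom(spheres_level1)
        shifted = geom.vertices.copy()
        inner_nodes = np.unique(geom.surfaces[0])
        shifted[inner_nodes] += np.array([500.0, 0.0, 0.0])
        bad = ConductorGeometry(shifted, geom.surfaces,
                                geom.region_conductivities)
        with pytest.raises(GeometryError, match="nested"):
            bad.validate()

    def test_epicardial_surface_is_closed_envelope(self, heart):
        tris, nodes = epicardial_surface(heart)
        from wholeheart.topology import shell_signed_volume
        assert shell_signed_volume(heart.vertices, tris) > 0
        e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                            tris[:, [2, 0]]])
        key = (np.minimum(e[:, 0], e[:, 1]) * (heart.n_nodes + 1)
               + np.maximum(e[:, 0], e[:, 1]))
        _, counts = np.unique(key, return_counts=True)
        assert np.all(counts == 2)


class TestForwardProjection:
    def test_zero_movie_gives_zero_bsp(self, small_bem):
        movie = PotentialMovie(np.zeros((small_bem.n_sources, 5)), 1.0)
        bsp = forward_project(small_bem, movie)
        assert np.all(bsp.data == 0)

    def test_linearity(self, small_bem):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(small_bem.n_sources, 4))
        y = rng.normal(size=(small_bem.n_sources, 4))
        fx = forward_project(small_bem, PotentialMovie(x, 1.0)).data
        fy = forward_project(small_bem, PotentialMovie(y, 1.0)).data
        fxy = forward_project(small_bem,
                              PotentialMovie(2 * x - 3 * y, 1.0)).data
        np.testing.assert_allclose(fxy, 2 * fx - 3 * fy, atol=1e-12)

    def test_single_node_spike_reads_matrix_column(self, small_bem):
        k = 5
        x = np.zeros((small_bem.n_sources, 1))
        x[k, 0] = 1.0
        bsp = forward_project(small_bem, PotentialMovie(x, 1.0))
        np.testing.assert_allclose(bsp.data[:, 0], small_bem.matrix[:, k])

    def test_dimension_mismatch_rejected(self, small_bem):
        with pytest.raises(ConfigurationError):
            forward_project(small_bem, PotentialMovie(np.zeros((3, 5)), 1.0))


class TestNoise:
    def test_huge_snr_leaves_data_unchanged(self):
        rng = np.random.default_rng(0)
        bsp = BSPRecording(rng.normal(size=(8, 100)), 1000.0)
        out = add_noise(bsp, 300.0, seed=1)
        np.testing.assert_allclose(out.data, bsp.data, atol=1e-12)

    def test_empirical_snr_matches_request(self):
        rng = np.random.default_rng(1)
        bsp = BSPRecording(rng.normal(size=(10, 1000)), 1000.0)
        out = add_noise(bsp, 20.0, seed=2)
        noise = out.data - bsp.data
        snr = 10 * np.log10(np.mean(bsp.data ** 2) / np.mean(noise ** 2))
        assert snr == pytest.approx(20.0, abs=0.5)

    def test_same_seed_reproducible(self):
        bsp = BSPRecording(np.ones((4, 50)), 1000.0)
        a = add_noise(bsp, 10.0, seed=9)
        b = add_noise(bsp, 10.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestTikhonov:
    def test_identity_lambda_zero_recovers_input(self):
        T = identity_transfer(6)
        rng = np.random.default_rng(3)
        b = rng.normal(size=(6, 4))
        x = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                             InverseSettings(lam=0.0, mean_reference=False))
        np.testing.assert_allclose(x.data, b, atol=1e-12)

    def test_identity_lambda_one_halves_input(self):
        T = identity_transfer(4)
        b = np.ones((4, 2))
        x = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                             InverseSettings(lam=1.0, mean_reference=False))
        np.testing.assert_allclose(x.data, b / 2, atol=1e-12)

    def test_round_trip_well_conditioned_within_1_percent(self):
        rng = np.random.default_rng(8)
        T = random_transfer(rng, 20, 15)
        x_true = rng.normal(size=(15, 10))
        b = T.matrix @ x_true
        x = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                             InverseSettings(lam=0.01,
                                             mean_reference=False))
        rel = np.linalg.norm(x.data - x_true) / np.linalg.norm(x_true)
        assert rel < 0.01

    def test_svd_and_normal_variants_agree(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            T = random_transfer(rng, 12, 9)
            b = rng.normal(size=(12, 5))
            xa = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                                  InverseSettings(lam=0.01, variant="normal"))
            xb = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                                  InverseSettings(lam=0.01, variant="svd"))
            rel = (np.linalg.norm(xa.data - xb.data)
                   / np.linalg.norm(xa.data))
            assert rel <= 1e-8

    def test_lambda_zero_rank_deficient_rejected(self):
        el = ElectrodeSet(np.zeros((4, 3)), list("abcd"), np.arange(4))
        m = np.zeros((4, 3))
        m[:, 0] = 1.0
        T = TransferMatrix(m, el, np.arange(3), "x", [0.2])
        with pytest.raises(RankError):
            tikhonov_inverse(T, BSPRecording(np.ones((4, 2)), 1000.0),
                             InverseSettings(lam=0.0))

    def test_lcurve_monotonicity(self):
        """Solution norm non-increasing, residual norm non-decreasing
        in lambda."""
        rng = np.random.default_rng(21)
        T = random_transfer(rng, 20, 15)
        b = rng.normal(size=(20, 3))
        lams = [0.0, 0.01, 0.1, 1.0, 10.0]
        sol_norms, res_norms = [], []
        for lam in lams:
            x = tikhonov_inverse(T, BSPRecording(b, 1000.0),
                                 InverseSettings(lam=lam,
                                                 mean_reference=False))
            sol_norms.append(np.linalg.norm(x.data))
            res_norms.append(np.linalg.norm(T.matrix @ x.data - b))
        assert np.all(np.diff(sol_norms) <= 1e-9)
        assert np.all(np.diff(res_norms) >= -1e-9)


class TestActivationEstimation:
    def test_round_trip_recovers_times_within_dt(self, slab,
                                                 slab_activation):
        tpl = make_default_template()
        movie = assign_node_potentials(slab_activation, tpl)
        for marker in ("threshold", "steepest"):
            est = estimate_activation_from_potentials(movie, marker=marker,
                                                      amplitude_gate=0.0)
            err = np.abs(est.times - slab_activation.times)
            assert np.nanmax(err[np.isfinite(slab_activation.times)]) <= \
                movie.dt + 1e-9

    def test_negative_marker_on_electrogram_shaped_trace(self):
        """The classical -dV/dt marker recovers the shift of a trace whose
        activation deflection is a sharp negative drop."""
        from wholeheart.potentials import ActionPotentialTemplate
        n = 200
        samples = np.zeros(60)
        samples[10:13] = [5.0, -20.0, 0.1]    # sharp R-S deflection
        samples[13:50] = np.linspace(0.1, 0.0, 37)
        samples[-1] = 0.0
        tpl = ActionPotentialTemplate(samples, 1.0, 0.0)
        from wholeheart.conduction import ActivationMap
        amap = ActivationMap(np.array([0.0, 40.0]), np.zeros(2, int), [])
        movie = assign_node_potentials(amap, tpl)
        est = estimate_activation_from_potentials(movie, marker="negative")
        assert est.times[1] - est.times[0] == pytest.approx(40.0, abs=1.0)

    def test_constant_movie_all_blocked(self):
        movie = PotentialMovie(np.full((5, 50), -90.0), 1.0)
        est = estimate_activation_from_potentials(movie)
        assert np.all(est.blocked)

    def test_single_shifted_node(self):
        tpl = make_default_template()
        from wholeheart.conduction import ActivationMap
        amap = ActivationMap(np.array([37.0]), np.zeros(1, int), [])
        movie = assign_node_potentials(amap, tpl)
        est = estimate_activation_from_potentials(movie, marker="steepest")
        assert est.times[0] == pytest.approx(37.0, abs=tpl.dt)


class TestBreakthrough:
    def test_single_source_breakthrough_is_nearest_node(self, slab,
                                                        slab_activation):
        bt = earliest_breakthrough(slab_activation, np.arange(slab.n_nodes))
        assert bt == (0, 0.0)

    def test_tie_breaks_to_lower_node_id(self):
        from wholeheart.conduction import ActivationMap
        amap = ActivationMap(np.array([5.0, 1.0, 1.0]), np.zeros(3, int), [])
        assert earliest_breakthrough(amap, [0, 1, 2]) == (1, 1.0)
        assert earliest_breakthrough(amap, [2, 1]) == (1, 1.0)

    def test_all_blocked_returns_none(self):
        from wholeheart.conduction import ActivationMap
        amap = ActivationMap(np.array([np.inf, np.inf]),
                             np.full(2, -1), [])
        assert earliest_breakthrough(amap, [0, 1]) is None


class TestIO:
    def test_bsp_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        el = ElectrodeSet(rng.normal(size=(4, 3)), list("abcd"),
                          np.arange(4))
        bsp = BSPRecording(rng.normal(size=(4, 20)), 2048.0, el, "fp123")
        p = tmp_path / "bsp.csv"
        write_bsp_csv(bsp, str(p), str(tmp_path / "el.csv"))
        back = read_bsp_csv(str(p))
        np.testing.assert_allclose(back.data, bsp.data, rtol=1e-12)
        assert back.sample_rate_hz == 2048.0
        assert back.transfer_fingerprint == "fp123"

    def test_transfer_matrix_round_trip(self, small_bem, tmp_path):
        p = tmp_path / "T.txt"
        write_transfer_matrix(small_bem, str(p))
        back = read_transfer_matrix(str(p))
        np.testing.assert_allclose(back.matrix, small_bem.matrix,
                                   rtol=1e-12)
        assert back.geometry_fingerprint == small_bem.geometry_fingerprint
        np.testing.assert_array_equal(back.source_nodes,
                                      small_bem.source_nodes)

    def test_fingerprint_mismatch_rejected(self, small_bem):
        bsp = BSPRecording(np.zeros((small_bem.n_electrodes, 3)), 1000.0,
                           transfer_fingerprint="bogus")
        with pytest.raises(ConfigurationError, match="fingerprint"):
            tikhonov_inverse(small_bem, bsp)


class TestEndToEnd:
    def test_noise_free_round_trip_recovers_epicardial_times(
            self, heart, heart_activation, heart_torso_transfer):
        """Activation times estimated from the noise-free inverse solution
        reproduce the simulated epicardial sequence (rank correlation)."""
        T = heart_torso_transfer
        tpl = make_default_template()
        movie = assign_node_potentials(heart_activation, tpl)
        bsp = mean_reference(
            forward_project(T, movie.restricted_to(T.source_nodes)))
        inv = tikhonov_inverse(T, bsp, InverseSettings(lam=0.01))
        est = estimate_activation_from_potentials(inv)
        true_t = heart_activation.times[T.source_nodes]
        fin = np.isfinite(est.times) & np.isfinite(true_t)
        corr = np.corrcoef(est.times[fin], true_t[fin])[0, 1]
        assert corr > 0.85
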