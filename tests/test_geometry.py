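import numpy as np
import pytest

from lvmodes.geometry import (GeometryError, PeriodicSurfaceSpline,
                              ProlateCoordinate, QuadratureGrid,
                              cartesian_to_prolate, make_fixture_geometry,
                              periodic_simpson_weights, prolate_to_cartesian,
                              scale_factors, wall_volume)


def shell_volume(a, mu1, mu2, nu_up):
    """Closed-form volume of a truncated confocal ellipsoidal shell."""
    c3 = lambda m: np.cosh(m) ** 3 / 3 - np.cosh(m)
    i1 = 1 + np.cos(nu_up)
    i3 = 2 / 3 - np.cos(nu_up) ** 3 / 3 + np.cos(nu_up)
    return 2 * np.pi * a ** 3 * ((c3(mu2) - c3(mu1)) * i1
                                 + (np.cosh(mu2) - np.cosh(mu1)) * i3)


class TestCoordinateMap:
    @pytest.mark.parametrize("mu,nu,phi,a,expected", [
        (0.8, 0.0, 1.7, 1.0, (0.0, 0.0, np.cosh(0.8))),   # on-axis
        (0.0, np.pi / 2, 0.0, 1.0, (0.0, 0.0, 0.0)),      # focal midpoint
        (1.0, np.pi / 2, 0.0, 1.0, (np.sinh(1.0), 0.0, 0.0)),
    ])
    def test_forward_map_values(self, mu, nu, phi, a, expected):
        assert np.allclose(prolate_to_cartesian(mu, nu, phi, a), expected,
                           atol=1e-14)

    def test_on_axis_inverse(self):
        mu, nu, phi = cartesian_to_prolate(0.0, 0.0, 2.0, 1.0)
        assert nu == pytest.approx(0.0, abs=1e-12)
        assert mu == pytest.approx(np.arccosh(2.0), abs=1e-12)

    def test_equator_inverse(self):
        a = 2.5
        mu, nu, phi = cartesian_to_prolate(a * np.sinh(1.0), 0.0, 0.0, a)
        assert (mu, nu, phi) == pytest.approx((1.0, np.pi / 2, 0.0), abs=1e-12)

    def test_roundtrip_random_interior(self, rng):
        mu = rng.uniform(0.1, 1.5, 100)
        nu = rng.uniform(0.05, np.pi - 0.05, 100)
        phi = rng.uniform(0, 2 * np.pi, 100)
        x, y, z = prolate_to_cartesian(mu, nu, phi, 3.1)
        m2, n2, p2 = cartesian_to_prolate(x, y, z, 3.1)
        for got, want in [(m2, mu), (n2, nu), (p2, phi)]:
            assert np.max(np.abs(got - want) / np.maximum(np.abs(want), 1)) < 1e-10

    def test_focal_segment_is_degenerate(self):
        with pytest.raises(GeometryError):
            cartesian_to_prolate(0.0, 0.0, 0.3, 1.0)

    def test_coordinate_invariants(self):
        with pytest.raises(GeometryError):
            ProlateCoordinate(-0.1, 1.0, 0.0)
        with pytest.raises(GeometryError):
            ProlateCoordinate(0.1, 3.5, 0.0)
        p = ProlateCoordinate(0.1, 1.0, 7.0)
        assert 0.0 <= p.phi < 2 * np.pi


class TestScaleFactors:
    def test_axis_singularity(self):
        assert scale_factors(0.0, 0.0, 1.0) == pytest.approx((0, 0, 0))

    def test_focal_equator(self):
        assert scale_factors(0.0, np.pi / 2, 1.0) == pytest.approx((1, 1, 0))

    def test_matches_arc_length_derivatives(self, rng):
        a, h = 2.0, 1e-6
        mu, nu, phi = 0.7, 1.1, 0.4
        g_mu, g_nu, g_phi = scale_factors(mu, nu, a)
        for i, g in enumerate((g_mu, g_nu, g_phi)):
            d = np.zeros(3)
            d[i] = h
            xp = np.array(prolate_to_cartesian(mu + d[0], nu + d[1],
                                               phi + d[2], a))
            xm = np.array(prolate_to_cartesian(mu - d[0], nu - d[1],
                                               phi - d[2], a))
            assert np.linalg.norm(xp - xm) / (2 * h) == pytest.approx(g, rel=1e-8)


class TestSurfaceSpline:
    def make(self, fun):
        nu = np.linspace(1.2, np.pi, 11)
        phi = np.linspace(0, 2 * np.pi, 13)
        NN, PP = np.meshgrid(nu, phi, indexing="ij")
        return PeriodicSurfaceSpline(nu, phi, fun(NN, PP))

    def test_constant_surface(self):
        s = self.make(lambda n, p: np.full_like(n, 0.63))
        pts = [(1.3, 0.1), (2.0, 3.0), (3.1, 6.0)]
        for nu, phi in pts:
            assert s(nu, phi) == pytest.approx(0.63, abs=1e-12)
            assert s(nu, phi, dnu=1) == pytest.approx(0.0, abs=1e-10)
            assert s(nu, phi, dphi=1) == pytest.approx(0.0, abs=1e-10)

    def test_seam_continuity(self):
        s = self.make(lambda n, p: 0.6 + 0.05 * np.sin(n) * np.cos(p))
        for d in [(0, 0), (1, 0), (0, 1)]:
            left = s(2.0, 0.0, dnu=d[0], dphi=d[1])
            right = s(2.0, 2 * np.pi - 1e-13, dnu=d[0], dphi=d[1])
            assert left == pytest.approx(right, abs=1e-9)

    def test_partials_match_finite_differences(self):
        s = self.make(lambda n, p: 0.6 + 0.04 * np.cos(n) * np.sin(2 * p))
        nu, phi, h = 2.1, 1.0, 1e-5
        fd_nu = (s(nu + h, phi) - s(nu - h, phi)) / (2 * h)
        fd_phi = (s(nu, phi + h) - s(nu, phi - h)) / (2 * h)
        assert s(nu, phi, dnu=1) == pytest.approx(fd_nu, abs=1e-8)
        assert s(nu, phi, dphi=1) == pytest.approx(fd_phi, abs=1e-8)

    def test_out_of_range_nu_rejected(self):
        s = self.make(lambda n, p: np.full_like(n, 0.6))
        with pytest.raises(GeometryError):
            s(0.3, 1.0)


class TestQuadratureAndVolume:
    def test_wall_volume_matches_closed_form(self):
        a, m1, m2, nu_up = 4.4, 0.6, 0.82, 0.45 * np.pi
        dom = make_fixture_geometry("axisymmetric", a=a, mu_in=m1,
                                    mu_out=m2, nu_up=nu_up)
        v = wall_volume(dom)
        assert v == pytest.approx(shell_volume(a, m1, m2, nu_up), rel=1e-3)

    def test_volume_scales_cubically_with_focal_length(self):
        v1 = wall_volume(make_fixture_geometry("axisymmetric", a=3.0))
        v2 = wall_volume(make_fixture_geometry("axisymmetric", a=6.0))
        assert v2 / v1 == pytest.approx(8.0, rel=1e-10)

    def test_thin_wall_limit(self):
        dom = make_fixture_geometry("axisymmetric", mu_in=0.7999, mu_out=0.8)
        assert wall_volume(dom) < 0.2

    def test_simpson_convergence_order(self):
        a, m1, m2, nu_up = 4.4, 0.6, 0.82, 0.45 * np.pi
        dom = make_fixture_geometry("axisymmetric")
        exact = shell_volume(a, m1, m2, nu_up)
        errs = [abs(wall_volume(dom, n_mu=m, n_nu=n, n_phi=p) - exact)
                for m, n, p in ((3, 5, 8), (5, 9, 16), (9, 17, 32))]
        assert errs[0] > errs[1] > errs[2]
        order = np.log2(errs[1] / errs[2])
        assert order > 2.0

    def test_grid_requires_odd_and_even_counts(self, dom_axi):
        with pytest.raises(GeometryError):
            QuadratureGrid.build(dom_axi, n_mu=4)
        with pytest.raises(GeometryError):
            periodic_simpson_weights(7)
        assert periodic_simpson_weights(20).sum() == pytest.approx(2 * np.pi)

    def test_grid_nodes_inside_domain(self, dom_asym):
        g = QuadratureGrid.build(dom_asym, n_mu=5, n_nu=11, n_phi=12)
        m_in = np.asarray(dom_asym.mu_in0(g.nu0, g.phi0))
        m_out = np.asarray(dom_asym.mu_out0(g.nu0, g.phi0))
        assert np.all(g.mu0 >= m_in - 1e-12)
        assert np.all(g.mu0 <= m_out + 1e-12)
        assert np.all(g.nu0 <= np.pi)
        assert np.all(g.nu0 >= np.asarray(dom_asym.nu_up0(g.phi0)) - 1e-12)


class TestFixtures:
    def test_axisymmetric_is_axisymmetric(self, dom_axi):
        nu = np.full(8, 2.2)
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        vals = np.asarray(dom_axi.mu_in0(nu, phi))
        assert np.ptp(vals) < 1e-12

    def test_asymmetric_preset_valid(self, dom_asym):
        dom_asym.validate()  # raises on wall inversion
        assert wall_volume(dom_asym) > 0

    def test_wall_inversion_rejected(self):
        with pytest.raises(GeometryError):
            make_fixture_geometry("asymmetric-septal", mu_in=0.79,
                                  mu_out=0.8, septal_amp=-0.05)

    def test_serialization_roundtrip(self, dom_asym, tmp_path):
        from lvmodes.geometry import ReferenceDomain
        path = tmp_path / "dom.json"
        dom_asym.to_json(path)
        dom2 = ReferenceDomain.from_json(str(path))
        nu, phi = 2.0, 1.1
        assert dom2.mu_in0(nu, phi) == pytest.approx(dom_asym.mu_in0(nu, phi))
        assert dom2.a == dom_asym.a
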