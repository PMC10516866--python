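"""Single-curve analyses against closed forms and brute-force oracles."""

import numpy as np
import pytest

from af4saxs import curves as C
from af4saxs import synth as S
from af4saxs.io import ScatteringCurve


def _curve(q, i, rel_sigma=1e-6):
    return ScatteringCurve(q, i, rel_sigma * np.maximum(np.abs(i), 1e-12))


class TestGuinier:
    def test_exact_gaussian_machine_precision(self):
        a, c0 = 3.0, 42.0
        q = np.linspace(0.01, 0.4, 100)
        i = c0 * np.exp(-(q**2) * a**2 / 3.0)
        g = C.guinier(_curve(q, i))
        assert g.rg == pytest.approx(a, rel=1e-9)
        assert g.i0 == pytest.approx(c0, rel=1e-9)

    def test_sphere_rg_closed_form(self):
        R = 10.0
        q = np.linspace(0.005, 1.0, 500)
        c = S.sphere_curve(q, R, 1000.0)
        g = C.guinier(_curve(q, c.intensity), q_rg_limit=0.7)
        assert g.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.01)

    def test_increasing_intensity_has_no_guinier_region(self):
        q = np.linspace(0.01, 0.2, 50)
        i = 1.0 + q**2
        with pytest.raises(C.NoGuinierRegionError):
            C.guinier(_curve(q, i))

    def test_scale_equivariance(self):
        q = np.linspace(0.01, 0.4, 80)
        i = 5.0 * np.exp(-(q**2) * 4.0 / 3.0)
        g1 = C.guinier(_curve(q, i))
        g2 = C.guinier(_curve(q, 10 * i))
        assert g2.rg == pytest.approx(g1.rg, rel=1e-12)
        assert g2.i0 == pytest.approx(10 * g1.i0, rel=1e-9)


class TestPorod:
    def test_ideal_porod_law(self):
        q = np.linspace(0.2, 2.0, 100)
        x, pre, flagged = C.porod_exponent(_curve(q, q**-4.0), (0.2, 2.0))
        assert x == pytest.approx(4.0, abs=1e-9)
        assert not flagged

    def test_scale_moves_prefactor_not_exponent(self):
        q = np.linspace(0.2, 2.0, 60)
        i = 3.0 * q**-3.5
        x1, p1, _ = C.porod_exponent(_curve(q, i), (0.2, 2.0))
        x2, p2, _ = C.porod_exponent(_curve(q, 10 * i), (0.2, 2.0))
        assert x2 == pytest.approx(x1, abs=1e-12)
        assert p2 == pytest.approx(10 * p1, rel=1e-9)

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(5)
        q = np.linspace(0.2, 0.7, 40)
        i = 2.0 * q**-3.63 * (1 + 0.01 * rng.normal(size=40))
        c = ScatteringCurve(q, i, 0.01 * i)
        x_fit, pre_fit, _ = C.porod_exponent(c, (0.2, 0.7))
        # brute force: weighted SSE in log space over (x, prefactor) grid
        xs = np.linspace(3.0, 4.2, 2401)
        w = 1.0 / (c.sigma / i) ** 2
        best = None
        ln_q, ln_i = np.log(q), np.log(i)
        for x in xs:
            a = np.sum(w * (ln_i + x * ln_q)) / np.sum(w)
            sse = np.sum(w * (ln_i - (a - x * ln_q)) ** 2)
            if best is None or sse < best[1]:
                best = (x, sse)
        assert x_fit == pytest.approx(best[0], abs=1e-3)

    def test_bragg_peak_inside_window_flagged(self):
        from af4saxs.bragg import lorentzian
        q = np.linspace(0.2, 1.4, 200)
        i = 5.0 * q**-3.6 + lorentzian(q, 0.0, 2.0, 0.08, 1.047)
        c = ScatteringCurve(q, i, 0.001 * i)
        _, _, flagged = C.porod_exponent(c, (0.7, 1.4))
        assert flagged


class TestKratky:
    def test_coil_plateau(self):
        q = np.linspace(0.1, 2.0, 50)
        qk, y = C.kratky(_curve(q, q**-2.0))
        assert np.allclose(y, 1.0)

    def test_globular_interior_maximum(self):
        q = np.linspace(0.01, 2.0, 300)
        i = np.exp(-(q**2) * 9.0 / 3.0)
        _, y = C.kratky(_curve(q, i))
        k = np.argmax(y)
        assert 0 < k < len(q) - 1

    def test_transform_invertible(self):
        q = np.linspace(0.1, 1.0, 40)
        i = np.exp(-q)
        qk, y = C.kratky(_curve(q, i))
        assert np.allclose(y / qk**2, i)


class TestMwFromVc:
    @staticmethod
    def _globular_66kda():
        # BSA-like globular model: Gaussian curve at Rg 2.7 nm <-> 66 kDa
        q = np.linspace(0.01, 4.0, 600)
        i = 100.0 * np.exp(-(q**2) * 2.7**2 / 3.0)
        return _curve(q, i + 1e-9)

    def test_scale_invariance_of_mw(self):
        c = self._globular_66kda()
        g = C.guinier(c)
        c2 = ScatteringCurve(c.q, 2 * c.intensity, 2 * c.sigma)
        g2 = C.guinier(c2)
        m1 = C.mw_from_vc(c, g, "protein")
        m2 = C.mw_from_vc(c2, g2, "protein")
        assert m2.mw == pytest.approx(m1.mw, rel=1e-6)

    def test_globular_mw_within_15pct(self):
        c = self._globular_66kda()
        g = C.guinier(c)
        m = C.mw_from_vc(c, g, "protein")
        assert m.mw == pytest.approx(66.0, rel=0.15)
        assert not m.truncated

    def test_truncated_curve_flagged_and_shifted(self):
        c = self._globular_66kda()
        g = C.guinier(c)
        m_full = C.mw_from_vc(c, g, "protein")
        sel = c.q <= 1.5
        c_cut = ScatteringCurve(c.q[sel], c.intensity[sel], c.sigma[sel])
        m_cut = C.mw_from_vc(c_cut, C.guinier(c_cut), "protein")
        assert m_cut.truncated
        assert m_cut.mw != pytest.approx(m_full.mw, rel=1e-12)

    def test_rna_class_uses_power_law_calibration(self):
        c = self._globular_66kda()
        g = C.guinier(c)
        m = C.mw_from_vc(c, g, "rna")
        assert m.mw > 0 and m.molecule_class == "rna"


class TestPofR:
    def test_solid_sphere_dmax_and_shape(self):
        R = 5.0
        q = np.linspace(0.05, 4.0, 300)
        c = S.sphere_curve(q, R, 1000.0)
        cc = ScatteringCurve(q, c.intensity, np.full_like(q, 1.0))
        res = C.pofr(cc, dmax_guess=11.0)
        assert res.dmax == pytest.approx(2 * R, rel=0.05)
        r = res.r
        x = np.minimum(r / (2 * R), 1.0)
        p_true = np.where(r <= 2 * R, r**2 * (1 - 1.5 * x + 0.5 * x**3), 0.0)
        corr = np.corrcoef(res.p, p_true)[0, 1]
        assert corr > 0.99
        assert res.p[0] == 0.0 and res.p[-1] == 0.0

    def test_rg_real_consistent_with_guinier(self):
        R = 5.0
        q = np.linspace(0.05, 4.0, 300)
        c = S.sphere_curve(q, R, 1000.0)
        cc = ScatteringCurve(q, c.intensity, np.full_like(q, 1.0))
        res = C.pofr(cc, dmax_guess=11.0)
        g = C.guinier(_curve(q, c.intensity + 1e-12), q_rg_limit=0.7)
        assert res.rg_real == pytest.approx(g.rg, rel=0.05)

    def test_bad_guess_rejected(self):
        q = np.linspace(0.05, 4.0, 300)
        c = S.sphere_curve(q, 5.0, 1000.0)
        cc = ScatteringCurve(q, c.intensity, np.full_like(q, 1.0))
        with pytest.raises(ValueError):
            C.pofr(cc, dmax_guess=-1.0)
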