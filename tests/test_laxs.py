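"""Smectic fluctuation model: correlations, structure factor, elasticity fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import j0

from membranescatter.laxs import (
    DiffuseMap,
    ElasticityFitter,
    StackParameters,
    StructureFactorEngine,
    correlation_functions,
    default_q_nodes,
    layer_modes,
    model_intensity,
    structure_factor,
    T_REF,
)
from membranescatter.sdp import SDPModel, SDPParams, default_composition
from membranescatter.synthetic import gen_diffuse_map


def small_stack(**kw):
    defaults = dict(kc=20.0, b=5e-6, n_layers=4, domain_lr=600.0, d_spacing=60.0)
    defaults.update(kw)
    return StackParameters(**defaults)


class TestCorrelations:
    def test_nonnegative_and_zero_at_origin(self):
        p = small_stack()
        r = np.linspace(0.0, 500.0, 40)
        delta = correlation_functions(p, r)
        assert delta.min() > -1e-10
        assert delta[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_coupling_limit(self):
        """Very large B locks neighbouring bilayers together."""
        soft = correlation_functions(small_stack(b=1e-5), [0.0], offsets=[1])[0, 0]
        rigid = correlation_functions(small_stack(b=10.0), [0.0], offsets=[1])[0, 0]
        assert rigid < 1e-3 * soft

    def test_equipartition_linear_in_temperature(self):
        r = np.array([0.0, 50.0, 300.0])
        d1 = correlation_functions(small_stack(temperature=300.0), r)
        d2 = correlation_functions(small_stack(temperature=600.0), r)
        assert np.allclose(d2, 2.0 * d1, rtol=1e-12)

    @pytest.mark.parametrize("field,factor", [("kc", 2.0), ("b", 2.0)])
    def test_stiffer_means_smaller_fluctuations(self, field, factor):
        base = dict(kc=20.0, b=5e-6)
        stiff = dict(base)
        stiff[field] = base[field] * factor
        r = np.array([0.0, 100.0])
        d_soft = correlation_functions(small_stack(**base), r, offsets=[1, 3])
        d_stiff = correlation_functions(small_stack(**stiff), r, offsets=[1, 3])
        assert np.all(d_stiff <= d_soft + 1e-12)
        assert d_stiff.sum() < d_soft.sum()

    def test_invalid_moduli_rejected(self):
        with pytest.raises(ValueError):
            StackParameters(kc=-1.0, b=1e-5)
        with pytest.raises(ValueError):
            StackParameters(kc=10.0, b=0.0)

    def test_monte_carlo_mode_sampling_oracle(self):
        """Gaussian equipartition sampling of an explicit coarse mode set
        reproduces the analytic height-difference correlations."""
        p = small_stack(n_layers=4)
        q = np.geomspace(2 * np.pi / p.domain_lr, 0.3, 12)
        w = np.gradient(q)
        r_vals = np.array([0.0, 40.0, 150.0])
        delta = correlation_functions(p, r_vals, q_nodes=(q, w), per_pair=True)

        V, b_mu = layer_modes(p.n_layers, p.b)
        pref = p.temperature / T_REF / (2 * np.pi)
        var = pref * (w * q)[:, None] / (p.kc * q[:, None] ** 4 + b_mu[None, :])
        rng = np.random.default_rng(99)
        draws = 200_000
        pairs = [(0, 1), (0, 3), (1, 2)]
        theta = rng.uniform(0, 2 * np.pi, (draws, q.size))
        a = rng.normal(0, 1, (draws, q.size, p.n_layers)) * np.sqrt(var)
        b = rng.normal(0, 1, (draws, q.size, p.n_layers)) * np.sqrt(var)
        for ir, r in enumerate(r_vals):
            phase = q[None, :] * r * np.cos(theta)
            cosp, sinp = np.cos(phase), np.sin(phase)
            for (n, m) in pairs:
                u_n = np.einsum("dqm,m->d", a * cosp[:, :, None], V[n]) + \
                      np.einsum("dqm,m->d", b * sinp[:, :, None], V[n])
                u_m = np.einsum("dqm,m->d", a, V[m])
                d2 = (u_n - u_m) ** 2
                se = d2.std() / np.sqrt(draws)
                assert abs(d2.mean() - delta[n, m, ir]) < 3 * se


class TestStructureFactor:
    def test_mirror_symmetry_in_qr(self):
        p = small_stack()
        qr = np.array([0.01, 0.03])
        qz = np.array([0.2, 0.3])
        s_pos = structure_factor(p, qr, qz)
        s_neg = structure_factor(p, -qr[::-1], qz)[:, ::-1]
        assert np.allclose(s_pos, s_neg, rtol=1e-12)

    def test_frozen_stack_collapses_to_bragg_sheets(self):
        p = small_stack(n_layers=6, temperature=1e-6)
        qz = np.linspace(0.08, 0.45, 200)
        # q_r inside the first lobe of the finite-domain disc transform
        qr = np.array([0.002])
        s = structure_factor(p, qr, qz, include_specular=True)[:, 0]
        bragg = 2 * np.pi * np.array([1, 2, 3, 4]) / p.d_spacing
        from scipy.signal import argrelmax
        peaks = qz[argrelmax(s, order=3)[0]]
        for h in bragg[(bragg > qz.min()) & (bragg < qz.max())]:
            assert np.min(np.abs(peaks - h)) < 2 * (qz[1] - qz[0])

    def test_brute_force_pair_sum_oracle(self):
        """Tiny instance: engine result equals an independent double sum
        over bilayer pairs with adaptive quadrature, to 1e-6 relative."""
        p = small_stack(n_layers=3, domain_lr=600.0)
        qr = np.array([0.005, 0.012, 0.02])
        qz = np.array([0.15, 0.22, 0.3])
        q, w = default_q_nodes(p.domain_lr, n_panels=24, nodes_per_panel=3)
        s_prod = structure_factor(p, qr, qz, q_nodes=(q, w), per_pair=True)

        V, b_mu = layer_modes(p.n_layers, p.b)
        pref = p.temperature / T_REF / (2 * np.pi)

        def g_mu(mu, r):
            return pref * np.sum(w * q * j0(q * r) / (p.kc * q**4 + b_mu[mu]))

        def delta_nm(n, m, r):
            tot = 0.0
            for mu in range(p.n_layers):
                tot += (V[n, mu] ** 2 + V[m, mu] ** 2) * g_mu(mu, 0.0) \
                    - 2 * V[n, mu] * V[m, mu] * g_mu(mu, r)
            return tot

        lr = p.domain_lr
        s_oracle = np.zeros((qz.size, qr.size))
        for iz, qzv in enumerate(qz):
            for ir, qrv in enumerate(qr):
                acc = 0.0
                for n in range(p.n_layers):
                    for m in range(p.n_layers):
                        e_end = np.exp(-0.5 * qzv**2 * delta_nm(n, m, lr))

                        def f(r):
                            e = np.exp(-0.5 * qzv**2 * delta_nm(n, m, r))
                            return r * j0(qrv * r) * (e - e_end)

                        val, _ = quad(f, 0.0, lr, limit=300, epsabs=1e-12,
                                      epsrel=1e-10)
                        acc += np.cos(qzv * p.d_spacing * (n - m)) * 2 * np.pi * val
                s_oracle[iz, ir] = acc / p.n_layers
        scale = np.max(np.abs(s_oracle))
        assert np.allclose(s_prod, s_oracle, atol=1e-6 * scale)

    def test_offset_average_close_to_per_pair(self):
        p = small_stack(n_layers=6)
        qr = np.array([0.005, 0.02])
        qz = np.array([0.2, 0.3])
        s_avg = structure_factor(p, qr, qz)
        s_pp = structure_factor(p, qr, qz, per_pair=True)
        assert np.allclose(s_avg, s_pp, rtol=2e-2, atol=1e-3 * np.abs(s_pp).max())

    def test_falloff_steepens_with_kc(self):
        p = StackParameters(kc=20.0, b=5e-6, n_layers=40, domain_lr=2500.0,
                            d_spacing=64.0)
        qr = np.linspace(3e-3, 0.06, 40)
        qz = np.array([0.3])
        engine = StructureFactorEngine(p, qr, qz)
        widths = []
        for kc in (10.0, 20.0, 40.0):
            row = engine.structure_factor(kc, p.b)[0]
            rn = row / row.max()
            widths.append(qr[np.argmax(rn < 0.5)])
        assert widths[0] > widths[1] > widths[2]

    def test_nonnegative_in_fit_window(self):
        p = StackParameters(kc=20.0, b=5e-6, n_layers=40, domain_lr=2500.0,
                            d_spacing=64.0)
        qr = np.linspace(3e-3, 0.15, 40)
        qz = np.linspace(0.1, 0.45, 40)
        s = structure_factor(p, qr, qz)
        assert s.min() > -1e-5 * s.max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            structure_factor(small_stack(), np.array([]), np.array([0.2]))


class TestModelIntensity:
    def setup_method(self):
        self.qr = np.linspace(1e-3, 0.1, 30)
        self.qz = np.linspace(0.1, 0.4, 20)
        rng = np.random.default_rng(0)
        self.s = rng.random((20, 30)) + 0.5

    def test_identity_form_factor(self):
        out = model_intensity(self.s, self.qr, self.qz, np.ones(20))
        assert np.allclose(out, self.s / self.qz[:, None])

    def test_scale_linearity(self):
        ff = np.linspace(1, 2, 20)
        a = model_intensity(self.s, self.qr, self.qz, ff, scale=1.0)
        b = model_intensity(self.s, self.qr, self.qz, ff, scale=2.0)
        assert np.allclose(b, 2 * a)

    def test_vanishing_smearing_width_is_identity(self):
        ff = np.ones(20)
        a = model_intensity(self.s, self.qr, self.qz, ff)
        b = model_intensity(self.s, self.qr, self.qz, ff,
                            qr_resolution=1e-12)
        assert np.allclose(a, b, atol=1e-8)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            model_intensity(self.s, self.qr, self.qz, np.ones(7))


class TestElasticityFit:
    def _truth(self):
        return StackParameters(kc=20.0, b=5e-6, n_layers=40, domain_lr=2500.0,
                               d_spacing=64.0)

    def _data(self, noise, seed=0):
        comp = default_composition()
        model = SDPModel(comp, SDPParams(a_l=71.0))
        qz = np.linspace(0.10, 0.45, 40)
        qr = np.linspace(1e-3, 0.15, 40)
        ff = model.form_factor(qz)
        data, _ = gen_diffuse_map(self._truth(), ff, qr, qz, noise_level=noise,
                                  seed=seed)
        return data, ff

    def test_noiseless_recovery(self):
        data, ff = self._data(0.0)
        init = StackParameters(kc=8.0, b=2e-6, n_layers=40, domain_lr=2500.0,
                               d_spacing=64.0)
        est = ElasticityFitter(init, n_starts=1).fit(data, ff)
        assert est.kc_ == pytest.approx(20.0, rel=1e-2)
        assert est.converged_
        assert est.kc_ci_[0] <= est.kc_ <= est.kc_ci_[1]

    def test_flat_map_rejected(self):
        data, ff = self._data(0.0)
        zeros = DiffuseMap(data.q_r, data.q_z, np.zeros_like(data.intensity))
        init = self._truth()
        with pytest.raises(ValueError, match="flat or empty"):
            ElasticityFitter(init).fit(zeros, ff)

    def test_init_outside_bounds_rejected(self):
        data, ff = self._data(0.0)
        init = StackParameters(kc=500.0, b=5e-6, n_layers=40)
        with pytest.raises(ValueError, match="bounds"):
            ElasticityFitter(init, kc_bounds=(1.0, 400.0)).fit(data, ff)
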