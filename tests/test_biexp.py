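import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cytodmri.biexp import (
    BiexpFitConfig,
    BiexpParams,
    fit_biexp,
    msd,
    predict_signal,
    rtop,
)
from cytodmri.io import GradientTable
from cytodmri.synthetic import make_protocol, rician_noise


def random_params(rng, isotropic=False):
    if isotropic:
        lam_f = np.full(3, rng.uniform(0.8e-3, 2.0e-3))
        lam_s = np.full(3, rng.uniform(1.5e-4, 6e-4))
        R = np.eye(3)
    else:
        lam_f = np.sort(rng.uniform(0.5e-3, 2.5e-3, 3))[::-1]
        lam_s = np.sort(rng.uniform(1e-4, 5e-4, 3))[::-1]
        R = Rotation.random(rng=rng).as_matrix()
    return BiexpParams(
        s0=100.0,
        f_iso=rng.uniform(0, 0.2),
        w=rng.uniform(0.3, 0.8),
        lam_f=lam_f,
        lam_s=lam_s,
        R=R,
    )


ANISO_TRUTH = dict(
    s0=100.0,
    f_iso=0.1,
    w=0.6,
    lam_f=1.2e-3 * np.array([2.2, 0.4, 0.4]),   # MD 1.2e-3, anisotropic fast pool
    lam_s=0.3e-3 * np.ones(3),                   # MD 0.3e-3, isotropic slow pool
    R=Rotation.from_euler("ZYZ", [0.4, 0.7, 0.2]).as_matrix(),
)


class TestForwardModel:
    def test_b0_returns_s0(self, rng):
        gt = GradientTable(np.zeros(3), np.zeros((3, 3)))
        p = random_params(rng)
        np.testing.assert_allclose(predict_signal(p, gt), p.s0)

    def test_monoexponential_limit(self):
        gt = make_protocol(1, 6)
        d = 1.1e-3
        p = BiexpParams(s0=50.0, f_iso=0.0, w=1.0, lam_f=np.full(3, d), lam_s=np.full(3, 2e-4))
        np.testing.assert_allclose(
            predict_signal(p, gt), 50.0 * np.exp(-gt.bvals * d), rtol=1e-12
        )

    def test_hand_evaluated_closed_form(self):
        # independent scalar evaluation at b=1000, g=(1,0,0), diagonal frame
        gt = GradientTable(np.array([1000.0]), np.array([[1.0, 0.0, 0.0]]))
        p = BiexpParams(
            s0=200.0, f_iso=0.15, w=0.55,
            lam_f=np.array([1.8e-3, 0.9e-3, 0.9e-3]),
            lam_s=np.array([4e-4, 2e-4, 2e-4]),
        )
        expected = 200.0 * (
            0.15 * np.exp(-1000 * 3.0e-3)
            + 0.85 * (0.55 * np.exp(-1000 * 1.8e-3) + 0.45 * np.exp(-1000 * 4e-4))
        )
        assert predict_signal(p, gt)[0] == pytest.approx(expected, rel=1e-12)


class TestPropagatorMeasures:
    def test_msd_isotropic_closed_form_and_monte_carlo(self, rng):
        d, tau = 1.0e-3, 0.030
        p = BiexpParams(s0=1, f_iso=0, w=1.0, lam_f=np.full(3, d), lam_s=np.full(3, d))
        assert msd(p) == pytest.approx(6 * d * tau, rel=1e-12)
        # displacement oracle: mean |r|^2 of N(0, 2 d tau I)
        samples = rng.normal(0, np.sqrt(2 * d * tau), (10**6, 3))
        mc = np.mean(np.sum(samples**2, axis=1))
        assert msd(p) == pytest.approx(mc, rel=0.01)

    def test_msd_mixture_linearity(self, rng):
        p = random_params(rng)
        fast = BiexpParams(p.s0, p.f_iso, 1.0, p.lam_f, p.lam_s, p.R)
        slow = BiexpParams(p.s0, p.f_iso, 0.0, p.lam_f, p.lam_s, p.R)
        assert msd(p) == pytest.approx(p.w * msd(fast) + (1 - p.w) * msd(slow), rel=1e-12)

    def test_msd_zero_tensors(self):
        p = BiexpParams(1, 0, 0.5, np.zeros(3), np.zeros(3))
        assert msd(p) == 0.0

    def test_rtop_isotropic_vs_quadrature(self):
        d, tau = 8e-4, 0.030
        p = BiexpParams(1, 0, 1.0, np.full(3, d), np.full(3, d))
        # numerical integral of the Gaussian characteristic function
        # E(q) = exp(-4 pi^2 tau q^T D q) over R^3 (separable per axis)
        q = np.linspace(-200, 200, 40001)
        one_axis = np.trapezoid(np.exp(-4 * np.pi**2 * tau * d * q**2), q)
        assert rtop(p) == pytest.approx(one_axis**3, rel=0.005)

    def test_rtop_monotone_in_diffusivity(self):
        taus = [rtop(BiexpParams(1, 0, 1.0, np.full(3, d), np.full(3, d)))
                for d in (5e-4, 1e-3, 2e-3)]
        assert taus[0] > taus[1] > taus[2]

    def test_rtop_mixture_between_pure_values(self, rng):
        p = random_params(rng)
        fast = BiexpParams(p.s0, p.f_iso, 1.0, p.lam_f, p.lam_s, p.R)
        slow = BiexpParams(p.s0, p.f_iso, 0.0, p.lam_f, p.lam_s, p.R)
        lo, hi = sorted([rtop(fast), rtop(slow)])
        assert lo <= rtop(p) <= hi

    def test_rtop_degenerate_tensor_rejected(self):
        p = BiexpParams(1, 0, 0.5, np.array([1e-3, 1e-3, 0.0]), np.full(3, 2e-4))
        with pytest.raises(ValueError):
            rtop(p)

    def test_rotation_invariance(self, rng):
        p = random_params(rng)
        R2 = Rotation.random(rng=rng).as_matrix()
        q = BiexpParams(p.s0, p.f_iso, p.w, p.lam_f, p.lam_s, R2)
        assert msd(p) == pytest.approx(msd(q), rel=1e-12)
        assert rtop(p) == pytest.approx(rtop(q), rel=1e-12)


class TestFit:
    def test_noise_free_recovery_full_model(self, full_protocol):
        truth = BiexpParams(**ANISO_TRUTH)
        sig = predict_signal(truth, full_protocol)
        fit = fit_biexp(sig[None, :], full_protocol, config=BiexpFitConfig(model="full", n_starts=5))
        assert fit.w[0] == pytest.approx(0.6, rel=1e-3)
        assert fit.lam_f[0].mean() == pytest.approx(1.2e-3, rel=1e-3)
        assert fit.lam_s[0].mean() == pytest.approx(0.3e-3, rel=1e-3)

    def test_single_shell_rejected(self):
        gt = make_protocol(2, 6, shells=(1000.0,))
        with pytest.raises(ValueError):
            fit_biexp(np.ones((1, len(gt))), gt)

    def test_fast_slow_relabeling(self, small_protocol):
        # generate with 'fast' pool actually slower; fit must relabel
        truth = BiexpParams(
            s0=100.0, f_iso=0.0, w=0.3,
            lam_f=np.full(3, 1.5e-3), lam_s=np.full(3, 3e-4),
        )
        sig = predict_signal(truth, small_protocol)
        fit = fit_biexp(
            sig[None, :], small_protocol,
            config=BiexpFitConfig(model="isotropic", average_shells=True, f_iso_fixed=0.0),
        )
        assert fit.lam_f[0].mean() >= fit.lam_s[0].mean()

    def test_vectorized_matches_scipy_cost(self, small_protocol, rng):
        """The batched LM solver must reach the per-voxel scipy optimum."""
        from scipy.optimize import least_squares

        truth = BiexpParams(
            s0=100.0, f_iso=0.05, w=0.6,
            lam_f=np.full(3, 1.3e-3), lam_s=np.full(3, 3.5e-4),
        )
        clean = predict_signal(truth, small_protocol)
        sig = rician_noise(np.tile(clean, (12, 1)), 2.5, rng)
        cfg = BiexpFitConfig(model="isotropic", average_shells=True, n_starts=3, f_iso_fixed=0.05)
        fit = fit_biexp(sig, small_protocol, config=cfg)

        b = small_protocol.bvals
        shells = small_protocol.shells()
        groups = [small_protocol.b0_mask] + [np.abs(b - s) < 1e-6 for s in shells]
        bs = np.array([b[m].mean() for m in groups])
        wts = np.sqrt([m.sum() for m in groups])

        def model(t):
            s0, w, df, ds = t
            return s0 * (0.05 * np.exp(-bs * 3e-3) + 0.95 * (w * np.exp(-bs * df) + (1 - w) * np.exp(-bs * ds)))

        for v in range(12):
            y = np.array([sig[v][m].mean() for m in groups])
            best = None
            for s in range(4):
                t0 = np.array([y[0], 0.5, 1.3e-3, 3e-4])
                if s:
                    t0 = t0 * np.random.default_rng(100 * v + s).uniform(0.5, 1.6, 4)
                t0 = np.clip(t0, [0, 0, 1e-6, 1e-6], [10 * y[0], 1, 4e-3, 4e-3])
                sol = least_squares(lambda t: wts * (model(t) - y), t0,
                                    bounds=([0, 0, 1e-6, 1e-6], [10 * y[0], 1, 4e-3, 4e-3]))
                if best is None or sol.cost < best.cost:
                    best = sol
            assert fit.residual[v] ** 2 <= 2 * best.cost * (1 + 1e-3) + 1e-6

    def test_csf_inflates_dti_trace(self, small_protocol):
        """With CSF present, the DTI trace exceeds the tissue trace mixture."""
        from cytodmri.dti import fit_dti, trace_measure

        truth = BiexpParams(
            s0=100.0, f_iso=0.2, w=0.6,
            lam_f=np.full(3, 1.2e-3), lam_s=np.full(3, 3e-4),
        )
        sig = predict_signal(truth, small_protocol)
        tensor = fit_dti(sig[None, :], small_protocol)
        tissue_trace = 3 * (0.6 * 1.2e-3 + 0.4 * 3e-4)
        assert trace_measure(tensor.evals)[0] > tissue_trace
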