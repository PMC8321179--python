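import numpy as np
import pytest

from daltonise.core import build_basis, modified_gradient, spatial_gradient
from daltonise.cvd import make_observer
from daltonise.diffusion import (
    SolverConfig,
    daltonise,
    diffusion_tensor,
    diffusivity,
    divergence,
    reintegrate,
    structure_tensor,
)


class TestStructureTensor:
    def test_constant_image_zero_tensor(self):
        S = structure_tensor(np.full((4, 5, 3), 0.7))
        np.testing.assert_array_equal(S, 0.0)

    def test_single_channel_ramp(self):
        h, w, g = 6, 8, 0.05
        img = np.zeros((h, w, 3))
        img[:, :, 0] = g * np.arange(w)[None, :]
        S = structure_tensor(img)
        # interior: only the x-x component is g^2
        np.testing.assert_allclose(S[:, :-1, 1, 1], g**2, atol=1e-15)
        np.testing.assert_allclose(S[..., 0, 0], 0.0, atol=1e-15)
        np.testing.assert_allclose(S[..., 0, 1], 0.0, atol=1e-15)

    def test_eigendecomposition_reconstructs(self, rng):
        img = rng.uniform(0, 1, (9, 7, 3))
        S = structure_tensor(img)
        w, v = np.linalg.eigh(S)
        back = np.einsum("...ik,...k,...jk->...ij", v, w, v)
        np.testing.assert_allclose(back, S, atol=1e-10)
        assert w.min() >= -1e-12  # PSD

    def test_summed_variant_differs_in_general(self, rng):
        img = rng.uniform(0, 1, (6, 6, 3))
        di_zenzo = structure_tensor(img, mode="di_zenzo")
        summed = structure_tensor(img, mode="summed")
        assert not np.allclose(di_zenzo, summed)


class TestDiffusivity:
    def test_zero_gives_one(self):
        assert diffusivity(0.0, 1e4) == 1.0

    def test_half_at_unit_kappa_lambda_sq(self):
        # kappa * lambda^2 = 1  =>  d = 0.5
        assert diffusivity(0.01, 1e4) == pytest.approx(0.5)

    def test_strictly_decreasing_to_zero(self):
        lams = np.linspace(0, 100, 1000)
        d = diffusivity(lams, 10.0)
        assert np.all(np.diff(d) < 0)
        assert d[-1] > 0
        assert diffusivity(1e6, 10.0) < 1e-10

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            diffusivity(-1e-3, 1.0)


class TestDiffusionTensor:
    def test_zero_tensor_gives_identity(self):
        S = np.zeros((3, 3, 2, 2))
        D = diffusion_tensor(S, 1e4)
        np.testing.assert_allclose(D, np.broadcast_to(np.eye(2), (3, 3, 2, 2)))

    def test_axis_aligned_ramp(self):
        g, kappa = 0.1, 1e3
        S = np.zeros((1, 1, 2, 2))
        S[0, 0] = [[g**2, 0], [0, 0]]
        D = diffusion_tensor(S, kappa)
        np.testing.assert_allclose(
            D[0, 0], [[1 / (1 + kappa * g**4), 0], [0, 1]], atol=1e-14
        )

    def test_commutes_with_s_and_spectrum_bounds(self, rng):
        img = rng.uniform(0, 1, (8, 6, 3))
        S = structure_tensor(img)
        D = diffusion_tensor(S, 1e4)
        np.testing.assert_allclose(D @ S, S @ D, atol=1e-10)
        eigs = np.linalg.eigvalsh(D)
        assert eigs.min() > 0 and eigs.max() <= 1 + 1e-12
        np.testing.assert_allclose(D, np.swapaxes(D, -1, -2), atol=1e-14)


class TestDivergence:
    def test_zero_field(self):
        np.testing.assert_array_equal(divergence(np.zeros((4, 5, 2, 3))), 0.0)

    def test_adjointness_exact(self, rng):
        """<grad u, p> = -<u, div p> to machine precision on random grids."""
        for _ in range(20):
            u = rng.normal(size=(8, 6, 3))
            p = rng.normal(size=(8, 6, 2, 3))
            lhs = float(np.sum(spatial_gradient(u) * p))
            rhs = -float(np.sum(u * divergence(p)))
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_div_grad_constant_zero(self):
        img = np.full((6, 6, 3), 0.4)
        np.testing.assert_allclose(divergence(spatial_gradient(img)), 0.0)


def poisson_oracle(u0, G):
    """Dense least-squares solution of min ||grad u - G||^2 per channel,
    with the mean pinned to the init's mean (explicit descent conserves it)."""
    h, w, _ = u0.shape
    n = h * w
    rows = []
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        ge = spatial_gradient(np.repeat(e.reshape(h, w, 1), 3, axis=2))[..., 0]
        rows.append(ge.reshape(-1))
    A = np.stack(rows, axis=1)  # (2n, n) gradient operator matrix
    out = np.zeros_like(u0)
    for c in range(3):
        b = G[:, :, :, c].reshape(-1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        sol = sol - sol.mean() + u0[:, :, c].mean()
        out[:, :, c] = sol.reshape(h, w)
    return out


class TestReintegrate:
    def test_fixed_point_both_modes(self, rng):
        u0 = rng.uniform(0.2, 0.8, (8, 8, 3))
        G = spatial_gradient(u0)
        for mode in ("isotropic", "anisotropic"):
            out, diag = reintegrate(u0, G, mode=mode, cfg=SolverConfig())
            np.testing.assert_allclose(out, u0, atol=1e-12)
            assert diag.iterations <= 1

    def test_isotropic_matches_poisson_oracle(self, rng):
        """Interior minimiser agrees with a dense least-squares solution."""
        h = w = 16
        u0 = 0.5 + 0.08 * rng.standard_normal((h, w, 3)).cumsum(axis=1) / np.sqrt(w)
        u0 = np.clip(u0, 0.3, 0.7)
        basis = build_basis(np.array([1.0, -1.0, 0.0]), "flat")
        G = spatial_gradient(u0) + 0.1 * modified_gradient(u0, basis)
        G *= 0.3  # keep the minimiser well inside the gamut
        cfg = SolverConfig(tol=1e-10, max_iter=60000)
        out, diag = reintegrate(u0, G, mode="isotropic", init=u0, cfg=cfg)
        oracle = poisson_oracle(u0, G)
        assert oracle.min() > 0.05 and oracle.max() < 0.95  # constraint inactive
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_energy_monotone_isotropic(self, rng):
        u0 = rng.uniform(0.3, 0.7, (12, 12, 3))
        basis = build_basis(np.array([1.0, -1.0, 0.0]), "flat")
        G = modified_gradient(u0, basis) * 0.5
        cfg = SolverConfig(dt=0.24, tol=1e-12, max_iter=300, record_energy=True)
        out, diag = reintegrate(u0, G, mode="isotropic", init=u0, cfg=cfg, clip=False)
        energy = np.array(diag.energy)
        assert np.all(np.diff(energy) <= 1e-12)

    def test_frozen_tensor_update_is_linear(self, rng):
        """Anisotropic update operator is linear in the deviation from a
        reference solution (the local linear property)."""
        u0 = rng.uniform(0.2, 0.8, (6, 6, 3))
        G = spatial_gradient(u0) * 1.3
        D = diffusion_tensor(structure_tensor(u0), 1e4)

        def one_step(u):
            from daltonise.diffusion import divergence as div

            r = spatial_gradient(u) - G
            r = np.einsum("hwij,hwjc->hwic", D, r)
            return 0.24 * div(r)

        base = rng.uniform(0.3, 0.7, (6, 6, 3))
        delta = rng.normal(scale=0.05, size=(6, 6, 3))
        s1 = one_step(base + delta) - one_step(base)
        s2 = one_step(base + 2 * delta) - one_step(base)
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-12)

    def test_instability_detected(self, rng):
        u0 = rng.uniform(0, 1, (8, 8, 3))
        G = spatial_gradient(u0) * 2
        cfg = SolverConfig(dt=0.25, tol=1e-12, max_iter=5000)
        # dt at the stability bound stays finite (no exception)
        out, _ = reintegrate(u0, G, mode="isotropic", init=u0, cfg=cfg)
        assert np.all(np.isfinite(out))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.3)
        with pytest.raises(ValueError):
            SolverConfig(kappa=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(max_iter=0)


class TestDaltonisePipeline:
    def test_greyscale_unchanged(self, rng):
        img = np.repeat(rng.uniform(0, 1, (8, 8, 1)), 3, axis=2)
        for method in ("simple", "isotropic", "anisotropic"):
            out, diag = daltonise(img, make_observer("rg", 1.0), method=method)
            np.testing.assert_array_equal(out, img)
            assert diag.iterations == 0

    def test_colour_normal_unchanged(self, rng):
        img = rng.uniform(0, 1, (8, 8, 3))
        out, _ = daltonise(img, make_observer("by", 0.0))
        np.testing.assert_array_equal(out, img)

    def test_output_in_gamut(self, rng):
        img = rng.uniform(0, 1, (16, 16, 3))
        cfg = SolverConfig(max_iter=50)
        for method in ("simple", "isotropic", "anisotropic"):
            out, _ = daltonise(img, make_observer("rg", 1.0), method=method, cfg=cfg)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            daltonise(np.zeros((2, 2, 3)) + 0.3, make_observer("rg", 1.0), method="magic")
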