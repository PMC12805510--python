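"""Sampler correctness, bias potentials, metadynamics and reweighting."""
import numpy as np
import pytest

from esfm import (
    BiasSpec,
    LinearCV,
    DihedralCV,
    bias_energy_and_force,
    bias_is_on_cg,
    compute_importance_weights,
    make_builtin_system,
    metadynamics_deposit,
    recompute_unbiased_forces,
    simulate,
    CGMapping,
    evaluate_force,
    evaluate_potential,
)
from esfm.sampling import TrajectoryDataset, bias_ambient_force, boltzmann_grid_sample
from esfm._util import stream_rng


def _chain_se_of_var(ds):
    """SE of the sample variance across independent chains."""
    x = ds.chain_view(ds.positions[:, 0])  # (T, C)
    per_chain = x.var(axis=0, ddof=1)
    return per_chain.mean(), per_chain.std(ddof=1) / np.sqrt(x.shape[1])


def test_harmonic_stationary_variance(harmonic_dataset):
    """Unbiased harmonic well at beta=1 has unit variance; the estimate over
    2e5 decorrelated frames must agree within 3 chain-level SE."""
    assert harmonic_dataset.n_frames == 200000
    var, se = _chain_se_of_var(harmonic_dataset)
    assert abs(var - 1.0) < 3 * se


def test_umbrella_stationary_variance(umbrella_harmonic_dataset):
    """Harmonic umbrella (kappa) on a harmonic well: a Gaussian product with
    variance 1 / (beta (1 + kappa))."""
    var, se = _chain_se_of_var(umbrella_harmonic_dataset)
    assert abs(var - 0.25) < 3 * se


def test_histogram_matches_quadrature_target():
    """Empirical CV histograms converge to exp(-beta(u+W)) for every static
    bias kind (KL < 0.01 at 5e5 frames)."""
    dw = make_builtin_system("double_well_1d")
    cv = LinearCV([[1.0]])
    biases = [
        BiasSpec(),
        BiasSpec(kind="harmonic_umbrella", cv=cv, kappa=2.0, center=[0.5]),
        BiasSpec(kind="gaussian_restraint", cv=cv, height=-4.0, center=[0.0], width=0.4),
    ]
    grid = np.linspace(-2.2, 2.2, 2001)[:, None]
    u = evaluate_potential(dw, grid)
    for bias in biases:
        w, _ = bias_ambient_force(bias, grid)
        target = np.exp(-dw.beta * (u + w - (u + w).min()))
        ds = simulate(
            dw, bias, n_steps=22000, dt=2e-3, seed=21, stride=20,
            n_chains=500, burn_in=2000,
        )
        assert ds.n_frames == 500000
        edges = np.linspace(-2.2, 2.2, 61)
        counts, _ = np.histogram(ds.positions[:, 0], bins=edges)
        p_emp = counts / counts.sum()
        centers = 0.5 * (edges[1:] + edges[:-1])
        p_ref = np.interp(centers, grid[:, 0], target)
        p_ref /= p_ref.sum()
        sel = p_ref > 1e-12
        kl = np.sum(p_ref[sel] * np.log(p_ref[sel] / np.maximum(p_emp[sel], 1e-300)))
        assert kl < 0.01, f"KL {kl} for bias kind {bias.kind}"


def test_bias_energy_and_force_values():
    cv = LinearCV([[1.0]])
    umb = BiasSpec(kind="harmonic_umbrella", cv=cv, kappa=2.0, center=[1.0])
    w, g = bias_energy_and_force(umb, np.array([[3.0]]))
    assert w[0] == pytest.approx(4.0) and g[0, 0] == pytest.approx(4.0)

    wtm = BiasSpec(kind="wt_metadynamics", cv=cv, h=0.7, sigma=0.2, tau=10, gamma=5.0)
    w, g = bias_energy_and_force(wtm, np.array([[0.3]]))
    assert w[0] == 0.0 and g[0, 0] == 0.0  # empty deposit list is valid

    one = metadynamics_deposit(wtm, [0.0], beta=1.0)
    w, _ = bias_energy_and_force(one, np.array([[0.2]]))  # R = sigma
    assert w[0] == pytest.approx(0.7 * np.exp(-0.5))


def test_bias_gradient_matches_finite_differences():
    cv = LinearCV([[1.0]])
    specs = [
        BiasSpec(kind="harmonic_umbrella", cv=cv, kappa=3.5, center=[0.7]),
        BiasSpec(kind="gaussian_restraint", cv=cv, height=-2.0, center=[0.1], width=0.3),
        metadynamics_deposit(
            metadynamics_deposit(
                BiasSpec(kind="wt_metadynamics", cv=cv, h=0.5, sigma=0.25, tau=5, gamma=3.0),
                [0.2], 1.0,
            ),
            [-0.4], 1.0,
        ),
    ]
    s = np.linspace(-1, 1, 17)[:, None]
    h = 1e-7
    for bias in specs:
        w, g = bias_energy_and_force(bias, s)
        wp, _ = bias_energy_and_force(bias, s + h)
        wm, _ = bias_energy_and_force(bias, s - h)
        fd = (wp - wm) / (2 * h)
        assert np.allclose(g[:, 0], fd, rtol=1e-6, atol=1e-9)


def test_deposit_tempering_rule():
    """First deposit has height h; a second deposit at the same point is
    reduced by exp(-h / (kBT (gamma-1))); repeated deposits are
    non-increasing."""
    cv = LinearCV([[1.0]])
    beta, gamma, h = 1.0, 4.0, 0.8
    bias = BiasSpec(kind="wt_metadynamics", cv=cv, h=h, sigma=0.2, tau=5, gamma=gamma)
    b1 = metadynamics_deposit(bias, [0.0], beta)
    assert b1.deposited[0][1] == pytest.approx(h)
    b2 = metadynamics_deposit(b1, [0.0], beta)
    assert b2.deposited[1][1] == pytest.approx(h * np.exp(-h * beta / (gamma - 1)))
    heights = [h]
    b = b1
    for _ in range(200):
        b = metadynamics_deposit(b, [0.0], beta)
        heights.append(b.deposited[-1][1])
    assert all(a >= b_ for a, b_ in zip(heights, heights[1:]))
    assert heights[-1] < 0.05 * h  # ~1/n tempering decay


def test_gamma_must_exceed_one():
    with pytest.raises(ValueError, match="gamma > 1"):
        BiasSpec(kind="wt_metadynamics", cv=LinearCV([[1.0]]), h=0.5, sigma=0.1, gamma=0.5)
    with pytest.raises(ValueError, match="deposits"):
        metadynamics_deposit(BiasSpec(), [0.0], 1.0)


def test_force_decomposition_frame_wise(umbrella_harmonic_dataset, harmonic_1d):
    """biased - unbiased forces equal the analytic bias force to 1e-10."""
    ds = umbrella_harmonic_dataset
    _, f_b = bias_ambient_force(ds.bias, ds.positions)
    resid = ds.biased_forces - ds.unbiased_forces - f_b
    assert np.abs(resid).max() < 1e-10
    ds.validate()


def test_zero_bias_dataset_identity(harmonic_dataset):
    assert np.array_equal(harmonic_dataset.biased_forces, harmonic_dataset.unbiased_forces)
    assert np.all(harmonic_dataset.weights == 1.0)


def test_recompute_fills_and_is_idempotent(harmonic_1d, umbrella_harmonic_dataset):
    ds = umbrella_harmonic_dataset
    before = ds.unbiased_forces.copy()
    recompute_unbiased_forces(ds, harmonic_1d)
    assert np.array_equal(ds.unbiased_forces, before)  # idempotent

    bare = TrajectoryDataset(
        positions=ds.positions[:100].copy(),
        bias=ds.bias,
        metadata={**ds.metadata, "n_chains": 1},
    )
    recompute_unbiased_forces(bare, harmonic_1d)
    assert np.allclose(bare.unbiased_forces, evaluate_force(harmonic_1d, bare.positions))
    bare.validate()


def test_recompute_refuses_wrong_system(umbrella_harmonic_dataset):
    other = make_builtin_system("harmonic_1d", {"k": 2.0})
    with pytest.raises(ValueError, match="hash mismatch"):
        recompute_unbiased_forces(umbrella_harmonic_dataset, other)


def test_importance_weights_formula(umbrella_harmonic_dataset, harmonic_1d):
    """omega = exp(beta W): 1 at the umbrella center, exp(beta kappa d^2/2)
    at distance d; the self-normalized mean recovers the unbiased mean."""
    ds = umbrella_harmonic_dataset
    kappa = ds.bias.kappa
    d = ds.positions[:, 0] - ds.bias.center[0]
    expect = np.exp(harmonic_1d.beta * 0.5 * kappa * d**2)
    assert np.allclose(ds.weights, expect, rtol=1e-12)
    x = ds.chain_view(ds.positions[:, 0])
    w = ds.chain_view(ds.weights)
    per_chain = (w * x).sum(axis=0) / w.sum(axis=0)
    se = per_chain.std(ddof=1) / np.sqrt(x.shape[1])
    assert abs(per_chain.mean() - 0.0) < 3 * se


def test_weight_overflow_uses_log_normalization():
    ds = TrajectoryDataset(
        positions=np.zeros((3, 1)),
        bias=BiasSpec(kind="harmonic_umbrella", cv=LinearCV([[1.0]]), kappa=1.0, center=[0.0]),
        bias_energy=np.array([0.0, 500.0, 1000.0]),
        metadata={"beta": 1.0},
    )
    with pytest.warns(UserWarning, match="overflow"):
        compute_importance_weights(ds)
    assert np.all(np.isfinite(ds.weights)) and ds.weights.max() == 1.0


def test_determinism_bit_identical(harmonic_1d):
    bias = BiasSpec(kind="harmonic_umbrella", cv=LinearCV([[1.0]]), kappa=3.0, center=[0.0])
    a = simulate(harmonic_1d, bias, n_steps=4000, dt=0.02, seed=5, stride=50, n_chains=8)
    b = simulate(harmonic_1d, bias, n_steps=4000, dt=0.02, seed=5, stride=50, n_chains=8)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.biased_forces, b.biased_forces)
    c = simulate(harmonic_1d, bias, n_steps=4000, dt=0.02, seed=6, stride=50, n_chains=8)
    assert not np.array_equal(a.positions, c.positions)


def test_stride_and_burnin_do_not_shift_noise(harmonic_1d):
    """Counter-based streams: recording settings never change the dynamics,
    so states at a common step coincide bit-for-bit."""
    bias = BiasSpec(kind="harmonic_umbrella", cv=LinearCV([[1.0]]), kappa=3.0, center=[0.0])
    a = simulate(harmonic_1d, bias, n_steps=3000, dt=0.02, seed=5, stride=30, n_chains=10, burn_in=0)
    b = simulate(harmonic_1d, bias, n_steps=3000, dt=0.02, seed=5, stride=60, n_chains=10, burn_in=120)
    # a records steps 0,30,60,...; b records 120,180,...; step 120 is a's 5th record
    assert np.array_equal(a.positions[4 * 10:5 * 10], b.positions[0:10])


def test_initial_configuration_outside_box_aborts(harmonic_1d):
    with pytest.raises(RuntimeError, match="outside domain_box"):
        simulate(
            harmonic_1d, BiasSpec(), n_steps=100, dt=0.02, seed=1, stride=10,
            n_chains=2, init=np.full((2, 1), 50.0),
        )


def test_equilibrium_grid_draw_matches_target(harmonic_1d):
    rng = stream_rng(3, 0)
    x = boltzmann_grid_sample(harmonic_1d, BiasSpec(), 200000, rng)[:, 0]
    assert abs(x.var() - 1.0) < 0.02
    assert abs(x.mean()) < 0.02


def test_metadynamics_heights_decay_on_flat_potential():
    """On a flat landscape the walker revisits everywhere; tempering makes
    late deposit heights decay toward zero."""
    flat = make_builtin_system("harmonic_1d", {"k": 0.0, "domain_box": [[-2.0, 2.0]]})
    wtm = BiasSpec(
        kind="wt_metadynamics", cv=LinearCV([[1.0]]), h=0.5, sigma=0.3, tau=100, gamma=3.0
    )
    ds = simulate(flat, wtm, n_steps=40000, dt=5e-3, seed=9, stride=200,
                  n_chains=4, burn_in=0, init=np.zeros((4, 1)))
    heights = np.array([h for _, h in ds.bias.deposited])
    n = len(heights)
    assert n > 100
    early = heights[: n // 10].mean()
    late = heights[-n // 10:].mean()
    assert late < 0.2 * early


def test_wtm_dataset_weights_use_final_bias():
    dw = make_builtin_system("double_well_1d")
    wtm = BiasSpec(kind="wt_metadynamics", cv=LinearCV([[1.0]]), h=0.5, sigma=0.2,
                   tau=100, gamma=3.0)
    ds = simulate(dw, wtm, n_steps=6000, dt=1e-3, seed=2, stride=50, n_chains=4)
    assert ds.weights is None  # not computed eagerly for metadynamics
    compute_importance_weights(ds)
    w_final, _ = bias_energy_and_force(ds.bias, ds.bias.cv.value(ds.positions))
    assert np.allclose(ds.weights, np.exp(dw.beta * w_final), rtol=1e-10)


def test_bias_on_cg_flag(x_mapping):
    cvx, cvy = LinearCV([[1.0, 0.0]]), LinearCV([[0.0, 1.0]])
    on = BiasSpec(kind="gaussian_restraint", cv=cvx, height=-1.0, center=[0.0], width=0.5)
    off = BiasSpec(kind="harmonic_umbrella", cv=cvy, kappa=1.0, center=[0.0])
    assert bias_is_on_cg(on, x_mapping)
    assert not bias_is_on_cg(off, x_mapping)
    assert bias_is_on_cg(BiasSpec(), x_mapping)
    d1, d2 = DihedralCV((0, 1, 2, 3)), DihedralCV((1, 2, 3, 0))
    t = BiasSpec(kind="harmonic_umbrella", cv=d1, kappa=1.0, center=[0.0])
    assert bias_is_on_cg(t, d1) and not bias_is_on_cg(t, d2)


def test_bias_spec_roundtrip():
    cv = LinearCV([[1.0, 0.0]])
    for bias in [
        BiasSpec(),
        BiasSpec(kind="harmonic_umbrella", cv=cv, kappa=2.0, center=[0.3]),
        metadynamics_deposit(
            BiasSpec(kind="wt_metadynamics", cv=LinearCV([[1.0]]), h=0.5, sigma=0.2,
                     tau=10, gamma=3.0),
            [0.1], 1.0,
        ),
    ]:
        back = BiasSpec.from_dict(bias.to_dict())
        s = np.array([[0.4, 0.0]]) if bias.cv is not None and bias.cv.matrix.shape[1] == 2 else np.array([[0.4]])
        if bias.kind != "none":
            w1, g1 = bias_energy_and_force(bias, bias.cv.value(np.zeros((1, bias.cv.matrix.shape[1])) + 0.4))
            w2, g2 = bias_energy_and_force(back, back.cv.value(np.zeros((1, back.cv.matrix.shape[1])) + 0.4))
            assert np.array_equal(w1, w2) and np.array_equal(g1, g2)
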