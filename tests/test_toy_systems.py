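"""Analytic potentials, gradients, CG mappings and quadrature oracles."""
import numpy as np
import pytest
from scipy.optimize import minimize

from esfm import CGMapping, compute_oracle, evaluate_force, evaluate_potential, make_builtin_system
from esfm.toy_systems import (
    InsufficientBoundsError,
    OracleGrid,
    builtin_names,
    dihedral_angle,
    dihedral_gradient,
    dihedral_rotation_generator,
    potential_and_force,
)


def _interior_points(system, n, rng):
    if system.name == "dihedral_chain_4bead":
        return system.init_position + 0.08 * rng.standard_normal((n, system.dim))
    lo, hi = system.domain_box[:, 0], system.domain_box[:, 1]
    return lo + (hi - lo) * rng.uniform(0.1, 0.9, (n, system.dim))


@pytest.mark.parametrize("name", builtin_names())
def test_analytic_gradient_matches_finite_differences(name):
    """Force equals -grad u by central differences at 500 random points."""
    system = make_builtin_system(name)
    rng = np.random.default_rng(0)
    pos = _interior_points(system, 500, rng)
    f = evaluate_force(system, pos)
    h = 1e-6
    scale = np.abs(f).max()
    for d in range(system.dim):
        pp, pm = pos.copy(), pos.copy()
        pp[:, d] += h
        pm[:, d] -= h
        fd = -(evaluate_potential(system, pp) - evaluate_potential(system, pm)) / (2 * h)
        assert np.abs(f[:, d] - fd).max() <= 1e-5 * scale
    u2, f2 = potential_and_force(system, pos)
    assert np.array_equal(u2, evaluate_potential(system, pos)) or np.allclose(
        u2, evaluate_potential(system, pos), rtol=1e-14
    )
    assert np.allclose(f2, f, rtol=1e-14)


def test_harmonic_trivial_values(harmonic_1d):
    assert evaluate_potential(harmonic_1d, [0.0]) == 0.0
    assert evaluate_force(harmonic_1d, [2.0])[0] == -2.0


def test_mb_minima_and_saddle_ordering(mb_system):
    """Grid scan finds three local minima; the global one lies in the upper
    -left basin and every minimum is below the saddle between basins."""
    xs = np.linspace(-1.6, 1.2, 561)
    ys = np.linspace(-0.6, 2.2, 561)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    U = evaluate_potential(mb_system, np.stack([X, Y], axis=-1))
    interior = U[1:-1, 1:-1]
    is_min = (
        (interior < U[:-2, 1:-1]) & (interior < U[2:, 1:-1])
        & (interior < U[1:-1, :-2]) & (interior < U[1:-1, 2:])
        & (interior < U[:-2, :-2]) & (interior < U[2:, 2:])
        & (interior < U[:-2, 2:]) & (interior < U[2:, :-2])
    )
    ii, jj = np.where(is_min)
    minima = sorted(
        ((interior[i, j], xs[i + 1], ys[j + 1]) for i, j in zip(ii, jj))
    )
    assert len(minima) == 3
    u_global, xg, yg = minima[0]
    assert xg < 0 and yg > 1.0  # upper-left basin hosts the global minimum
    # saddle between the outer basins sits far above every minimum
    u_saddle = U[np.argmin(np.abs(xs - (-0.8))), np.argmin(np.abs(ys - 0.6))]
    for u_min, _, _ in minima:
        assert u_min < u_saddle


def test_stationary_points_have_zero_force(mb_system):
    for guess in [(-0.5, 1.5), (0.0, 0.5), (0.6, 0.0)]:
        res = minimize(
            lambda p: evaluate_potential(mb_system, p),
            guess,
            jac=lambda p: -evaluate_force(mb_system, p),
            method="BFGS",
            options={"gtol": 1e-10},
        )
        assert np.linalg.norm(evaluate_force(mb_system, res.x)) < 1e-6


def test_chain_dihedral_scan_minimum():
    """Rotating the distal bead at fixed bond geometry, the cosine dihedral
    term is minimal at phi = pi and the scan minimum matches it."""
    chain = make_builtin_system("dihedral_chain_4bead")
    base = chain.init_position.reshape(4, 3)
    b2 = base[2] - base[1]
    b2h = b2 / np.linalg.norm(b2)
    v = base[3] - base[2]
    angles = np.linspace(-np.pi, np.pi, 720, endpoint=False)
    energies = []
    for a in angles:
        vr = (
            v * np.cos(a)
            + np.cross(b2h, v) * np.sin(a)
            + b2h * (b2h @ v) * (1 - np.cos(a))
        )
        pos = base.copy()
        pos[3] = base[2] + vr
        energies.append(evaluate_potential(chain, pos.reshape(-1)))
    energies = np.asarray(energies)
    phi0 = dihedral_angle(base[None])[0]
    # rotation leaves bonds/angles at equilibrium: energy is the dihedral term
    k = chain.potential_params["k_dih"]
    best = angles[np.argmin(energies)]
    phi_best = dihedral_angle(_rotated(base, best)[None])[0]
    assert abs(abs(phi_best) - np.pi) < 0.01
    assert energies.min() == pytest.approx(0.0, abs=1e-10)
    assert energies.max() == pytest.approx(2 * k, rel=1e-4)


def _rotated(base, a):
    b2 = base[2] - base[1]
    b2h = b2 / np.linalg.norm(b2)
    v = base[3] - base[2]
    vr = v * np.cos(a) + np.cross(b2h, v) * np.sin(a) + b2h * (b2h @ v) * (1 - np.cos(a))
    pos = base.copy()
    pos[3] = base[2] + vr
    return pos


def test_dihedral_gradient_and_generator():
    """Analytic dihedral gradient matches finite differences and the
    rotation generator is exactly conjugate (grad . dr/dphi = 1)."""
    rng = np.random.default_rng(3)
    base = make_builtin_system("dihedral_chain_4bead").init_position.reshape(4, 3)
    P = base[None] + 0.2 * rng.standard_normal((40, 4, 3))
    g = dihedral_gradient(P)
    gen = dihedral_rotation_generator(P)
    assert np.abs((g * gen).sum(axis=(-1, -2)) - 1.0).max() < 1e-12
    h = 1e-6
    for a in range(4):
        for d in range(3):
            pp, pm = P.copy(), P.copy()
            pp[:, a, d] += h
            pm[:, a, d] -= h
            fd = (dihedral_angle(pp) - dihedral_angle(pm)) / (2 * h)
            assert np.abs(g[:, a, d] - fd).max() < 1e-6


def test_unknown_builtin_rejected():
    with pytest.raises(KeyError, match="unknown builtin"):
        make_builtin_system("unknown")


def test_double_well_symmetry():
    dw = make_builtin_system("double_well_1d")
    x = np.linspace(0, 2, 50)[:, None]
    assert np.allclose(
        evaluate_potential(dw, x), evaluate_potential(dw, -x), rtol=1e-14
    )
    assert evaluate_potential(dw, [1.0]) == pytest.approx(0.0)


def test_oracle_validates_and_routes_agree(mb_oracle):
    """Marginal normalized to 1, pmf min-shifted, and the two independent
    mean-force routes (PMF derivative vs conditional average) agree."""
    mb_oracle.validate()
    assert np.trapezoid(mb_oracle.marginal_density, mb_oracle.grid) == pytest.approx(
        1.0, abs=1e-6
    )
    assert mb_oracle.pmf.min() == 0.0
    assert mb_oracle.quadrature_meta["dual_route_rel_l2"] < 1e-4


def test_oracle_separable_closed_form():
    """For u(x,y) = v(x) + w(y) the x-PMF equals v(x) up to a constant."""
    sys2 = make_builtin_system("double_well_harmonic_2d")
    orc = compute_oracle(sys2, CGMapping.axis(2, 0), (-2.0, 2.0, 1001))
    v = evaluate_potential(make_builtin_system("double_well_1d"), orc.grid[:, None])
    assert np.abs(orc.pmf - (v - v.min())).max() < 1e-6


def test_oracle_gaussian_mean_force():
    """u = (x^2+y^2)/2 at beta=1: marginal over y is standard normal, so the
    mean force at x=1 is exactly -1."""
    h2 = make_builtin_system("harmonic_2d")
    orc = compute_oracle(h2, CGMapping.axis(2, 0), (-7.6, 7.6, 1201))
    assert orc.interp_mean_force(1.0) == pytest.approx(-1.0, abs=1e-8)


def test_oracle_refuses_tight_bounds(mb_system, x_mapping):
    tight = make_builtin_system(
        "muller_brown", {"domain_box": [[-1.0, 1.0], [-0.2, 1.8]]}
    )
    with pytest.raises(InsufficientBoundsError):
        compute_oracle(tight, x_mapping, (-1.0, 1.0, 301), n_orth=301)


def test_oracle_table_roundtrip(mb_oracle):
    text = mb_oracle.to_table()
    back = OracleGrid.from_table(text)
    assert np.array_equal(back.grid, mb_oracle.grid)
    assert np.array_equal(back.pmf, mb_oracle.pmf)
    assert back.to_table() == text


def test_affine_transform_consistency():
    """energy_scale/offset/scale reparameterize the surface exactly."""
    plain = make_builtin_system("double_well_1d")
    scaled = make_builtin_system(
        "double_well_1d",
        {"affine_offset": [2.0], "affine_scale": [0.5], "energy_scale": 3.0,
         "domain_box": [[0.9, 3.1]]},
    )
    x = np.linspace(1.2, 2.8, 41)[:, None]
    u_expect = 3.0 * evaluate_potential(plain, (x - 2.0) / 0.5)
    assert np.allclose(evaluate_potential(scaled, x), u_expect, rtol=1e-13)
    h = 1e-6
    fd = -(evaluate_potential(scaled, x + h) - evaluate_potential(scaled, x - h)) / (2 * h)
    assert np.allclose(evaluate_force(scaled, x)[:, 0], fd, rtol=1e-5)


def test_mapping_orthonormality_enforced():
    with pytest.raises(ValueError, match="orthonormal"):
        CGMapping(np.array([[1.0, 1.0]]))
    m = CGMapping(np.array([[0.6, 0.8]]))
    f = np.array([[1.0, 2.0]])
    assert m.apply(f)[0, 0] == pytest.approx(0.6 + 1.6)


def test_shape_mismatch_rejected(mb_system):
    with pytest.raises(ValueError, match="dimension"):
        evaluate_potential(mb_system, np.zeros((5, 3)))


def test_nonfinite_parameter_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        make_builtin_system("harmonic_1d", {"k": float("nan")})
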