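"""Analytic model systems, linear CG mappings and exact quadrature oracles.

This module defines the low-dimensional benchmark systems used throughout the
package: a 1D harmonic well, a 1D quartic double well, 2D harmonic and
separable surfaces, the two-dimensional Mueller-Brown surface, and a four-bead
chain with bond, angle and cosine-dihedral terms.  Each system carries an
analytic potential ``u(r)`` and its exact gradient, an inverse temperature
``beta`` and a rectangular ``domain_box`` that bounds quadrature and sampling.

For systems of ambient dimension <= 2 with a one-dimensional linear CG
mapping, :func:`compute_oracle` evaluates the exact potential of mean force

    U*(R) = -(1/beta) * ln  integral exp(-beta u) dy_perp   (min-shifted to 0)

together with the marginal density and the mean force.  The mean force is
computed two independent ways -- as the negative derivative of the quadrature
PMF and as the direct conditional average of the projected force -- and the
two routes must agree; this grid is the ground truth for every accuracy
metric in the package.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import canonical_json, sha256_of_text

__all__ = [
    "SystemSpec",
    "CGMapping",
    "OracleGrid",
    "evaluate_potential",
    "evaluate_force",
    "potential_and_force",
    "compute_oracle",
    "make_builtin_system",
    "builtin_names",
    "dihedral_angle",
    "dihedral_gradient",
    "dihedral_rotation_generator",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemSpec:
    """An analytic potential energy surface with parameters and temperature.

    Parameters
    ----------
    name
        Registered builtin identifier (dispatches the functional form).
    dim
        Ambient dimension of the configuration space.
    potential_params
        All numeric parameters of the potential, including the optional
        affine transform keys ``affine_offset``, ``affine_scale`` (per axis)
        and ``energy_scale``.
    beta
        Inverse temperature 1/kBT (1/energy units).
    domain_box
        Per-dimension ``(lower, upper)`` bounds; quadrature and histogram
        support, and reflective walls for the samplers.
    init_position
        A reference configuration inside the box (sampler starting point for
        systems too high-dimensional for grid-based equilibrium draws).
    """

    name: str
    dim: int
    potential_params: dict
    beta: float
    domain_box: np.ndarray
    init_position: np.ndarray | None = None

    def __post_init__(self):
        box = np.atleast_2d(np.asarray(self.domain_box, dtype=float))
        if box.shape != (self.dim, 2) or not np.all(box[:, 1] > box[:, 0]):
            raise ValueError(f"domain_box must be ({self.dim}, 2) with upper > lower")
        object.__setattr__(self, "domain_box", box)
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be positive and finite")
        for key, val in self.potential_params.items():
            if not np.all(np.isfinite(np.asarray(val, dtype=float))):
                raise ValueError(f"non-finite potential parameter {key!r}")
        if self.init_position is not None:
            object.__setattr__(
                self, "init_position", np.asarray(self.init_position, dtype=float)
            )

    # affine transform: u(r) = energy_scale * u0((r - offset) / scale)
    def _affine(self):
        p = self.potential_params
        off = np.asarray(p.get("affine_offset", np.zeros(self.dim)), dtype=float)
        scl = np.asarray(p.get("affine_scale", np.ones(self.dim)), dtype=float)
        esc = float(p.get("energy_scale", 1.0))
        return off, scl, esc

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "dim": self.dim,
            "potential_params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.potential_params.items()
            },
            "beta": float(self.beta),
            "domain_box": self.domain_box.tolist(),
        }
        if self.init_position is not None:
            d["init_position"] = self.init_position.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        d = dict(d)
        init = d.pop("init_position", None)
        return cls(
            name=d["name"],
            dim=int(d["dim"]),
            potential_params={k: _as_param(v) for k, v in d["potential_params"].items()},
            beta=float(d["beta"]),
            domain_box=np.asarray(d["domain_box"], dtype=float),
            init_position=None if init is None else np.asarray(init, dtype=float),
        )

    def content_hash(self) -> str:
        return sha256_of_text(canonical_json(self.to_dict()))


def _as_param(v):
    if isinstance(v, list):
        return np.asarray(v, dtype=float)
    return float(v)


@dataclass(frozen=True)
class CGMapping:
    """Linear orthogonal projection from ambient to CG coordinates.

    The same matrix is applied to positions and to forces: ``R = M r`` and
    ``G = M f``.  Rows must be orthonormal.
    """

    matrix: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        gram = m @ m.T
        if not np.allclose(gram, np.eye(m.shape[0]), atol=1e-10):
            raise ValueError("CG mapping rows must be orthonormal")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"R{i}" for i in range(m.shape[0]))
            )

    @property
    def n_cg(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Project positions or forces: shape (..., dim) -> (..., n_cg)."""
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] != self.dim:
            raise ValueError(
                f"array last dimension {arr.shape[-1]} != mapping dim {self.dim}"
            )
        return arr @ self.matrix.T

    @classmethod
    def axis(cls, dim: int, index: int, label: str | None = None) -> "CGMapping":
        """Projection onto a single Cartesian axis."""
        row = np.zeros((1, dim))
        row[0, index] = 1.0
        return cls(row, (label,) if label else ())


class InsufficientBoundsError(ValueError):
    """Quadrature or histogram bounds do not cover the relevant density."""


@dataclass
class OracleGrid:
    """Exact PMF, mean force and marginal density on a CG-coordinate grid."""

    grid: np.ndarray
    pmf: np.ndarray
    mean_force: np.ndarray
    marginal_density: np.ndarray
    quadrature_meta: dict = field(default_factory=dict)

    def validate(self):
        g = self.grid
        if not np.all(np.diff(g) > 0):
            raise ValueError("oracle grid must be strictly increasing")
        norm = np.trapezoid(self.marginal_density, g)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"marginal density integrates to {norm}, not 1")
        if abs(self.pmf.min()) > 1e-9:
            raise ValueError("pmf must be min-shifted to zero")
        fd = -_derivative_on_grid(self.pmf, g)
        rel = np.linalg.norm(fd - self.mean_force) / np.linalg.norm(self.mean_force)
        if rel > 1e-4:
            raise ValueError(
                f"mean force inconsistent with -d(pmf)/dR (relative L2 {rel:.2e})"
            )
        return self

    def interp_pmf(self, x):
        return np.interp(x, self.grid, self.pmf)

    def interp_mean_force(self, x):
        return np.interp(x, self.grid, self.mean_force)

    def density_interval(self, coverage: float = 0.999) -> tuple:
        """Central interval of the marginal holding ``coverage`` of the mass."""
        dx = np.gradient(self.grid)
        cdf = np.cumsum(self.marginal_density * dx)
        cdf /= cdf[-1]
        tail = (1.0 - coverage) / 2.0
        lo = self.grid[np.searchsorted(cdf, tail)]
        hi = self.grid[min(np.searchsorted(cdf, 1.0 - tail), len(self.grid) - 1)]
        return float(lo), float(hi)

    def to_table(self) -> str:
        from ._util import fmt_float

        lines = ["grid\tpmf\tmean_force\tdensity"]
        for g, p, f, d in zip(self.grid, self.pmf, self.mean_force, self.marginal_density):
            lines.append("\t".join(map(fmt_float, (g, p, f, d))))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "OracleGrid":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


# ---------------------------------------------------------------------------
# Builtin potentials (base forms, before the affine transform)
# ---------------------------------------------------------------------------

# Canonical Mueller-Brown four-Gaussian parameterization.
_MB_DEFAULTS = {
    "A": np.array([-200.0, -100.0, -170.0, 15.0]),
    "a": np.array([-1.0, -1.0, -6.5, 0.7]),
    "b": np.array([0.0, 0.0, 11.0, 0.6]),
    "c": np.array([-10.0, -10.0, -6.5, 0.7]),
    "x0": np.array([1.0, 0.0, -0.5, -1.0]),
    "y0": np.array([0.0, 0.5, 1.5, 1.0]),
}


def _mb_terms(p, q):
    dx = q[..., 0, None] - p["x0"]
    dy = q[..., 1, None] - p["y0"]
    expo = p["a"] * dx**2 + p["b"] * dx * dy + p["c"] * dy**2
    return p["A"] * np.exp(expo), dx, dy


def _mb_u(p, q):
    t, _, _ = _mb_terms(p, q)
    return t.sum(axis=-1)


def _mb_grad(p, q):
    t, dx, dy = _mb_terms(p, q)
    gx = (t * (2 * p["a"] * dx + p["b"] * dy)).sum(axis=-1)
    gy = (t * (p["b"] * dx + 2 * p["c"] * dy)).sum(axis=-1)
    return np.stack([gx, gy], axis=-1)


def _mb_both(p, q):
    t, dx, dy = _mb_terms(p, q)
    gx = (t * (2 * p["a"] * dx + p["b"] * dy)).sum(axis=-1)
    gy = (t * (p["b"] * dx + 2 * p["c"] * dy)).sum(axis=-1)
    return t.sum(axis=-1), np.stack([gx, gy], axis=-1)


def _harm1_u(p, q):
    return 0.5 * p["k"] * q[..., 0] ** 2


def _harm1_grad(p, q):
    return (p["k"] * q[..., 0])[..., None]


def _harm2_u(p, q):
    return 0.5 * (p["kx"] * q[..., 0] ** 2 + p["ky"] * q[..., 1] ** 2)


def _harm2_grad(p, q):
    return np.stack([p["kx"] * q[..., 0], p["ky"] * q[..., 1]], axis=-1)


def _dw1_u(p, q):
    x = q[..., 0]
    return p["a"] * (x**2 - 1.0) ** 2


def _dw1_grad(p, q):
    x = q[..., 0]
    return (4.0 * p["a"] * x * (x**2 - 1.0))[..., None]


def _ch2_u(p, q):
    x, y = q[..., 0], q[..., 1]
    return 0.5 * p["kx"] * x**2 + 0.5 * p["ky"] * (y - p["c"] * x) ** 2


def _ch2_grad(p, q):
    x, y = q[..., 0], q[..., 1]
    d = y - p["c"] * x
    return np.stack(
        [p["kx"] * x - p["c"] * p["ky"] * d, p["ky"] * d], axis=-1
    )


def _dwh2_u(p, q):
    x, y = q[..., 0], q[..., 1]
    return p["a"] * (x**2 - 1.0) ** 2 + 0.5 * p["ky"] * y**2


def _dwh2_grad(p, q):
    x, y = q[..., 0], q[..., 1]
    return np.stack([4.0 * p["a"] * x * (x**2 - 1.0), p["ky"] * y], axis=-1)


# --- four-bead chain geometry helpers --------------------------------------

def _bond_terms(pos, i, j, k, r0):
    b = pos[..., j, :] - pos[..., i, :]
    r = np.linalg.norm(b, axis=-1)
    u = 0.5 * k * (r - r0) ** 2
    # dU/dr_j = k (r - r0) b/r ; dU/dr_i = -that
    g = (k * (r - r0) / r)[..., None] * b
    return u, g


def _angle_terms(pos, i, j, k_idx, ka, t0):
    u_v = pos[..., i, :] - pos[..., j, :]
    v_v = pos[..., k_idx, :] - pos[..., j, :]
    nu = np.linalg.norm(u_v, axis=-1)
    nv = np.linalg.norm(v_v, axis=-1)
    uh = u_v / nu[..., None]
    vh = v_v / nv[..., None]
    cos_t = np.clip((uh * vh).sum(-1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-14))
    u_e = 0.5 * ka * (theta - t0) ** 2
    dU = ka * (theta - t0)
    gi = (dU / (nu * sin_t))[..., None] * (cos_t[..., None] * uh - vh)
    gk = (dU / (nv * sin_t))[..., None] * (cos_t[..., None] * vh - uh)
    gj = -(gi + gk)
    return u_e, gi, gj, gk


def dihedral_angle(pos4: np.ndarray) -> np.ndarray:
    """Signed dihedral in (-pi, pi] (IUPAC convention) for atoms (i,j,k,l).

    ``pos4`` has shape (..., 4, 3).
    """
    b1 = pos4[..., 1, :] - pos4[..., 0, :]
    b2 = pos4[..., 2, :] - pos4[..., 1, :]
    b3 = pos4[..., 3, :] - pos4[..., 2, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    return np.arctan2((np.cross(n1, n2) * b2n).sum(-1), (n1 * n2).sum(-1))


def dihedral_gradient(pos4: np.ndarray) -> np.ndarray:
    """Analytic gradient d(phi)/d(r_i), shape (..., 4, 3).

    Standard four-point dihedral-gradient formulas (Blondel-Karplus form).
    """
    b1 = pos4[..., 1, :] - pos4[..., 0, :]
    b2 = pos4[..., 2, :] - pos4[..., 1, :]
    b3 = pos4[..., 3, :] - pos4[..., 2, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    n1sq = (n1 * n1).sum(-1)
    n2sq = (n2 * n2).sum(-1)
    gi = (-nb2 / n1sq)[..., None] * n1
    gl = (nb2 / n2sq)[..., None] * n2
    f12 = ((b1 * b2).sum(-1) / nb2**2)[..., None]
    f32 = ((b3 * b2).sum(-1) / nb2**2)[..., None]
    gj = -(1.0 + f12) * gi + f32 * gl
    gk = f12 * gi - (1.0 + f32) * gl
    return np.stack([gi, gj, gk, gl], axis=-2)


def dihedral_rotation_generator(pos4: np.ndarray) -> np.ndarray:
    """Displacement field dr/d(phi), shape (..., 4, 3).

    Convention: a unit change of the dihedral rigidly rotates the distal atom
    ``l`` about the central-bond axis j->k; atoms i, j, k do not move.  The
    rotation preserves the bond length k-l and the angle j-k-l, is
    volume-preserving, and satisfies grad(phi) . dr/d(phi) = 1 exactly.
    """
    b2 = pos4[..., 2, :] - pos4[..., 1, :]
    b3 = pos4[..., 3, :] - pos4[..., 2, :]
    b2h = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    gen = np.zeros_like(pos4)
    gen[..., 3, :] = np.cross(b2h, b3)
    return gen


def _chain_u(p, q):
    pos = q.reshape(q.shape[:-1] + (4, 3))
    u = np.zeros(pos.shape[:-2])
    for i, j in ((0, 1), (1, 2), (2, 3)):
        ub, _ = _bond_terms(pos, i, j, p["k_bond"], p["r0"])
        u = u + ub
    for i, j, k in ((0, 1, 2), (1, 2, 3)):
        ua, *_ = _angle_terms(pos, i, j, k, p["k_angle"], p["theta0"])
        u = u + ua
    phi = dihedral_angle(pos)
    u = u + p["k_dih"] * (1.0 + np.cos(phi))
    return u


def _chain_grad(p, q):
    pos = q.reshape(q.shape[:-1] + (4, 3))
    g = np.zeros_like(pos)
    for i, j in ((0, 1), (1, 2), (2, 3)):
        _, gb = _bond_terms(pos, i, j, p["k_bond"], p["r0"])
        g[..., j, :] += gb
        g[..., i, :] -= gb
    for i, j, k in ((0, 1, 2), (1, 2, 3)):
        _, gi, gj, gk = _angle_terms(pos, i, j, k, p["k_angle"], p["theta0"])
        g[..., i, :] += gi
        g[..., j, :] += gj
        g[..., k, :] += gk
    phi = dihedral_angle(pos)
    dphi = dihedral_gradient(pos)
    g += (-p["k_dih"] * np.sin(phi))[..., None, None] * dphi
    return g.reshape(q.shape)


def _chain_init(p):
    """Planar trans zig-zag (phi = pi) with equilibrium bonds and angles.

    Bond directions alternate by +/- (pi - theta0)/2 about the x axis, which
    gives bond angles exactly theta0 and a planar (trans) dihedral.
    """
    r0, t0 = p["r0"], p["theta0"]
    half = (math.pi - t0) / 2.0
    dirs = [
        np.array([math.cos(half), math.sin(half), 0.0]),
        np.array([math.cos(half), -math.sin(half), 0.0]),
        np.array([math.cos(half), math.sin(half), 0.0]),
    ]
    pts = [np.zeros(3)]
    for d in dirs:
        pts.append(pts[-1] + r0 * d)
    arr = np.stack(pts)
    return (arr - arr.mean(axis=0)).reshape(-1)


_BUILTINS: dict = {}


def _register(name, dim, u, grad, defaults, beta, box, init=None, both=None):
    _BUILTINS[name] = {
        "dim": dim,
        "u": u,
        "grad": grad,
        "both": both,
        "defaults": defaults,
        "beta": beta,
        "box": np.asarray(box, dtype=float),
        "init": init,
    }


_register(
    "muller_brown", 2, _mb_u, _mb_grad, _MB_DEFAULTS, beta=0.125,
    box=[[-3.1, 1.4], [-1.3, 3.1]], init=np.array([-0.558, 1.442]),
    both=_mb_both,
)
_register(
    "harmonic_1d", 1, _harm1_u, _harm1_grad, {"k": 1.0}, beta=1.0,
    box=[[-8.0, 8.0]], init=np.array([0.0]),
)
_register(
    "harmonic_2d", 2, _harm2_u, _harm2_grad, {"kx": 1.0, "ky": 1.0}, beta=1.0,
    box=[[-8.0, 8.0], [-8.0, 8.0]], init=np.array([0.0, 0.0]),
)
_register(
    # conditional force noise along x is exactly c^2 ky / beta: a cheap
    # closed-form target for noise and SE calibration checks
    "coupled_harmonic_2d", 2, _ch2_u, _ch2_grad,
    {"kx": 1.0, "ky": 1.0, "c": 0.5}, beta=1.0,
    box=[[-8.0, 8.0], [-10.0, 10.0]], init=np.array([0.0, 0.0]),
)
_register(
    "double_well_1d", 1, _dw1_u, _dw1_grad, {"a": 5.0}, beta=1.0,
    box=[[-2.2, 2.2]], init=np.array([-1.0]),
)
_register(
    "double_well_harmonic_2d", 2, _dwh2_u, _dwh2_grad, {"a": 5.0, "ky": 2.0},
    beta=1.0, box=[[-2.2, 2.2], [-6.0, 6.0]], init=np.array([-1.0, 0.0]),
)
_register(
    "dihedral_chain_4bead", 12, _chain_u, _chain_grad,
    {"r0": 1.0, "k_bond": 100.0, "k_angle": 50.0,
     "theta0": 1.9106332362490186, "k_dih": 2.0},
    beta=1.0, box=[[-6.0, 6.0]] * 12, init=None,
)


def builtin_names() -> tuple:
    return tuple(sorted(_BUILTINS))


def make_builtin_system(name: str, overrides: dict | None = None) -> SystemSpec:
    """Factory for the registered builtin systems.

    ``overrides`` may replace any potential parameter and the special keys
    ``beta`` and ``domain_box``.
    """
    if name not in _BUILTINS:
        raise KeyError(
            f"unknown builtin system {name!r}; available: {', '.join(builtin_names())}"
        )
    entry = _BUILTINS[name]
    params = {
        k: (v.copy() if isinstance(v, np.ndarray) else v)
        for k, v in entry["defaults"].items()
    }
    beta = entry["beta"]
    box = entry["box"].copy()
    overrides = dict(overrides or {})
    if "beta" in overrides:
        beta = float(overrides.pop("beta"))
    if "domain_box" in overrides:
        box = np.asarray(overrides.pop("domain_box"), dtype=float)
    for k, v in overrides.items():
        if k not in params and k not in ("affine_offset", "affine_scale", "energy_scale"):
            raise KeyError(f"unknown parameter {k!r} for system {name!r}")
        params[k] = _as_param(v) if isinstance(v, (list, tuple)) else (
            np.asarray(v, dtype=float) if isinstance(v, np.ndarray) else float(v)
        )
    init = entry["init"]
    if init is None and name == "dihedral_chain_4bead":
        init = _chain_init(params)
    return SystemSpec(
        name=name, dim=entry["dim"], potential_params=params, beta=beta,
        domain_box=box, init_position=init,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _check_positions(system: SystemSpec, positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.shape[-1] != system.dim:
        raise ValueError(
            f"positions last dimension {pos.shape[-1]} != system dim {system.dim}"
        )
    return pos


def evaluate_potential(system: SystemSpec, positions) -> np.ndarray:
    """Potential energy u(r) per configuration; shape (..., dim) -> (...)."""
    pos = _check_positions(system, positions)
    entry = _BUILTINS[system.name]
    off, scl, esc = system._affine()
    q = (pos - off) / scl
    return esc * entry["u"](system.potential_params, q)


def evaluate_force(system: SystemSpec, positions) -> np.ndarray:
    """Unbiased force f(r) = -grad u(r); same shape as positions."""
    pos = _check_positions(system, positions)
    entry = _BUILTINS[system.name]
    off, scl, esc = system._affine()
    q = (pos - off) / scl
    return -(esc / scl) * entry["grad"](system.potential_params, q)


def potential_and_force(system: SystemSpec, positions) -> tuple:
    """Energy and force in one pass (shares the exponential terms)."""
    pos = _check_positions(system, positions)
    entry = _BUILTINS[system.name]
    off, scl, esc = system._affine()
    q = (pos - off) / scl
    if entry["both"] is not None:
        u, g = entry["both"](system.potential_params, q)
    else:
        u = entry["u"](system.potential_params, q)
        g = entry["grad"](system.potential_params, q)
    return esc * u, -(esc / scl) * g


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------

def _derivative_on_grid(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Fourth-order finite-difference derivative on a uniform grid."""
    h = x[1] - x[0]
    d = np.empty_like(y)
    d[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12 * h)
    # one-sided fourth-order stencils at the edges
    c = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0
    d[0] = (c * y[:5]).sum() / h
    d[1] = (c * y[1:6]).sum() / h
    d[-1] = -(c * y[-5:][::-1]).sum() / h
    d[-2] = -(c * y[-6:-1][::-1]).sum() / h
    return d


def compute_oracle(
    system: SystemSpec,
    mapping: CGMapping,
    grid_spec: tuple | dict,
    n_orth: int = 2001,
) -> OracleGrid:
    """Exact PMF / mean force / marginal density along a 1D CG coordinate.

    ``grid_spec`` is ``(lo, hi, n)`` (or a dict with those keys) for the CG
    coordinate.  Supported for ambient dimension 1 and 2 with a single-row
    orthonormal mapping.  The mean force is computed both as the derivative
    of the quadrature PMF and as the direct conditional average of the
    projected force; the two routes must agree to 1e-4 relative L2.

    Raises
    ------
    InsufficientBoundsError
        If the Boltzmann density at the quadrature boundary exceeds 1e-12 of
        its maximum (bounds too tight for the stated temperature).
    """
    if mapping.n_cg != 1:
        raise ValueError("oracle quadrature supports one-dimensional CG coordinates")
    if system.dim > 2:
        raise ValueError("oracle quadrature supports ambient dimension <= 2")
    if isinstance(grid_spec, dict):
        lo, hi, n = grid_spec["lo"], grid_spec["hi"], grid_spec["n"]
    else:
        lo, hi, n = grid_spec
    grid = np.linspace(float(lo), float(hi), int(n))
    beta = system.beta
    row = mapping.matrix[0]

    if system.dim == 1:
        pos = grid[:, None] * row[None, :]
        u = evaluate_potential(system, pos)
        f = evaluate_force(system, pos)
        w = np.exp(-beta * (u - u.min()))
        if w[0] > 1e-12 * w.max() or w[-1] > 1e-12 * w.max():
            raise InsufficientBoundsError(
                "grid boundary density exceeds 1e-12 of maximum; widen the grid "
                f"(edge/max = {max(w[0], w[-1]) / w.max():.2e})"
            )
        logm = -beta * (u - u.min())
        mean_force = mapping.apply(f)[:, 0]
        marg = w
    else:
        # rotate: r = R * row + Y * row_perp
        perp = np.array([-row[1], row[0]])
        corners = np.array(
            [[bx, by] for bx in system.domain_box[0] for by in system.domain_box[1]]
        )
        yc = corners @ perp
        ylo, yhi = yc.min(), yc.max()
        ys = np.linspace(ylo, yhi, int(n_orth))
        logm = np.empty(len(grid))
        mean_force = np.empty(len(grid))
        edge_ratio = 0.0
        # global reference for stable exponentials
        u_ref = None
        chunk = max(1, int(2e6 // len(ys)))
        # first pass: find global min of u on the product grid (chunked)
        umin = np.inf
        for i0 in range(0, len(grid), chunk):
            R = grid[i0:i0 + chunk]
            pos = R[:, None, None] * row + ys[None, :, None] * perp
            u = evaluate_potential(system, pos)
            umin = min(umin, u.min())
        for i0 in range(0, len(grid), chunk):
            R = grid[i0:i0 + chunk]
            pos = R[:, None, None] * row + ys[None, :, None] * perp
            u = evaluate_potential(system, pos)
            w = np.exp(-beta * (u - umin))
            edge_ratio = max(edge_ratio, w[:, 0].max(), w[:, -1].max())
            z = np.trapezoid(w, ys, axis=1)
            logm[i0:i0 + chunk] = np.log(z)
            fproj = mapping.apply(evaluate_force(system, pos))[..., 0]
            mean_force[i0:i0 + chunk] = np.trapezoid(fproj * w, ys, axis=1) / z
        if edge_ratio > 1e-12:
            raise InsufficientBoundsError(
                "orthogonal quadrature boundary density exceeds 1e-12 of maximum "
                f"(edge/max = {edge_ratio:.2e}); widen domain_box"
            )
        m = np.exp(logm - logm.max())
        if m[0] > 1e-12 or m[-1] > 1e-12:
            raise InsufficientBoundsError(
                "CG-grid boundary density exceeds 1e-12 of maximum; widen the grid "
                f"(edge/max = {max(m[0], m[-1]):.2e})"
            )
        marg = m

    pmf = -logm / beta
    pmf = pmf - pmf.min()
    density = marg / np.trapezoid(marg, grid)

    oracle = OracleGrid(
        grid=grid,
        pmf=pmf,
        mean_force=mean_force,
        marginal_density=density,
        quadrature_meta={
            "lo": float(lo), "hi": float(hi), "n": int(n),
            "n_orth": int(n_orth) if system.dim == 2 else 0,
            "beta": float(beta), "system": system.name,
        },
    )
    # dual-route consistency (route i: -d pmf/dR, route ii: conditional average)
    fd = -_derivative_on_grid(pmf, grid)
    rel = float(np.linalg.norm(fd - mean_force) / np.linalg.norm(mean_force))
    oracle.quadrature_meta["dual_route_rel_l2"] = rel
    if rel > 1e-4:
        raise RuntimeError(
            f"quadrature mean-force routes disagree (relative L2 {rel:.2e}); "
            "increase grid resolution"
        )
    return oracle.validate()
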