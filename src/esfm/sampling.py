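"""Biased and unbiased trajectory generation on the analytic model systems.

The sampler integrates Metropolis-adjusted overdamped Langevin dynamics
(MALA, unit mobility): an Euler-Maruyama proposal

    r' = r - grad(u + W o xi)(r) dt + sqrt(2 dt / beta) eta

followed by a Metropolis accept/reject step, so the stationary distribution
is *exactly* the biased Boltzmann law ``exp(-beta (u + W(xi(r))))`` with no
O(dt) discretization bias; proposals outside ``domain_box`` are rejected,
which realizes hard walls exactly.  Many statistically independent chains
are propagated in parallel (vectorized over the leading axis) and frames are
recorded every ``stride`` steps after a burn-in; choosing ``stride`` of a
few relaxation times makes recorded frames effectively independent, which
the binned standard errors downstream rely on.

Bias potentials act on a collective variable (CV): a linear projection of the
coordinates or a four-point dihedral angle.  Three bias kinds are supported:

* ``harmonic_umbrella`` -- W(R) = kappa/2 ||R - R0||^2,
* ``gaussian_restraint`` -- a static Gaussian hill or well,
* ``wt_metadynamics``   -- history-dependent Gaussians with heights tempered
  by the bias factor gamma > 1.

Every frame records the biased force actually applied, the unbiased force
-grad u, the bias energy and (for static biases) the importance weight
exp(beta W), so that unbiased statistics can be recovered either by force
recomputation (bias on the CG coordinate) or by self-normalized reweighting.

Determinism: all draws come from counter-based Philox streams keyed by the
master seed, with separate sub-streams for initialization and dynamics, so
identical configurations reproduce bit-identical trajectories and changes to
stride or burn-in never shift the noise sequence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import stream_rng
from .toy_systems import (
    CGMapping,
    SystemSpec,
    dihedral_angle,
    dihedral_gradient,
    evaluate_force,
    evaluate_potential,
    potential_and_force,
)

__all__ = [
    "LinearCV",
    "DihedralCV",
    "BiasSpec",
    "TrajectoryDataset",
    "simulate",
    "bias_energy_and_force",
    "bias_ambient_force",
    "metadynamics_deposit",
    "recompute_unbiased_forces",
    "compute_importance_weights",
    "bias_is_on_cg",
    "boltzmann_grid_sample",
]


# ---------------------------------------------------------------------------
# Collective variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearCV:
    """Linear collective variable s = M r (rows need not be orthonormal)."""

    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.atleast_2d(np.asarray(self.matrix, float)))

    @property
    def n_cv(self):
        return self.matrix.shape[0]

    period = None  # aperiodic

    def value(self, positions):
        return np.asarray(positions, float) @ self.matrix.T

    def jacobian(self, positions):
        pos = np.asarray(positions, float)
        shape = pos.shape[:-1] + self.matrix.shape
        return np.broadcast_to(self.matrix, shape)

    def to_dict(self):
        return {"type": "linear", "matrix": self.matrix.tolist()}


@dataclass(frozen=True)
class DihedralCV:
    """Signed dihedral angle of four particles; periodic on (-pi, pi]."""

    indices: tuple

    period = 2.0 * np.pi
    n_cv = 1

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) != 4 or len(set(idx)) != 4:
            raise ValueError("dihedral CV needs four distinct particle indices")
        object.__setattr__(self, "indices", idx)

    def _gather(self, positions):
        pos = np.asarray(positions, float)
        p = pos.reshape(pos.shape[:-1] + (-1, 3))
        return p[..., list(self.indices), :]

    def value(self, positions):
        return dihedral_angle(self._gather(positions))[..., None]

    def jacobian(self, positions):
        pos = np.asarray(positions, float)
        p4 = self._gather(positions)
        grad4 = dihedral_gradient(p4)  # (..., 4, 3)
        jac = np.zeros(pos.shape[:-1] + (1, pos.shape[-1]))
        full = jac.reshape(pos.shape[:-1] + (1, -1, 3))
        for slot, atom in enumerate(self.indices):
            full[..., 0, atom, :] = grad4[..., slot, :]
        return jac

    def to_dict(self):
        return {"type": "dihedral", "indices": list(self.indices)}


def cv_from_dict(d):
    if d is None:
        return None
    if d["type"] == "linear":
        return LinearCV(np.asarray(d["matrix"], float))
    if d["type"] == "dihedral":
        return DihedralCV(tuple(d["indices"]))
    raise ValueError(f"unknown CV type {d['type']!r}")


def _wrap(delta, period):
    if period is None:
        return delta
    return delta - period * np.round(delta / period)


# ---------------------------------------------------------------------------
# Bias specification
# ---------------------------------------------------------------------------

_BIAS_KINDS = ("none", "harmonic_umbrella", "gaussian_restraint", "wt_metadynamics")


@dataclass(frozen=True)
class BiasSpec:
    """A bias potential over a collective variable.

    Parameters by kind:

    * ``harmonic_umbrella``: ``kappa`` (energy / CV-unit^2), ``center``.
    * ``gaussian_restraint``: ``height`` (energy; negative = well),
      ``center``, ``width`` (CV units).
    * ``wt_metadynamics``: ``h`` (initial Gaussian height, energy),
      ``sigma`` (width), ``tau`` (deposition stride, steps), ``gamma``
      (bias factor > 1), ``deposited`` (list of (center, effective height)).
    """

    kind: str = "none"
    cv: object = None
    kappa: float = 0.0
    center: np.ndarray | None = None
    height: float = 0.0
    width: float = 1.0
    h: float = 0.0
    sigma: float = 0.1
    tau: int = 500
    gamma: float = 10.0
    deposited: tuple = ()

    def __post_init__(self):
        if self.kind not in _BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind != "none" and self.cv is None:
            raise ValueError("biased kinds require a collective variable")
        if self.kind == "wt_metadynamics":
            if not self.gamma > 1.0:
                raise ValueError("well-tempered metadynamics requires gamma > 1")
            if self.sigma <= 0 or self.tau < 1:
                raise ValueError("wt_metadynamics requires sigma > 0 and tau >= 1")
        if self.center is not None:
            object.__setattr__(self, "center", np.atleast_1d(np.asarray(self.center, float)))
        dep = tuple((np.atleast_1d(np.asarray(c, float)), float(h)) for c, h in self.deposited)
        object.__setattr__(self, "deposited", dep)

    @property
    def period(self):
        return None if self.cv is None else self.cv.period

    def to_dict(self):
        d = {"kind": self.kind, "cv": None if self.cv is None else self.cv.to_dict()}
        if self.kind == "harmonic_umbrella":
            d.update(kappa=self.kappa, center=self.center.tolist())
        elif self.kind == "gaussian_restraint":
            d.update(height=self.height, center=self.center.tolist(), width=self.width)
        elif self.kind == "wt_metadynamics":
            d.update(
                h=self.h, sigma=self.sigma, tau=self.tau, gamma=self.gamma,
                deposited=[[c.tolist(), h] for c, h in self.deposited],
            )
        return d

    @classmethod
    def from_dict(cls, d):
        if d is None or d.get("kind", "none") == "none":
            return cls()
        kw = dict(d)
        kw["cv"] = cv_from_dict(kw.get("cv"))
        if "deposited" in kw:
            kw["deposited"] = tuple((np.asarray(c, float), float(h)) for c, h in kw["deposited"])
        return cls(**kw)


def bias_energy_and_force(bias: BiasSpec, cv_values) -> tuple:
    """Bias energy W and CV-space gradient dW/dR at the given CV values.

    ``cv_values`` has shape (..., n_cv); returns (W (...), grad (..., n_cv)).
    For ``wt_metadynamics`` this is the exact sum over deposited Gaussians
    (empty list: zeros — the valid initial state).
    """
    s = np.atleast_2d(np.asarray(cv_values, float))
    if bias.kind == "none":
        return np.zeros(s.shape[:-1]), np.zeros_like(s)
    if bias.kind == "harmonic_umbrella":
        d = _wrap(s - bias.center, bias.period)
        w = 0.5 * bias.kappa * (d**2).sum(-1)
        return w, bias.kappa * d
    if bias.kind == "gaussian_restraint":
        d = _wrap(s - bias.center, bias.period)
        q = (d**2).sum(-1) / (2.0 * bias.width**2)
        w = bias.height * np.exp(-q)
        return w, (-w / bias.width**2)[..., None] * d
    # wt_metadynamics: exact Gaussian sum, chunked over deposits
    w = np.zeros(s.shape[:-1])
    g = np.zeros_like(s)
    if bias.deposited:
        centers = np.stack([c for c, _ in bias.deposited])  # (D, n_cv)
        heights = np.asarray([h for _, h in bias.deposited])
        chunk = max(1, int(4e6) // max(s[..., 0].size, 1))
        for i0 in range(0, len(centers), chunk):
            d = _wrap(s[..., None, :] - centers[i0:i0 + chunk], bias.period)
            e = heights[i0:i0 + chunk] * np.exp(-(d**2).sum(-1) / (2 * bias.sigma**2))
            w += e.sum(-1)
            g += (e[..., None] * (-d / bias.sigma**2)).sum(-2)
    return w, g


def bias_ambient_force(bias: BiasSpec, positions) -> tuple:
    """Bias energy and ambient-space bias force -J^T dW/dR at positions."""
    pos = np.asarray(positions, float)
    if bias.kind == "none":
        return np.zeros(pos.shape[:-1]), np.zeros_like(pos)
    s = bias.cv.value(pos)
    w, g = bias_energy_and_force(bias, s)
    jac = bias.cv.jacobian(pos)  # (..., n_cv, dim)
    force = -np.einsum("...cd,...c->...d", jac, g)
    return w, force


def metadynamics_deposit(bias: BiasSpec, current_cv, beta: float) -> BiasSpec:
    """Append a tempered Gaussian at ``current_cv`` (well-tempered rule).

    The effective height is ``h * exp(-W_tau(s) * beta / (gamma - 1))`` where
    ``W_tau`` is the bias before this deposit, so repeated visits to the same
    point deposit non-increasing heights.
    """
    if bias.kind != "wt_metadynamics":
        raise ValueError("deposits only apply to wt_metadynamics biases")
    s = np.atleast_1d(np.asarray(current_cv, float))
    w_here, _ = bias_energy_and_force(bias, s[None, :])
    eff = bias.h * float(np.exp(-w_here[0] * beta / (bias.gamma - 1.0)))
    return replace(bias, deposited=bias.deposited + ((s, eff),))


def bias_is_on_cg(bias: BiasSpec, mapping) -> bool:
    """True iff the bias CV is a function of the CG coordinates only.

    Linear CVs are checked against the row space of the CG mapping; a
    dihedral CV matches only an identical dihedral CG coordinate.  This flag
    decides whether recomputed forces can be trusted without reweighting.
    """
    if bias.kind == "none":
        return True
    cv = bias.cv
    if isinstance(mapping, CGMapping) and isinstance(cv, LinearCV):
        m = mapping.matrix
        resid = cv.matrix - (cv.matrix @ m.T) @ m
        return bool(np.abs(resid).max() < 1e-10)
    if isinstance(cv, DihedralCV) and isinstance(mapping, DihedralCV):
        return cv.indices == mapping.indices
    return False


# ---------------------------------------------------------------------------
# Trajectory dataset
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryDataset:
    """Sampled configurations with forces, bias energies and weights.

    ``biased_forces`` are the forces that acted during the simulation,
    ``unbiased_forces`` are -grad u recomputed with the unbiased potential,
    and ``bias_forces`` is the bias contribution actually applied, so that
    ``biased_forces == unbiased_forces + bias_forces`` frame-wise.
    ``weights`` are the unnormalized importance weights exp(beta W); ``None``
    until computed (well-tempered metadynamics fills them on demand from the
    final bias state).
    """

    positions: np.ndarray
    biased_forces: np.ndarray | None = None
    unbiased_forces: np.ndarray | None = None
    bias_forces: np.ndarray | None = None
    bias_energy: np.ndarray | None = None
    weights: np.ndarray | None = None
    bias: BiasSpec = field(default_factory=BiasSpec)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self):
        return self.positions.shape[0]

    @property
    def dim(self):
        return self.positions.shape[1]

    def validate(self, atol_decomp: float = 1e-10):
        n, d = self.positions.shape
        if n == 0:
            raise ValueError("dataset has zero frames")
        for name in ("biased_forces", "unbiased_forces", "bias_forces"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n, d):
                raise ValueError(f"{name} shape {arr.shape} != {(n, d)}")
        if self.bias_energy is not None and self.bias_energy.shape != (n,):
            raise ValueError("bias_energy shape mismatch")
        if self.weights is not None:
            if self.weights.shape != (n,):
                raise ValueError("weights shape mismatch")
            if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive and finite")
        if (
            self.biased_forces is not None
            and self.unbiased_forces is not None
            and self.bias_forces is not None
        ):
            scale = max(np.abs(self.biased_forces).max(), 1.0)
            resid = np.abs(self.biased_forces - self.unbiased_forces - self.bias_forces)
            if resid.max() > atol_decomp * scale:
                raise ValueError(
                    "force decomposition violated: max |f_biased - f_unbiased - "
                    f"f_bias| = {resid.max():.3e}"
                )
        if self.bias.kind == "none":
            if self.biased_forces is not None and self.unbiased_forces is not None:
                if not np.array_equal(self.biased_forces, self.unbiased_forces):
                    raise ValueError("zero-bias dataset must have identical force arrays")
            if self.weights is not None and not np.all(self.weights == 1.0):
                raise ValueError("zero-bias dataset must have unit weights")
        return self

    @property
    def chain_ids(self) -> np.ndarray:
        """Chain index of every frame (frames are time-major interleaved)."""
        c = int(self.metadata.get("n_chains", 1))
        return np.tile(np.arange(c), self.n_frames // c + 1)[: self.n_frames]

    def chain_view(self, arr: np.ndarray) -> np.ndarray:
        """Reshape a per-frame array to (n_records, n_chains, ...).

        Frames are stored time-major interleaved across the independent
        chains; this view exposes the chain structure for block statistics.
        """
        c = int(self.metadata.get("n_chains", 1))
        return arr.reshape((-1, c) + arr.shape[1:])

    def subset(self, idx) -> "TrajectoryDataset":
        take = lambda a: None if a is None else a[idx]
        return TrajectoryDataset(
            positions=self.positions[idx],
            biased_forces=take(self.biased_forces),
            unbiased_forces=take(self.unbiased_forces),
            bias_forces=take(self.bias_forces),
            bias_energy=take(self.bias_energy),
            weights=take(self.weights),
            bias=self.bias,
            metadata={**self.metadata, "subset_of": self.metadata.get("n_frames")},
        )


# ---------------------------------------------------------------------------
# Equilibrium initialization (grid inverse-CDF draw, dim <= 2)
# ---------------------------------------------------------------------------

def boltzmann_grid_sample(
    system: SystemSpec,
    bias: BiasSpec,
    n: int,
    rng: np.random.Generator,
    grid_n: int = 512,
) -> np.ndarray:
    """Draw ``n`` configurations from exp(-beta (u + W)) on a dense grid.

    Cell probabilities come from the density at cell centers; a uniform
    jitter within each cell smooths the discretization.  Only for ambient
    dimension <= 2.
    """
    if system.dim > 2:
        raise ValueError("grid-based equilibrium draws require dim <= 2")
    axes = [
        np.linspace(lo, hi, grid_n + 1) for lo, hi in system.domain_box
    ]
    centers = [0.5 * (ax[1:] + ax[:-1]) for ax in axes]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    u = evaluate_potential(system, pts)
    if bias.kind not in ("none", "wt_metadynamics"):
        w, _ = bias_ambient_force(bias, pts)
        u = u + w
    logp = -system.beta * (u - u.min())
    p = np.exp(logp)
    p /= p.sum()
    idx = rng.choice(len(pts), size=n, p=p)
    jitter = rng.uniform(-0.5, 0.5, size=(n, system.dim))
    widths = np.array([ax[1] - ax[0] for ax in axes])
    return pts[idx] + jitter * widths


# ---------------------------------------------------------------------------
# Metadynamics grid cache (1D CV): PLUMED-style tabulated bias
# ---------------------------------------------------------------------------

class _MetadGrid:
    def __init__(self, bias: BiasSpec, lo: float, hi: float, n: int = 4096):
        self.lo, self.hi, self.n = float(lo), float(hi), int(n)
        self.period = bias.period
        self.sigma = bias.sigma
        self.x = np.linspace(lo, hi, n)
        self.w = np.zeros(n)
        self.dw = np.zeros(n)
        for c, h in bias.deposited:
            self.add(float(c[0]), h)

    def add(self, center: float, height: float):
        d = _wrap(self.x - center, self.period)
        e = height * np.exp(-(d**2) / (2 * self.sigma**2))
        self.w += e
        self.dw += -e * d / self.sigma**2

    def eval(self, s: np.ndarray) -> tuple:
        if self.period is not None:
            s = self.lo + np.mod(s - self.lo, self.period)
        t = (s - self.lo) / (self.hi - self.lo) * (self.n - 1)
        i = np.clip(t.astype(int), 0, self.n - 2)
        frac = t - i
        w = self.w[i] * (1 - frac) + self.w[i + 1] * frac
        dw = self.dw[i] * (1 - frac) + self.dw[i + 1] * frac
        return w, dw


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def simulate(
    system: SystemSpec,
    bias: BiasSpec,
    n_steps: int,
    dt: float,
    seed: int,
    stride: int = 10,
    n_chains: int = 1,
    burn_in: int | None = None,
    init: str | np.ndarray = "auto",
    recenter: bool = False,
    escape_margin: float = 0.25,
) -> TrajectoryDataset:
    """Run Metropolis-adjusted overdamped Langevin dynamics (MALA).

    Parameters
    ----------
    n_steps
        Steps per chain.  Efficient proposals need ``dt * max curvature <
        0.1`` (documented heuristic); the Metropolis step keeps the sampled
        distribution exact regardless, and a diverging trajectory aborts
        with a diagnostic.
    stride, burn_in
        Frames are recorded every ``stride`` steps once ``burn_in`` steps
        (default: 10% of ``n_steps``) have passed.
    n_chains
        Independent chains propagated in parallel; recorded frames are
        interleaved time-major (see :meth:`TrajectoryDataset.chain_view`).
    init
        ``"equilibrium"`` (grid Boltzmann draw, dim <= 2), ``"point"``
        (the system's reference configuration plus a small jitter), an
        explicit ``(n_chains, dim)`` array, or ``"auto"``.
    recenter
        Remove the mean coordinate drift each step (translation-invariant
        systems only; internal coordinates are unaffected).
    """
    if n_steps < stride:
        raise ValueError("n_steps must be at least stride")
    if burn_in is None:
        burn_in = n_steps // 10
    beta = system.beta
    box_lo = system.domain_box[:, 0]
    box_hi = system.domain_box[:, 1]
    span = box_hi - box_lo
    margin = escape_margin * span

    rng_dyn = stream_rng(seed, 0)
    rng_init = stream_rng(seed, 1)

    # --- initial positions ---
    if isinstance(init, np.ndarray):
        pos = np.array(init, dtype=float)
        if pos.shape != (n_chains, system.dim):
            raise ValueError("explicit init must have shape (n_chains, dim)")
    else:
        mode = init
        if mode == "auto":
            mode = "equilibrium" if system.dim <= 2 else "point"
        if mode == "equilibrium":
            pos = boltzmann_grid_sample(system, bias, n_chains, rng_init)
        elif mode == "point":
            if system.init_position is None:
                raise ValueError(f"system {system.name!r} has no reference configuration")
            pos = system.init_position[None, :] + 1e-3 * rng_init.standard_normal(
                (n_chains, system.dim)
            )
        else:
            raise ValueError(f"unknown init mode {init!r}")

    # --- bias evaluation strategy ---
    wtm = bias.kind == "wt_metadynamics"
    grid = None
    deposited = list(bias.deposited)
    if wtm:
        if bias.cv.n_cv != 1:
            raise ValueError("metadynamics supported for one-dimensional CVs")
        if bias.period is not None:
            glo, ghi = -np.pi, np.pi
        else:
            corners = _box_corners(system.domain_box)
            proj = bias.cv.value(corners)[:, 0] if isinstance(bias.cv, LinearCV) else None
            if proj is None:
                raise ValueError("aperiodic metadynamics needs a linear CV")
            glo, ghi = proj.min(), proj.max()
        grid = _MetadGrid(bias, glo, ghi)

    def bias_terms(p):
        if bias.kind == "none":
            return np.zeros(p.shape[0]), np.zeros_like(p)
        if wtm:
            s = bias.cv.value(p)
            w, dw = grid.eval(s[:, 0])
            jac = bias.cv.jacobian(p)
            return w, -jac[:, 0, :] * dw[:, None]
        return bias_ambient_force(bias, p)

    rec_pos, rec_fb, rec_fu, rec_fbias, rec_w = [], [], [], [], []
    sqrt_noise = np.sqrt(2.0 * dt / beta)
    inv4dt = beta / (4.0 * dt)
    n_accept = 0

    if np.any(pos < box_lo - margin) or np.any(pos > box_hi + margin):
        raise RuntimeError("initial configuration lies outside domain_box + margin")

    u_cur, fu_cur = potential_and_force(system, pos)
    w_cur, fb_cur = bias_terms(pos)
    if not np.all(np.isfinite(u_cur)):
        raise RuntimeError("non-finite energy at the initial configuration")

    for t in range(n_steps):
        if wtm and t > 0 and t % bias.tau == 0:
            s_now = bias.cv.value(pos)[:, 0]
            for c in range(len(s_now)):
                w_here, _ = grid.eval(np.array([s_now[c]]))
                eff = bias.h * float(np.exp(-w_here[0] * beta / (bias.gamma - 1.0)))
                deposited.append((np.array([s_now[c]]), eff))
                grid.add(s_now[c], eff)
            w_cur, fb_cur = bias_terms(pos)  # bias changed under our feet

        if t >= burn_in and (t - burn_in) % stride == 0:
            rec_pos.append(pos.copy())
            rec_fu.append(fu_cur.copy())
            rec_fbias.append(fb_cur.copy())
            rec_fb.append(fu_cur + fb_cur)
            rec_w.append(w_cur.copy())

        f_cur = fu_cur + fb_cur
        noise = rng_dyn.standard_normal(pos.shape)
        unif = rng_dyn.random(pos.shape[0])
        prop = pos + f_cur * dt + sqrt_noise * noise

        in_box = np.all((prop >= box_lo) & (prop <= box_hi), axis=1)
        u_p, fu_p = potential_and_force(system, prop)
        w_p, fb_p = bias_terms(prop)
        f_p = fu_p + fb_p
        ok = in_box & np.isfinite(u_p) & np.all(np.isfinite(f_p), axis=1)

        # Metropolis-Hastings ratio with the Langevin proposal kernel
        fwd = ((prop - pos - f_cur * dt) ** 2).sum(axis=1)
        rev = ((pos - prop - f_p * dt) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", over="ignore"):
            log_alpha = -beta * ((u_p + w_p) - (u_cur + w_cur)) - inv4dt * (rev - fwd)
        accept = ok & (np.log(unif) < np.nan_to_num(log_alpha, nan=-np.inf))
        n_accept += int(accept.sum())

        pos = np.where(accept[:, None], prop, pos)
        u_cur = np.where(accept, u_p, u_cur)
        w_cur = np.where(accept, w_p, w_cur)
        fu_cur = np.where(accept[:, None], fu_p, fu_cur)
        fb_cur = np.where(accept[:, None], fb_p, fb_cur)
        if recenter:
            shift = pos.reshape(pos.shape[0], -1, 3).mean(axis=1)
            pos = (pos.reshape(pos.shape[0], -1, 3) - shift[:, None, :]).reshape(pos.shape)

    if not rec_pos:
        raise ValueError("no frames recorded; increase n_steps or reduce burn_in/stride")

    # time-major interleave: frame k is chain k % n_chains at record k // n_chains
    positions = np.concatenate(rec_pos, axis=0)
    final_bias = replace(bias, deposited=tuple(deposited)) if wtm else bias
    ds = TrajectoryDataset(
        positions=positions,
        biased_forces=np.concatenate(rec_fb, axis=0),
        unbiased_forces=np.concatenate(rec_fu, axis=0),
        bias_forces=np.concatenate(rec_fbias, axis=0),
        bias_energy=np.concatenate(rec_w, axis=0),
        bias=final_bias,
        metadata={
            "system": system.to_dict(),
            "system_hash": system.content_hash(),
            "bias": final_bias.to_dict(),
            "beta": float(beta),
            "dt": float(dt),
            "n_steps": int(n_steps),
            "stride": int(stride),
            "burn_in": int(burn_in),
            "n_chains": int(n_chains),
            "seed": int(seed),
            "recenter": bool(recenter),
            "n_frames": int(positions.shape[0]),
            "acceptance_rate": n_accept / float(n_steps * n_chains),
        },
    )
    if bias.kind == "none":
        ds.biased_forces = ds.unbiased_forces.copy()
        ds.bias_forces = np.zeros_like(ds.unbiased_forces)
        ds.weights = np.ones(ds.n_frames)
    elif not wtm:
        ds = compute_importance_weights(ds)
    return ds.validate()


def _box_corners(box):
    dim = box.shape[0]
    corners = np.array(
        [[box[d, (i >> d) & 1] for d in range(dim)] for i in range(2**dim)]
    )
    return corners


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def recompute_unbiased_forces(dataset: TrajectoryDataset, system: SystemSpec) -> TrajectoryDataset:
    """Fill ``unbiased_forces = -grad u`` at every frame (idempotent).

    Refuses if the dataset was generated with a different potential (hash
    mismatch), which would silently produce inconsistent training targets.
    """
    recorded = dataset.metadata.get("system_hash")
    if recorded is not None and recorded != system.content_hash():
        raise ValueError(
            "system hash mismatch: dataset was generated with a different "
            "potential; refusing to recompute forces against it"
        )
    f_unb = evaluate_force(system, dataset.positions)
    dataset.unbiased_forces = f_unb
    if dataset.bias.kind == "none":
        if dataset.biased_forces is None:
            dataset.biased_forces = f_unb.copy()
        dataset.bias_forces = np.zeros_like(f_unb)
    elif dataset.bias_forces is None and dataset.biased_forces is not None:
        dataset.bias_forces = dataset.biased_forces - f_unb
    elif dataset.biased_forces is None and dataset.bias_forces is not None:
        dataset.biased_forces = f_unb + dataset.bias_forces
    elif dataset.biased_forces is None and dataset.bias.kind != "wt_metadynamics":
        w, f_b = bias_ambient_force(dataset.bias, dataset.positions)
        dataset.bias_energy = w
        dataset.bias_forces = f_b
        dataset.biased_forces = f_unb + f_b
    return dataset.validate()


def compute_importance_weights(dataset: TrajectoryDataset) -> TrajectoryDataset:
    """Fill importance weights omega = exp(beta W) per frame.

    For static biases W is the recorded bias energy.  For well-tempered
    metadynamics the weights are a diagnostic computed from the FINAL bias
    state evaluated at each frame's CV (last-bias approximation); training
    on metadynamics data uses recomputed forces without reweighting.
    If exp would overflow, the log-weights are shifted by their maximum
    (self-normalized estimators are invariant to this normalization).
    """
    beta = dataset.metadata.get("beta")
    if beta is None:
        raise ValueError("dataset metadata lacks beta")
    if dataset.bias.kind == "none":
        dataset.weights = np.ones(dataset.n_frames)
        return dataset
    if dataset.bias.kind == "wt_metadynamics":
        s = dataset.bias.cv.value(dataset.positions)
        w, _ = bias_energy_and_force(dataset.bias, s)
    else:
        if dataset.bias_energy is None:
            w, _ = bias_ambient_force(dataset.bias, dataset.positions)
            dataset.bias_energy = w
        w = dataset.bias_energy
    logw = beta * np.asarray(w, float)
    if logw.max() > 700.0:
        warnings.warn(
            "importance weights overflow; returning weights normalized by the "
            "maximum log-weight (valid for self-normalized estimators)"
        )
        logw = logw - logw.max()
    dataset.weights = np.exp(logw)
    return dataset
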