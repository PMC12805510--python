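"""Accuracy and stability metrics for trained CG potentials.

Compares model predictions and sampled ensembles against the quadrature
oracle: root-mean-square error of the predicted mean force on an evaluation
grid, discrete histogram free energies F_b = -ln p_b (in kBT units), their
mean-squared error and Kullback-Leibler divergence, and stability counts of
CG Langevin simulations run with the learned potential (chains whose model
energy exceeds a threshold, or which leave the supported region, are counted
unstable and excluded from the pooled statistics -- the exclusion is
reported, never silent).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import canonical_json, fmt_float, stream_rng
from .forcematch import CGPotentialModel
from .toy_systems import OracleGrid

__all__ = [
    "EvaluationReport",
    "FreeEnergyTable",
    "mean_force_rmse",
    "histogram_free_energy",
    "fe_divergences",
    "run_cg_simulation",
]


@dataclass
class EvaluationReport:
    """Summary metrics of a trained model against the oracle."""

    rmse_mean_force: float
    fe_mse: float
    fe_kl: float
    n_unstable: int
    n_traj: int
    protocol_echo: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_unstable > self.n_traj:
            raise ValueError("n_unstable cannot exceed the number of trajectories")
        for name in ("rmse_mean_force", "fe_mse", "fe_kl"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_json(self) -> str:
        return canonical_json(
            {
                "rmse_mean_force": self.rmse_mean_force,
                "fe_mse": self.fe_mse,
                "fe_kl": self.fe_kl,
                "n_unstable": self.n_unstable,
                "n_traj": self.n_traj,
                "protocol_echo": self.protocol_echo,
            }
        )


@dataclass
class FreeEnergyTable:
    """Discrete free energies F_b = -ln p_b on a fixed binning (kBT units)."""

    bin_edges: np.ndarray
    free_energy: np.ndarray      # min-shifted; +inf marks empty bins
    counts: np.ndarray           # (effective) counts per bin

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])

    def probabilities(self, pseudo_count: float = 0.0) -> np.ndarray:
        c = self.counts + pseudo_count
        return c / c.sum()

    def to_table(self) -> str:
        lines = ["bin_center\tfree_energy\tcount"]
        for c, f, n in zip(self.centers, self.free_energy, self.counts):
            lines.append("\t".join([fmt_float(c), fmt_float(f), fmt_float(n)]))
        return "\n".join(lines) + "\n"


def mean_force_rmse(model: CGPotentialModel, oracle: OracleGrid, eval_grid) -> float:
    """RMS error of the model mean force against the oracle on a grid.

    ``eval_grid`` may be an array of CG values or ``(lo, hi, n)`` for ``n``
    equally spaced points; the oracle mean force is interpolated linearly
    onto it.  The grid must lie inside the oracle span.
    """
    if isinstance(eval_grid, tuple):
        lo, hi, n = eval_grid
        grid = np.linspace(lo, hi, int(n))
    else:
        grid = np.asarray(eval_grid, float).reshape(-1)
    if grid.min() < oracle.grid[0] or grid.max() > oracle.grid[-1]:
        raise ValueError("evaluation grid extends outside the oracle span")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warning handled by caller
        pred = model.force(grid[:, None])[:, 0]
    ref = oracle.interp_mean_force(grid)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def histogram_free_energy(samples, bin_edges, weights=None) -> FreeEnergyTable:
    """Discrete free energy -ln p_b from a (optionally weighted) histogram.

    The profile is shifted so its minimum is zero; empty bins get +inf.
    """
    x = np.asarray(samples, float).reshape(-1)
    edges = np.asarray(bin_edges, float)
    if len(x) == 0:
        raise ValueError("no samples")
    counts, _ = np.histogram(x, bins=edges, weights=weights)
    counts = counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("all samples fall outside the binning range")
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -np.log(p)
    f = f - f[np.isfinite(f)].min()
    return FreeEnergyTable(bin_edges=edges, free_energy=f, counts=counts)


def fe_divergences(
    fe_model: FreeEnergyTable,
    fe_ref: FreeEnergyTable,
    pseudo_count: float = 0.5,
) -> tuple:
    """(MSE, KL) between two discrete free-energy tables on identical bins.

    MSE is taken over bins occupied in both tables (after re-shifting each
    profile on the common support).  KL = sum p_ref ln(p_ref / p_model)
    uses probabilities re-derived from the histograms, with an add-half
    pseudo-count applied to the *model* histogram only so that bins the
    model never visits contribute a large but finite penalty.  The reference
    must have no empty bins over its support.
    """
    if fe_model.bin_edges.shape != fe_ref.bin_edges.shape or not np.allclose(
        fe_model.bin_edges, fe_ref.bin_edges
    ):
        raise ValueError("free-energy tables use different binnings")
    both = np.isfinite(fe_model.free_energy) & np.isfinite(fe_ref.free_energy)
    if not np.any(both):
        raise ValueError("no commonly occupied bins")
    fm = fe_model.free_energy[both] - fe_model.free_energy[both].min()
    fr = fe_ref.free_energy[both] - fe_ref.free_energy[both].min()
    mse = float(np.mean((fm - fr) ** 2))

    p_ref = fe_ref.probabilities()
    support = p_ref > 0
    p_model = fe_model.probabilities(pseudo_count=pseudo_count)
    kl = float(np.sum(p_ref[support] * np.log(p_ref[support] / p_model[support])))
    return mse, max(kl, 0.0)


def run_cg_simulation(
    model: CGPotentialModel,
    n_traj: int,
    n_steps: int,
    dt: float,
    seed: int,
    energy_abort_threshold: float,
    init_range: tuple,
    beta: float = 1.0,
    stride: int = 10,
    burn_in: int | None = None,
    escape_factor: float = 0.5,
    init_positions=None,
) -> tuple:
    """Langevin dynamics on the learned potential U(R; theta).

    ``n_traj`` chains start uniformly in ``init_range`` -- or at the given
    ``init_positions`` (e.g. random frames of the training ensemble) -- and
    run MALA steps (Euler-Maruyama proposal + Metropolis correction on U).
    A chain is
    flagged unstable -- and its frames excluded from the pooled samples --
    as soon as its model energy exceeds ``energy_abort_threshold`` (absolute,
    same units/offset as ``model.energy``) or it wanders further than
    ``escape_factor`` times the span outside ``init_range`` (no prior
    confines the model there, so escaped chains never return reliably).

    Returns ``(samples, n_unstable)`` with samples pooled over stable chains
    only -- a chain that turns unstable is removed with all of its frames.
    Raises if every chain is unstable.
    """
    if model.cg_dim != 1:
        raise ValueError("CG simulation currently supports 1D CG coordinates")
    lo, hi = float(init_range[0]), float(init_range[1])
    span = hi - lo
    esc_lo, esc_hi = lo - escape_factor * span, hi + escape_factor * span
    rng = stream_rng(seed, 21)
    if init_positions is not None:
        pos = np.asarray(init_positions, float).reshape(n_traj, 1).copy()
    else:
        pos = rng.uniform(lo, hi, size=(n_traj, 1))
    unstable = np.zeros(n_traj, dtype=bool)

    u_cur = model.energy(pos)
    f_cur = model.force(pos)
    unstable |= ~np.isfinite(u_cur) | (u_cur > energy_abort_threshold)

    if burn_in is None:
        burn_in = n_steps // 10
    sqrt_noise = np.sqrt(2.0 * dt / beta)
    inv4dt = beta / (4.0 * dt)
    frames = []
    for t in range(n_steps):
        if t >= burn_in and (t - burn_in) % stride == 0:
            frames.append(pos[:, 0].copy())
        noise = rng.standard_normal(pos.shape)
        unif = rng.random(n_traj)
        prop = pos + f_cur * dt + sqrt_noise * noise
        u_p = model.energy(prop)
        f_p = model.force(prop)
        ok = np.isfinite(u_p) & np.isfinite(f_p[:, 0])
        fwd = ((prop - pos - f_cur * dt) ** 2).sum(1)
        rev = ((pos - prop - f_p * dt) ** 2).sum(1)
        with np.errstate(invalid="ignore", over="ignore"):
            log_alpha = -beta * (u_p - u_cur) - inv4dt * (rev - fwd)
        accept = ok & (np.log(unif) < np.nan_to_num(log_alpha, nan=-np.inf)) & ~unstable
        pos = np.where(accept[:, None], prop, pos)
        u_cur = np.where(accept, u_p, u_cur)
        f_cur = np.where(accept[:, None], f_p, f_cur)
        newly = (~unstable) & (
            (u_cur > energy_abort_threshold)
            | (pos[:, 0] < esc_lo)
            | (pos[:, 0] > esc_hi)
        )
        unstable |= newly

    n_unstable = int(unstable.sum())
    if n_unstable == n_traj:
        raise RuntimeError(
            f"all {n_traj} CG chains unstable (threshold {energy_abort_threshold:g}); "
            "the model potential does not confine the dynamics"
        )
    stacked = np.stack(frames, axis=0) if frames else np.empty((0, n_traj))
    pooled = stacked[:, ~unstable].reshape(-1)
    return pooled[np.isfinite(pooled)], n_unstable
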