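"""Nonparametric estimators for mean forces, reweighting and force noise.

The central object is the binned mean-force profile: frames are grouped by
their CG coordinate and the projected forces are averaged per bin, either
plainly (``direct`` forces from a biased run, or ``recomputed`` unbiased
forces) or with self-normalized importance weights (``reweighted``).  When
the bias acts along the CG coordinate itself, the recomputed-force profile
is an unbiased estimate of the mean force without any reweighting; when the
bias touches orthogonal degrees of freedom it is not, and the reweighted
estimator must be used instead.  The binned conditional variance of the
projected force estimates the irreducible noise floor of force matching.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import fmt_float
from .toy_systems import dihedral_rotation_generator

__all__ = [
    "BinnedMeanForce",
    "NoiseEstimate",
    "binned_mean_force",
    "reweighted_expectation",
    "generalized_torque",
    "estimate_noise",
]


@dataclass
class BinnedMeanForce:
    """Per-bin mean projected force with standard errors and counts."""

    bin_edges: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    count: np.ndarray
    mode: str = "direct"
    ess: np.ndarray | None = None  # Kish effective sample size (reweighted mode)
    x_mean: np.ndarray | None = None  # per-bin (weighted) mean CG position
    n_blocks: np.ndarray | None = None  # independent chains contributing per bin
    low_confidence_min_count: int = 10

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])

    @property
    def positions(self) -> np.ndarray:
        """Representative CG position per bin: the sample mean where
        available (avoids the within-bin curvature bias of comparing a
        nonuniformly filled bin against its geometric center), else the
        center."""
        if self.x_mean is None:
            return self.centers
        return np.where(np.isfinite(self.x_mean), self.x_mean, self.centers)

    @property
    def low_confidence(self) -> np.ndarray:
        return self.count < self.low_confidence_min_count

    def to_table(self) -> str:
        lines = ["bin_center\tmean\tse\tcount\tmode"]
        for c, m, s, n in zip(self.centers, self.mean, self.se, self.count):
            lines.append(
                "\t".join([fmt_float(c), fmt_float(m), fmt_float(s), str(int(n)), self.mode])
            )
        return "\n".join(lines) + "\n"


@dataclass
class NoiseEstimate:
    """Binned conditional variance of projected forces (noise floor)."""

    bin_edges: np.ndarray
    per_bin_variance: np.ndarray
    count: np.ndarray
    pooled: float
    excluded_bins: int = 0


def binned_mean_force(
    cg_positions,
    projected_forces,
    bin_edges,
    weights=None,
    mode: str | None = None,
    block_ids=None,
) -> BinnedMeanForce:
    """Bin-averaged mean force along a 1D CG coordinate.

    Without weights each occupied bin carries the plain average of the
    projected force; with weights, the self-normalized weighted mean (the
    Kish effective sample size ESS = (sum w)^2 / sum w^2 is recorded per
    bin).

    Standard errors: if ``block_ids`` labels statistically independent
    blocks (e.g. the chain index of a multi-chain run), the SE is the
    cluster-robust estimate across blocks -- within-block autocorrelation,
    such as slow orthogonal degrees of freedom, then cannot bias it.
    Otherwise frames are treated as independent (s / sqrt(n), or the
    weighted deviation over sqrt(ESS)).

    Bins with fewer than 2 frames (or blocks) have their SE flagged NaN.
    """
    x = np.asarray(cg_positions, float).reshape(-1)
    g = np.asarray(projected_forces, float).reshape(-1)
    if x.shape != g.shape:
        raise ValueError("cg_positions and projected_forces must align")
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    if weights is not None:
        w = np.asarray(weights, float).reshape(-1)
        if w.shape != x.shape:
            raise ValueError("weights must align with frames")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
    blocks = None
    if block_ids is not None:
        blocks = np.asarray(block_ids).reshape(-1)
        if blocks.shape != x.shape:
            raise ValueError("block_ids must align with frames")
    nb = len(edges) - 1
    idx = np.digitize(x, edges) - 1
    inside = (idx >= 0) & (idx < nb) & ~((x == edges[-1]))
    idx_last = x == edges[-1]  # right-closed last bin
    idx = np.where(idx_last, nb - 1, idx)
    inside = inside | idx_last
    if not np.any(inside):
        raise ValueError("no frames fall inside the binning range")

    mean = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    x_mean = np.full(nb, np.nan)
    ess = np.full(nb, np.nan) if weights is not None else None
    n_blocks = np.zeros(nb, dtype=int) if blocks is not None else None

    for b in range(nb):
        sel = inside & (idx == b)
        n = int(sel.sum())
        count[b] = n
        if n == 0:
            continue
        gb = g[sel]
        xb = x[sel]
        wb = w[sel] if weights is not None else np.ones(n)
        wn = wb / wb.sum()
        mu = float(wn @ gb)
        mean[b] = mu
        x_mean[b] = float(wn @ xb)
        if weights is not None:
            ess[b] = float(wb.sum() ** 2 / (wb**2).sum())  # Kish ESS
        if blocks is not None:
            n_blocks[b] = len(np.unique(blocks[sel]))
            se[b] = _cluster_se(gb, wb, blocks[sel], mu)
        elif n >= 2:
            if weights is None:
                se[b] = gb.std(ddof=1) / np.sqrt(n)
            elif ess[b] > 1.0:
                var_w = float(wn @ (gb - mu) ** 2) * ess[b] / (ess[b] - 1.0)
                se[b] = np.sqrt(var_w / ess[b])

    resolved_mode = mode or ("reweighted" if weights is not None else "direct")
    return BinnedMeanForce(
        bin_edges=edges, mean=mean, se=se, count=count, mode=resolved_mode,
        ess=ess, x_mean=x_mean, n_blocks=n_blocks,
    )


def _cluster_se(gb, wb, blk, mu) -> float:
    """Cluster-robust SE of a self-normalized weighted mean.

    Linearization estimator: with per-block weight masses W_c and block
    residual sums S_c = sum_{i in c} w_i (g_i - mu),
    Var(mu_hat) ~= sum_c (S_c / W_tot)^2 * B/(B-1).
    """
    uniq, inv = np.unique(blk, return_inverse=True)
    B = len(uniq)
    if B < 2:
        return np.nan
    wtot = wb.sum()
    s_c = np.bincount(inv, weights=wb * (gb - mu), minlength=B)
    var = float(((s_c / wtot) ** 2).sum()) * B / (B - 1.0)
    return np.sqrt(var)


def reweighted_expectation(values, weights) -> tuple:
    """Self-normalized importance-sampling estimate and its Kish ESS.

    Returns ``(sum_i wbar_i phi_i, ESS)`` with ``wbar_i = w_i / sum_j w_j``
    and ``ESS = (sum w)^2 / sum w^2``.  Degenerate weights (ESS < 2) emit a
    warning; the estimate is still returned.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float).reshape(-1)
    if v.shape[0] == 0:
        raise ValueError("need at least one frame")
    if v.shape[0] != w.shape[0]:
        raise ValueError("values and weights must align")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    wn = w / w.sum()
    est = np.tensordot(wn, v, axes=(0, 0))
    ess = float(w.sum() ** 2 / (w**2).sum())
    if ess < 2.0:
        warnings.warn(
            f"importance weights are degenerate (ESS = {ess:.2f}); the "
            "reweighted estimate is dominated by very few frames"
        )
    return est, ess


def generalized_torque(positions, forces, cv, collinear_tol: float = 1e-8) -> tuple:
    """Per-frame generalized torque Q = sum_i f_i . dr_i/d(theta).

    ``cv`` is a dihedral collective variable (four particle indices).  The
    displacement field dr/d(theta) rigidly rotates the distal atom about the
    central bond, so bond and bond-angle forces are exactly orthogonal to it
    and Q reduces to the force conjugate to the dihedral.  Frames with a
    collinear atom triple (undefined dihedral) are flagged invalid and get
    ``Q = NaN``.

    Returns ``(q, valid)`` arrays of shape (n_frames,).
    """
    pos = np.asarray(positions, float)
    frc = np.asarray(forces, float)
    if pos.shape != frc.shape:
        raise ValueError("positions and forces must have identical shapes")
    idx = getattr(cv, "indices", None)
    if idx is None:
        raise ValueError("generalized_torque requires a dihedral CV")
    p = pos.reshape(pos.shape[0], -1, 3)
    f = frc.reshape(frc.shape[0], -1, 3)
    if p.shape[1] < 4:
        raise ValueError("a dihedral needs at least 4 particles")
    p4 = p[:, list(idx), :]
    f4 = f[:, list(idx), :]
    b1 = p4[:, 1] - p4[:, 0]
    b2 = p4[:, 2] - p4[:, 1]
    b3 = p4[:, 3] - p4[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = (np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)) ** 2
    valid = ((n1**2).sum(1) > collinear_tol * scale) & (
        (n2**2).sum(1) > collinear_tol * (np.linalg.norm(b2, axis=1) * np.linalg.norm(b3, axis=1)) ** 2
    )
    gen = dihedral_rotation_generator(p4)
    q = (f4 * gen).sum(axis=(1, 2))
    q = np.where(valid, q, np.nan)
    return q, valid


def estimate_noise(cg_positions, projected_forces, bin_edges, min_count: int = 2) -> NoiseEstimate:
    """Binned conditional variance of the projected force (noise floor).

    The pooled value is the count-weighted average of the per-bin variances
    over bins with at least ``min_count`` frames; it estimates the
    irreducible term of the force-matching loss, which depends only on the
    CG mapping.
    """
    x = np.asarray(cg_positions, float).reshape(-1)
    g = np.asarray(projected_forces, float).reshape(-1)
    edges = np.asarray(bin_edges, float)
    nb = len(edges) - 1
    idx = np.digitize(x, edges) - 1
    idx = np.where(x == edges[-1], nb - 1, idx)
    inside = (idx >= 0) & (idx < nb)
    var = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = inside & (idx == b)
        n = int(sel.sum())
        count[b] = n
        if n >= min_count:
            var[b] = g[sel].var(ddof=1)
    used = count >= min_count
    excluded = int((count > 0).sum() - used.sum())
    if not np.any(used):
        raise ValueError("no bin has enough frames for a variance estimate")
    pooled = float(np.sum(var[used] * count[used]) / np.sum(count[used]))
    return NoiseEstimate(
        bin_edges=edges, per_bin_variance=var, count=count, pooled=pooled,
        excluded_bins=excluded,
    )
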