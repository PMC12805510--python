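"""CG potential model (RBF features + dense layers) and force-matching.

The model maps a CG configuration R (usually one-dimensional here) to a
scalar energy

    U(R; theta) = s * MLP(phi(R)),   phi_j(R) = exp(-||R - c_j||^2 / 2 sigma^2)

with Gaussian radial-basis features phi, tanh hidden layers and a fixed
output scale s (set from the force scale of the training data).  The
predicted force is the exact negative gradient -dU/dR, so forces are
conservative by construction; both the input-gradient and the parameter
gradients of the force-matching loss

    chi^2(theta) = 1/(D M) sum_i || G_i + dU/dR(R_i; theta) ||^2

are evaluated analytically (forward tangent propagation for dU/dR and a
hand-derived adjoint pass through it for d chi^2 / d theta).  G_i are the
projected, *unbiased* atomistic forces.  Training uses mini-batch Adam with
a validation split, plateau learning-rate decay and early stopping.

No prior potential is added: the network learns the PMF purely from data,
and queries outside the RBF-center span only emit a warning.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import stream_rng

__all__ = [
    "CGPotentialModel",
    "OptimizerConfig",
    "TrainingResult",
    "project_dataset",
    "fm_loss",
    "fm_loss_from_forces",
    "train",
    "predict_mean_force",
]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class CGPotentialModel:
    """Scalar CG potential with RBF features and tanh dense layers."""

    rbf_centers: np.ndarray          # (K, D)
    rbf_width: float                 # shared Gaussian width sigma
    layer_sizes: tuple               # hidden widths, e.g. (64, 64)
    params: dict                     # W1, b1, ..., w_out, b_out
    activation: str = "tanh"
    output_scale: float = 1.0

    def __post_init__(self):
        self.rbf_centers = np.atleast_2d(np.asarray(self.rbf_centers, float))
        if self.rbf_centers.ndim != 2:
            raise ValueError("rbf_centers must have shape (K, D)")
        if self.activation != "tanh":
            raise ValueError("only the tanh activation is implemented")
        if self.rbf_width <= 0:
            raise ValueError("rbf_width must be positive")

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(
        cls,
        rbf_centers,
        rbf_width: float,
        layer_sizes: tuple = (64, 64),
        seed: int = 0,
        output_scale: float = 1.0,
    ) -> "CGPotentialModel":
        centers = np.atleast_2d(np.asarray(rbf_centers, float))
        if centers.shape[0] < centers.shape[1]:
            centers = centers.T
        rng = stream_rng(seed, 7)
        sizes = [centers.shape[0], *layer_sizes]
        params = {}
        for l in range(1, len(sizes)):
            params[f"W{l}"] = rng.standard_normal((sizes[l], sizes[l - 1])) / np.sqrt(sizes[l - 1])
            params[f"b{l}"] = np.zeros(sizes[l])
        # small last layer: initial predicted forces start near zero, so the
        # first loss is the raw force variance rather than a large multiple
        params["w_out"] = 0.1 * rng.standard_normal(sizes[-1]) / np.sqrt(sizes[-1])
        params["b_out"] = np.zeros(1)
        return cls(
            rbf_centers=centers,
            rbf_width=float(rbf_width),
            layer_sizes=tuple(layer_sizes),
            params=params,
            output_scale=float(output_scale),
        )

    @classmethod
    def for_data(
        cls,
        cg_positions,
        projected_forces,
        n_rbf: int = 64,
        layer_sizes: tuple = (64, 64),
        seed: int = 0,
    ) -> "CGPotentialModel":
        """Default architecture for a 1D CG coordinate.

        RBF centers span the sampled range uniformly, the width equals the
        center spacing, and the output scale is the standard deviation of
        the projected forces (so the network trains on order-one targets).
        """
        x = np.asarray(cg_positions, float).reshape(-1)
        g = np.asarray(projected_forces, float).reshape(-1)
        lo, hi = x.min(), x.max()
        centers = np.linspace(lo, hi, n_rbf)[:, None]
        width = (hi - lo) / max(n_rbf - 1, 1)
        scale = max(float(g.std()), 1e-12)
        return cls.initialize(centers, width, layer_sizes, seed=seed, output_scale=scale)

    @property
    def cg_dim(self) -> int:
        return self.rbf_centers.shape[1]

    # -- forward / gradients -------------------------------------------------

    def _features(self, R):
        d = R[:, None, :] - self.rbf_centers[None, :, :]   # (M, K, D)
        phi = np.exp(-(d**2).sum(-1) / (2.0 * self.rbf_width**2))
        t0 = phi[:, :, None] * (-d / self.rbf_width**2)     # d phi / d R
        return phi, t0

    def _forward(self, R):
        """Forward pass with input-tangent propagation.

        Returns (energy_net, dE_net/dR, cache); the physical energy and
        gradient carry the extra factor ``output_scale``.  For a 1D CG
        coordinate the tangent tensors collapse to matrices and everything
        runs as BLAS matrix products.
        """
        phi, t = self._features(R)
        flat = R.shape[1] == 1
        if flat:
            t = t[:, :, 0]
        xs, ts, As = [phi], [t], [None]
        x = phi
        for l in range(1, len(self.layer_sizes) + 1):
            W, b = self.params[f"W{l}"], self.params[f"b{l}"]
            s = x @ W.T + b
            x = np.tanh(s)
            if flat:
                A = ts[-1] @ W.T
                t = (1.0 - x**2) * A
            else:
                A = np.einsum("hk,mkd->mhd", W, ts[-1], optimize=True)
                t = (1.0 - x**2)[:, :, None] * A
            xs.append(x)
            ts.append(t)
            As.append(A)
        w_out = self.params["w_out"]
        e = x @ w_out + self.params["b_out"][0]
        z = (t @ w_out)[:, None] if flat else np.einsum("h,mhd->md", w_out, t)
        return e, z, (xs, ts, As, flat)

    def _check_input(self, R):
        R = np.asarray(R, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[1] != self.cg_dim:
            raise ValueError(f"expected CG dimension {self.cg_dim}, got {R.shape[1]}")
        return R

    def energy(self, R) -> np.ndarray:
        """Scalar energy per CG configuration (up to an additive constant)."""
        R = self._check_input(R)
        e, _, _ = self._forward(R)
        return self.output_scale * e

    def force(self, R) -> np.ndarray:
        """Conservative force -dU/dR, exact gradient of :meth:`energy`."""
        R = self._check_input(R)
        _, z, _ = self._forward(R)
        return -self.output_scale * z

    # -- loss and adjoint ----------------------------------------------------

    def _loss_and_grads(self, R, G):
        """FM loss and its analytic parameter gradients on a batch."""
        M, D = R.shape
        _, z, (xs, ts, As, flat) = self._forward(R)
        resid = G + self.output_scale * z          # G + dU/dR
        loss = float((resid**2).sum() / (D * M))
        r = (2.0 * self.output_scale / (D * M)) * resid    # dL/dz

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        w_out = self.params["w_out"]
        if flat:
            r1 = r[:, 0]
            grads["w_out"] = ts[-1].T @ r1
            t_hat = np.outer(r1, w_out)
            x_hat = np.zeros_like(xs[-1])
            for l in range(len(self.layer_sizes), 0, -1):
                x, A = xs[l], As[l]
                a1 = 1.0 - x**2
                a2 = -2.0 * x * a1
                s_hat = (t_hat * A) * a2 + x_hat * a1
                A_hat = t_hat * a1
                grads[f"W{l}"] = s_hat.T @ xs[l - 1] + A_hat.T @ ts[l - 1]
                grads[f"b{l}"] = s_hat.sum(0)
                W = self.params[f"W{l}"]
                x_hat = s_hat @ W
                t_hat = A_hat @ W
            return loss, grads
        grads["w_out"] = np.einsum("mhd,md->h", ts[-1], r, optimize=True)
        t_hat = w_out[None, :, None] * r[:, None, :]
        x_hat = np.zeros_like(xs[-1])
        for l in range(len(self.layer_sizes), 0, -1):
            x, A = xs[l], As[l]
            a1 = 1.0 - x**2
            a2 = -2.0 * x * a1
            s_hat = np.einsum("mhd,mhd->mh", t_hat, A, optimize=True) * a2 + x_hat * a1
            A_hat = t_hat * a1[:, :, None]
            grads[f"W{l}"] = (
                s_hat.T @ xs[l - 1]
                + np.einsum("mhd,mkd->hk", A_hat, ts[l - 1], optimize=True)
            )
            grads[f"b{l}"] = s_hat.sum(0)
            W = self.params[f"W{l}"]
            x_hat = s_hat @ W
            t_hat = np.einsum("hk,mhd->mkd", W, A_hat, optimize=True)
        return loss, grads

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "architecture": {
                "n_rbf": int(self.rbf_centers.shape[0]),
                "cg_dim": int(self.cg_dim),
                "layer_sizes": list(self.layer_sizes),
                "activation": self.activation,
            },
            "rbf_width": float(self.rbf_width),
            "output_scale": float(self.output_scale),
            "rbf_centers": _encode(self.rbf_centers),
            "params": {
                k: {"shape": list(v.shape), "data": _encode(v)}
                for k, v in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CGPotentialModel":
        arch = d["architecture"]
        centers = _decode(d["rbf_centers"]).reshape(arch["n_rbf"], arch["cg_dim"])
        params = {
            k: _decode(v["data"]).reshape(v["shape"]) for k, v in d["params"].items()
        }
        return cls(
            rbf_centers=centers,
            rbf_width=float(d["rbf_width"]),
            layer_sizes=tuple(arch["layer_sizes"]),
            params=params,
            activation=arch["activation"],
            output_scale=float(d["output_scale"]),
        )

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


def _encode(arr: np.ndarray) -> str:
    return np.ascontiguousarray(arr, dtype="<f8").tobytes().hex()


def _decode(hexstr: str) -> np.ndarray:
    return np.frombuffer(bytes.fromhex(hexstr), dtype="<f8").copy()


# ---------------------------------------------------------------------------
# Dataset projection and loss
# ---------------------------------------------------------------------------

def project_dataset(dataset, mapping) -> tuple:
    """CG positions and projected unbiased forces: R_i = M r_i, G_i = M f_i.

    Requires recomputed unbiased forces on biased datasets (refuses
    otherwise) and an orthonormal mapping (validated by ``CGMapping``).
    """
    if dataset.unbiased_forces is None:
        raise ValueError(
            "dataset lacks unbiased forces; run recompute_unbiased_forces "
            "before projecting a biased dataset"
        )
    R = mapping.apply(dataset.positions)
    G = mapping.apply(dataset.unbiased_forces)
    return R, G


def fm_loss(model: CGPotentialModel, cg_positions, projected_forces) -> float:
    """Empirical force-matching loss 1/(D M) sum ||G_i + dU/dR(R_i)||^2."""
    R = model._check_input(cg_positions)
    G = np.asarray(projected_forces, float)
    if G.ndim == 1:
        G = G[:, None]
    if R.shape != G.shape:
        raise ValueError("positions and forces must align")
    if R.shape[0] == 0:
        raise ValueError("empty dataset")
    _, z, _ = model._forward(R)
    resid = G + model.output_scale * z
    return float((resid**2).sum() / resid.size)


def fm_loss_from_forces(predicted_forces, projected_forces) -> float:
    """FM loss for externally supplied force predictions.

    Evaluates 1/(D M) sum ||G_i - F_pred,i||^2, e.g. with the oracle mean
    force plugged in as the "perfect model" to estimate the irreducible
    noise term of the loss decomposition.
    """
    F = np.asarray(predicted_forces, float)
    G = np.asarray(projected_forces, float)
    if F.shape != G.shape:
        raise ValueError("force arrays must align")
    if F.size == 0:
        raise ValueError("empty dataset")
    return float(((G - F) ** 2).sum() / G.size)


def predict_mean_force(model: CGPotentialModel, grid) -> np.ndarray:
    """Model mean force -dU/dR on a grid of CG values.

    Warns when the grid leaves the RBF-center span: with no prior potential
    the network extrapolates freely there.
    """
    arr = np.asarray(grid, float)
    squeeze = arr.ndim == 1 and model.cg_dim == 1
    R = model._check_input(arr)
    lo = model.rbf_centers.min(axis=0)
    hi = model.rbf_centers.max(axis=0)
    if np.any(R < lo) or np.any(R > hi):
        warnings.warn(
            "grid extends outside the RBF-center span; predictions there are "
            "unconstrained extrapolation"
        )
    f = model.force(R)
    return f[:, 0] if squeeze else f


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """Adam + early-stopping settings for force-matching training."""

    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 400
    patience: int = 40             # early stop after this many stale epochs
    min_delta: float = 1e-5        # relative improvement threshold
    val_fraction: float = 0.1
    lr_decay: float = 0.5          # plateau decay factor
    lr_patience: int = 15
    min_lr: float = 1e-5
    # deterministic step decay: fractions of the epoch budget at which the
    # learning rate is multiplied by lr_step_factor.  When set, plateau
    # decay is disabled -- appropriate when the validation loss is dominated
    # by irreducible force noise and plateau detection triggers on noise.
    lr_milestones: tuple = ()
    lr_step_factor: float = 0.3
    # tail averaging: average the parameters over the final fraction of
    # epochs (0 disables).  Standard variance-reduction for SGD on noisy
    # regression targets; only meaningful together with lr_milestones.
    average_tail: float = 0.0

    def to_dict(self):
        d = dict(self.__dict__)
        d["lr_milestones"] = list(d["lr_milestones"])
        return d


@dataclass
class TrainingResult:
    """Outcome of a force-matching fit."""

    final_params: dict
    loss_history: np.ndarray       # full-training-set FM loss, epoch 0 = init
    val_history: np.ndarray
    config_echo: dict
    dataset_fingerprint: str
    best_epoch: int
    final_loss: float


def _fingerprint(R, G) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(R).tobytes())
    h.update(np.ascontiguousarray(G).tobytes())
    return h.hexdigest()


def train(
    model: CGPotentialModel,
    cg_positions,
    projected_forces,
    config: OptimizerConfig | dict | None = None,
    seed: int = 0,
) -> TrainingResult:
    """Minimize the FM loss with mini-batch Adam; the model is updated in place.

    A seeded 90/10 train/validation split drives plateau learning-rate decay
    and early stopping; the parameters with the best validation loss
    (including the initial ones) are restored at the end, so the final loss
    never exceeds the initial loss.  A non-finite loss aborts training and
    restores the last finite best checkpoint.
    """
    if config is None:
        config = OptimizerConfig()
    elif isinstance(config, dict):
        config = OptimizerConfig(**{**config, "lr_milestones": tuple(config.get("lr_milestones", ()))})
    R = model._check_input(cg_positions)
    G = np.asarray(projected_forces, float)
    if G.ndim == 1:
        G = G[:, None]
    if R.shape[0] == 0:
        raise ValueError("empty dataset")
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(G))):
        raise ValueError("training data contain non-finite values")
    M = R.shape[0]

    rng = stream_rng(seed, 11)
    perm = rng.permutation(M)
    n_val = int(round(config.val_fraction * M)) if M >= 20 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Rtr, Gtr = R[tr_idx], G[tr_idx]
    Rval, Gval = R[val_idx], G[val_idx]

    def full_loss():
        return fm_loss(model, R, G)

    def val_loss():
        if n_val == 0:
            return fm_loss(model, Rtr, Gtr)
        return fm_loss(model, Rval, Gval)

    initial_full = full_loss()
    initial_params = model.copy_params()
    loss_hist = [initial_full]
    val_hist = [val_loss()]
    best_val = val_hist[0]
    best_params = model.copy_params()
    best_epoch = 0

    # Adam state
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    lr = config.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    stale = 0
    lr_stale = 0
    aborted = False

    milestones = {
        max(1, int(round(f * config.epochs))) for f in config.lr_milestones
    }
    tail_start = (
        config.epochs - int(round(config.average_tail * config.epochs)) + 1
        if config.average_tail > 0
        else None
    )
    tail_sum, tail_n = None, 0
    n_tr = len(tr_idx)
    bs = min(config.batch_size, max(n_tr, 1))
    for epoch in range(1, config.epochs + 1):
        if epoch in milestones:
            lr = max(lr * config.lr_step_factor, config.min_lr)
        order = rng.permutation(n_tr)
        batch_losses = []
        for i0 in range(0, n_tr, bs):
            sel = order[i0:i0 + bs]
            loss_b, grads = model._loss_and_grads(Rtr[sel], Gtr[sel])
            if not np.isfinite(loss_b):
                aborted = True
                break
            batch_losses.append(loss_b)
            step += 1
            for k in model.params:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1**step)
                vhat = v_state[k] / (1 - beta2**step)
                model.params[k] = model.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
        if aborted:
            warnings.warn("non-finite loss; training aborted at the last finite checkpoint")
            break
        l_val = val_loss()
        if not np.isfinite(l_val):
            aborted = True
            warnings.warn("non-finite loss; training aborted at the last finite checkpoint")
            break
        loss_hist.append(float(np.mean(batch_losses)))  # running training loss
        val_hist.append(l_val)
        if tail_start is not None and epoch >= tail_start:
            if tail_sum is None:
                tail_sum = {k: v.copy() for k, v in model.params.items()}
            else:
                for k in tail_sum:
                    tail_sum[k] += model.params[k]
            tail_n += 1
        if l_val < best_val * (1.0 - config.min_delta):
            best_val = l_val
            best_params = model.copy_params()
            best_epoch = epoch
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if not milestones and lr_stale >= config.lr_patience and lr > config.min_lr:
                lr = max(lr * config.lr_decay, config.min_lr)
                lr_stale = 0
            if stale >= config.patience:
                break

    if tail_sum is not None and tail_n > 0 and not aborted:
        # tail-averaged parameters replace the val-selected checkpoint
        model.params = {k: v / tail_n for k, v in tail_sum.items()}
        best_params = model.copy_params()
    else:
        model.params = best_params
    final = full_loss()
    if final > initial_full:
        # validation-selected checkpoint failed to improve on the whole set;
        # fall back to the initial parameters (no-op training)
        model.params = initial_params
        final = initial_full
        best_epoch = 0
    return TrainingResult(
        final_params=model.copy_params(),
        loss_history=np.asarray(loss_hist),
        val_history=np.asarray(val_hist),
        config_echo={**config.to_dict(), "seed": int(seed)},
        dataset_fingerprint=_fingerprint(R, G),
        best_epoch=best_epoch,
        final_loss=final,
    )
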