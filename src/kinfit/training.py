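"""Gradient-based parameter training.

The training loop follows the neural-ODE recipe adapted to kinetic models:

* mean-centered squared-error loss so that metabolites on very different
  concentration scales contribute comparably;
* gradients obtained by differentiating through the ODE integrator
  (:mod:`kinfit.sensitivities`);
* optimization in log parameter space for positivity-flagged (kinetic)
  parameters — neural-network weights, when present, stay linear;
* gradient clipping by global L2 norm (default cap 4);
* the AdaBelief optimizer (β1=0.9, β2=0.999, ε=1e-16), learning rate 1e-3,
  full-batch (no mini-batching over time points);
* early stopping when the loss falls below 1e-6, with 1e-3 the
  "successfully trained" reporting threshold;
* multi-dataset fitting by averaging per-dataset gradients elementwise
  before the (single) clip + update.

Everything is vectorized over a batch of parameter initializations, so a
100-start screen costs one loop, not 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np

from .core import initial_conditions_from_data
from .data import TimeSeriesDataset
from .errors import DivergedOptimizerError, GradientUnavailableError, NonFiniteGradientError
from .sensitivities import GradientEngine, MeanCenteredLoss

__all__ = [
    "TrainerConfig",
    "TrainingTrace",
    "FitResult",
    "AdaBeliefState",
    "mean_centered_loss",
    "global_norm",
    "clip_by_global_norm",
    "loss_gradient",
    "adabelief_step",
    "train",
    "train_multi",
]


@dataclass(frozen=True)
class TrainerConfig:
    learning_rate: float = 1e-3
    max_iter: int = 3000  # 10000 is typical for large models
    clip_norm: float = 4.0  # ĝ, cap on the gradient global norm
    lambda_stop: float = 1e-6  # early-stopping loss threshold
    lambda_success: float = 1e-3  # "successfully trained" reporting threshold
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-16
    grid_resolution: int = 200  # integration steps spanning the data window
    snapshot_stride: int = 0  # parameter snapshots every k iterations (0 = off)
    loss_cls: type = MeanCenteredLoss

    def __post_init__(self):
        if self.lambda_stop <= 0 or self.lambda_success <= 0:
            raise ValueError("loss thresholds must be positive")
        if self.lambda_stop >= self.lambda_success:
            raise ValueError("lambda_stop must be below lambda_success")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")


# ---------------------------------------------------------------------------
# loss / gradient primitives
# ---------------------------------------------------------------------------


def mean_centered_loss(pred, obs: TimeSeriesDataset) -> float:
    """Mean-centered squared error of predictions against a dataset.

    ``pred`` is (n_species, n_times) aligned with ``obs.species`` and
    ``obs.times``; missing observations are excluded, and each species is
    scaled by its own observed mean.
    """
    pred = np.asarray(pred, float)
    return float(MeanCenteredLoss(obs).value(pred[None])[0])


def global_norm(g) -> float:
    """L2 norm over all gradient components: sqrt(Σ_i g_i²)."""
    g = np.asarray(g, float)
    if not np.all(np.isfinite(g)):
        raise NonFiniteGradientError("non-finite-gradient")
    return float(np.sqrt(np.sum(g * g)))


def clip_by_global_norm(g, max_norm: float = 4.0):
    """Rescale g so its global norm never exceeds ``max_norm``."""
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    g = np.asarray(g, float)
    norm = global_norm(g)
    if norm <= max_norm:
        return g.copy()
    return g * (max_norm / norm)


# ---------------------------------------------------------------------------
# AdaBelief
# ---------------------------------------------------------------------------


@dataclass
class AdaBeliefState:
    """AdaBelief moment accumulators for a (batch of) parameter vector(s).

    Follows the published update: first moment m (EMA of g), belief
    s (EMA of (g−m)²), bias correction on both, step −lr·m̂/(√ŝ+ε).
    """

    m: np.ndarray
    s: np.ndarray
    step_count: int = 0

    @classmethod
    def zeros(cls, shape) -> "AdaBeliefState":
        return cls(m=np.zeros(shape), s=np.zeros(shape))

    def step(self, g: np.ndarray, config: TrainerConfig) -> np.ndarray:
        """One update; returns the (negative) parameter increment Δ."""
        b1, b2, eps = config.beta1, config.beta2, config.eps
        self.step_count += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.s = b2 * self.s + (1 - b2) * (g - self.m) ** 2 + eps
        m_hat = self.m / (1 - b1**self.step_count)
        s_hat = self.s / (1 - b2**self.step_count)
        delta = -config.learning_rate * m_hat / (np.sqrt(s_hat) + eps)
        if not np.all(np.isfinite(delta)):
            raise DivergedOptimizerError("diverged-optimizer: non-finite update")
        return delta


def adabelief_step(state: AdaBeliefState, g, config: TrainerConfig | None = None):
    """Functional one-step AdaBelief update; returns (new_values_delta, state)."""
    config = config or TrainerConfig()
    return state.step(np.asarray(g, float), config), state


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class TrainingTrace:
    loss: np.ndarray  # per-iteration loss J
    grad_norm: np.ndarray  # per-iteration ‖∇J‖ (log-space, pre-clip)
    clipped_norm: np.ndarray  # norm actually fed to the optimizer
    snapshots: list = field(default_factory=list)  # [(iteration, theta vector)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.loss)),
                "loss": self.loss,
                "grad_norm": self.grad_norm,
                "clipped_grad_norm": self.clipped_norm,
            }
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class FitResult:
    """Outcome of one training run (a Results object in the statsmodels
    sense: estimates, diagnostics, trace, summary)."""

    param_ids: list[str]
    theta0: np.ndarray  # linear-space initialization
    theta: np.ndarray  # linear-space final (best-so-far on failure)
    status: str  # converged-early | max-iters | failed-at-iteration-k
    n_iter: int
    final_loss: float
    initial_loss: float
    trace: TrainingTrace
    config: TrainerConfig
    fail_iteration: int | None = None
    model: object | None = None
    datasets: list | None = None

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_ids, self.theta.tolist()))

    @property
    def converged(self) -> bool:
        return self.status == "converged-early"

    @property
    def succeeded(self) -> bool:
        """Training success in the reporting sense: final loss < λ_success."""
        return bool(self.final_loss < self.config.lambda_success)

    def bse(self, dataset: TimeSeriesDataset | None = None, rel_step: float = 1e-5):
        """Approximate standard errors of log-parameters via a Gauss–Newton
        (J'J) approximation with a finite-difference residual Jacobian."""
        if self.model is None:
            raise ValueError("fit was not run through a model; no bse available")
        ds = dataset or (self.datasets[0] if self.datasets else None)
        if ds is None:
            raise ValueError("a dataset is required for standard errors")
        from .sensitivities import GradientEngine

        m0 = initial_conditions_from_data(self.model, ds)
        span = ds.times[-1] - ds.times[0]
        engine = GradientEngine(
            self.model, ds, m0, max_step=max(span, 1e-12) / self.config.grid_resolution
        )
        loss = engine.loss

        def residuals(theta):
            pred, ok = engine.predictions(theta)
            res = (pred[0] - np.where(loss.mask, loss.obs, 0.0)) / loss.means[:, None]
            return res[loss.mask]

        p = len(self.theta)
        r0 = residuals(self.theta)
        Jac = np.empty((r0.size, p))
        for j in range(p):
            step = rel_step * max(abs(self.theta[j]), 1e-12)
            up, dn = self.theta.copy(), self.theta.copy()
            up[j] += step
            dn[j] -= step
            Jac[:, j] = (residuals(up) - residuals(dn)) / (2 * step) * self.theta[j]
        dof = max(r0.size - p, 1)
        s2 = float(r0 @ r0) / dof
        cov = s2 * np.linalg.pinv(Jac.T @ Jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))

    def summary(self) -> str:
        lines = [
            "Kinetic model fit",
            "=" * 58,
            f"status: {self.status:<22} iterations: {self.n_iter}",
            f"initial loss: {self.initial_loss:<12.4e} final loss: {self.final_loss:.4e}",
            f"trained successfully (loss < {self.config.lambda_success:g}): "
            f"{'yes' if self.succeeded else 'no'}",
            "-" * 58,
            f"{'parameter':<24}{'start':>16}{'estimate':>16}",
            "-" * 58,
        ]
        for pid, t0, t1 in zip(self.param_ids, self.theta0, self.theta):
            lines.append(f"{pid:<24}{t0:>16.6g}{t1:>16.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "n_iter": self.n_iter,
                "final_loss": self.final_loss,
                "initial_loss": self.initial_loss,
                "params": self.params,
            },
            indent=2,
        )

    def plot_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.trace.loss, label="loss")
        ax.semilogy(self.trace.grad_norm, label="gradient global norm", alpha=0.7)
        ax.set_xlabel("iteration")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def _to_opt_space(theta: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Log-transform positivity-flagged parameters (identity otherwise)."""
    out = np.array(theta, float, copy=True)
    out[..., positive] = np.log(out[..., positive])
    return out


def _from_opt_space(phi: np.ndarray, positive: np.ndarray) -> np.ndarray:
    out = np.array(phi, float, copy=True)
    out[..., positive] = np.exp(out[..., positive])
    return out


# ---------------------------------------------------------------------------
# core loop
# ---------------------------------------------------------------------------


def _make_engines(model, datasets, config, m0=None):
    engines = []
    for ds in datasets:
        m0_ds = initial_conditions_from_data(model, ds) if m0 is None else np.asarray(m0, float)
        span = float(ds.times[-1] - ds.times[0])
        max_step = max(span, 1e-12) / config.grid_resolution
        engines.append(GradientEngine(model, ds, m0_ds, max_step, loss_cls=config.loss_cls))
    return engines


def _batch_loss_grad(engines, positive, Phi):
    """Mean-over-datasets loss and opt-space gradient for a batch Phi (B,P)."""
    Theta = _from_opt_space(Phi, positive)
    J_acc, G_acc, ok = None, None, None
    for eng in engines:
        J, G, ok_e = eng.loss_and_gradient(Theta)
        # chain rule into opt (log) space
        G = np.where(positive[None, :], G * Theta, G)
        J_acc = J if J_acc is None else J_acc + J
        G_acc = G if G_acc is None else G_acc + G
        ok = ok_e if ok is None else (ok & ok_e)
    n = len(engines)
    return J_acc / n, G_acc / n, ok


def _train_batch(model, Theta0: np.ndarray, datasets, config: TrainerConfig, m0=None):
    """Vectorized training of a batch of initializations; returns one
    FitResult per batch row."""
    engines = _make_engines(model, datasets, config, m0=m0)
    positive = np.asarray(model.positive, bool)
    B, P = Theta0.shape
    Phi = _to_opt_space(Theta0, positive)

    opt = AdaBeliefState.zeros((B, P))
    active = np.ones(B, dtype=bool)
    status = np.array(["max-iters"] * B, dtype=object)
    fail_iter = np.full(B, -1)
    n_iter = np.zeros(B, dtype=int)
    final_theta = _from_opt_space(Phi, positive)
    final_loss = np.full(B, np.inf)
    initial_loss = np.full(B, np.inf)
    best_loss = np.full(B, np.inf)
    best_theta = final_theta.copy()
    traces = [
        TrainingTrace(loss=[], grad_norm=[], clipped_norm=[], snapshots=[]) for _ in range(B)
    ]

    it = 0
    for it in range(config.max_iter):
        J, G, ok = _batch_loss_grad(engines, positive, Phi)
        ok &= np.all(np.isfinite(G), axis=1) & np.isfinite(J)
        # overflow-safe global norm: scale by the largest component first
        Gm = np.where(ok[:, None], G, 0.0)
        maxabs = np.maximum(np.max(np.abs(Gm), axis=1), 1e-300)
        Gs = Gm / maxabs[:, None]
        norms = maxabs * np.sqrt(np.einsum("bp,bp->b", Gs, Gs))
        factor = np.where(norms > config.clip_norm, config.clip_norm / np.maximum(norms, 1e-300), 1.0)
        Theta = _from_opt_space(Phi, positive)

        for b in np.nonzero(active)[0]:
            if ok[b]:
                traces[b].loss.append(J[b])
                traces[b].grad_norm.append(norms[b])
                traces[b].clipped_norm.append(norms[b] * factor[b])
                if config.snapshot_stride and it % config.snapshot_stride == 0:
                    traces[b].snapshots.append((it, Theta[b].copy()))
                if it == 0:
                    initial_loss[b] = J[b]
                if J[b] < best_loss[b]:
                    best_loss[b] = J[b]
                    best_theta[b] = Theta[b]

        newly_failed = active & ~ok
        for b in np.nonzero(newly_failed)[0]:
            status[b] = f"failed-at-iteration-{it}"
            fail_iter[b] = it
            n_iter[b] = it
            final_theta[b] = best_theta[b]
            final_loss[b] = best_loss[b]
        converged = active & ok & (J < config.lambda_stop)
        for b in np.nonzero(converged)[0]:
            status[b] = "converged-early"
            n_iter[b] = it
            final_theta[b] = Theta[b]
            final_loss[b] = J[b]
        active &= ~(newly_failed | converged)
        if not active.any():
            break

        G_clipped = G * factor[:, None]
        delta = opt.step(np.where(active[:, None] & ok[:, None], G_clipped, 0.0), config)
        Phi = np.where(active[:, None], Phi + delta, Phi)

    if active.any():
        # budget exhausted: evaluate the final iterate once for reporting
        J, _, ok = _batch_loss_grad(engines, positive, Phi)
        Theta = _from_opt_space(Phi, positive)
        for b in np.nonzero(active)[0]:
            n_iter[b] = config.max_iter
            if ok[b]:
                final_theta[b] = Theta[b]
                final_loss[b] = J[b]
            else:
                status[b] = f"failed-at-iteration-{config.max_iter}"
                fail_iter[b] = config.max_iter
                final_theta[b] = best_theta[b]
                final_loss[b] = best_loss[b]

    results = []
    for b in range(B):
        tr = TrainingTrace(
            loss=np.asarray(traces[b].loss, float),
            grad_norm=np.asarray(traces[b].grad_norm, float),
            clipped_norm=np.asarray(traces[b].clipped_norm, float),
            snapshots=traces[b].snapshots,
        )
        results.append(
            FitResult(
                param_ids=list(model.param_ids),
                theta0=Theta0[b].copy(),
                theta=final_theta[b].copy(),
                status=str(status[b]),
                n_iter=int(n_iter[b]),
                final_loss=float(final_loss[b]),
                initial_loss=float(initial_loss[b]),
                trace=tr,
                config=config,
                fail_iteration=int(fail_iter[b]) if fail_iter[b] >= 0 else None,
                model=model,
                datasets=list(datasets),
            )
        )
    return results


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def loss_gradient(model, theta, dataset: TimeSeriesDataset, config: TrainerConfig | None = None,
                  m0=None):
    """Loss and its gradient with respect to the log-space parameters.

    Raises :class:`~kinfit.errors.GradientUnavailableError` when the
    underlying integration fails.
    """
    config = config or TrainerConfig()
    engines = _make_engines(model, [dataset], config, m0=m0)
    positive = np.asarray(model.positive, bool)
    theta = model.theta_vector(theta) if hasattr(model, "theta_vector") else np.asarray(theta)
    Phi = _to_opt_space(theta[None, :], positive)
    J, G, ok = _batch_loss_grad(engines, positive, Phi)
    if not ok[0]:
        raise GradientUnavailableError("integration failed at the supplied parameters")
    return float(J[0]), G[0]


def train(model, theta0=None, dataset: TimeSeriesDataset = None, config=None, m0=None) -> FitResult:
    """Fit one model to one dataset from one initialization (full-batch
    gradient descent with AdaBelief, clipping, log-space parameters)."""
    return train_multi(model, theta0, [dataset], config=config, m0=m0)


def train_multi(model, theta0=None, datasets=None, config=None, m0=None) -> FitResult:
    """Fit against several datasets at once: per-dataset gradients are
    averaged elementwise each iteration, then clipped once and applied."""
    config = config or TrainerConfig()
    theta0 = model.theta_vector(theta0)
    return _train_batch(model, theta0[None, :], list(datasets), config, m0=m0)[0]
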