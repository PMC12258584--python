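"""Hybrid mechanistic / neural-network models.

When one reaction's mechanism (and its stoichiometry) is unknown, the
model keeps the remaining mechanistic structure and adds a trainable
multilayer-perceptron term directly to the mass balance:

    dm/dt = S₍₋ᵢ₎ · v₍₋ᵢ₎(t, m, θ)  +  NN(t, m; w, b)

The network output lives in species space (one rate per dynamic species),
absorbing the unknown stoichiometric column, so nothing multiplies it.
Default architecture: input (t, m), two hidden layers of 16 softplus
units, linear output, with the output layer zero-initialized — before any
training step the hybrid model is exactly the masked mechanistic model,
which makes the construction testable and stabilizes early training.

Kinetic parameters stay log-transformed during joint training; network
weights are updated in linear space.
"""

from __future__ import annotations

import json
import warnings
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import KineticModel, SolverConfig, Trajectory
from .data import TimeSeriesDataset
from .errors import KinfitError

__all__ = [
    "NeuralFlux",
    "HybridModel",
    "mask_reaction",
    "hybridize",
    "train_hybrid",
    "masking_experiment",
]


def _softplus(z):
    return np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))


def _stable_sigmoid(z):
    return 1.0 / (1.0 + np.exp(np.clip(-z, -500, 500)))


class NeuralFlux:
    """Multilayer perceptron flux term NN(t, m; w, b).

    Stateless: weights travel as a flat vector alongside the kinetic
    parameters, so the training loop treats them uniformly.
    """

    def __init__(self, n_species: int, hidden=(16, 16), include_time: bool = True, seed=0):
        self.n_species = n_species
        self.include_time = include_time
        n_in = n_species + (1 if include_time else 0)
        self.layer_sizes = [n_in, *hidden, n_species]
        rng = np.random.default_rng(seed)
        self._shapes = []
        w0 = []
        for i, (a, b) in enumerate(zip(self.layer_sizes[:-1], self.layer_sizes[1:])):
            last = i == len(self.layer_sizes) - 2
            W = np.zeros((b, a)) if last else rng.normal(0.0, np.sqrt(2.0 / a), (b, a))
            bias = np.zeros(b)
            self._shapes.append((W.shape, bias.shape))
            w0.extend([W.ravel(), bias])
        self.weights0 = np.concatenate(w0)
        self.n_weights = self.weights0.size

    # ------------------------------------------------------------------ utils
    def unflatten(self, flat: np.ndarray):
        """flat (B, n_weights) -> list of (W (B,b,a), bias (B,b))."""
        layers = []
        i = 0
        for (ws, bs) in self._shapes:
            size_w = int(np.prod(ws))
            W = flat[:, i : i + size_w].reshape(-1, *ws)
            i += size_w
            bias = flat[:, i : i + bs[0]]
            i += bs[0]
            layers.append((W, bias))
        return layers

    def _inputs(self, t: float, m: np.ndarray) -> np.ndarray:
        if self.include_time:
            tcol = np.full((m.shape[0], 1), float(t))
            return np.concatenate([tcol, m], axis=1)
        return m

    def _forward(self, flat: np.ndarray, t: float, m: np.ndarray):
        layers = self.unflatten(flat)
        x = self._inputs(t, m)
        acts = [x]
        pre = []
        h = x
        for li, (W, b) in enumerate(layers):
            z = np.einsum("boa,ba->bo", W, h) + b
            pre.append(z)
            h = z if li == len(layers) - 1 else _softplus(z)
            acts.append(h)
        return acts, pre, layers

    # ------------------------------------------------------------- public API
    def apply(self, flat: np.ndarray, t: float, m: np.ndarray) -> np.ndarray:
        """Network output (B, n_species) for a batch of weight vectors."""
        acts, _, _ = self._forward(flat, t, m)
        return acts[-1]

    def vjp(self, flat: np.ndarray, t: float, m: np.ndarray, cot: np.ndarray):
        """Backpropagate a species-space cotangent; returns
        (d/dm (B, n_species), d/dweights (B, n_weights))."""
        acts, pre, layers = self._forward(flat, t, m)
        B = m.shape[0]
        grads = []
        delta = cot  # gradient w.r.t. layer output
        for li in range(len(layers) - 1, -1, -1):
            W, _ = layers[li]
            if li != len(layers) - 1:
                delta = delta * _stable_sigmoid(pre[li])
            W_bar = np.einsum("bo,ba->boa", delta, acts[li])
            b_bar = delta
            grads.append((W_bar, b_bar))
            delta = np.einsum("boa,bo->ba", W, delta)
        grads.reverse()
        flat_grad = np.concatenate(
            [np.concatenate([W.reshape(B, -1), b], axis=1) for W, b in grads], axis=1
        )
        m_bar = delta[:, 1:] if self.include_time else delta
        return m_bar, flat_grad

    # -------------------------------------------------------------- save/load
    def manifest(self) -> dict:
        return {
            "layer_sizes": self.layer_sizes,
            "activation": "softplus",
            "include_time": self.include_time,
        }

    def save(self, path, weights: np.ndarray | None = None) -> None:
        payload = self.manifest()
        w = self.weights0 if weights is None else np.asarray(weights)
        payload["weights"] = w.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> tuple["NeuralFlux", np.ndarray]:
        with open(path) as fh:
            payload = json.load(fh)
        hidden = tuple(payload["layer_sizes"][1:-1])
        nn = cls(
            n_species=payload["layer_sizes"][-1],
            hidden=hidden,
            include_time=payload["include_time"],
        )
        return nn, np.asarray(payload["weights"], float)


class HybridModel:
    """Masked mechanistic model plus a neural flux term (joint trainable).

    The parameter vector is the concatenation of the kinetic parameters
    (log-transformed during training) and the flat network weights
    (linear).  Implements the same batched RHS/VJP protocol as
    :class:`~kinfit.core.KineticModel`, so training and screening code is
    shared unchanged.
    """

    def __init__(self, kinetic: KineticModel, flux: NeuralFlux, weights: np.ndarray | None = None):
        if flux.n_species != kinetic.n_state:
            raise KinfitError(
                f"neural flux outputs {flux.n_species} species, model has {kinetic.n_state}"
            )
        self.kinetic = kinetic
        self.flux = flux
        self.spec = kinetic.spec
        self.species_ids = kinetic.species_ids
        self.n_state = kinetic.n_state
        self.n_kinetic = kinetic.n_params
        self.param_ids = list(kinetic.param_ids) + [f"nn_w{i}" for i in range(flux.n_weights)]
        self.n_params = len(self.param_ids)
        w0 = flux.weights0 if weights is None else np.asarray(weights, float)
        self.theta_ref = np.concatenate([kinetic.theta_ref, w0])
        self.positive = np.concatenate(
            [kinetic.positive, np.zeros(flux.n_weights, dtype=bool)]
        )

    def theta_vector(self, theta=None) -> np.ndarray:
        if theta is None:
            return self.theta_ref.copy()
        theta = np.asarray(theta, float)
        if theta.shape == (self.n_kinetic,):
            return np.concatenate([theta, self.theta_ref[self.n_kinetic :]])
        if theta.shape != (self.n_params,):
            raise KinfitError(
                f"theta must have length {self.n_kinetic} (kinetic only) or {self.n_params}"
            )
        return theta

    def split(self, theta: np.ndarray):
        return theta[..., : self.n_kinetic], theta[..., self.n_kinetic :]

    def rhs_batch(self, t: float, m: np.ndarray, theta: np.ndarray) -> np.ndarray:
        kin, w = self.split(theta)
        return self.kinetic.rhs_batch(t, m, kin) + self.flux.apply(w, t, m)

    def vjp_batch(self, t, m, theta, cotangent):
        kin, w = self.split(theta)
        vm_k, vp_k = self.kinetic.vjp_batch(t, m, kin, cotangent)
        vm_n, vw = self.flux.vjp(w, t, m, cotangent)
        return vm_k + vm_n, np.concatenate([vp_k, vw], axis=1)

    @property
    def m0_ref(self) -> np.ndarray:
        return self.kinetic.m0_ref

    def simulate(self, theta=None, t_eval=None, m0=None, config: SolverConfig | None = None):
        """Integrate the hybrid ODEs with the adaptive stiff solver."""
        config = config or SolverConfig()
        theta = self.theta_vector(theta)
        t_eval = np.asarray(t_eval, float)
        m0 = self.m0_ref if m0 is None else np.asarray(m0, float)

        def rhs(t, y):
            with np.errstate(all="ignore"):
                return self.rhs_batch(t, y[None, :], theta[None, :])[0]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_ivp(
                rhs,
                (float(t_eval[0]), float(t_eval[-1])),
                m0,
                method="Radau" if config.method in ("stiff", "Radau") else config.method,
                t_eval=t_eval,
                rtol=config.rtol,
                atol=config.atol,
            )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            return Trajectory(t_eval, np.full((self.n_state, t_eval.size), np.nan),
                              list(self.species_ids), success=False,
                              diagnostic="step-size-underflow" if not sol.success
                              else "non-finite-state")
        return Trajectory(t_eval, sol.y, list(self.species_ids), success=True)

    def fit(self, dataset, theta0=None, config=None, m0=None):
        from . import training

        if isinstance(dataset, TimeSeriesDataset):
            dataset = [dataset]
        return training.train_multi(self, theta0, dataset, config=config, m0=m0)

    def __repr__(self):
        return (
            f"<HybridModel: {self.kinetic!r} + MLP{tuple(self.flux.layer_sizes)} "
            f"({self.flux.n_weights} weights)>"
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def mask_reaction(model: KineticModel, index: int) -> KineticModel:
    """Remove reaction ``index`` (0-based, document order): S loses the
    column, the flux vector loses the entry, and parameters used only by
    that reaction leave the trainable registry."""
    return model.drop_reaction(index)


def hybridize(masked: KineticModel, flux: NeuralFlux, weights=None) -> HybridModel:
    """Couple a masked mechanistic model with a neural flux term."""
    return HybridModel(masked, flux, weights=weights)


def train_hybrid(hybrid: HybridModel, dataset, config=None, theta0=None, m0=None):
    """Joint training of kinetic parameters (log-space) and network
    weights (linear space) with the standard loop."""
    return hybrid.fit(dataset, theta0=theta0, config=config, m0=m0)


def masking_experiment(
    model: KineticModel,
    theta_true=None,
    t_end: float | None = None,
    n_points: int = 100,
    noise_pct: float = 0.05,
    seed: int = 0,
    config=None,
    recovery_threshold: float = 1e-2,
    hidden=(16, 16),
) -> pd.DataFrame:
    """Mask every reaction in turn, hybridize, train, and score recovery.

    For each reaction *i*: a noisy dataset (multiplicative Gaussian noise,
    ``noise_pct`` percent standard deviation) is generated from the full
    model at the true parameters, reaction *i* is replaced by a neural
    flux term, and the hybrid is trained on the noisy data.  Recovery is
    scored as the mean-centered loss of the trained hybrid against the
    *noiseless* ground-truth trajectories on the training grid; below
    ``recovery_threshold`` counts as recovered.
    """
    from .evaluation import generate_synthetic_dataset
    from .sensitivities import GradientEngine
    from .training import TrainerConfig

    config = config or TrainerConfig()
    theta_vec = model.theta_vector(theta_true)
    if t_end is None:
        raise KinfitError("t_end is required")

    clean = generate_synthetic_dataset(
        model, theta_vec, t_end, points_per_species=n_points, noise_pct=0.0
    )
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(model.n_reactions):
        rid = model.spec.reactions[i].id
        noisy = generate_synthetic_dataset(
            model, theta_vec, t_end, points_per_species=n_points,
            noise_pct=noise_pct, seed=int(rng.integers(0, 2**31 - 1)),
        )
        masked = mask_reaction(model, i)
        flux = NeuralFlux(
            masked.n_state, hidden=hidden, seed=int(rng.integers(0, 2**31 - 1))
        )
        hybrid = hybridize(masked, flux)
        result = hybrid.fit(noisy, config=config)
        span = clean.times[-1] - clean.times[0]
        engine = GradientEngine(
            hybrid, clean, m0=hybrid.m0_ref, max_step=span / config.grid_resolution
        )
        J_truth, ok = engine.loss_value(result.theta[None, :])
        J_truth = float(J_truth[0])
        rows.append(
            {
                "reaction": rid,
                "index": i,
                "status": result.status,
                "final_loss_noisy": result.final_loss,
                "loss_vs_truth": J_truth,
                "recovered": bool(ok[0] and J_truth < recovery_threshold),
            }
        )
    return pd.DataFrame(rows)
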