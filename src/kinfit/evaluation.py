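"""Benchmarking machinery: synthetic data, multi-start screening, metrics.

The screening protocol mirrors the way convergence of gradient-based
kinetic-model training is usually studied: simulate a ground-truth dataset
from the model at its true parameters (ten time points per species,
noiseless by default), draw 100 initializations by Latin-hypercube sampling
within a factor-X band around the truth (θ_true/X ≤ θ ≤ X·θ_true, sampled
in log10 space), and report

* initialization success — the fraction of starts at which the loss and
  its gradient can be evaluated at all (the ODEs integrate);
* training success — the fraction whose final loss after at most 3000
  AdaBelief iterations falls below 1e-3 (always ≤ initialization success);
* per-run relative improvement r = (J_init − J_final)/J_init.

Experiments are replicated (three times by default) with distinct RNG
seeds; identical seeds reproduce a screen bitwise.

Four built-in fixture models (f1–f4) make every experiment runnable
without downloads; the same functions accept any SBML-imported model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .core import KineticModel, SolverConfig
from .data import TimeSeriesDataset
from .errors import FixtureUnsolvableError, InvalidBoundsError, KinfitError
from .mechanisms import instantiate_law
from .sensitivities import GradientEngine
from .training import TrainerConfig, _train_batch

__all__ = [
    "PriorBounds",
    "ScreenResult",
    "FIXTURES",
    "fixture",
    "generate_synthetic_dataset",
    "lhs_sample",
    "initialization_screen",
    "training_screen",
    "relative_improvement",
    "replicated_screen",
]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _f1():
    """1-species exponential decay, 1 parameter."""
    rxn = instantiate_law(
        "mass_action_irrev_uni", species={"S": "A"}, parameters={"k": "k"}, reaction_id="v_decay"
    )
    model = KineticModel.from_reactions(
        [("A", 2.0)], [rxn], {"k": 0.5}, model_id="f1_decay"
    )
    return model, {"k": 0.5}, 5.0


def _f2():
    """3-species irreversible mass-action chain A -> B -> C."""
    r1 = instantiate_law(
        "mass_action_irrev_uni", {"S": "A"}, {"k": "k1"}, reaction_id="v1"
    )
    r1 = _with_product(r1, "B")
    r2 = instantiate_law(
        "mass_action_irrev_uni", {"S": "B"}, {"k": "k2"}, reaction_id="v2"
    )
    r2 = _with_product(r2, "C")
    model = KineticModel.from_reactions(
        [("A", 2.0), ("B", 0.0), ("C", 0.0)],
        [r1, r2],
        {"k1": 0.7, "k2": 0.3},
        model_id="f2_chain",
    )
    return model, {"k1": 0.7, "k2": 0.3}, 10.0


def _f3():
    """2-reaction reversible Michaelis-Menten pathway A <=> B <=> C.

    keq of each step is a fixed thermodynamic constant (bound numerically),
    leaving 6 trainable parameters.
    """
    r1 = instantiate_law(
        "michaelis_menten_rev",
        {"S": "A", "P": "B"},
        {"vmax": "vmax1", "km_s": "kms1", "km_p": "kmp1", "keq": 4.0},
        reaction_id="v1",
    )
    r2 = instantiate_law(
        "michaelis_menten_rev",
        {"S": "B", "P": "C"},
        {"vmax": "vmax2", "km_s": "kms2", "km_p": "kmp2", "keq": 3.0},
        reaction_id="v2",
    )
    theta = {
        "vmax1": 1.0,
        "kms1": 0.5,
        "kmp1": 1.0,
        "vmax2": 0.8,
        "kms2": 0.6,
        "kmp2": 1.2,
    }
    model = KineticModel.from_reactions(
        [("A", 2.0), ("B", 0.2), ("C", 0.1)], [r1, r2], theta, model_id="f3_revmm"
    )
    return model, theta, 20.0


def _f4():
    """6-species mass-action ring A1 -> A2 -> ... -> A6 -> A1, 6 parameters."""
    ks = [1.0, 0.6, 0.9, 0.4, 0.8, 0.5]
    reactions = []
    for i in range(6):
        r = instantiate_law(
            "mass_action_irrev_uni",
            {"S": f"A{i + 1}"},
            {"k": f"k{i + 1}"},
            reaction_id=f"v{i + 1}",
        )
        reactions.append(_with_product(r, f"A{(i + 1) % 6 + 1}"))
    inits = [("A1", 3.0)] + [(f"A{i}", 0.5) for i in range(2, 7)]
    theta = {f"k{i + 1}": ks[i] for i in range(6)}
    model = KineticModel.from_reactions(inits, reactions, theta, model_id="f4_ring")
    return model, theta, 6.0


def _with_product(reaction, species_id, coeff: float = 1.0):
    from dataclasses import replace

    products = dict(reaction.products)
    products[species_id] = products.get(species_id, 0.0) + coeff
    return replace(reaction, products=products)


FIXTURES = {"f1": _f1, "f2": _f2, "f3": _f3, "f4": _f4}


def fixture(name: str):
    """Built-in model by name; returns (model, theta_true dict, t_end)."""
    if name not in FIXTURES:
        raise KinfitError(f"unknown fixture '{name}' (have {sorted(FIXTURES)})")
    return FIXTURES[name]()


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


def generate_synthetic_dataset(
    model: KineticModel,
    theta_true=None,
    t_end: float = None,
    points_per_species: int = 10,
    noise_pct: float = 0.0,
    seed: int | None = None,
    t0: float = 0.0,
    solver_config: SolverConfig | None = None,
) -> TimeSeriesDataset:
    """Sample ground-truth trajectories at uniformly spaced time points.

    Every dynamic species is observed at the same ``points_per_species``
    times (inclusive of t0 and t_end), so the dataset carries
    ``points_per_species × n_species`` observations.  Optional
    multiplicative Gaussian noise y·(1+ε), ε ~ N(0, (noise_pct/100)²).
    """
    theta = model.theta_vector(theta_true)
    times = np.linspace(t0, float(t_end), points_per_species)
    traj = model.simulate(theta, t_eval=times, config=solver_config)
    if not traj.success:
        raise FixtureUnsolvableError(
            f"fixture-unsolvable: {model.spec.model_id} at theta_true ({traj.diagnostic})"
        )
    values = traj.values.copy()
    if noise_pct:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(0.0, noise_pct / 100.0, size=values.shape))
    return TimeSeriesDataset(
        times=times,
        species=list(model.species_ids),
        values=values,
        name=f"{model.spec.model_id}_synthetic",
    )


# ---------------------------------------------------------------------------
# priors and sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorBounds:
    """Multiplicative prior band θ_true/X ≤ θ ≤ X·θ_true."""

    theta_true: np.ndarray
    X: float

    def __post_init__(self):
        theta = np.asarray(self.theta_true, float)
        object.__setattr__(self, "theta_true", theta)
        if self.X < 1:
            raise InvalidBoundsError("bound factor X must be >= 1")
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise InvalidBoundsError("invalid-bounds: theta_true must be positive and finite")

    @property
    def lower(self) -> np.ndarray:
        return self.theta_true / self.X

    @property
    def upper(self) -> np.ndarray:
        return self.theta_true * self.X


def lhs_sample(theta_true, X: float, n: int = 100, seed=None, log_space: bool = True):
    """Latin-hypercube parameter initializations in the prior band.

    Stratified per dimension in log10 space (default): each of the n
    equal-log-width bins of [θ/X, Xθ] contains exactly one sample.
    Deterministic under ``seed``.
    """
    bounds = PriorBounds(np.asarray(theta_true, float), float(X))
    p = bounds.theta_true.size
    if n < 1:
        raise KinfitError("n must be >= 1")
    if X == 1.0:
        return np.tile(bounds.theta_true, (n, 1))
    u = qmc.LatinHypercube(d=p, seed=seed).random(n)  # one point per bin per dim
    if log_space:
        lo, hi = np.log10(bounds.lower), np.log10(bounds.upper)
        return 10 ** (lo[None, :] + u * (hi - lo)[None, :])
    lo, hi = bounds.lower, bounds.upper
    return lo[None, :] + u * (hi - lo)[None, :]


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-initialization outcomes plus the aggregate screen metrics."""

    n_samples: int
    init_success: np.ndarray  # (n,) bool
    statuses: list[str]  # per init-successful run, "" otherwise
    init_losses: np.ndarray  # (n,), inf where init failed
    final_losses: np.ndarray  # (n,), inf where init failed
    rel_improvements: np.ndarray  # (n,), NaN where init failed
    lambda_success: float
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def init_success_pct(self) -> float:
        return 100.0 * float(self.init_success.sum()) / self.n_samples

    @property
    def training_success_pct(self) -> float:
        trained = self.init_success & (self.final_losses < self.lambda_success)
        return 100.0 * float(trained.sum()) / self.n_samples

    @property
    def median_rel_improvement(self) -> float:
        r = self.rel_improvements[self.init_success]
        return float(np.median(r)) if r.size else float("nan")

    def summary_row(self) -> dict:
        return {
            **self.meta,
            "replicate": self.replicate,
            "n": self.n_samples,
            "init_success_pct": self.init_success_pct,
            "training_success_pct": self.training_success_pct,
            "median_rel_improvement": self.median_rel_improvement,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                **self.summary_row(),
                "statuses": list(self.statuses),
                "init_losses": [None if not np.isfinite(x) else x for x in self.init_losses],
                "final_losses": [None if not np.isfinite(x) else x for x in self.final_losses],
            },
            indent=2,
        )


def relative_improvement(J_init: float, J_final: float, lambda_stop: float = 1e-6) -> float:
    """r = (J_init − J_final)/J_init; zero when the start was already
    converged (J_init < λ_stop) or J_init is zero."""
    if J_init <= 0 or J_init < lambda_stop:
        return 0.0
    return (J_init - J_final) / J_init


def initialization_screen(
    model,
    dataset: TimeSeriesDataset,
    samples: np.ndarray,
    config: TrainerConfig | None = None,
    m0=None,
):
    """Per-sample initialization success: loss and gradient evaluate finite
    at the sample (the ODEs integrate there).  Returns (flags, losses)."""
    config = config or TrainerConfig()
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.size == 0:
        raise KinfitError("samples must be non-empty")
    from .core import initial_conditions_from_data

    m0_ds = initial_conditions_from_data(model, dataset) if m0 is None else np.asarray(m0)
    span = float(dataset.times[-1] - dataset.times[0])
    engine = GradientEngine(
        model, dataset, m0_ds, max_step=max(span, 1e-12) / config.grid_resolution,
        loss_cls=config.loss_cls,
    )
    J, G, ok = engine.loss_and_gradient(samples)
    flags = ok & np.isfinite(J) & np.all(np.isfinite(G), axis=1)
    return flags, np.where(flags, J, np.inf)


def training_screen(
    model,
    dataset: TimeSeriesDataset,
    samples: np.ndarray,
    config: TrainerConfig | None = None,
    replicate: int = 0,
    meta: dict | None = None,
) -> ScreenResult:
    """Train every init-successful sample and aggregate the screen metrics."""
    config = config or TrainerConfig()
    samples = np.atleast_2d(np.asarray(samples, float))
    n = samples.shape[0]
    flags, init_losses = initialization_screen(model, dataset, samples, config)

    statuses = [""] * n
    final_losses = np.full(n, np.inf)
    rel = np.full(n, np.nan)
    idx = np.nonzero(flags)[0]
    if idx.size:
        results = _train_batch(model, samples[idx], [dataset], config)
        for j, b in enumerate(idx):
            res = results[j]
            statuses[b] = res.status
            final_losses[b] = res.final_loss
            rel[b] = relative_improvement(
                init_losses[b], res.final_loss, config.lambda_stop
            )
    return ScreenResult(
        n_samples=n,
        init_success=flags,
        statuses=statuses,
        init_losses=init_losses,
        final_losses=final_losses,
        rel_improvements=rel,
        lambda_success=config.lambda_success,
        replicate=replicate,
        meta=meta or {},
    )


def replicated_screen(
    model,
    theta_true,
    t_end: float,
    X: float,
    n: int = 100,
    replicates: int = 3,
    seed: int = 0,
    points_per_species: int = 10,
    noise_pct: float = 0.0,
    config: TrainerConfig | None = None,
) -> tuple[list[ScreenResult], pd.DataFrame]:
    """Full screening experiment: synthetic data, LHS starts, training —
    repeated ``replicates`` times with distinct RNG seeds."""
    config = config or TrainerConfig()
    theta_vec = model.theta_vector(theta_true)
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        dataset = generate_synthetic_dataset(
            model, theta_vec, t_end, points_per_species=points_per_species,
            noise_pct=noise_pct, seed=rep_seed,
        )
        samples = lhs_sample(theta_vec, X, n=n, seed=rep_seed)
        results.append(
            training_screen(
                model, dataset, samples, config, replicate=rep,
                meta={"model": model.spec.model_id, "X": X, "seed": rep_seed},
            )
        )
    table = pd.DataFrame([r.summary_row() for r in results])
    return results, table
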