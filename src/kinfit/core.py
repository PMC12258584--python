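"""Executable ODE form of a kinetic model.

:class:`KineticModel` assembles the mass-balance right-hand side
dm/dt = S·v(t, m, θ) (divided per species by its compartment size, so the
state is in concentration units) from a flattened :class:`~kinfit.sbml.ModelSpec`.
Flux expressions and their Jacobians with respect to state and parameters
are compiled once with sympy.lambdify into vectorized numpy functions that
evaluate batches of parameter vectors simultaneously; this is what makes
multi-start training cheap.

Simulation uses scipy's Radau solver (5th-order, implicit, adaptive) with
an analytic state Jacobian, at tolerances suited to stiff biochemical
systems (rtol 1e-8, atol 1e-11, initial step 1e-10 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .data import TimeSeriesDataset
from .errors import KinfitError, UnknownSpeciesError
from .sbml import (
    TIME,
    ModelSpec,
    Reaction,
    Species,
    build_stoichiometric_matrix,
    flatten_model,
    parse_sbml,
)

__all__ = ["KineticModel", "SolverConfig", "Trajectory", "initial_conditions_from_data"]


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive stiff-solver settings for :meth:`KineticModel.simulate`."""

    method: str = "Radau"  # >=5th-order implicit with adaptive steps
    rtol: float = 1e-8
    atol: float = 1e-11
    first_step: float = 1e-10
    max_steps: int = 1_000_000  # cap on RHS evaluations; exceeding = failed run

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.first_step <= 0:
            raise KinfitError("solver tolerances and first step must be positive")


@dataclass
class Trajectory:
    """Sampled solution of the ODE system (concentrations)."""

    times: np.ndarray  # (T,), ascending, the requested sample times
    values: np.ndarray  # (n_species, T)
    species: list[str]
    success: bool = True
    diagnostic: str = ""  # "", "step-size-underflow", "max-steps", "non-finite-state"

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values.T, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Concentration-vs-time lines, one per species."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sid, row in zip(self.species, self.values):
            ax.plot(self.times, row, label=sid, **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("concentration")
        ax.legend()
        return ax


class _MaxStepsExceeded(Exception):
    pass


class _Compiled:
    """One lambdified function evaluating a flat list of expressions on a
    batch, scattering results into a dense (B, n) array."""

    def __init__(self, args, exprs):
        self.n = len(exprs)
        self._const = [float(e) if e.is_number else None for e in exprs]
        self._fun = sympy.lambdify(args, list(exprs), modules="numpy") if exprs else None

    def __call__(self, t, m_cols, p_cols, batch: int) -> np.ndarray:
        out = np.empty((batch, self.n))
        if self._fun is None:
            return out
        vals = self._fun(t, *m_cols, *p_cols)
        for i, v in enumerate(vals):
            out[:, i] = v
        return out


class KineticModel:
    """Pure right-hand-side form of a kinetic model.

    Parameters are held in a canonical registry (``param_ids`` in document
    order, reference values ``theta_ref``, positivity flags); the RHS is a
    pure function of (t, m, θ) with no hidden state.
    """

    def __init__(self, spec: ModelSpec, positive: dict[str, bool] | None = None):
        if not spec.flattened:
            spec = flatten_model(spec)
        spec.validate()
        self.spec = spec
        self.species_ids: list[str] = [s.id for s in spec.dynamic_species]
        self.n_state = len(self.species_ids)
        self.n_reactions = len(spec.reactions)
        self.param_ids: list[str] = list(spec.global_params)
        self.n_params = len(self.param_ids)
        self.theta_ref = np.array([spec.global_params[p] for p in self.param_ids])
        positive = positive or {}
        self.positive = np.array([positive.get(p, True) for p in self.param_ids])

        self.S = build_stoichiometric_matrix(spec)
        comp = np.array(
            [spec.compartments.get(s.compartment, 1.0) for s in spec.dynamic_species]
        )
        # SN maps fluxes to concentration rates: dm/dt = SN @ v
        self.SN = self.S / comp[:, None]

        m_syms = [sympy.Symbol(s) for s in self.species_ids]
        p_syms = [sympy.Symbol(p) for p in self.param_ids]
        args = [TIME] + m_syms + p_syms
        self.flux_exprs = [r.rate for r in spec.reactions]

        self._v = _Compiled(args, self.flux_exprs)
        jm_entries, jp_entries = [], []
        self._jm_idx, self._jp_idx = [], []
        for i, expr in enumerate(self.flux_exprs):
            for j, sym in enumerate(m_syms):
                d = sympy.diff(expr, sym)
                if d != 0:
                    jm_entries.append(d)
                    self._jm_idx.append((i, j))
            for j, sym in enumerate(p_syms):
                d = sympy.diff(expr, sym)
                if d != 0:
                    jp_entries.append(d)
                    self._jp_idx.append((i, j))
        self._jm = _Compiled(args, jm_entries)
        self._jp = _Compiled(args, jp_entries)

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_sbml(cls, document: str, **kwargs) -> "KineticModel":
        """Build from SBML text or a path to an .xml file."""
        return cls(parse_sbml(document), **kwargs)

    @classmethod
    def from_reactions(
        cls,
        species: list[tuple[str, float]],
        reactions: list[Reaction],
        params: dict[str, float],
        compartments: dict[str, float] | None = None,
        model_id: str = "model",
        **kwargs,
    ) -> "KineticModel":
        """Build a model directly from mechanism-instantiated reactions."""
        compartments = compartments or {"cell": 1.0}
        default_comp = next(iter(compartments))
        spec = ModelSpec(
            species=[Species(sid, float(v), default_comp) for sid, v in species],
            compartments=compartments,
            global_params=dict(params),
            reactions=list(reactions),
            model_id=model_id,
        )
        return cls(spec, **kwargs)

    # --------------------------------------------------------------- defaults
    @property
    def m0_ref(self) -> np.ndarray:
        """Initial state from the model's declared initial values."""
        return np.array([s.initial_value for s in self.spec.dynamic_species])

    def theta_dict(self, theta: np.ndarray | None = None) -> dict[str, float]:
        theta = self.theta_ref if theta is None else np.asarray(theta, float)
        return dict(zip(self.param_ids, theta.tolist()))

    def theta_vector(self, theta: dict[str, float] | np.ndarray | None = None) -> np.ndarray:
        if theta is None:
            return self.theta_ref.copy()
        if isinstance(theta, dict):
            full = self.theta_dict()
            for k in theta:
                if k not in full:
                    raise KinfitError(f"unknown parameter '{k}'")
            full.update(theta)
            return np.array([full[p] for p in self.param_ids])
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_params,):
            raise KinfitError(f"theta must have shape ({self.n_params},)")
        return theta

    # ------------------------------------------------------------- evaluation
    def flux_batch(self, t: float, m: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Fluxes v(t, m, θ) for a batch: m (B,n), theta (B,p) -> (B,r)."""
        B = m.shape[0]
        return self._v(t, [m[:, i] for i in range(self.n_state)],
                       [theta[:, i] for i in range(self.n_params)], B)

    def rhs_batch(self, t: float, m: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """dm/dt for a batch of states/parameter vectors."""
        return self.flux_batch(t, m, theta) @ self.SN.T

    def rhs(self, t: float, m: np.ndarray, theta=None) -> np.ndarray:
        """Single-evaluation right-hand side f(t, m, θ)."""
        theta = self.theta_vector(theta)
        return self.rhs_batch(t, np.asarray(m, float)[None, :], theta[None, :])[0]

    def flux_jacobians(self, t, m, theta):
        """(v, dv/dm, dv/dθ) for a batch; Jacobians shaped (B, r, n)/(B, r, p)."""
        B = m.shape[0]
        m_cols = [m[:, i] for i in range(self.n_state)]
        p_cols = [theta[:, i] for i in range(self.n_params)]
        v = self._v(t, m_cols, p_cols, B)
        Jm = np.zeros((B, self.n_reactions, self.n_state))
        vals = self._jm(t, m_cols, p_cols, B)
        for k, (i, j) in enumerate(self._jm_idx):
            Jm[:, i, j] = vals[:, k]
        Jp = np.zeros((B, self.n_reactions, self.n_params))
        vals = self._jp(t, m_cols, p_cols, B)
        for k, (i, j) in enumerate(self._jp_idx):
            Jp[:, i, j] = vals[:, k]
        return v, Jm, Jp

    def vjp_batch(self, t, m, theta, cotangent):
        """Vector-Jacobian products of the RHS: given the cotangent w of
        f(t,m,θ), return (wᵀ∂f/∂m, wᵀ∂f/∂θ), shapes (B,n) and (B,p)."""
        _, Jm, Jp = self.flux_jacobians(t, m, theta)
        w_v = cotangent @ self.SN  # (B, r)
        return (
            np.einsum("br,brn->bn", w_v, Jm),
            np.einsum("br,brp->bp", w_v, Jp),
        )

    def state_jacobian(self, t, m, theta) -> np.ndarray:
        """df/dm (n x n) for a single state — the stiff solver's Jacobian."""
        _, Jm, _ = self.flux_jacobians(t, m[None, :], theta[None, :])
        return self.SN @ Jm[0]

    # ------------------------------------------------------------- simulation
    def simulate(
        self,
        theta=None,
        t_eval=None,
        m0: np.ndarray | None = None,
        config: SolverConfig | None = None,
    ) -> Trajectory:
        """Integrate the ODEs and sample exactly at ``t_eval``.

        Failures (step-size underflow, step budget, non-finite state) are
        reported in the returned :class:`Trajectory`, never raised.
        """
        config = config or SolverConfig()
        theta = self.theta_vector(theta)
        if t_eval is None:
            raise KinfitError("t_eval is required")
        t_eval = np.asarray(t_eval, float)
        if t_eval.size == 0 or np.any(np.diff(t_eval) < 0):
            raise KinfitError("t_eval must be non-empty and ascending")
        m0 = self.m0_ref if m0 is None else np.asarray(m0, float)
        if m0.shape != (self.n_state,) or not np.all(np.isfinite(m0)):
            raise KinfitError(f"m0 must be a finite vector of length {self.n_state}")

        counter = {"nfev": 0}

        def rhs(t, y):
            counter["nfev"] += 1
            if counter["nfev"] > config.max_steps:
                raise _MaxStepsExceeded
            with np.errstate(all="ignore"):
                return self.rhs(t, y, theta)

        def jac(t, y):
            with np.errstate(all="ignore"):
                return self.state_jacobian(t, y, theta)

        method = "Radau" if config.method in ("stiff", "Radau") else config.method
        span = (float(t_eval[0]), float(t_eval[-1]))
        first_step = min(config.first_step, (span[1] - span[0]) or config.first_step)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = solve_ivp(
                    rhs,
                    span,
                    m0,
                    method=method,
                    t_eval=t_eval,
                    rtol=config.rtol,
                    atol=config.atol,
                    first_step=first_step if span[1] > span[0] else None,
                    jac=jac if method in ("Radau", "BDF", "LSODA") else None,
                )
        except _MaxStepsExceeded:
            return Trajectory(t_eval, np.full((self.n_state, t_eval.size), np.nan),
                              list(self.species_ids), success=False, diagnostic="max-steps")
        if not sol.success:
            return Trajectory(t_eval, np.full((self.n_state, t_eval.size), np.nan),
                              list(self.species_ids), success=False,
                              diagnostic="step-size-underflow")
        if not np.all(np.isfinite(sol.y)):
            return Trajectory(t_eval, sol.y, list(self.species_ids), success=False,
                              diagnostic="non-finite-state")
        return Trajectory(t_eval, sol.y, list(self.species_ids), success=True)

    # ---------------------------------------------------------------- fitting
    def fit(self, data, theta0=None, config=None, m0=None):
        """Fit parameters to one dataset or a list of datasets.

        Thin wrapper over :func:`kinfit.training.train` /
        :func:`kinfit.training.train_multi`; returns a
        :class:`~kinfit.training.FitResult`.
        """
        from . import training

        if isinstance(data, TimeSeriesDataset):
            return training.train(self, theta0, data, config=config, m0=m0)
        return training.train_multi(self, theta0, list(data), config=config, m0=m0)

    # ---------------------------------------------------------------- masking
    def drop_reaction(self, index: int) -> "KineticModel":
        """New model without reaction ``index``; parameters used only by that
        reaction leave the trainable registry."""
        if not 0 <= index < self.n_reactions:
            raise KinfitError(f"reaction index {index} out of range")
        kept = [r for i, r in enumerate(self.spec.reactions) if i != index]
        drop = self._params_only_in(index)
        params = {p: v for p, v in self.spec.global_params.items() if p not in drop}
        spec = replace(self.spec, reactions=kept, global_params=params)
        pos = dict(zip(self.param_ids, self.positive.tolist()))
        return KineticModel(spec, positive={p: pos[p] for p in params})

    def _params_only_in(self, index: int) -> set[str]:
        target = {str(s) for s in self.spec.reactions[index].rate.free_symbols}
        others = set()
        for i, r in enumerate(self.spec.reactions):
            if i != index:
                others |= {str(s) for s in r.rate.free_symbols}
        return (target - others) & set(self.spec.global_params)

    def __repr__(self):
        return (
            f"<KineticModel '{self.spec.model_id}': {self.n_state} species, "
            f"{self.n_reactions} reactions, {self.n_params} parameters>"
        )


def initial_conditions_from_data(
    model: KineticModel | ModelSpec,
    dataset: TimeSeriesDataset,
    on_unknown: str = "raise",
) -> np.ndarray:
    """Initial state m0: per dynamic species, the value observed at the
    dataset's earliest time if present and non-missing, else the model's
    declared initial value.

    ``on_unknown`` controls dataset columns matching no model species:
    ``"raise"`` (default) or ``"warn"``.
    """
    spec = getattr(model, "spec", model)
    known = {s.id for s in spec.species}
    unknown = [s for s in dataset.species if s not in known]
    if unknown:
        if on_unknown == "raise":
            raise UnknownSpeciesError(f"unknown-species: {unknown}")
        warnings.warn(f"ignoring dataset columns with no matching species: {unknown}")
    m0 = []
    for s in spec.dynamic_species:
        obs = dataset.first_observation(s.id)
        m0.append(s.initial_value if np.isnan(obs) else obs)
    return np.array(m0)
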