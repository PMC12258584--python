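"""Differentiation through the ODE integrator.

Training gradients are computed by discrete backpropagation (the exact
adjoint of the integration scheme): the forward pass integrates the model
on a fixed grid — the observed time points, each interval subdivided so no
step exceeds a configurable fraction of the span — with the classical
4th-order Runge–Kutta scheme, storing the stage states; the backward pass
reverses every stage using vector–Jacobian products of the right-hand side,
accumulating the loss gradient with respect to the parameters.  Because the
backward pass is the exact transpose of the forward computation, gradients
agree with finite differences of the discrete loss to solver precision, and
the cost per iteration is independent of the number of parameters — the
property that makes joint training of neural-network flux terms feasible.

The whole pass is vectorized over a batch of parameter vectors, which is
what multi-start screening runs on.  A batch entry whose state becomes
non-finite (stiffness blow-up, divergence) is frozen and flagged; callers
count these as failed initializations/iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TimeSeriesDataset
from .errors import UnknownSpeciesError

__all__ = ["IntegrationGrid", "GradientEngine", "MeanCenteredLoss"]


@dataclass(frozen=True)
class IntegrationGrid:
    points: np.ndarray  # (G,) ascending integration nodes
    obs_index: np.ndarray  # (T,) indices of observed times within points

    @classmethod
    def for_times(cls, times: np.ndarray, max_step: float) -> "IntegrationGrid":
        """Grid containing every observed time, with intervals subdivided
        uniformly so that no step exceeds ``max_step``."""
        times = np.asarray(times, float)
        pts = [times[0]]
        idx = [0]
        for a, b in zip(times[:-1], times[1:]):
            if b <= a:  # duplicate observation time
                idx.append(len(pts) - 1)
                continue
            nsub = max(1, int(np.ceil((b - a) / max_step - 1e-12)))
            seg = np.linspace(a, b, nsub + 1)[1:]
            pts.extend(seg.tolist())
            idx.append(len(pts) - 1)
        return cls(points=np.asarray(pts), obs_index=np.asarray(idx, dtype=int))


class MeanCenteredLoss:
    """Mean-centered squared error.

    J = (1/N) Σ over non-missing (species s, time t) of
    ((pred[s,t] − obs[s,t]) / ⟨obs_s⟩)², with ⟨obs_s⟩ the per-species mean
    over that species' non-missing observations and N the total count of
    non-missing pairs.  Scale-invariant: rescaling a species in both pred
    and obs leaves its contribution unchanged.
    """

    def __init__(self, dataset: TimeSeriesDataset):
        self.obs = dataset.values  # (S, T), NaN = missing
        self.mask = ~np.isnan(self.obs)
        self.N = int(self.mask.sum())
        self.means = dataset.species_means(check_nonzero=True)
        self._obs_filled = np.where(self.mask, self.obs, 0.0)

    def value(self, pred: np.ndarray) -> np.ndarray:
        """pred (B, S, T) -> J (B,)."""
        res = (pred - self._obs_filled) / self.means[None, :, None]
        res = np.where(self.mask[None], res, 0.0)
        return np.einsum("bst,bst->b", res, res) / self.N

    def pred_gradient(self, pred: np.ndarray) -> np.ndarray:
        """dJ/dpred, zero at missing observations."""
        g = 2.0 * (pred - self._obs_filled) / (self.N * self.means[None, :, None] ** 2)
        return np.where(self.mask[None], g, 0.0)


class GradientEngine:
    """Loss and loss-gradient evaluation for one (model, dataset) pair.

    ``model`` is anything exposing ``n_state``, ``n_params``,
    ``species_ids``, ``rhs_batch(t, m, theta)`` and
    ``vjp_batch(t, m, theta, cotangent)`` — a plain
    :class:`~kinfit.core.KineticModel` or a hybrid model with a neural
    flux term.  Gradients are with respect to the *linear* parameter
    vector; log-space chain rules are applied by the caller.
    """

    def __init__(
        self,
        model,
        dataset: TimeSeriesDataset,
        m0: np.ndarray,
        max_step: float,
        loss_cls=MeanCenteredLoss,
    ):
        unknown = [s for s in dataset.species if s not in model.species_ids]
        if unknown:
            raise UnknownSpeciesError(f"unknown-species: {unknown}")
        self.model = model
        self.dataset = dataset
        self.m0 = np.asarray(m0, float)
        self.grid = IntegrationGrid.for_times(dataset.times, max_step)
        self.obs_state_idx = np.array(
            [model.species_ids.index(s) for s in dataset.species], dtype=int
        )
        self.loss = loss_cls(dataset)

    # ---------------------------------------------------------------- forward
    def _forward(self, theta: np.ndarray, store_stages: bool):
        """RK4 over the grid.  Returns (ys, ks, ok, fail_step)."""
        t = self.grid.points
        B = theta.shape[0]
        n = self.model.n_state
        G = t.size
        ys = np.empty((B, G, n))
        ys[:, 0] = self.m0[None, :]
        ks = np.empty((B, G - 1, 3, n)) if store_stages else None
        ok = np.ones(B, dtype=bool)
        fail_step = np.full(B, -1, dtype=int)
        rhs = self.model.rhs_batch
        with np.errstate(all="ignore"):
            y = ys[:, 0].copy()
            for s in range(G - 1):
                h = t[s + 1] - t[s]
                t0 = t[s]
                k1 = rhs(t0, y, theta)
                k2 = rhs(t0 + h / 2, y + (h / 2) * k1, theta)
                k3 = rhs(t0 + h / 2, y + (h / 2) * k2, theta)
                k4 = rhs(t0 + h, y + h * k3, theta)
                y_new = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
                finite = np.isfinite(y_new).all(axis=1)
                newly_failed = ok & ~finite
                fail_step[newly_failed] = s
                ok &= finite
                # freeze failed runs at their last finite state
                y_new = np.where(ok[:, None], y_new, y)
                if store_stages:
                    ks[:, s, 0] = k1
                    ks[:, s, 1] = k2
                    ks[:, s, 2] = k3
                ys[:, s + 1] = y_new
                y = y_new
        return ys, ks, ok, fail_step

    def predictions(self, theta: np.ndarray):
        """Model predictions at the observed (species, time) grid.

        Returns (pred (B, S, T), ok (B,))."""
        theta = np.atleast_2d(np.asarray(theta, float))
        ys, _, ok, _ = self._forward(theta, store_stages=False)
        pred = ys[:, self.grid.obs_index][:, :, self.obs_state_idx].transpose(0, 2, 1)
        return pred, ok

    def loss_value(self, theta: np.ndarray):
        pred, ok = self.predictions(theta)
        J = self.loss.value(pred)
        J = np.where(ok, J, np.inf)
        return J, ok

    # --------------------------------------------------------------- backward
    def loss_and_gradient(self, theta: np.ndarray):
        """(J (B,), dJ/dθ (B,P) linear-space, ok (B,)).

        Failed runs get J = inf and NaN gradients.
        """
        theta = np.atleast_2d(np.asarray(theta, float))
        B, P = theta.shape
        t = self.grid.points
        ys, ks, ok, _ = self._forward(theta, store_stages=True)
        pred = ys[:, self.grid.obs_index][:, :, self.obs_state_idx].transpose(0, 2, 1)
        J = self.loss.value(pred)
        J = np.where(ok, J, np.inf)

        # scatter dJ/dpred onto grid indices in state space
        dJdpred = self.loss.pred_gradient(pred)  # (B, S, T)
        inject = np.zeros((B, t.size, self.model.n_state))
        np.add.at(
            inject,
            (slice(None), self.grid.obs_index[:, None], self.obs_state_idx[None, :]),
            dJdpred.transpose(0, 2, 1),
        )

        vjp = self.model.vjp_batch
        ybar = np.zeros((B, self.model.n_state))
        theta_bar = np.zeros((B, P))
        with np.errstate(all="ignore"):
            for s in range(t.size - 2, -1, -1):
                ybar = ybar + inject[:, s + 1]
                h = t[s + 1] - t[s]
                t0 = t[s]
                y = ys[:, s]
                k1, k2, k3 = ks[:, s, 0], ks[:, s, 1], ks[:, s, 2]
                a2 = y + (h / 2) * k1
                a3 = y + (h / 2) * k2
                a4 = y + h * k3
                kb1 = (h / 6) * ybar
                kb2 = (h / 3) * ybar
                kb3 = (h / 3) * ybar
                kb4 = (h / 6) * ybar
                ynew_bar = ybar.copy()
                vm, vp = vjp(t0 + h, a4, theta, kb4)
                ynew_bar += vm
                theta_bar += vp
                kb3 = kb3 + h * vm
                vm, vp = vjp(t0 + h / 2, a3, theta, kb3)
                ynew_bar += vm
                theta_bar += vp
                kb2 = kb2 + (h / 2) * vm
                vm, vp = vjp(t0 + h / 2, a2, theta, kb2)
                ynew_bar += vm
                theta_bar += vp
                kb1 = kb1 + (h / 2) * vm
                vm, vp = vjp(t0, y, theta, kb1)
                ynew_bar += vm
                theta_bar += vp
                ybar = ynew_bar
        theta_bar[~ok] = np.nan
        return J, theta_bar, ok
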