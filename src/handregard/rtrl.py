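"""Modified real-time recurrent learning with feedback-error teaching.

The trainer combines two ideas:

1. **Feedback-error conversion.**  There is no external teacher.  Instead
   the proprioceptively perceived hand positions are converted into
   motor-command errors ``e_0..e_7`` on the output units: for the left hand

   .. math::

        e_0 = (x_0 + d - x_L)/d, \\quad e_1 = (y_0 + d - y_L)/d, \\quad
        e_2 = -e_0, \\quad e_3 = -e_1,

   and likewise ``e_4..e_7`` for the right hand, where ``(x_0 + d, y_0 + d)``
   is the center of the central block and ``d`` the block pitch (20 cm).
   Because perceived positions are block centers, every ``e_k`` is exactly
   -1, 0 or +1 — zero only when the hand is perceived at the central block.
   The overall error is ``J = 1/2 * sum(e_k^2)``.  The ``e_k`` are treated
   as injected output errors (they are piecewise constant in hand position,
   so no gradient flows through the environment into them).

2. **Exact online sensitivities (RTRL).**  The recurrent hidden layer's
   sensitivities ``P_j(t) = d h_j(t) / d w`` are carried forward in time:

   ``P_j(t) = s'(net_j) * [ sum_m W_hh[m, j] P_m(t-1) + d net_j / d w ]``

   for every trainable hidden-layer weight ``w`` (input, recurrent and
   bias), with ``s'(net) = h (1 - h)``.  Output-layer gradients follow by
   the chain rule through ``W_out`` without extra state.  Per-step gradient
   contributions ``sum_k e_k * d y_k / d w`` are accumulated and applied as
   ``dw = eta * sum_t grad(t)`` every ``update_period`` (default 10) steps;
   this ascends ``sum e_k y_k``, i.e. descends ``J`` in the feedback-error
   sense.  The ownership-units' corollary-discharge mask is re-enforced
   after every update and masked weights carry zero sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network
from .world import GridGeometry


class NonFiniteGradientError(RuntimeError):
    """Raised when a weight update would apply a non-finite gradient."""


def motor_errors(
    perceived_left: tuple[float, float],
    perceived_right: tuple[float, float],
    geometry: GridGeometry,
) -> np.ndarray:
    """Feedback errors ``e_0..e_7`` from perceived block-center positions.

    Inputs must be block centers (cm) as returned by
    :func:`handregard.world.perceived_block`; anything else violates the
    quantized-proprioception contract and raises ``ValueError``.
    """
    x0, y0, d = geometry.x0, geometry.y0, geometry.d
    e = np.empty(8)
    for base, (px, py) in ((0, perceived_left), (4, perceived_right)):
        for v, v0 in ((px, x0), (py, y0)):
            k = round((v - v0) / d)
            if not (0 <= k <= 2 and abs(v0 + k * d - v) < 1e-9):
                raise ValueError(f"{(px, py)} is not a block-center coordinate")
        ex = (x0 + d - px) / d
        ey = (y0 + d - py) / d
        e[base : base + 4] = (ex, ey, -ex, -ey)
    return e


def network_error(errors: np.ndarray) -> float:
    """Overall network error ``J = 1/2 * sum(e_k^2)``."""
    return 0.5 * float(np.dot(errors, errors))


@dataclass(frozen=True)
class TrainerConfig:
    """Learning-rate and scheduling knobs of the online trainer.

    ``accumulate="sum"`` applies the summed gradient of the whole
    ``update_period`` window (default; uses all error information);
    ``"last"`` applies only the final step's instantaneous gradient.
    ``reset_sensitivities_on_reposition`` optionally clears the sensitivity
    state whenever entities are re-placed (off by default: the network runs
    continuously through one developmental run).
    """

    learning_rate: float = 0.1
    update_period: int = 10
    accumulate: str = "sum"  # "sum" | "last"
    mask_enforcement: bool = True
    reset_sensitivities_on_reposition: bool = False

    def __post_init__(self) -> None:
        if self.update_period < 1:
            raise ValueError("update_period must be >= 1")
        if self.accumulate not in ("sum", "last"):
            raise ValueError("accumulate must be 'sum' or 'last'")


class RTRLTrainer:
    """Carries sensitivities and accumulated gradients across steps.

    The sensitivity tensor is stored flat as ``P[j, z*H + j']`` =
    d hidden_j / d W_h[z, j'] with ``Z = n_in + H + 1`` pre-synaptic rows,
    so the recurrent propagation is one ``(H, H) @ (H, Z*H)`` product.
    """

    def __init__(self, network: Network, config: TrainerConfig = TrainerConfig()):
        self.net = network
        self.config = config
        H, Z = network.n_hidden, network.n_pre
        self._H, self._Z = H, Z
        self.P = np.zeros((H, Z * H))
        self._buf = np.zeros_like(self.P)
        self._gtmp = np.empty(Z * H)
        self.grad_hid = np.zeros(Z * H)
        self.grad_out = np.zeros_like(network.W_out)
        self.grad_b_out = np.zeros_like(network.b_out)
        self.steps_since_update = 0
        self._diag = np.arange(H)

    # -- pieces (exposed for testing) ------------------------------------

    def propagate(self, z: np.ndarray, h: np.ndarray) -> None:
        """Advance sensitivities one step (after the forward pass).

        ``z`` is the pre-synaptic vector actually used by that forward pass
        (it still contains the *previous* hidden state) and ``h`` the new
        hidden activations.
        """
        H, Z = self._H, self._Z
        np.dot(self.net.W_hid_hid.T, self.P, out=self._buf)
        T3 = self._buf.reshape(H, Z, H)
        T3[self._diag, :, self._diag] += z
        T3 *= (h * (1.0 - h))[:, None, None]
        # Masked (ownership x CD) weights are frozen at zero: keep their
        # sensitivities identically zero as well.
        T3[:, self.net.cd_slice, self.net.ownership_slice] = 0.0
        self.P, self._buf = self._buf, self.P

    def accumulate(self, h: np.ndarray, y: np.ndarray, errors: np.ndarray) -> None:
        """Add this step's contribution ``sum_k e_k dy_k/dw`` to the gradient."""
        if self.config.accumulate == "last":
            self._zero_grads()
        if not errors.any():
            return
        eyp = errors * y * (1.0 - y)
        dvec = self.net.W_out @ eyp
        np.dot(dvec, self.P, out=self._gtmp)
        self.grad_hid += self._gtmp
        self.grad_out += np.outer(h, eyp)
        self.grad_b_out += eyp

    def apply_update(self) -> None:
        """Apply ``dw = eta * grad`` and re-enforce the connectivity mask."""
        g = self.grad_hid
        if not (np.isfinite(g).all() and np.isfinite(self.grad_out).all()):
            raise NonFiniteGradientError(
                "non-finite gradient at trainer step "
                f"{self.steps_since_update}; aborting run"
            )
        eta = self.config.learning_rate
        self.net.W_h += eta * g.reshape(self._Z, self._H)
        self.net.W_out += eta * self.grad_out
        self.net.b_out += eta * self.grad_b_out
        if self.config.mask_enforcement:
            self.net.enforce_mask()
        self._zero_grads()

    def _zero_grads(self) -> None:
        self.grad_hid[:] = 0.0
        self.grad_out[:] = 0.0
        self.grad_b_out[:] = 0.0

    def reset_sensitivities(self) -> None:
        self.P[:] = 0.0

    # -- the per-step entry point -----------------------------------------

    def step(
        self, z: np.ndarray, h: np.ndarray, y: np.ndarray, errors: np.ndarray
    ) -> bool:
        """Propagate, accumulate, and update when the period elapses.

        Returns True when a weight update was applied this step.
        """
        self.propagate(z, h)
        self.accumulate(h, y, errors)
        self.steps_since_update += 1
        if self.steps_since_update >= self.config.update_period:
            self.apply_update()
            self.steps_since_update = 0
            return True
        return False

    # -- introspection -----------------------------------------------------

    @property
    def grad_hidden_matrix(self) -> np.ndarray:
        """Accumulated hidden-layer gradient reshaped to ``(Z, H)``."""
        return self.grad_hid.reshape(self._Z, self._H)

    def sensitivity_tensor(self) -> np.ndarray:
        """Sensitivities as ``(H, Z, H)``: d h_j / d W_h[z, j']."""
        return self.P.reshape(self._H, self._Z, self._H)
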