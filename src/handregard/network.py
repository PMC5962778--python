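"""Partitioned three-layer logistic network with a recurrent hidden layer.

Architecture (defaults): 238 input units -> 48 hidden units -> 8 output
units.  Hidden units are logistic and fully recurrent (one step of history,
Jordan/Elman style); output units are feedforward logistic readouts — the
functional feedback path runs through the environment and the corollary
discharge, not through output-to-hidden weights.

The hidden layer is split into two equal subpopulations:

* **agency** units (first half) receive every input, including the
  corollary discharge — they can compare predicted and actual feedback;
* **ownership** units (second half) receive only visual and proprioceptive
  input: their weights from corollary-discharge input units are masked to
  zero and the mask is re-enforced after every weight update.

Internally the hidden layer's parameters live in one ``(Z, H)`` matrix
``W_h`` over the *pre-synaptic vector* ``z = [input, hidden_prev, 1]``
(``Z = n_in + H + 1``), which keeps the online-gradient recursion a single
matrix product.  Views expose the conventional blocks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np


def logistic(net):
    """Logistic activation 1 / (1 + exp(-net)); output strictly in (0, 1).

    The net input is clamped to +/-36 — beyond that the output is within
    one float64 ulp of 0 or 1 anyway — which keeps activations strictly
    inside (0, 1) and avoids exp overflow for runaway weights.
    """
    return 1.0 / (1.0 + np.exp(-np.clip(net, -36.0, 36.0)))


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes and initialization of the network.

    ``n_agency`` hidden units receive the corollary discharge; the remaining
    ``n_hidden - n_agency`` "ownership" units do not.  Weights and biases
    are drawn uniformly from ``[-init_scale, init_scale]``.
    """

    n_hidden: int = 48
    n_agency: int = 24
    n_outputs: int = 8
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.n_agency <= self.n_hidden:
            raise ValueError("n_agency must lie in [0, n_hidden]")


class Network:
    """Mutable network state: masked weights, biases and activations."""

    def __init__(
        self,
        n_in: int,
        config: NetworkConfig,
        cd_slice: slice,
        rng: np.random.Generator,
    ):
        self.n_in = n_in
        self.config = config
        self.cd_slice = cd_slice
        H, O, s = config.n_hidden, config.n_outputs, config.init_scale
        Z = n_in + H + 1
        self.W_h = rng.uniform(-s, s, size=(Z, H))
        self.W_out = rng.uniform(-s, s, size=(H, O))
        self.b_out = rng.uniform(-s, s, size=O)
        # Mask over the combined hidden-parameter matrix: ownership columns
        # may not receive corollary-discharge input rows.
        self.mask = np.ones((Z, H))
        self.mask[cd_slice, self.ownership_slice] = 0.0
        self.W_h *= self.mask
        self.hidden_prev = np.full(H, 0.5)  # logistic(0): quiescent start
        self.hidden = np.full(H, 0.5)
        self.output = np.full(O, 0.5)

    # -- structural views -------------------------------------------------

    @property
    def n_hidden(self) -> int:
        return self.config.n_hidden

    @property
    def n_outputs(self) -> int:
        return self.config.n_outputs

    @property
    def n_pre(self) -> int:
        """Length of the pre-synaptic vector [input, hidden_prev, bias]."""
        return self.n_in + self.n_hidden + 1

    @property
    def ownership_slice(self) -> slice:
        return slice(self.config.n_agency, self.config.n_hidden)

    @property
    def agency_slice(self) -> slice:
        return slice(0, self.config.n_agency)

    @property
    def W_in_hid(self) -> np.ndarray:
        return self.W_h[: self.n_in]

    @property
    def W_hid_hid(self) -> np.ndarray:
        """Recurrent weights; ``W_hid_hid[m, j]`` connects unit m to unit j."""
        return self.W_h[self.n_in : self.n_in + self.n_hidden]

    @property
    def b_hid(self) -> np.ndarray:
        return self.W_h[-1]

    # -- dynamics ---------------------------------------------------------

    def build_pre(self, x: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        """Pre-synaptic vector ``z = [x, hidden_prev, 1]`` for this step."""
        if out is None:
            out = np.empty(self.n_pre)
        out[: self.n_in] = x
        out[self.n_in : -1] = self.hidden_prev
        out[-1] = 1.0
        return out

    def forward_pre(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One step given the pre-built pre-synaptic vector.

        Updates ``hidden_prev`` to the new hidden activations (exactly one
        step of recurrent history is carried).
        """
        h = logistic(z @ self.W_h)
        y = logistic(h @ self.W_out + self.b_out)
        self.hidden_prev = h
        self.hidden = h
        self.output = y
        return h, y

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One step from an input vector (hidden state advances)."""
        if x.shape[0] != self.n_in:
            raise ValueError(f"input length {x.shape[0]} != n_in {self.n_in}")
        return self.forward_pre(self.build_pre(x))

    # -- bookkeeping ------------------------------------------------------

    def enforce_mask(self) -> None:
        self.W_h *= self.mask

    def weights_hash(self) -> str:
        """SHA-256 over all weights — cheap frozen-weights assertion."""
        m = hashlib.sha256()
        for a in (self.W_h, self.W_out, self.b_out):
            m.update(np.ascontiguousarray(a).tobytes())
        return m.hexdigest()

    def copy(self) -> "Network":
        dup = object.__new__(Network)
        dup.n_in = self.n_in
        dup.config = self.config
        dup.cd_slice = self.cd_slice
        dup.W_h = self.W_h.copy()
        dup.W_out = self.W_out.copy()
        dup.b_out = self.b_out.copy()
        dup.mask = self.mask.copy()
        dup.hidden_prev = self.hidden_prev.copy()
        dup.hidden = self.hidden.copy()
        dup.output = self.output.copy()
        return dup


def init_network(
    rng: np.random.Generator, n_in: int, config: NetworkConfig, cd_slice: slice
) -> Network:
    """Fresh network with uniform ``[-init_scale, init_scale]`` weights."""
    return Network(n_in, config, cd_slice, rng)
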