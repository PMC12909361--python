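"""Neural surrogate mapping time to per-state moment outputs.

A small feed-forward tanh network takes (scaled) time as input and outputs,
per observed state, a central-tendency node and a spread node (variance or
SD, per layout), and per unobserved state a single central-tendency node.
A softplus output transform keeps every moment strictly positive; min-max
scaling maps network outputs back to the observed scale.

The time derivative of every output is computed by forward-mode tangent
propagation expressed with autodiff primitives, so that loss gradients with
respect to the weights flow through the derivative as well (derivative-of-
network-output with respect to its input, inside the training graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = ["NetworkSpec", "OutputLayout", "ScalingSpec", "MLP",
           "SurrogateOutputs"]


@dataclass
class NetworkSpec:
    hidden_layers: int = 2
    hidden_width: int = 3
    activation: str = "tanh"
    output_transform: str = "softplus"
    weight_init: str = "glorot_normal"
    softplus_floor: float = 1e-6  # positive floor added to spread outputs

    def __post_init__(self):
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("need at least one hidden layer and one unit")
        if self.activation != "tanh":
            raise ValueError("only tanh activation is supported")


@dataclass
class OutputLayout:
    """Two output nodes (mean, spread) per observed state; one (mean) per
    unobserved state.  `spread` names the quantity the spread node carries."""
    n_observed: int = 1
    n_unobserved: int = 0
    spread: str = "variance"  # or "sd"

    @property
    def n_outputs(self) -> int:
        return 2 * self.n_observed + self.n_unobserved


@dataclass
class ScalingSpec:
    """Per-output (x_min, x_max) bounds on the observed scale.  Identity
    scaling is (0, 1)."""
    x_min: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    x_max: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        self.x_min = np.atleast_1d(np.asarray(self.x_min, dtype=float))
        self.x_max = np.atleast_1d(np.asarray(self.x_max, dtype=float))
        if np.any(self.x_max <= self.x_min):
            raise ValueError("x_max must exceed x_min")

    @classmethod
    def identity(cls, n: int) -> "ScalingSpec":
        return cls(np.zeros(n), np.ones(n))

    @property
    def span(self) -> np.ndarray:
        return self.x_max - self.x_min


@dataclass
class SurrogateOutputs:
    values: Tensor       # (n_times, n_outputs), unscaled
    derivatives: Tensor  # (n_times, n_outputs), unscaled d/dt


class MLP:
    """Feed-forward tanh network with softplus-positive outputs.

    Weights are Glorot-normal initialised from a seeded generator, so two
    networks built with the same seed are bit-identical.
    """

    def __init__(self, spec: NetworkSpec, layout: OutputLayout,
                 scaling: ScalingSpec | None = None,
                 t_max: float = 1.0, seed: int = 0,
                 input_transform: str = "linear"):
        self.spec = spec
        self.layout = layout
        self.scaling = scaling if scaling is not None \
            else ScalingSpec.identity(layout.n_outputs)
        if len(self.scaling.x_min) != layout.n_outputs:
            raise ValueError("scaling bounds must match output count")
        if input_transform not in ("linear", "log1p"):
            raise ValueError("input_transform must be 'linear' or 'log1p'")
        self.input_transform = input_transform
        self.t_max = float(t_max)
        rng = np.random.default_rng(seed)
        sizes = [1] + [spec.hidden_width] * spec.hidden_layers \
            + [layout.n_outputs]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(Tensor(rng.standard_normal((fan_in, fan_out)) * std,
                                       requires_grad=True))
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))

    @property
    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def forward(self, t: np.ndarray) -> SurrogateOutputs:
        """Evaluate outputs and their time derivatives at times `t` (hours,
        unscaled).  Both are returned on the observed (unscaled) scale."""
        t = np.asarray(t, dtype=float).reshape(-1, 1)
        if self.input_transform == "log1p":
            # compresses a multi-scale horizon (hours-long infusion on a
            # multi-week study) so early-time dynamics stay resolvable
            denom = np.log1p(self.t_max)
            h = Tensor(np.log1p(t) / denom)
            u = Tensor(1.0 / ((1.0 + t) * denom))  # dh/dt tangent
        else:
            h = Tensor(t / self.t_max)
            u = Tensor(np.full_like(t, 1.0 / self.t_max))  # dh/dt tangent
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = h @ W + b
            ua = u @ W
            if i < n_layers - 1:
                h = a.tanh()
                u = (1.0 - h * h) * ua
            else:
                y = a.softplus() + self.spec.softplus_floor
                uy = a.sigmoid() * ua
        span = self.scaling.span
        values = y * span + self.scaling.x_min
        derivs = uy * span
        return SurrogateOutputs(values=values, derivatives=derivs)

    # convenience accessors keyed by the layout ---------------------------

    def split_observed(self, out: SurrogateOutputs):
        """Return (means, spreads, unobserved_means) column groups, with
        derivatives in a matching second triple."""
        n_obs = self.layout.n_observed
        v, d = out.values, out.derivatives
        means = v[:, 0:2 * n_obs:2]
        spreads = v[:, 1:2 * n_obs:2]
        unobs = v[:, 2 * n_obs:]
        d_means = d[:, 0:2 * n_obs:2]
        d_spreads = d[:, 1:2 * n_obs:2]
        d_unobs = d[:, 2 * n_obs:]
        return (means, spreads, unobs), (d_means, d_spreads, d_unobs)

    # checkpointing -------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def set_weights(self, arrays) -> None:
        for p, a in zip(self.parameters, arrays):
            p.data[...] = a
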