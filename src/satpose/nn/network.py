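"""Architecture specification, shape-audited construction and checkpoints.

The keypoint regressor is five convolutional stages — each convolution
followed by an ELU and a 2x2 pooling layer (mean by default, max as the
comparator) — then three ELU fully connected layers and a linear output of
26 units (x, y for each of 13 landmarks).  The first convolution strides
2x2; with a 256-px input the feature map reaches 4x4x256 before flattening,
retaining coarse spatial detail for localization.

Initialization: uniform weights with bound sqrt(6 / fan_in) for ELU units
and sqrt(3 / fan_in) for the linear output, where fan_in counts spatial x
feature inputs for convolutional units and feature inputs for fully
connected units; biases start at zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .layers import ELU, Conv2D, Dense, Flatten, Layer, MaxPool2D, MeanPool2D

__all__ = [
    "ArchitectureSpec",
    "InitScheme",
    "Network",
    "build_network",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = 1


@dataclass
class ArchitectureSpec:
    conv_channels: list = field(default_factory=lambda: [64, 64, 128, 128, 256])
    conv_filters: list = field(default_factory=lambda: [9, 5, 5, 3, 3])
    conv_strides: list = field(default_factory=lambda: [2, 1, 1, 1, 1])
    pool: str = "mean"
    fc_sizes: list = field(default_factory=lambda: [512, 512, 512])
    output_units: int = 26
    input_size: int = 256
    input_channels: int = 3

    def __post_init__(self) -> None:
        n = len(self.conv_channels)
        if not (len(self.conv_filters) == len(self.conv_strides) == n):
            raise ValueError("conv_channels/filters/strides lengths must match")
        if self.pool not in ("mean", "max"):
            raise ValueError("pool must be 'mean' or 'max'")

    @classmethod
    def full(cls, pool: str = "mean") -> "ArchitectureSpec":
        """The published 256-px architecture."""
        return cls(pool=pool)

    @classmethod
    def small(cls, pool: str = "mean") -> "ArchitectureSpec":
        """Desk-scale 64-px preset for CPU experiments.

        Keeps five conv+pool stages with channels [16, 16, 32, 32, 64] but
        drops the initial stride to 1: stride 2 plus five 2x2 pools would
        collapse a 64-px input to 1x1 and destroy the spatial detail the
        mean-pooling design exists to preserve.  Final map: 2x2x64.
        """
        return cls(
            conv_channels=[16, 16, 32, 32, 64],
            conv_filters=[9, 5, 5, 3, 3],
            conv_strides=[1, 1, 1, 1, 1],
            pool=pool,
            fc_sizes=[128, 128, 128],
            input_size=64,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls(**json.loads(text))


@dataclass
class InitScheme:
    """Uniform init bounds as multiples of 1/sqrt(fan_in)."""

    linear_gain: float = 3.0  # bound = sqrt(linear_gain / fan_in)
    elu_gain: float = 6.0  # bound = sqrt(elu_gain / fan_in)

    def bound(self, fan_in: int, linear: bool) -> float:
        gain = self.linear_gain if linear else self.elu_gain
        return float(np.sqrt(gain / fan_in))


class Network:
    """An ordered stack of layers with explicit forward/backward."""

    def __init__(self, layers: list, spec: ArchitectureSpec | None = None,
                 seed: int | None = None) -> None:
        self.layers = layers
        self.spec = spec
        self.seed = seed

    def forward(self, x: np.ndarray, check_finite: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
            if check_finite and not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"non-finite activations in layer {layer.name!r}"
                )
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    def shape_trace(self) -> list:
        """(layer name, output shape) for the configured input size."""
        assert self.spec is not None
        shape = (self.spec.input_channels, self.spec.input_size, self.spec.input_size)
        trace = [("input", shape)]
        for layer in self.layers:
            shape = layer.output_shape(shape)
            trace.append((layer.name, shape))
        return trace

    def state_arrays(self) -> dict:
        return {f"param_{i}": p for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            a = arrays[f"param_{i}"]
            if a.shape != p.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p[...] = a

    def copy_parameters(self) -> list:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, arrays: list) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p[...] = a


def build_network(
    spec: ArchitectureSpec, init: InitScheme | None = None, seed: int = 0
) -> Network:
    """Construct and initialize a network, auditing shapes layer by layer.

    Identical (spec, init, seed) yields bit-identical parameters.  A spec
    whose shapes do not propagate (e.g. an odd map reaching a pool) raises
    with the full layer-by-layer shape trace.
    """
    init = init or InitScheme()
    pool_cls = MeanPool2D if spec.pool == "mean" else MaxPool2D
    layers: list[Layer] = []
    cin = spec.input_channels
    for i, (cout, k, s) in enumerate(
        zip(spec.conv_channels, spec.conv_filters, spec.conv_strides), start=1
    ):
        layers.append(
            Conv2D(cin, cout, k, stride=s, name=f"conv{i}",
                   needs_input_grad=i > 1)
        )
        layers.append(ELU(name=f"elu_conv{i}"))
        layers.append(pool_cls(name=f"{spec.pool}pool{i}"))
        cin = cout
    layers.append(Flatten(name="flatten"))

    # audit the convolutional shapes before sizing the fully connected stack
    shape = (spec.input_channels, spec.input_size, spec.input_size)
    trace = [("input", shape)]
    try:
        for layer in layers:
            shape = layer.output_shape(shape)
            trace.append((layer.name, shape))
    except ValueError as err:
        lines = "\n".join(f"  {name}: {shp}" for name, shp in trace)
        raise ValueError(f"shape propagation failed: {err}\ntrace so far:\n{lines}")

    fan = shape[0]
    for j, width in enumerate(spec.fc_sizes, start=1):
        layers.append(Dense(fan, width, name=f"fc{j}"))
        layers.append(ELU(name=f"elu_fc{j}"))
        fan = width
    layers.append(Dense(fan, spec.output_units, name="output"))

    rng = np.random.default_rng(seed)
    for layer in layers:
        if isinstance(layer, (Conv2D, Dense)):
            linear = layer.name == "output"
            b = init.bound(layer.fan_in, linear=linear)
            layer.weight[...] = rng.uniform(-b, b, size=layer.weight.shape).astype(
                np.float32
            )
            layer.bias[...] = 0.0
    return Network(layers, spec=spec, seed=seed)


def count_parameters(net: Network) -> int:
    """Exact trainable parameter count (3 402 074 for the full 256-px spec)."""
    return int(sum(layer.n_params() for layer in net.layers))


def save_checkpoint(net: Network, path, extra: dict | None = None) -> None:
    """Versioned checkpoint: architecture spec + parameters + seed (npz)."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "spec": json.loads(net.spec.to_json()) if net.spec else None,
        "seed": net.seed,
        "extra": extra or {},
    }
    arrays = net.state_arrays()
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format')}")
        spec = ArchitectureSpec(**meta["spec"])
        net = build_network(spec, seed=meta.get("seed") or 0)
        net.load_state_arrays({k: data[k] for k in data.files if k != "meta"})
    return net
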