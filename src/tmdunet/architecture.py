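"""Construction of the Unet-baseline, T-Unet and TMD-Unet computation graphs.

The triple-Unet family replaces each resolution level ("node") of a
conventional Unet with three densely connected convolution units.  Unit
``i`` of a node applies two 3x3 dilated convolutions (dilation rate
``4 - i``) and one batch normalization.  Chaining unit ``i`` across the
four encoder nodes, the transition node and the four decoder nodes yields
sub-Unet ``i``; the three sub-Unets run in parallel and each emits its own
sigmoid map, fused by a final 1x1 convolution.

TMD-Unet adds two connectivity enrichments on top of T-Unet:

* a multi-scale input (MSI) pyramid: the stem features, concatenated with
  the raw input, are repeatedly 2x2 max-pooled and injected into every
  encoder unit of the matching resolution;
* dense skip connections (DS): decoder unit ``i`` concatenates encoder unit
  outputs ``1..i`` instead of only its unit-matched counterpart.
"""
from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from .nn import Conv2d, ConvTranspose2d, BatchNorm2d, Tensor
from .nn import ops

__all__ = [
    "ConfigurationError", "ConstructionError", "NetworkConfig",
    "SegmentationModel", "ParameterReport", "build_model",
    "count_parameters", "parameter_report", "encoder_input_channels",
    "decoder_input_channels", "msi_channels", "receptive_field",
    "write_summary_csv", "dump_outputs",
]

VARIANTS = ("unet", "tunet", "tmdunet")


class ConfigurationError(ValueError):
    """Invalid network configuration."""


class ConstructionError(RuntimeError):
    """Inconsistent tensors fed to a node under construction."""


@dataclass
class NetworkConfig:
    """Declarative description of one model variant.

    The defaults mirror the published architecture table: five node filter
    widths ``base_filters * [1, 2, 4, 8, 16]``, three units per node with
    dilation rates 3/2/1, dropout 0.2 after every convolution activation.
    The Unet baseline uses ``base_filters=32`` and ignores the unit fields.
    """

    variant: str = "tmdunet"
    input_height: int = 128
    input_width: int = 128
    input_channels: int = 1
    base_filters: int = 16
    node_filters: tuple = None
    units_per_node: int = 3
    dilation_rates: tuple = (3, 2, 1)
    dropout_rate: float = 0.2
    use_msi: bool = None
    use_dense_skip: bool = None
    upsample_kernel: int = 2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant == "unet" and self.base_filters == 16 \
                and self.node_filters is None:
            self.base_filters = 32
        if self.node_filters is None:
            self.node_filters = tuple(self.base_filters * 2 ** i for i in range(5))
        self.node_filters = tuple(int(f) for f in self.node_filters)
        if self.use_msi is None:
            self.use_msi = self.variant == "tmdunet"
        if self.use_dense_skip is None:
            self.use_dense_skip = self.variant == "tmdunet"
        self.dilation_rates = tuple(self.dilation_rates)
        self.validate()

    def validate(self):
        if self.input_height != self.input_width:
            raise ConfigurationError("input must be square")
        if self.input_height % 16 != 0:
            raise ConfigurationError(
                f"input size {self.input_height} not divisible by 16 "
                "(four pooling stages)")
        if len(self.node_filters) != 5 or \
                any(a >= b for a, b in zip(self.node_filters, self.node_filters[1:])):
            raise ConfigurationError("node_filters must be 5 strictly increasing counts")
        if self.variant != "unet":
            if len(self.dilation_rates) != self.units_per_node:
                raise ConfigurationError("need one dilation rate per unit")
            want = self.variant == "tmdunet"
            if self.use_msi != want or self.use_dense_skip != want:
                raise ConfigurationError(
                    "use_msi/use_dense_skip must both be %s for %s"
                    % (want, self.variant))
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["node_filters"] = list(d["node_filters"])
        d["dilation_rates"] = list(d["dilation_rates"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        return cls(**d)


def msi_channels(config: NetworkConfig) -> int:
    """Channel width of every MSI pyramid level: the stem features fused
    with the raw input image at matching scale."""
    return config.base_filters + config.input_channels


def encoder_input_channels(config: NetworkConfig, h: int, i: int) -> int:
    """Channels entering the first convolution of encoder unit ``i`` of
    node ``h`` (h=5 is the transition node): the intra-node predecessors,
    the pooled unit-matched feature from node ``h-1`` (or the stem output
    at h=1), and the MSI level for TMD-Unet."""
    f = config.node_filters
    c = (i - 1) * f[h - 1]
    if h == 1:
        c += config.base_filters
    else:
        c += f[h - 2]
        if config.use_msi:
            c += msi_channels(config)
    return c


def decoder_input_channels(config: NetworkConfig, h: int, i: int) -> int:
    """Channels entering the first convolution of decoder unit ``i`` of
    node ``h``: intra-node predecessors, the upsampled unit-matched feature
    from below, and the (dense) skip from encoder node ``h``."""
    f = config.node_filters
    c = (i - 1) * f[h - 1] + f[h - 1]          # predecessors + transposed conv
    c += i * f[h - 1] if config.use_dense_skip else f[h - 1]
    return c


def receptive_field(kernel: int, dilation: int, n_convs: int = 2) -> int:
    """Receptive field of a stack of stride-1 dilated convolutions."""
    return n_convs * dilation * (kernel - 1) + 1


class SegmentationModel:
    """A built network: a named-layer registry plus the forward graph.

    Outputs of the triple variants are ``sub_output_1..3`` and
    ``final_output``; the Unet baseline exposes ``final_output`` only.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.layers = {}           # name -> Layer
        self._tags = {}            # name -> ("stem"|"unit","head","final", idx)
        rng = np.random.default_rng(seed)
        if config.variant == "unet":
            self._build_unet(rng)
        else:
            self._build_triple(rng)

    # -- construction ------------------------------------------------------

    def _add(self, name, layer, tag):
        self.layers[name] = layer
        self._tags[name] = tag
        return layer

    def _build_triple(self, rng):
        cfg = self.config
        f = cfg.node_filters
        self._add("stem.conv", Conv2d(cfg.input_channels, cfg.base_filters,
                                      3, 1, rng), ("stem", 0))
        for h in range(1, 6):
            for i in range(1, cfg.units_per_node + 1):
                cin = encoder_input_channels(cfg, h, i)
                self._add_unit(f"enc{h}.u{i}", cin, f[h - 1],
                               cfg.dilation_rates[i - 1], i, rng)
        for h in range(4, 0, -1):
            for i in range(1, cfg.units_per_node + 1):
                self._add(f"dec{h}.u{i}.up",
                          ConvTranspose2d(f[h], f[h - 1], cfg.upsample_kernel, rng),
                          ("unit", i))
                cin = decoder_input_channels(cfg, h, i)
                self._add_unit(f"dec{h}.u{i}", cin, f[h - 1],
                               cfg.dilation_rates[i - 1], i, rng)
        for i in range(1, cfg.units_per_node + 1):
            self._add(f"head.sub{i}", Conv2d(f[0], 1, 1, 1, rng), ("head", i))
        self._add("head.final", Conv2d(cfg.units_per_node, 1, 1, 1, rng),
                  ("final", 0))

    def _add_unit(self, prefix, cin, cout, dilation, tag_i, rng):
        self._add(f"{prefix}.conv1", Conv2d(cin, cout, 3, dilation, rng),
                  ("unit", tag_i))
        self._add(f"{prefix}.conv2", Conv2d(cout, cout, 3, dilation, rng),
                  ("unit", tag_i))
        self._add(f"{prefix}.bn", BatchNorm2d(cout), ("unit", tag_i))

    def _build_unet(self, rng):
        cfg = self.config
        f = cfg.node_filters
        for h in range(1, 6):
            cin = cfg.input_channels if h == 1 else f[h - 2]
            self._add(f"enc{h}.conv1", Conv2d(cin, f[h - 1], 3, 1, rng), ("unit", 1))
            self._add(f"enc{h}.bn1", BatchNorm2d(f[h - 1]), ("unit", 1))
            self._add(f"enc{h}.conv2", Conv2d(f[h - 1], f[h - 1], 3, 1, rng), ("unit", 1))
            self._add(f"enc{h}.bn2", BatchNorm2d(f[h - 1]), ("unit", 1))
        for h in range(4, 0, -1):
            self._add(f"dec{h}.up", ConvTranspose2d(f[h], f[h - 1],
                                                    cfg.upsample_kernel, rng),
                      ("unit", 1))
            self._add(f"dec{h}.conv1", Conv2d(2 * f[h - 1], f[h - 1], 3, 1, rng),
                      ("unit", 1))
            self._add(f"dec{h}.bn1", BatchNorm2d(f[h - 1]), ("unit", 1))
            self._add(f"dec{h}.conv2", Conv2d(f[h - 1], f[h - 1], 3, 1, rng),
                      ("unit", 1))
            self._add(f"dec{h}.bn2", BatchNorm2d(f[h - 1]), ("unit", 1))
        self._add("head.final", Conv2d(f[0], 1, 1, 1, rng), ("head", 1))

    # -- forward -----------------------------------------------------------

    def _unit_forward(self, prefix, z, training, rng):
        cfg = self.config
        a = ops.relu(self.layers[f"{prefix}.conv1"](z))
        a = ops.dropout(a, cfg.dropout_rate, training, rng)
        a = ops.relu(self.layers[f"{prefix}.conv2"](a))
        a = ops.dropout(a, cfg.dropout_rate, training, rng)
        return self.layers[f"{prefix}.bn"](a, training)

    def forward(self, x, training=False, rng=None):
        """Run the graph on an (N,C,H,W) array; returns dict of Tensors."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        if x.shape[1] != cfg.input_channels or \
                x.shape[2] != cfg.input_height or x.shape[3] != cfg.input_width:
            raise ConstructionError(
                f"input shape {x.shape[1:]} does not match configuration "
                f"({cfg.input_channels},{cfg.input_height},{cfg.input_width})")
        rng = rng or np.random.default_rng()
        xt = Tensor(x)
        if cfg.variant == "unet":
            return self._forward_unet(xt, training, rng)
        return self._forward_triple(xt, training, rng)

    def _forward_triple(self, xt, training, rng):
        cfg = self.config
        i0 = self.layers["stem.conv"](xt)
        levels = []
        if cfg.use_msi:
            lvl = ops.concat([i0, xt])
            for _ in range(4):
                lvl = ops.max_pool2(lvl)
                levels.append(lvl)
        units_prev_pooled = None
        enc = {}
        for h in range(1, 6):
            units = []
            for i in range(1, cfg.units_per_node + 1):
                ins = list(units)
                if h == 1:
                    ins.append(i0)
                else:
                    ins.append(units_prev_pooled[i - 1])
                    if cfg.use_msi:
                        ins.append(levels[h - 2])
                self._check_spatial(ins)
                units.append(self._unit_forward(f"enc{h}.u{i}",
                                                ops.concat(ins), training, rng))
            enc[h] = units
            if h < 5:
                units_prev_pooled = [ops.max_pool2(u) for u in units]
        below = enc[5]
        for h in range(4, 0, -1):
            units = []
            for i in range(1, cfg.units_per_node + 1):
                up = self.layers[f"dec{h}.u{i}.up"](below[i - 1])
                ins = list(units) + [up]
                ins += enc[h][:i] if cfg.use_dense_skip else [enc[h][i - 1]]
                self._check_spatial(ins)
                units.append(self._unit_forward(f"dec{h}.u{i}",
                                                ops.concat(ins), training, rng))
            below = units
        subs = [ops.sigmoid(self.layers[f"head.sub{i}"](below[i - 1]))
                for i in range(1, cfg.units_per_node + 1)]
        final = ops.sigmoid(self.layers["head.final"](ops.concat(subs)))
        out = {f"sub_output_{i}": s for i, s in enumerate(subs, 1)}
        out["final_output"] = final
        return out

    def _forward_unet(self, xt, training, rng):
        cfg = self.config
        drop = lambda t: ops.dropout(t, cfg.dropout_rate, training, rng)
        enc = {}
        a = xt
        for h in range(1, 6):
            a = self.layers[f"enc{h}.bn1"](
                drop(ops.relu(self.layers[f"enc{h}.conv1"](a))), training)
            a = self.layers[f"enc{h}.bn2"](
                drop(ops.relu(self.layers[f"enc{h}.conv2"](a))), training)
            enc[h] = a
            if h < 5:
                a = ops.max_pool2(a)
        for h in range(4, 0, -1):
            up = self.layers[f"dec{h}.up"](a)
            a = ops.concat([up, enc[h]])
            a = self.layers[f"dec{h}.bn1"](
                drop(ops.relu(self.layers[f"dec{h}.conv1"](a))), training)
            a = self.layers[f"dec{h}.bn2"](
                drop(ops.relu(self.layers[f"dec{h}.conv2"](a))), training)
        return {"final_output": ops.sigmoid(self.layers["head.final"](a))}

    @staticmethod
    def _check_spatial(tensors):
        sizes = {t.data.shape[2:] for t in tensors}
        if len(sizes) > 1:
            raise ConstructionError(f"mismatched spatial sizes {sizes}")

    def predict(self, x):
        """Inference-mode forward; returns dict of numpy arrays."""
        return {k: v.data for k, v in self.forward(x, training=False).items()}

    # -- parameters --------------------------------------------------------

    @property
    def n_outputs(self):
        return 1 if self.config.variant == "unet" else self.config.units_per_node

    def parameters(self):
        out = []
        for layer in self.layers.values():
            out.extend(layer.parameters())
        return out

    def count_parameters(self, output_index: int) -> int:
        """Trainable parameters of the subgraph upstream of sub-output
        ``output_index`` (units 1..index of every node via the intra-node
        dense links, their transposed convolutions, the stem/MSI path and
        the 1x1 output convolution; the fusion head for the last index)."""
        if not (1 <= output_index <= self.n_outputs):
            raise ConfigurationError(
                f"output index {output_index} out of range 1..{self.n_outputs}")
        last = self.n_outputs
        total = 0
        for name, layer in self.layers.items():
            kind, i = self._tags[name]
            keep = (kind == "stem"
                    or (kind == "unit" and i <= output_index)
                    or (kind == "head" and (i == output_index
                                            or output_index == last))
                    or (kind == "final" and output_index == last))
            if keep:
                total += layer.n_params
        return total

    def layer_shapes(self):
        """(name, class, parameter shapes) for every layer — the graph
        fingerprint used by the reduction-isomorphism check."""
        return [(name, type(layer).__name__,
                 tuple(tuple(p.data.shape) for p in layer.parameters()))
                for name, layer in sorted(self.layers.items())]

    # -- weights -----------------------------------------------------------

    def state_dict(self):
        state = {}
        for name, layer in self.layers.items():
            for attr, val in vars(layer).items():
                if hasattr(val, "data") and isinstance(val.data, np.ndarray):
                    state[f"{name}/{attr}"] = val.data
                elif isinstance(val, np.ndarray):
                    state[f"{name}/{attr}"] = val
        return state

    def load_state_dict(self, state):
        for name, layer in self.layers.items():
            for attr, val in vars(layer).items():
                key = f"{name}/{attr}"
                if key in state:
                    arr = np.asarray(state[key], dtype=np.float32)
                    if hasattr(val, "data") and isinstance(val.data, np.ndarray):
                        val.data = arr.copy()
                    else:
                        setattr(layer, attr, arr.copy())

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})


@dataclass
class ParameterReport:
    """Per-sub-output trainable-parameter accounting."""

    variant: str
    per_output_counts: tuple
    per_output_millions: tuple = field(init=False)

    def __post_init__(self):
        counts = tuple(int(c) for c in self.per_output_counts)
        if any(a >= b for a, b in zip(counts, counts[1:])):
            raise ValueError("per-output counts must strictly increase")
        self.per_output_counts = counts
        # whole-parameter totals render to millions by truncation at the
        # third decimal (1,944,609 -> 1.944)
        self.per_output_millions = tuple(c // 1000 / 1000 for c in counts)


def build_model(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Assemble the computation graph described by ``config``."""
    return SegmentationModel(config, seed=seed)


def count_parameters(model: SegmentationModel, output_index: int) -> int:
    return model.count_parameters(output_index)


def parameter_report(model: SegmentationModel) -> ParameterReport:
    counts = [model.count_parameters(i) for i in range(1, model.n_outputs + 1)]
    return ParameterReport(model.config.variant, tuple(counts))


def write_summary_csv(report: ParameterReport, path_or_buf) -> None:
    """CSV export: variant, output_index, parameter_count, millions_3dp."""
    close = False
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        buf = open(path_or_buf, "w", newline="")
        close = True
    else:
        buf = path_or_buf
    try:
        w = csv.writer(buf)
        w.writerow(["variant", "output_index", "parameter_count", "millions_3dp"])
        for i, (c, m) in enumerate(zip(report.per_output_counts,
                                       report.per_output_millions), 1):
            w.writerow([report.variant, i, c, f"{m:.3f}"])
    finally:
        if close:
            buf.close()


def dump_outputs(outputs, directory, prefix="pred"):
    """Write each named probability map as an 8-bit PNG (value=round(255*p))."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in outputs.items():
        a = np.asarray(arr)
        a = a[0, 0] if a.ndim == 4 else np.squeeze(a)
        img = np.rint(255.0 * np.clip(a, 0.0, 1.0)).astype(np.uint8)
        p = directory / f"{prefix}_{name}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths
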