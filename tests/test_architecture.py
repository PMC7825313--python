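"""Construction, connectivity arithmetic and parameter accounting of the
triple-Unet family, checked against independent closed-form counts."""
import io

import numpy as np
import pytest

from tmdunet.architecture import (
    ConfigurationError, ConstructionError, NetworkConfig, ParameterReport,
    build_model, count_parameters, parameter_report, encoder_input_channels,
    decoder_input_channels, msi_channels, receptive_field, write_summary_csv,
)


# ---------------------------------------------------------------- oracles

def conv_params(k, cin, cout):
    return (k * k * cin + 1) * cout


def analytic_count(cfg: NetworkConfig, output_index: int) -> int:
    """Closed-form parameter count from the connectivity equations alone
    (independent of the layer registry)."""
    f = cfg.node_filters
    total = conv_params(3, cfg.input_channels, cfg.base_filters)
    for h in range(1, 6):
        for i in range(1, output_index + 1):
            cin = encoder_input_channels(cfg, h, i)
            total += conv_params(3, cin, f[h - 1])
            total += conv_params(3, f[h - 1], f[h - 1])
            total += 2 * f[h - 1]                      # BN gamma/beta
    for h in range(4, 0, -1):
        for i in range(1, output_index + 1):
            total += conv_params(cfg.upsample_kernel, f[h], f[h - 1])
            cin = decoder_input_channels(cfg, h, i)
            total += conv_params(3, cin, f[h - 1])
            total += conv_params(3, f[h - 1], f[h - 1])
            total += 2 * f[h - 1]
    total += conv_params(1, f[0], 1)                   # own 1x1 head
    if output_index == cfg.units_per_node:             # full fusion head
        total += 2 * conv_params(1, f[0], 1) + conv_params(1, 3, 1)
    return total


def analytic_unet_count(cfg: NetworkConfig) -> int:
    f = cfg.node_filters
    total = 0
    for h in range(1, 6):
        cin = cfg.input_channels if h == 1 else f[h - 2]
        total += conv_params(3, cin, f[h - 1]) + 2 * f[h - 1]
        total += conv_params(3, f[h - 1], f[h - 1]) + 2 * f[h - 1]
    for h in range(4, 0, -1):
        total += conv_params(cfg.upsample_kernel, f[h], f[h - 1])
        total += conv_params(3, 2 * f[h - 1], f[h - 1]) + 2 * f[h - 1]
        total += conv_params(3, f[h - 1], f[h - 1]) + 2 * f[h - 1]
    return total + conv_params(1, f[0], 1)


# ----------------------------------------------------------- configuration

def test_config_rejects_bad_geometry():
    with pytest.raises(ConfigurationError):
        NetworkConfig(variant="tmdunet", input_height=100, input_width=100)
    with pytest.raises(ConfigurationError):
        NetworkConfig(variant="tmdunet", input_height=128, input_width=96)
    with pytest.raises(ConfigurationError):
        NetworkConfig(variant="nope")
    with pytest.raises(ConfigurationError):
        NetworkConfig(variant="tunet", use_msi=True, use_dense_skip=True)
    with pytest.raises(ConfigurationError):
        NetworkConfig(variant="tmdunet", node_filters=(16, 16, 64, 128, 256))


def test_config_variant_defaults_and_yaml_roundtrip():
    cfg = NetworkConfig(variant="tmdunet")
    assert cfg.use_msi and cfg.use_dense_skip
    assert cfg.node_filters == (16, 32, 64, 128, 256)
    t = NetworkConfig(variant="tunet")
    assert not t.use_msi and not t.use_dense_skip
    u = NetworkConfig(variant="unet")
    assert u.base_filters == 32 and u.node_filters[-1] == 512
    back = NetworkConfig.from_yaml(cfg.to_yaml())
    assert back == cfg


# ------------------------------------------------- connectivity arithmetic

@pytest.mark.parametrize("variant,h,expected", [
    # node 1: unit i concatenates its intra-node predecessors with the stem
    ("tunet", 1, (16, 32, 48)),
    ("tmdunet", 1, (16, 32, 48)),
    # node 2 T-Unet: (i-1)*32 + pooled 16
    ("tunet", 2, (16, 48, 80)),
    # node 2 TMD-Unet adds the 17-channel MSI level (stem + raw input)
    ("tmdunet", 2, (33, 65, 97)),
])
def test_encoder_unit_input_channels(variant, h, expected):
    cfg = NetworkConfig(variant=variant)
    got = tuple(encoder_input_channels(cfg, h, i) for i in (1, 2, 3))
    assert got == expected


def test_decoder_unit_input_channels():
    t = NetworkConfig(variant="tunet")
    # unit 2 of node 1: gamma_1^1 (16) + upsampled (16) + skip chi_1^2 (16)
    assert decoder_input_channels(t, 1, 2) == 48
    # unit 1 has no intra-node predecessors
    assert decoder_input_channels(t, 1, 1) == 32
    tmd = NetworkConfig(variant="tmdunet")
    # dense skip adds chi_1^1 as well
    assert decoder_input_channels(tmd, 1, 2) == 64


def test_msi_channel_width():
    cfg = NetworkConfig(variant="tmdunet", input_channels=3)
    assert msi_channels(cfg) == 19
    assert msi_channels(NetworkConfig(variant="tmdunet")) == 17


def test_stem_layer_shape_and_weight_count():
    m = build_model(NetworkConfig(variant="tmdunet"))
    stem = m.layers["stem.conv"]
    assert stem.weight.data.shape == (16, 1, 3, 3)
    assert stem.n_params == (3 * 3 * 1 + 1) * 16 == 160


def test_fusion_head_parameter_total():
    m = build_model(NetworkConfig(variant="tmdunet"))
    head = sum(m.layers[f"head.sub{i}"].n_params for i in (1, 2, 3))
    head += m.layers["head.final"].n_params
    assert head == 3 * (16 + 1) + (3 + 1) == 55


# ------------------------------------------------------ parameter counting

@pytest.mark.parametrize("variant", ["tunet", "tmdunet"])
@pytest.mark.parametrize("base", [2, 16])
def test_registry_count_equals_analytic_count(variant, base):
    cfg = NetworkConfig(variant=variant, input_height=32, input_width=32,
                        base_filters=base)
    m = build_model(cfg)
    for i in (1, 2, 3):
        assert m.count_parameters(i) == analytic_count(cfg, i)


def test_unet_registry_count_equals_analytic_count():
    cfg = NetworkConfig(variant="unet", input_height=32, input_width=32)
    m = build_model(cfg)
    assert m.count_parameters(1) == analytic_unet_count(cfg)


def test_counts_increase_and_tmd_dominates_tunet():
    t = parameter_report(build_model(NetworkConfig(variant="tunet")))
    d = parameter_report(build_model(NetworkConfig(variant="tmdunet")))
    assert t.per_output_counts[0] < t.per_output_counts[1] < t.per_output_counts[2]
    assert all(dc >= tc for dc, tc in
               zip(d.per_output_counts, t.per_output_counts))


def test_count_parameters_output_index_out_of_range(tiny_model):
    with pytest.raises(ConfigurationError):
        tiny_model.count_parameters(4)
    with pytest.raises(ConfigurationError):
        tiny_model.count_parameters(0)


def test_parameter_report_requires_increasing_counts():
    with pytest.raises(ValueError):
        ParameterReport("tunet", (5, 5, 6))


def test_millions_truncate_to_three_decimals():
    r = ParameterReport("tunet", (1_944_609, 4_870_545, 8_778_023))
    assert r.per_output_millions == (1.944, 4.870, 8.778)


def test_summary_csv_roundtrip(tiny_model):
    buf = io.StringIO()
    write_summary_csv(parameter_report(tiny_model), buf)
    lines = buf.getvalue().strip().splitlines()
    assert lines[0] == "variant,output_index,parameter_count,millions_3dp"
    assert len(lines) == 4 and lines[1].startswith("tmdunet,1,")


# ------------------------------------------------------------ forward pass

def test_forward_outputs_full_resolution_probabilities(tiny_model, rng):
    x = rng.random((2, 1, 32, 32), dtype=np.float32)
    out = tiny_model.predict(x)
    assert set(out) == {"sub_output_1", "sub_output_2", "sub_output_3",
                        "final_output"}
    for v in out.values():
        assert v.shape == (2, 1, 32, 32)
        assert (v > 0).all() and (v < 1).all()


def test_unet_forward_single_output(rng):
    m = build_model(NetworkConfig(variant="unet", input_height=32,
                                  input_width=32, base_filters=2,
                                  node_filters=(2, 4, 8, 16, 32)))
    out = m.predict(rng.random((1, 1, 32, 32), dtype=np.float32))
    assert list(out) == ["final_output"]
    assert out["final_output"].shape == (1, 1, 32, 32)


def test_forward_rejects_wrong_input_shape(tiny_model, rng):
    with pytest.raises(ConstructionError):
        tiny_model.forward(rng.random((1, 1, 48, 48), dtype=np.float32))


def test_msi_pyramid_halves_and_preserves_constants(tiny_model):
    """A constant input stays constant through stem-free pooling levels:
    max-pooling a constant field is the identity on its value."""
    from tmdunet.nn import Tensor
    from tmdunet.nn.ops import max_pool2, concat
    lvl = Tensor(np.full((1, 3, 32, 32), 0.7, dtype=np.float32))
    sizes = []
    for _ in range(4):
        lvl = max_pool2(lvl)
        sizes.append(lvl.data.shape[-1])
        assert np.allclose(lvl.data, 0.7)
    assert sizes == [16, 8, 4, 2]


def test_single_maximum_survives_pool_chain(rng):
    """Brute-force: one maximal pixel propagates through every level."""
    from tmdunet.nn import Tensor
    from tmdunet.nn.ops import max_pool2
    x = rng.random((1, 1, 16, 16), dtype=np.float32)
    x[0, 0, 5, 9] = 7.0
    t = Tensor(x)
    for _ in range(4):
        t = max_pool2(t)
        assert t.data.max() == 7.0


# ----------------------------------------------- graph reduction & dilation

def _strip(name):
    return name


def test_tmdunet_reduction_reproduces_tunet_graph():
    """Disabling MSI and downgrading dense skips in the TMD configuration
    yields, layer for layer, the T-Unet graph (same names, kinds and
    parameter shapes)."""
    tmd = NetworkConfig(variant="tmdunet", input_height=32, input_width=32,
                        base_filters=4)
    reduced = NetworkConfig(variant="tunet", input_height=32, input_width=32,
                            base_filters=4, use_msi=False,
                            use_dense_skip=False)
    a = build_model(reduced).layer_shapes()
    b = build_model(NetworkConfig(variant="tunet", input_height=32,
                                  input_width=32, base_filters=4)).layer_shapes()
    assert a == b
    # and the TMD graph differs from T-Unet only in first-conv input widths
    shapes_tmd = dict((n, s) for n, k, s in build_model(tmd).layer_shapes())
    shapes_t = dict((n, s) for n, k, s in a)
    assert set(shapes_tmd) == set(shapes_t)
    for name in shapes_t:
        if name.endswith(".conv1") and not name.startswith(("stem", "head")):
            continue
        assert shapes_tmd[name] == shapes_t[name], name


def test_receptive_field_ordering():
    """Unit 1 (rate 3) sees strictly more context per unit than unit 3
    (rate 1), by dilation bookkeeping."""
    cfg = NetworkConfig(variant="tmdunet")
    fields = [receptive_field(3, r) for r in cfg.dilation_rates]
    assert fields[0] > fields[1] > fields[2]
    assert fields == [13, 9, 5]
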