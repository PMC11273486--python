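"""Declarative architecture of the two-stream residual networks.

The networks are built from a declarative stage table: a stem stage is a
single plain convolution, a residual stage is a run of pre-activation
bottleneck units (1x1 reduce, 3x1 transform, 1x1 expand) whose first unit may
carry a stride (or a transposed-convolution upsample in the decoder) and a
learned 1x1 projection shortcut. The default tables are:

Encoder:    stem 7x1,16 /4 (384->96); stem 7x1,16 /3 (96->32);
            5 x (16,16,64) (32->32); 5 x (32,32,128) /2 (32->16)
Decoder:    5 x (128,32,32) transposed x2 (16->32); 5 x (64,16,16) (32->32);
            transposed stem 5x1,16 x3 (32->96); transposed stem 7x1,4 x4 (96->384)
Classifier: stems as encoder; 22 x (16,16,64) (32->32); 11 x (32,32,128) /2
            (32->16); fusion with the encoder output; 11 x (32,32,128);
            22 x (64,64,256) /2 (->8); BN-ReLU; global average pool (256);
            fully connected -> 4 classes

Fusion joins the encoder's compressed feature map (128 x 16) with the
classifier's stage-3 output (128 x 16). Two readings of the printed join are
supported: ``"channel"`` (default) stacks along the channel axis (256 x 16,
stage 4 unstrided) and reproduces the published parameter/FLOP budget
(1.53 M / 16.4 M); ``"time"`` appends along the temporal axis (128 x 32,
stage 4 strided), matching the printed per-stage temporal sizes. Both give
identical shapes from stage 5 onward.

``width_scale``/``depth_scale`` produce desk-scale variants by scaling channel
counts and unit counts (each floored at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "StageSpec",
    "ArchitectureSpec",
    "ModelSummary",
    "default_architecture",
    "scnn_architecture",
    "conv_out_length",
    "count_parameters_spec",
    "count_flops_spec",
    "count_weight_layers",
    "summarize_spec",
]


def conv_out_length(L: int, kernel: int, stride: int, padding: int | None = None) -> int:
    if padding is None:
        padding = kernel // 2 if kernel > 1 else 0
    return (L + 2 * padding - kernel) // stride + 1


def transposed_out_length(L: int, kernel: int, stride: int, padding: int,
                          output_padding: int) -> int:
    return (L - 1) * stride - 2 * padding + kernel + output_padding


@dataclass(frozen=True)
class StageSpec:
    """One row of the stage table.

    ``kind`` is ``"stem"`` (single plain convolution, ``channels`` an int) or
    ``"units"`` (``n_blocks`` bottleneck units, ``channels`` the (c1, c2, c3)
    triple). ``stride`` applies to the stem conv or to the first unit's first
    convolution; ``transposed`` marks decoder upsampling stages.
    """

    name: str
    kind: str  # "stem" | "units"
    channels: int | tuple[int, int, int]
    kernel: int
    n_blocks: int = 1
    stride: int = 1
    transposed: bool = False
    in_channels: int = 0
    in_length: int = 0
    out_length: int = 0

    @property
    def out_channels(self) -> int:
        return self.channels if self.kind == "stem" else self.channels[2]


@dataclass(frozen=True)
class ModelSummary:
    """Machine-checkable complexity figures for one input window."""

    n_parameters: int
    n_flops: int  # multiply-accumulates for one forward pass
    n_weight_layers: int

    @property
    def n_parameters_m(self) -> float:
        return self.n_parameters / 1e6

    @property
    def n_flops_m(self) -> float:
        return self.n_flops / 1e6


@dataclass(frozen=True)
class ArchitectureSpec:
    encoder_stages: tuple[StageSpec, ...]
    decoder_stages: tuple[StageSpec, ...]
    classifier_front: tuple[StageSpec, ...]  # stages up to and incl. the fusion input
    classifier_back: tuple[StageSpec, ...]  # stages after the fusion
    fusion: str = "channel"  # "channel" | "time" | "none" (single-stream)
    n_channels: int = 4
    n_classes: int = 4
    window_length: int = 384
    pooled_features: int = 256
    conv_bias: bool = True
    width_scale: float = 1.0
    depth_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fusion not in ("channel", "time", "none"):
            raise ValueError("fusion must be 'channel', 'time' or 'none'")

    @property
    def has_autoencoder(self) -> bool:
        return self.fusion != "none"

    @property
    def fusion_shapes(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((C, L) classifier operand, (C, L) encoder operand) at the join."""
        enc = self.encoder_stages[-1]
        cls = self.classifier_front[-1]
        return (cls.out_channels, cls.out_length), (enc.out_channels, enc.out_length)


def _sc(c: int, w: float) -> int:
    return max(1, round(c * w))


def _sb(n: int, d: float) -> int:
    return max(1, round(n * d))


def _chain(stages: list[dict], in_channels: int, in_length: int) -> tuple[StageSpec, ...]:
    """Resolve input/output channels and lengths along a stage chain."""
    out, c, L = [], in_channels, in_length
    for st in stages:
        kernel, stride = st["kernel"], st.get("stride", 1)
        transposed = st.get("transposed", False)
        if transposed:
            pad, _ = _transposed_geometry(L, st["out_length"], kernel, stride)
            L_out = st["out_length"]
        else:
            L_out = conv_out_length(L, kernel, stride)
        spec = StageSpec(
            name=st["name"], kind=st["kind"], channels=st["channels"],
            kernel=kernel, n_blocks=st.get("n_blocks", 1), stride=stride,
            transposed=transposed, in_channels=c, in_length=L, out_length=L_out,
        )
        out.append(spec)
        c, L = spec.out_channels, L_out
    return tuple(out)


def _transposed_geometry(L_in: int, L_out: int, kernel: int, stride: int) -> tuple[int, int]:
    base = (L_in - 1) * stride + kernel
    for padding in range(max(kernel, 1)):
        op = L_out - base + 2 * padding
        if 0 <= op < max(stride, 1) or (op == 0):
            return padding, op
    raise ValueError(f"no geometry {L_in}->{L_out} k={kernel} s={stride}")


def default_architecture(
    n_channels: int = 4,
    n_classes: int = 4,
    window_length: int = 384,
    width_scale: float = 1.0,
    depth_scale: float = 1.0,
    fusion: str = "channel",
    conv_bias: bool = True,
    block_numbers: tuple[int, int, int, int] = (22, 11, 11, 22),
) -> ArchitectureSpec:
    """The full two-stream stage table (optionally width/depth scaled).

    ``block_numbers`` are the classifier residual-stage unit counts
    (stages 2, 3, 4, 5) before depth scaling.
    """
    w, d = width_scale, depth_scale
    c16, c32, c64, c128, c256 = (_sc(c, w) for c in (16, 32, 64, 128, 256))
    n2, n3, n4, n5 = (_sb(n, d) for n in block_numbers)
    enc_blocks = _sb(5, d)

    L = window_length
    encoder = _chain(
        [
            dict(name="enc/stage0", kind="stem", channels=c16, kernel=7, stride=4),
            dict(name="enc/stage1", kind="stem", channels=c16, kernel=7, stride=3),
            dict(name="enc/stage2", kind="units", channels=(c16, c16, c64),
                 kernel=3, n_blocks=enc_blocks),
            dict(name="enc/stage3", kind="units", channels=(c32, c32, c128),
                 kernel=3, n_blocks=enc_blocks, stride=2),
        ],
        n_channels, L,
    )
    eL = encoder[-1].out_length  # compressed length (16 at defaults)
    L1 = encoder[0].out_length  # 96
    L2 = encoder[1].out_length  # 32
    decoder = _chain(
        [
            dict(name="dec/stage0", kind="units", channels=(c128, c32, c32),
                 kernel=3, n_blocks=enc_blocks, stride=2, transposed=True,
                 out_length=L2),
            dict(name="dec/stage1", kind="units", channels=(c64, c16, c16),
                 kernel=3, n_blocks=enc_blocks),
            dict(name="dec/stage2", kind="stem", channels=c16, kernel=5, stride=3,
                 transposed=True, out_length=L1),
            dict(name="dec/stage3", kind="stem", channels=n_channels, kernel=7,
                 stride=4, transposed=True, out_length=window_length),
        ],
        encoder[-1].out_channels, eL,
    )
    front = _chain(
        [
            dict(name="cls/stage0", kind="stem", channels=c16, kernel=7, stride=4),
            dict(name="cls/stage1", kind="stem", channels=c16, kernel=7, stride=3),
            dict(name="cls/stage2", kind="units", channels=(c16, c16, c64),
                 kernel=3, n_blocks=n2),
            dict(name="cls/stage3", kind="units", channels=(c32, c32, c128),
                 kernel=3, n_blocks=n3, stride=2),
        ],
        n_channels, L,
    )
    if fusion == "channel":
        fused_c, fused_L, s4_stride = front[-1].out_channels + c128, eL, 1
    elif fusion == "time":
        fused_c, fused_L, s4_stride = front[-1].out_channels, 2 * eL, 2
    else:  # single-stream: stage 3 runs unstrided, see scnn_architecture
        fused_c, fused_L, s4_stride = front[-1].out_channels, front[-1].out_length, 2
    back = _chain(
        [
            dict(name="cls/stage4", kind="units", channels=(c32, c32, c128),
                 kernel=3, n_blocks=n4, stride=s4_stride),
            dict(name="cls/stage5", kind="units", channels=(c64, c64, c256),
                 kernel=3, n_blocks=n5, stride=2),
        ],
        fused_c, fused_L,
    )
    return ArchitectureSpec(
        encoder_stages=encoder,
        decoder_stages=decoder,
        classifier_front=front,
        classifier_back=back,
        fusion=fusion,
        n_channels=n_channels,
        n_classes=n_classes,
        window_length=window_length,
        pooled_features=c256,
        conv_bias=conv_bias,
        width_scale=w,
        depth_scale=d,
    )


def _allocate_extra_blocks(base: tuple[int, ...], total: int) -> tuple[int, ...]:
    """Scale block counts proportionally to a new total (largest remainder)."""
    base_total = sum(base)
    raw = [b * total / base_total for b in base]
    out = [int(x) for x in raw]
    remainders = sorted(
        range(len(base)), key=lambda i: (raw[i] - out[i], -i), reverse=True
    )
    for i in range(total - sum(out)):
        out[remainders[i]] += 1
    return tuple(out)


def scnn_architecture(
    n_layers: int = 201,
    n_channels: int = 4,
    n_classes: int = 4,
    window_length: int = 384,
    width_scale: float = 1.0,
    depth_scale: float = 1.0,
    conv_bias: bool = True,
) -> ArchitectureSpec:
    """Single-stream variant: no autoencoder, no fusion.

    Stage 3 runs unstrided so its output length (32) equals the two-stream
    model's post-fusion extent and stage 4 geometry is preserved. The
    264-layer variant distributes 21 extra units over stages 2-5 in proportion
    to their existing counts.
    """
    if n_layers == 201:
        blocks = (22, 11, 11, 22)
    elif n_layers == 264:
        blocks = _allocate_extra_blocks((22, 11, 11, 22), (264 - 3) // 3)
    else:
        raise ValueError("supported single-stream depths: 201, 264")
    spec = default_architecture(
        n_channels=n_channels, n_classes=n_classes, window_length=window_length,
        width_scale=width_scale, depth_scale=depth_scale, fusion="none",
        conv_bias=conv_bias, block_numbers=blocks,
    )
    # stage 3 unstrided: rebuild the front chain with stride 1 there
    front = list(spec.classifier_front)
    s3 = front[-1]
    front[-1] = replace(s3, stride=1, out_length=s3.in_length)
    back = _chain(
        [
            dict(name="cls/stage4", kind="units",
                 channels=spec.classifier_back[0].channels, kernel=3,
                 n_blocks=spec.classifier_back[0].n_blocks, stride=2),
            dict(name="cls/stage5", kind="units",
                 channels=spec.classifier_back[1].channels, kernel=3,
                 n_blocks=spec.classifier_back[1].n_blocks, stride=2),
        ],
        front[-1].out_channels, front[-1].out_length,
    )
    return replace(spec, classifier_front=tuple(front), classifier_back=back)


# ---------------------------------------------------------------------------
# closed-form complexity accounting (walks the spec, no network instantiated)
# ---------------------------------------------------------------------------

def _conv_params(cin: int, cout: int, k: int, bias: bool) -> int:
    return k * cin * cout + (cout if bias else 0)


def _unit_params(cin: int, c: tuple[int, int, int], k: int, bias: bool,
                 projected: bool) -> int:
    c1, c2, c3 = c
    n = 2 * cin + _conv_params(cin, c1, 1, bias)  # bn1 + conv1
    n += 2 * c1 + _conv_params(c1, c2, k, bias)
    n += 2 * c2 + _conv_params(c2, c3, 1, bias)
    if projected:
        n += _conv_params(cin, c3, 1, bias)
    return n


def _stage_params(st: StageSpec, bias: bool) -> int:
    if st.kind == "stem":
        return _conv_params(st.in_channels, st.channels, st.kernel, bias)
    c = st.channels
    total = _unit_params(st.in_channels, c, st.kernel, bias,
                         projected=(st.in_channels != c[2] or st.stride != 1))
    total += (st.n_blocks - 1) * _unit_params(c[2], c, st.kernel, bias, projected=False)
    return total


def _unit_flops(cin: int, c: tuple[int, int, int], k: int, lin: int, lout: int,
                transposed: bool, projected: bool) -> int:
    c1, c2, c3 = c
    # first conv carries the stride/upsample: 1x1, cost Cin*C1*L where L is the
    # input extent for a transposed conv and the output extent otherwise
    f = cin * c1 * (lin if transposed else lout)
    f += k * c1 * c2 * lout
    f += c2 * c3 * lout
    if projected:
        f += cin * c3 * (lin if transposed else lout)
    return f


def _stage_flops(st: StageSpec) -> int:
    if st.kind == "stem":
        if st.transposed:
            return st.kernel * st.in_channels * st.channels * st.in_length
        return st.kernel * st.in_channels * st.channels * st.out_length
    c = st.channels
    total = _unit_flops(st.in_channels, c, st.kernel, st.in_length, st.out_length,
                        st.transposed,
                        projected=(st.in_channels != c[2] or st.stride != 1))
    total += (st.n_blocks - 1) * _unit_flops(
        c[2], c, st.kernel, st.out_length, st.out_length, False, False
    )
    return total


def count_parameters_spec(spec: ArchitectureSpec, include_decoder: bool = False) -> int:
    """Learnable scalars from the stage table alone (spec-walking oracle).

    By default this is the inference path — encoder and classifier — which is
    the published complexity convention; ``include_decoder`` adds the decoder
    used during (pre)training.
    """
    parts: list[StageSpec] = list(spec.classifier_front) + list(spec.classifier_back)
    if spec.has_autoencoder:
        parts += list(spec.encoder_stages)
        if include_decoder:
            parts += list(spec.decoder_stages)
    total = sum(_stage_params(st, spec.conv_bias) for st in parts)
    total += 2 * spec.pooled_features  # final BN before pooling
    total += spec.pooled_features * spec.n_classes + spec.n_classes  # FC
    return total


def count_flops_spec(spec: ArchitectureSpec, include_decoder: bool = False) -> int:
    """Multiply-accumulates for one window (MAC = 1 FLOP convention)."""
    parts: list[StageSpec] = list(spec.classifier_front) + list(spec.classifier_back)
    if spec.has_autoencoder:
        parts += list(spec.encoder_stages)
        if include_decoder:
            parts += list(spec.decoder_stages)
    total = sum(_stage_flops(st) for st in parts)
    total += spec.pooled_features * spec.classifier_back[-1].out_length  # pooling adds
    total += spec.pooled_features * spec.n_classes  # FC
    return total


def count_weight_layers(spec: ArchitectureSpec, part: str = "classifier") -> int:
    """Convolutional + fully connected layer count.

    Follows residual-network naming: projection shortcuts and normalization
    layers are not counted. ``part`` is ``"classifier"`` (the depth quoted for
    the model, e.g. 201), ``"autoencoder"`` or ``"model"`` (everything).
    """
    def stages_layers(stages) -> int:
        return sum(1 if st.kind == "stem" else 3 * st.n_blocks for st in stages)

    cls = stages_layers(spec.classifier_front) + stages_layers(spec.classifier_back) + 1
    if part == "classifier":
        return cls
    ae = stages_layers(spec.encoder_stages) + stages_layers(spec.decoder_stages)
    if part == "autoencoder":
        return ae
    if part == "model":
        return cls + (ae if spec.has_autoencoder else 0)
    raise ValueError("part must be 'classifier', 'autoencoder' or 'model'")


def summarize_spec(spec: ArchitectureSpec, include_decoder: bool = False) -> ModelSummary:
    return ModelSummary(
        n_parameters=count_parameters_spec(spec, include_decoder),
        n_flops=count_flops_spec(spec, include_decoder),
        n_weight_layers=count_weight_layers(spec, "classifier"),
    )
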