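"""Construction of the two-stream and single-stream residual networks.

:func:`build_tcnn` instantiates the full two-stream model — encoder, decoder
and classifier with feature fusion — from an :class:`~nirsbreath.arch.ArchitectureSpec`;
:func:`build_scnn` builds the single-stream ablation (classifier only, no
fusion). Complexity accounting on *built* models (:func:`count_parameters`,
:func:`count_flops`) walks the instantiated layer objects and is checked in
the tests against the closed-form spec-walking counts in
:mod:`nirsbreath.arch`, which never instantiate a network.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchitectureSpec, ModelSummary, StageSpec, count_weight_layers
from .nn.layers import (
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    ConvTranspose1d,
    Linear,
    Module,
    Param,
    PreActBottleneck,
    ReLU,
    Sequential,
)

__all__ = [
    "build_residual_unit",
    "build_tcnn",
    "build_scnn",
    "TwoStreamNet",
    "SingleStreamNet",
    "count_parameters",
    "count_flops",
    "summarize_model",
]


def build_residual_unit(
    in_channels: int,
    channels: tuple[int, int, int],
    kernel: int = 3,
    stride: int = 1,
    transposed: bool = False,
    in_length: int | None = None,
    out_length: int | None = None,
    bias: bool = True,
    rng: np.random.Generator | None = None,
) -> PreActBottleneck:
    """One pre-activation bottleneck unit; shortcut resolved from shapes.

    For transposed (upsampling) units the output padding is solved so that
    ``in_length`` maps exactly onto ``out_length``.
    """
    output_padding = 0
    if transposed:
        if in_length is None or out_length is None:
            raise ValueError("transposed units need in_length and out_length")
        padding, output_padding = ConvTranspose1d.geometry_for(
            in_length, out_length, 1, stride
        )
        if padding != 0:
            raise ValueError("1x1 transposed shortcut expects zero padding")
    c1, c2, c3 = channels
    return PreActBottleneck(
        in_channels, c1, c2, c3, kernel=kernel, stride=stride,
        transposed=transposed, output_padding=output_padding, bias=bias, rng=rng,
    )


def _build_stage(st: StageSpec, bias: bool, rng: np.random.Generator) -> list[Module]:
    if st.kind == "stem":
        if st.transposed:
            padding, op = ConvTranspose1d.geometry_for(
                st.in_length, st.out_length, st.kernel, st.stride
            )
            return [ConvTranspose1d(st.in_channels, st.channels, st.kernel,
                                    stride=st.stride, padding=padding,
                                    output_padding=op, bias=bias, rng=rng)]
        return [Conv1d(st.in_channels, st.channels, st.kernel, stride=st.stride,
                       bias=bias, rng=rng)]
    mods: list[Module] = [
        build_residual_unit(
            st.in_channels, st.channels, kernel=st.kernel, stride=st.stride,
            transposed=st.transposed, in_length=st.in_length,
            out_length=st.out_length, bias=bias, rng=rng,
        )
    ]
    for _ in range(st.n_blocks - 1):
        mods.append(
            build_residual_unit(st.channels[2], st.channels, kernel=st.kernel,
                                bias=bias, rng=rng)
        )
    return mods


class _Head(Module):
    """Final BN-ReLU, global average pooling and the fully connected layer."""

    def __init__(self, channels: int, n_classes: int, rng: np.random.Generator):
        self.bn = BatchNorm1d(channels)
        self.relu = ReLU()
        self.pool = AvgPool1d()
        self.fc = Linear(channels, n_classes, rng=rng)

    def parameters(self) -> list[Param]:
        return self.bn.parameters() + self.fc.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu.forward(self.bn.forward(x, train), train)
        return self.fc.forward(self.pool.forward(h, train), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.pool.backward(self.fc.backward(gy))
        return self.bn.backward(self.relu.backward(g))


class SingleStreamNet(Module):
    """Classifier-only network: stages 0-5, head; returns class scores."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        stages = list(spec.classifier_front) + list(spec.classifier_back)
        self.body = Sequential(
            *[m for st in stages for m in _build_stage(st, spec.conv_bias, rng)]
        )
        self.head = _Head(spec.pooled_features, spec.n_classes, rng)
        self.spec = spec

    def parameters(self) -> list[Param]:
        return self.body.parameters() + self.head.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.body.forward(x, train), train)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(glogits))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return _predict_batched(self, x, batch_size)


class TwoStreamNet(Module):
    """Autoencoder + classifier with feature fusion.

    ``forward`` returns ``(logits, reconstruction)``; the encoder output feeds
    both the decoder and the classifier fusion, so gradients from both losses
    reach the encoder through :meth:`backward`.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        if not spec.has_autoencoder:
            raise ValueError("spec has no autoencoder stream; use SingleStreamNet")
        rng = np.random.default_rng(seed)
        bias = spec.conv_bias
        self.encoder = Sequential(
            *[m for st in spec.encoder_stages for m in _build_stage(st, bias, rng)]
        )
        self.decoder = Sequential(
            *[m for st in spec.decoder_stages for m in _build_stage(st, bias, rng)]
        )
        self.cls_front = Sequential(
            *[m for st in spec.classifier_front for m in _build_stage(st, bias, rng)]
        )
        self.cls_back = Sequential(
            *[m for st in spec.classifier_back for m in _build_stage(st, bias, rng)]
        )
        self.head = _Head(spec.pooled_features, spec.n_classes, rng)
        self.spec = spec
        self._split: int | None = None

    # -- parameter groups ---------------------------------------------------
    def parameters(self) -> list[Param]:
        return (self.encoder.parameters() + self.decoder.parameters()
                + self.cls_front.parameters() + self.cls_back.parameters()
                + self.head.parameters())

    def autoencoder_parameters(self) -> list[Param]:
        return self.encoder.parameters() + self.decoder.parameters()

    def classifier_parameters(self) -> list[Param]:
        return (self.cls_front.parameters() + self.cls_back.parameters()
                + self.head.parameters())

    # -- forward/backward ---------------------------------------------------
    def _fuse(self, h: np.ndarray, f: np.ndarray) -> np.ndarray:
        axis = 1 if self.spec.fusion == "channel" else 2
        self._split = h.shape[axis]
        return np.concatenate([h, f], axis=axis)

    def forward(self, x: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        f = self.encoder.forward(x, train)
        recon = self.decoder.forward(f, train)
        h = self.cls_front.forward(x, train)
        fused = self._fuse(h, f)
        logits = self.head.forward(self.cls_back.forward(fused, train), train)
        return logits, recon

    def backward(self, glogits: np.ndarray, grecon: np.ndarray) -> np.ndarray:
        gfused = self.cls_back.backward(self.head.backward(glogits))
        axis = 1 if self.spec.fusion == "channel" else 2
        gh, gf_cls = np.split(gfused, [self._split], axis=axis)
        gx_cls = self.cls_front.backward(np.ascontiguousarray(gh))
        gf_dec = self.decoder.backward(grecon)
        gx_enc = self.encoder.backward(np.ascontiguousarray(gf_cls) + gf_dec)
        return gx_cls + gx_enc

    # -- autoencoder-only path (pretraining) --------------------------------
    def forward_autoencoder(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x, train), train)

    def backward_autoencoder(self, grecon: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(grecon))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return _predict_batched(self, x, batch_size, two_stream=True)

    # -- state --------------------------------------------------------------
    def get_autoencoder_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.autoencoder_parameters()]

    def set_autoencoder_state(self, state: list[np.ndarray]) -> None:
        params = self.autoencoder_parameters()
        if len(state) != len(params):
            raise ValueError("autoencoder state does not match this architecture")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(
                    f"shape mismatch in autoencoder state: {p.data.shape} vs {s.shape}"
                )
            p.data[...] = s


def _predict_batched(model: Module, x: np.ndarray, batch_size: int,
                     two_stream: bool = False) -> np.ndarray:
    out = []
    for i in range(0, x.shape[0], batch_size):
        res = model.forward(x[i : i + batch_size], train=False)
        logits = res[0] if two_stream else res
        out.append(np.argmax(logits, axis=1))
    return np.concatenate(out)


def get_state(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def set_state(model: Module, state: list[np.ndarray]) -> None:
    params = model.parameters()
    if len(state) != len(params):
        raise ValueError("state does not match this architecture")
    for p, s in zip(params, state):
        p.data[...] = s


def build_tcnn(spec: ArchitectureSpec, seed: int = 0) -> TwoStreamNet:
    """Instantiate the two-stream network; raises if fusion shapes clash."""
    (cc, cl), (ec, el) = spec.fusion_shapes
    if spec.fusion == "channel" and cl != el:
        raise ValueError(f"channel fusion needs equal lengths, got {cl} vs {el}")
    if spec.fusion == "time" and cc != ec:
        raise ValueError(f"temporal fusion needs equal channel counts, got {cc} vs {ec}")
    return TwoStreamNet(spec, seed=seed)


def build_scnn(spec: ArchitectureSpec, seed: int = 0) -> SingleStreamNet:
    """Instantiate the single-stream ablation from a fusion-free spec."""
    if spec.has_autoencoder:
        raise ValueError("single-stream spec must have fusion='none' "
                         "(use arch.scnn_architecture)")
    return SingleStreamNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# complexity accounting on built models
# ---------------------------------------------------------------------------

def count_parameters(model: Module) -> int:
    """Sum of all learnable scalars in a built network."""
    return sum(p.size for p in model.parameters())


def _unit_macs(unit: PreActBottleneck, L_in: int) -> tuple[int, int]:
    conv1 = unit.conv1
    L_mid = conv1.out_length(L_in)
    macs = conv1.macs(L_in)
    macs += unit.conv2.macs(L_mid)
    L_out = unit.conv2.out_length(L_mid)
    macs += unit.conv3.macs(L_out)
    if unit.proj is not None:
        macs += unit.proj.macs(L_in)
    return macs, unit.conv3.out_length(L_out)


def _sequential_macs(seq: Sequential, L: int) -> tuple[int, int]:
    total = 0
    for m in seq.modules:
        if isinstance(m, PreActBottleneck):
            macs, L = _unit_macs(m, L)
            total += macs
        elif isinstance(m, (Conv1d, ConvTranspose1d)):
            total += m.macs(L)
            L = m.out_length(L)
        else:  # pragma: no cover - stages contain only the above
            raise TypeError(f"unexpected module {type(m).__name__}")
    return total, L


def count_flops(model: Module, input_length: int | None = None,
                include_decoder: bool = False) -> int:
    """Multiply-accumulate count for one forward pass of a built model.

    Counts every convolution (shortcut projections and transposed convolutions
    included, one MAC per kernel tap actually applied), the pooling adds and
    the fully connected layer. The default is the inference path; pass
    ``include_decoder=True`` to add the reconstruction stream.
    """
    L = input_length if input_length is not None else model.spec.window_length
    if isinstance(model, TwoStreamNet):
        total, Lf = _sequential_macs(model.cls_front, L)
        enc, Le = _sequential_macs(model.encoder, L)
        total += enc
        if include_decoder:
            total += _sequential_macs(model.decoder, Le)[0]
        Lb = Lf + Le if model.spec.fusion == "time" else Lf
        back, Lb = _sequential_macs(model.cls_back, Lb)
        total += back
    elif isinstance(model, SingleStreamNet):
        total, Lb = _sequential_macs(model.body, L)
    else:
        raise TypeError("expected a TwoStreamNet or SingleStreamNet")
    total += model.spec.pooled_features * Lb  # global average pooling adds
    total += model.head.fc.macs()
    return total


def summarize_model(model: Module, include_decoder: bool = False) -> ModelSummary:
    """Complexity figures of a built model (parameters include the decoder
    only when requested, matching the published inference-path convention)."""
    if isinstance(model, TwoStreamNet) and not include_decoder:
        n_params = count_parameters(model) - sum(
            p.size for p in model.decoder.parameters()
        )
    else:
        n_params = count_parameters(model)
    return ModelSummary(
        n_parameters=n_params,
        n_flops=count_flops(model, include_decoder=include_decoder),
        n_weight_layers=count_weight_layers(model.spec, "classifier"),
    )
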