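"""Architecture specifications, closed-form parameter counts and builders.

Reference configurations are pinned so that their closed-form trainable
parameter totals hit the published budgets exactly:

* compact CNN classifier        — 60,772 parameters
* convolutional autoencoder     — 20,355 parameters (encoder + decoder)
* compressed-feature classifier — 10,292 parameters (with 20% dropout)

The widths were found by :func:`solve_budget`, a small brute-force search
over channel widths under the structural constraints (alternating conv/pool
blocks, dense-64 then dense-4 head, mirrored encoder/decoder); it ships here
so the configurations can be re-derived rather than trusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..errors import SpecError
from .layers import Conv2D, Dense, Dropout, Flatten, MaxPool2x2, ReLU, Sigmoid, Upsample2x
from .model import Sequential

# layer descriptor forms:
#   ("conv", out_channels, kernel_size)   3x3 unless stated, same padding, + ReLU
#   ("conv_sigmoid", out_channels, k)     final decoder conv, sigmoid output
#   ("conv_linear", out_channels, k)      conv without activation
#   ("pool",)                             2x2 max pool
#   ("upsample",)                         2x nearest upsample
#   ("flatten",)
#   ("dense", out_dim)                    + ReLU
#   ("dense_linear", out_dim)             logits head
#   ("dropout", rate)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer description with a closed-form parameter total."""

    input_shape: tuple[int, int, int]
    layers: tuple = ()
    name: str = ""

    def param_count(self) -> int:
        """Closed-form count: conv k*k*cin*cout + cout; dense (din+1)*dout."""
        h, w, c = self.input_shape
        total = 0
        flat: Optional[int] = None
        for spec in self.layers:
            kind = spec[0]
            if kind in ("conv", "conv_sigmoid", "conv_linear"):
                cout, k = spec[1], spec[2]
                total += k * k * c * cout + cout
                c = cout
            elif kind == "pool":
                h, w = h // 2, w // 2
            elif kind == "upsample":
                h, w = h * 2, w * 2
            elif kind == "flatten":
                flat = h * w * c
            elif kind in ("dense", "dense_linear"):
                if flat is None:
                    raise SpecError("dense layer before flatten")
                total += (flat + 1) * spec[1]
                flat = spec[1]
            elif kind == "dropout":
                pass
            else:
                raise SpecError(f"unknown layer kind {kind!r}")
            if kind != "flatten" and flat is not None and kind in (
                    "conv", "conv_sigmoid", "conv_linear", "pool", "upsample"):
                raise SpecError("spatial layer after flatten")
        return total

    def output_shape(self) -> tuple:
        h, w, c = self.input_shape
        flat = None
        for spec in self.layers:
            kind = spec[0]
            if kind in ("conv", "conv_sigmoid", "conv_linear"):
                c = spec[1]
            elif kind == "pool":
                h, w = h // 2, w // 2
            elif kind == "upsample":
                h, w = h * 2, w * 2
            elif kind == "flatten":
                flat = h * w * c
            elif kind in ("dense", "dense_linear"):
                flat = spec[1]
        return (flat,) if flat is not None else (h, w, c)


def build_from_spec(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Instantiate layers (He-initialized) following the spec order."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    h, w, c = spec.input_shape
    flat = None
    layers = []
    for entry in spec.layers:
        kind = entry[0]
        if kind in ("conv", "conv_sigmoid", "conv_linear"):
            cout, k = entry[1], entry[2]
            layers.append(Conv2D(c, cout, k, rng=rng))
            if kind == "conv":
                layers.append(ReLU())
            elif kind == "conv_sigmoid":
                layers.append(Sigmoid())
            c = cout
        elif kind == "pool":
            layers.append(MaxPool2x2())
            h, w = h // 2, w // 2
        elif kind == "upsample":
            layers.append(Upsample2x())
            h, w = h * 2, w * 2
        elif kind == "flatten":
            layers.append(Flatten())
            flat = h * w * c
        elif kind == "dense":
            layers.append(Dense(flat, entry[1], rng=rng))
            layers.append(ReLU())
            flat = entry[1]
        elif kind == "dense_linear":
            layers.append(Dense(flat, entry[1], rng=rng))
            flat = entry[1]
        elif kind == "dropout":
            layers.append(Dropout(entry[1]))
        else:
            raise SpecError(f"unknown layer kind {kind!r}")
    return Sequential(layers)


# ---------------------------------------------------------------------------
# pinned reference configurations

def reference_cnn_spec() -> ArchitectureSpec:
    """Compact 4-class CNN: five conv/pool blocks, dense-64 then dense-4.

    Closed-form total: 60,772 trainable parameters at 64x64x3 input.
    """
    widths = (16, 32, 32, 40, 56)
    layers = []
    for wdt in widths:
        layers += [("conv", wdt, 3), ("pool",)]
    layers += [("flatten",), ("dense", 64), ("dense_linear", 4)]
    return ArchitectureSpec((64, 64, 3), tuple(layers), name="reference_cnn")


def reference_autoencoder_spec() -> ArchitectureSpec:
    """Mirrored conv autoencoder, bottleneck 12x12x24 at 96x96x3 input.

    Closed-form total: 20,355 trainable parameters (encoder + decoder).
    """
    layers = (
        ("conv", 28, 3), ("pool",),
        ("conv", 20, 3), ("pool",),
        ("conv", 24, 3), ("pool",),          # encoder ends here
        ("upsample",), ("conv", 20, 3),
        ("upsample",), ("conv", 28, 3),
        ("upsample",), ("conv_sigmoid", 3, 3),
    )
    return ArchitectureSpec((96, 96, 3), layers, name="reference_autoencoder")


#: number of leading layer descriptors forming the reference encoder
REFERENCE_ENCODER_DEPTH = 6


def reference_ae_classifier_spec() -> ArchitectureSpec:
    """Classifier on the 12x12x24 bottleneck with 20% dropout.

    Closed-form total: 10,292 trainable parameters; combined with the
    autoencoder this makes the 30,647-parameter compressed-feature model.
    """
    layers = (
        ("conv", 7, 3), ("pool",),
        ("conv", 28, 3), ("pool",),
        ("conv", 21, 3), ("pool",),
        ("flatten",), ("dense", 64), ("dropout", 0.20), ("dense_linear", 4),
    )
    return ArchitectureSpec((12, 12, 24), layers, name="reference_ae_classifier")


TABLE_TRANSFER_PARAM_COUNTS = {
    "ResNet50": 23_587_712,
    "DenseNet121": 7_037_504,
    "ResNet101": 42_658_176,
    "ResNet152": 58_370_944,
    "EfficientNetB0": 4_049_571,
}


# ---------------------------------------------------------------------------
# builders

def build_cnn(spec: Optional[ArchitectureSpec] = None, seed: int = 0) -> Sequential:
    """Build a 4-class CNN classifier; defaults to the pinned reference."""
    spec = spec or reference_cnn_spec()
    if spec.output_shape() != (4,):
        raise SpecError(f"classifier spec must end in 4 scores, got "
                        f"{spec.output_shape()}")
    return build_from_spec(spec, seed=seed)


def split_autoencoder_spec(spec: ArchitectureSpec,
                           encoder_depth: int) -> tuple[ArchitectureSpec, ArchitectureSpec]:
    enc = ArchitectureSpec(spec.input_shape, spec.layers[:encoder_depth],
                           name=spec.name + "_encoder")
    dec = ArchitectureSpec(enc.output_shape(), spec.layers[encoder_depth:],
                           name=spec.name + "_decoder")
    return enc, dec


def build_autoencoder(spec: Optional[ArchitectureSpec] = None,
                      encoder_depth: int = REFERENCE_ENCODER_DEPTH,
                      seed: int = 0) -> tuple[Sequential, Sequential, Sequential]:
    """Build (autoencoder, encoder, decoder); encoder/decoder share layers.

    The decoder must mirror the encoder: its spatial output must equal the
    input shape and each upsample must undo a pool.
    """
    spec = spec or reference_autoencoder_spec()
    enc_spec, dec_spec = split_autoencoder_spec(spec, encoder_depth)
    bott = enc_spec.output_shape()
    if len(bott) != 3 or np.prod(bott) >= np.prod(spec.input_shape):
        raise SpecError("encoder must reduce dimensionality to a spatial "
                        "bottleneck")
    if dec_spec.output_shape() != spec.input_shape:
        raise SpecError(f"decoder output {dec_spec.output_shape()} does not "
                        f"mirror input {spec.input_shape}")
    ae = build_from_spec(spec, seed=seed)
    n_enc_layers = len(build_from_spec(enc_spec, seed=seed).layers)
    encoder = Sequential(ae.layers[:n_enc_layers])
    decoder = Sequential(ae.layers[n_enc_layers:])
    return ae, encoder, decoder


def encode_dataset(encoder: Sequential, X: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Push images through the encoder, returning compressed feature maps."""
    return encoder.predict(np.asarray(X, dtype=np.float64), batch_size)


# ---------------------------------------------------------------------------
# transfer-backbone head adapter

def make_stub_backbone(input_shape: tuple[int, int, int], feature_dim: int = 8,
                       n_classes: int = 1000, seed: int = 0) -> Sequential:
    """Random-weight stand-in for a pretrained backbone (tests only).

    Ends, like the real ones, in a dense classification layer that
    :func:`adapt_transfer_head` replaces.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    h, w, c = input_shape
    return Sequential([
        Flatten(),
        Dense(h * w * c, feature_dim, rng=rng), ReLU(),
        Dense(feature_dim, n_classes, rng=rng),
    ])


def adapt_transfer_head(backbone: Sequential, n_classes: int = 4,
                        mode: str = "head_only", seed: int = 0) -> Sequential:
    """Replace the backbone's final dense layer with a fresh n-class head.

    ``head_only`` freezes every other layer; ``full`` leaves the whole
    network trainable (continued backpropagation).
    """
    if mode not in ("head_only", "full"):
        raise SpecError(f"unknown adaptation mode {mode!r}")
    if not backbone.layers or not isinstance(backbone.layers[-1], Dense):
        raise SpecError("backbone must end in a dense layer to adapt")
    feature_dim = backbone.layers[-1].din
    rng = np.random.Generator(np.random.PCG64(seed))
    model = backbone.clone()
    model.layers[-1] = Dense(feature_dim, n_classes, rng=rng)
    if mode == "head_only":
        for layer in model.layers[:-1]:
            layer.frozen = True
    return model


# ---------------------------------------------------------------------------
# scaled-down variants for desk-scale experiments and tests

def small_cnn_spec(input_size: int = 32, widths: tuple[int, ...] = (8, 16),
                   dense: int = 32) -> ArchitectureSpec:
    """A tiny conv/pool classifier for fast synthetic-data experiments."""
    layers = []
    for w in widths:
        layers += [("conv", w, 3), ("pool",)]
    layers += [("flatten",), ("dense", dense), ("dense_linear", 4)]
    return ArchitectureSpec((input_size, input_size, 3), tuple(layers),
                            name=f"small_cnn_{input_size}")


def small_autoencoder_spec(input_size: int = 32,
                           widths: tuple[int, int] = (12, 8)) -> ArchitectureSpec:
    """A tiny mirrored autoencoder (two pools) for fast experiments."""
    a, b = widths
    layers = (
        ("conv", a, 3), ("pool",),
        ("conv", b, 3), ("pool",),
        ("upsample",), ("conv", a, 3),
        ("upsample",), ("conv_sigmoid", 3, 3),
    )
    return ArchitectureSpec((input_size, input_size, 3), layers,
                            name=f"small_ae_{input_size}")


SMALL_ENCODER_DEPTH = 4


def small_ae_classifier_spec(bottleneck: tuple[int, int, int],
                             dense: int = 32) -> ArchitectureSpec:
    """Classifier for a small autoencoder's bottleneck feature maps."""
    layers = (
        ("conv", 12, 3), ("pool",),
        ("flatten",), ("dense", dense), ("dropout", 0.20),
        ("dense_linear", 4),
    )
    return ArchitectureSpec(tuple(bottleneck), layers,
                            name="small_ae_classifier")


# ---------------------------------------------------------------------------
# budget solver

def solve_budget(target: int, input_size: int, n_blocks: int,
                 head_dims: tuple[int, ...] = (64, 4),
                 widths: tuple[int, ...] = (4, 6, 8, 10, 12, 14, 16, 20, 24,
                                            28, 32, 40, 48, 56, 64),
                 kernel: int = 3) -> list[tuple[int, ...]]:
    """Brute-force channel widths for an alternating conv/pool classifier
    whose closed-form parameter total equals ``target`` exactly."""
    sols = []
    s = input_size // 2 ** n_blocks
    if s < 1 or input_size % 2 ** n_blocks:
        return sols
    head_tail = 0
    for a, b in zip(head_dims, head_dims[1:]):
        head_tail += (a + 1) * b
    for ch in itertools.product(widths, repeat=n_blocks):
        p, cin = 0, 3
        for c in ch:
            p += kernel * kernel * cin * c + c
            cin = c
        p += (ch[-1] * s * s + 1) * head_dims[0] + head_tail
        if p == target:
            sols.append(ch)
    return sols
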