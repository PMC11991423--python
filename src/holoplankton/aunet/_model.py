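"""Symmetric encoder-decoder for single-frame hologram inversion.

Each level is a pair of (conv 3x3 -> batch norm -> ReLU) units; levels
are joined by 2x2 max pooling on the way down and 2x2 transposed
convolution on the way up.  Encoder features re-enter the decoder either
by elementwise addition after the encoder block (``skip_mode="add"``,
the default, which keeps channel counts and hence parameters down) or by
channel concatenation (``skip_mode="cat"``).  A 1x1 convolution plus
sigmoid maps the last feature map to a single output channel in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import (
    F32,
    Adam,
    BatchNorm2d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2,
    Layer,
    MaxPool2,
    ReLU,
)

__all__ = ["NetworkSpec", "AUnet", "build_model", "infer",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of the encoder-decoder.

    ``depth`` counts resolution levels (so ``depth - 1`` poolings);
    encoder widths are ``base_channels * 2**level``.  ``decoder_channels``
    defaults to the mirror of the encoder; in add mode a width mismatch
    at any scale needs a 1x1 projection on the skip path
    (``allow_projection``), otherwise the build is rejected.
    """

    depth: int = 3
    base_channels: int = 8
    skip_mode: str = "add"
    decoder_channels: tuple[int, ...] | None = None
    allow_projection: bool = True
    pad_inputs: bool = True
    input_norm: str = "none"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.skip_mode not in ("add", "cat"):
            raise ValueError(f"skip_mode must be 'add' or 'cat', got {self.skip_mode!r}")
        if self.input_norm not in ("none", "mean"):
            raise ValueError(f"input_norm must be 'none' or 'mean', got {self.input_norm!r}")
        if self.decoder_channels is not None and len(self.decoder_channels) != self.depth - 1:
            raise ValueError(
                f"decoder_channels needs {self.depth - 1} entries, "
                f"got {len(self.decoder_channels)}"
            )

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.depth))

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        """Decoder widths from the coarsest skip level to the finest."""
        if self.decoder_channels is not None:
            return self.decoder_channels
        return tuple(reversed(self.encoder_channels[:-1]))

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.depth - 1)


#: Paper-scale topology: depth 4, widths 32/64/128/256.
PAPER_SPEC = NetworkSpec(depth=4, base_channels=32)
#: Desk-scale topology: depth 3, widths 8/16/32 with per-image mean input
#: normalization (CPU-friendly).
DESK_SPEC = NetworkSpec(depth=3, base_channels=8, input_norm="mean")


def _block(c_in: int, c_out: int, rng) -> list[Layer]:
    return [Conv3x3(c_in, c_out, rng), BatchNorm2d(c_out), ReLU(),
            Conv3x3(c_out, c_out, rng), BatchNorm2d(c_out), ReLU()]


class AUnet:
    """The network object: explicit forward/backward over the layer graph."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc_ch = spec.encoder_channels
        dec_ch = spec.decoder_widths
        cat = spec.skip_mode == "cat"

        self.enc_blocks = []
        self.pools = []
        c_prev = 1
        for level in range(spec.depth - 1):
            self.enc_blocks.append(_block(c_prev, enc_ch[level], rng))
            self.pools.append(MaxPool2())
            c_prev = enc_ch[level]
        self.bottleneck = _block(c_prev, enc_ch[-1], rng)

        self.ups = []
        self.skip_projections: list[Conv1x1 | None] = []
        self.dec_blocks = []
        c_prev = enc_ch[-1]
        # decoder runs coarse -> fine; skip level for step i is depth-2-i
        for i, width in enumerate(dec_ch):
            self.ups.append(ConvTranspose2(c_prev, width, rng))
            skip_width = enc_ch[spec.depth - 2 - i]
            proj = None
            if cat:
                block_in = width + skip_width
            else:
                if skip_width != width:
                    if not spec.allow_projection:
                        raise ValueError(
                            f"add-skip width mismatch at level {spec.depth - 2 - i}: "
                            f"encoder {skip_width} vs decoder {width}, and "
                            "projection is disabled"
                        )
                    proj = Conv1x1(skip_width, width, rng)
                block_in = width
            self.skip_projections.append(proj)
            self.dec_blocks.append(_block(block_in, width, rng))
            c_prev = width
        self.head = Conv1x1(c_prev, 1, rng)

    # -- bookkeeping --------------------------------------------------------

    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for up, proj, blk in zip(self.ups, self.skip_projections, self.dec_blocks):
            out.append(up)
            if proj is not None:
                out.append(proj)
            out.extend(blk)
        out.append(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        f = self.spec.pool_factor
        h, w = x.shape[2], x.shape[3]
        ph, pw = (-h) % f, (-w) % f
        if ph or pw:
            if not self.spec.pad_inputs:
                raise ValueError(
                    f"input {h}x{w} is not divisible by 2^(depth-1) = {f} "
                    "and pad_inputs is disabled"
                )
            x = np.pad(x, ((0, 0), (0, 0),
                           (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
        return x, (h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if self.spec.input_norm == "mean":
            # per-image mean normalization: removes the scene-to-scene scale
            # jitter that peak normalization of the raw holograms leaves in
            mean = x.mean(axis=(1, 2, 3), keepdims=True)
            x = np.where(mean > 0, 0.5 * x / np.maximum(mean, 1e-12), x).astype(F32)
        x, (h0, w0) = self._pad(x)

        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._cat_widths = []
        for up, proj, blk, skip in zip(self.ups, self.skip_projections,
                                       self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            if self.spec.skip_mode == "cat":
                self._cat_widths.append(x.shape[1])
                x = np.concatenate([x, skip], axis=1)
            else:
                s = proj.forward(skip, train) if proj is not None else skip
                x = x + s
            for layer in blk:
                x = layer.forward(x, train)
        z = self.head.forward(x, train)
        self._out = (1.0 / (1.0 + np.exp(-z))).astype(F32)
        out = self._out
        fh, fw = out.shape[2], out.shape[3]
        if (fh, fw) != (h0, w0):
            top, left = (fh - h0) // 2, (fw - w0) // 2
            out = out[:, :, top:top + h0, left:left + w0]
        return out[0, 0] if squeeze else out[:, 0]

    def backward(self, d_out: np.ndarray) -> None:
        """Backpropagate d(loss)/d(sigmoid output); shapes as in training."""
        dz = (d_out * self._out * (1.0 - self._out)).astype(F32)
        dx = self.head.backward(dz)
        d_skips = []
        for up, proj, blk in zip(reversed(self.ups),
                                 reversed(self.skip_projections),
                                 reversed(self.dec_blocks)):
            for layer in reversed(blk):
                dx = layer.backward(dx)
            if self.spec.skip_mode == "cat":
                width = self._cat_widths[len(self.ups) - 1 - len(d_skips)]
                d_skips.append(dx[:, width:])
                dx = np.ascontiguousarray(dx[:, :width])
            else:
                d_skip = proj.backward(dx) if proj is not None else dx
                d_skips.append(d_skip)
            dx = up.backward(dx)
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for blk, pool, d_skip in zip(reversed(self.enc_blocks),
                                     reversed(self.pools),
                                     reversed(d_skips)):
            dx = pool.backward(dx) + d_skip
            for layer in reversed(blk):
                dx = layer.backward(dx)


def build_model(spec: NetworkSpec | None = None, seed: int = 0) -> AUnet:
    """Construct the network; identical seeds give identical parameters."""
    return AUnet(spec or NetworkSpec(), seed=seed)


def infer(model: AUnet, hologram: np.ndarray) -> np.ndarray:
    """Evaluation-mode reconstruction of one hologram; output in [0, 1]."""
    out = model.forward(np.asarray(hologram, dtype=F32), train=False)
    return np.clip(out, 0.0, 1.0)


def save_checkpoint(model: AUnet, path) -> None:
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    for j, layer in enumerate(model._layers()):
        for key, buf in layer.state().items():
            arrays[f"state_{j}_{key}"] = buf
    spec = model.spec
    arrays["spec"] = np.array([spec.depth, spec.base_channels,
                               int(spec.skip_mode == "cat"),
                               int(spec.input_norm == "mean")])
    np.savez(path, **arrays)


def load_checkpoint(path) -> AUnet:
    data = np.load(path)
    depth, base, cat, mean_norm = (int(v) for v in data["spec"])
    model = build_model(NetworkSpec(depth=depth, base_channels=base,
                                    skip_mode="cat" if cat else "add",
                                    input_norm="mean" if mean_norm else "none"))
    for i, p in enumerate(model.parameters()):
        p[...] = data[f"param_{i}"]
    for j, layer in enumerate(model._layers()):
        state = {key: data[f"state_{j}_{key}"] for key in layer.state()}
        if state:
            layer.load_state(state)
    return model
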