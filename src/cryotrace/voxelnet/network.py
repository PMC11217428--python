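"""The 3D transformer voxel classifier.

A UNETR-style architecture: a 32-cubed density sub-grid is cut into
non-overlapping 16-cubed patches, embedded to 768 dimensions by a linear
patch projection with a learnable positional encoding, and processed by a
12-block transformer encoder.  Features tapped after blocks 3, 6, 9 and 12
are reshaped onto the 2x2x2 patch lattice and merged by a convolutional
decoder (deconvolution + instance norm + leaky ReLU, U-Net-style skip
concatenation), together with a stem convolution of the raw input, into a
32-cubed feature field of 16 channels.  A 1x1x1 convolution classifies each
voxel into ``out_channels`` classes (4 backbone-atom classes or 21
amino-acid classes).

Decoder channel widths (152 at 4^3, 53 at 8^3, 38 at 16^3, a 47-channel
stem hidden layer, 16 final features) are fixed so that the total trainable
parameter count of the reference configuration is exactly 92,281,604 for
the 4-class head and 92,281,893 for the 21-class head; the widths are not
round numbers because the count constraint is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Var
from .layers import (Conv1, Conv3, Deconv2, Dense, EncoderBlock,
                     InstanceNorm3d, LayerNorm, Module)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture constants; defaults are the reference configuration."""

    out_channels: int = 4
    input_size: int = 32
    in_channels: int = 1
    patch_size: int = 16
    embed_dim: int = 768
    num_blocks: int = 12
    tap_blocks: tuple[int, ...] = (3, 6, 9, 12)
    mlp_dim: int = 3072
    num_heads: int = 12
    decoder_channels: tuple[int, int, int] = (152, 53, 38)
    stem_hidden: int = 47
    decoder_feature_size: int = 16
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.input_size % self.patch_size:
            raise ValueError(
                f"patch size {self.patch_size} does not divide input size "
                f"{self.input_size}")
        if self.input_size // self.patch_size != 2:
            raise ValueError("the decoder ladder assumes 2 patches per axis")
        if self.out_channels < 2:
            raise ValueError("need at least 2 output classes")

    @property
    def num_patches(self) -> int:
        return (self.input_size // self.patch_size) ** 3


def _lrelu(x: Var) -> Var:
    return ag.leaky_relu(x, 0.01)


class VoxelClassifier(Module):
    """Voxel classification network (one head; build one per task)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        K, P = spec.embed_dim, spec.patch_size
        c3, c2, c1 = spec.decoder_channels
        c0, h = spec.decoder_feature_size, spec.stem_hidden

        self.patch_embed = Dense(P ** 3 * spec.in_channels, K, rng)
        self.pos_embed = Var(
            rng.normal(0.0, 0.02, (spec.num_patches, K)).astype(np.float32),
            requires_grad=True)
        self.blocks = [EncoderBlock(K, spec.num_heads, spec.mlp_dim, rng)
                       for _ in range(spec.num_blocks)]
        self.final_ln = LayerNorm(K)

        # deepest stage: z12 and z9 meet at 4^3
        self.up12 = Deconv2(K, c3, rng)
        self.skip9 = Deconv2(K, c3, rng)
        self.skip9_norm = InstanceNorm3d(c3)
        self.merge4 = Conv3(2 * c3, c3, rng)
        self.merge4_norm = InstanceNorm3d(c3)
        self.up4 = Deconv2(c3, c2, rng)
        # z6 reaches 8^3 through two upsamplings
        self.skip6a = Deconv2(K, c2, rng)
        self.skip6a_norm = InstanceNorm3d(c2)
        self.skip6b = Deconv2(c2, c2, rng)
        self.skip6b_norm = InstanceNorm3d(c2)
        self.merge8 = Conv3(2 * c2, c2, rng)
        self.merge8_norm = InstanceNorm3d(c2)
        self.up8 = Deconv2(c2, c1, rng)
        # z3 reaches 16^3 through three upsamplings
        self.skip3a = Deconv2(K, c1, rng)
        self.skip3a_norm = InstanceNorm3d(c1)
        self.skip3b = Deconv2(c1, c1, rng)
        self.skip3b_norm = InstanceNorm3d(c1)
        self.skip3c = Deconv2(c1, c1, rng)
        self.skip3c_norm = InstanceNorm3d(c1)
        self.merge16 = Conv3(2 * c1, c1, rng)
        self.merge16_norm = InstanceNorm3d(c1)
        self.up16 = Deconv2(c1, c0, rng)
        # raw-input stem at full resolution
        self.stem1 = Conv3(spec.in_channels, h, rng)
        self.stem1_norm = InstanceNorm3d(h)
        self.stem2 = Conv3(h, c0, rng)
        self.stem2_norm = InstanceNorm3d(c0)
        self.merge32 = Conv3(2 * c0, c0, rng)
        self.merge32_norm = InstanceNorm3d(c0)
        self.head = Conv1(c0, spec.out_channels, rng)

    # -- forward -----------------------------------------------------------

    def _patchify(self, x: Var) -> Var:
        """(B, C, S, S, S) -> (B, N, P^3*C) in C-order patch layout."""
        s = self.spec
        B = x.shape[0]
        n, P = s.input_size // s.patch_size, s.patch_size
        t = ag.reshape(x, (B, s.in_channels, n, P, n, P, n, P))
        t = ag.transpose(t, (0, 2, 4, 6, 1, 3, 5, 7))
        return ag.reshape(t, (B, n ** 3, s.in_channels * P ** 3))

    def _tap_to_grid(self, z: Var) -> Var:
        """(B, N, K) -> (B, K, 2, 2, 2) matching the patch layout."""
        B = z.shape[0]
        K = self.spec.embed_dim
        return ag.reshape(ag.transpose(z, (0, 2, 1)), (B, K, 2, 2, 2))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Var:
        """Logits of shape (B, out_channels, S, S, S) for input (B, 1, S^3)."""
        drop = self.spec.dropout if train else 0.0
        xin = Var(np.asarray(x, dtype=np.float32))
        tok = self.patch_embed(self._patchify(xin)) + self.pos_embed
        taps: dict[int, Var] = {}
        for i, block in enumerate(self.blocks, start=1):
            tok = block(tok, drop, rng)
            if i in self.spec.tap_blocks:
                taps[i] = tok
        t3, t6, t9, t12 = (taps[i] for i in self.spec.tap_blocks)
        z12 = self._tap_to_grid(self.final_ln(t12))
        z9 = self._tap_to_grid(t9)
        z6 = self._tap_to_grid(t6)
        z3 = self._tap_to_grid(t3)

        d = self.up12(z12)
        s9 = _lrelu(self.skip9_norm(self.skip9(z9)))
        d = _lrelu(self.merge4_norm(self.merge4(ag.concat([d, s9], 1))))
        d = self.up4(d)
        s6 = _lrelu(self.skip6a_norm(self.skip6a(z6)))
        s6 = _lrelu(self.skip6b_norm(self.skip6b(s6)))
        d = _lrelu(self.merge8_norm(self.merge8(ag.concat([d, s6], 1))))
        d = self.up8(d)
        s3 = _lrelu(self.skip3a_norm(self.skip3a(z3)))
        s3 = _lrelu(self.skip3b_norm(self.skip3b(s3)))
        s3 = _lrelu(self.skip3c_norm(self.skip3c(s3)))
        d = _lrelu(self.merge16_norm(self.merge16(ag.concat([d, s3], 1))))
        d = self.up16(d)
        stem = _lrelu(self.stem1_norm(self.stem1(xin)))
        stem = _lrelu(self.stem2_norm(self.stem2(stem)))
        d = _lrelu(self.merge32_norm(self.merge32(ag.concat([d, stem], 1))))
        return self.head(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, dropout disabled."""
        logits = self.forward(x, train=False)
        return ag.softmax(Var(logits.data), axis=1).data

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        arrays["__version__"] = np.array(CHECKPOINT_VERSION)
        arrays["__out_channels__"] = np.array(self.spec.out_channels)
        np.savez_compressed(path, **arrays)

    def load(self, path) -> None:
        with np.load(path) as data:
            if int(data["__version__"]) != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {int(data['__version__'])} != "
                    f"{CHECKPOINT_VERSION}")
            for name, p in self.named_parameters():
                if name not in data:
                    raise ValueError(f"checkpoint missing parameter {name}")
                if data[name].shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {name}")
                p.data = data[name].astype(np.float32)


def build_network(spec: NetworkSpec, seed: int = 0) -> VoxelClassifier:
    """Instantiate the voxel classifier for a given architecture spec."""
    return VoxelClassifier(spec, seed=seed)


def count_parameters(network: VoxelClassifier) -> int:
    """Number of trainable scalar parameters."""
    return network.count_parameters()
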