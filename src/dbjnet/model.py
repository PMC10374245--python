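"""DBJNet: a dual-branch joint network for multichannel hemodynamic trials.

The CNN branch applies two channel-axis (spatial) convolutions — kernels
(8,1)/stride(4,1) with 32 maps, then (4,1)/stride(2,1) with 64 maps, each
followed by ELU — adaptive-average-pools the result to 8x8, flattens, and
projects to a 256-d representation. The statistical branch takes each
channel's temporal mean (a 40-vector) through three ELU-activated fully
connected layers (64, 128, 256). Each branch output is L2-normalized so the
two live in the same domain, concatenated, and classified by a single
linear layer. Either branch can be disabled for ablation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn

VARIANTS = ("full", "cnn_only", "stat_only")


@dataclass(frozen=True)
class DBJNetConfig:
    n_channels: int = 40
    n_samples: int = 160
    conv1_kernels: int = 32
    conv1_size: int = 8
    conv1_stride: int = 4
    conv2_kernels: int = 64
    conv2_size: int = 4
    conv2_stride: int = 2
    pool_out: tuple[int, int] = (8, 8)
    cnn_embed_dim: int = 256
    stat_fc_dims: tuple[int, ...] = (64, 128, 256)
    n_classes: int = 3
    use_cnn_branch: bool = True
    use_stat_branch: bool = True
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.use_cnn_branch or self.use_stat_branch):
            raise ValueError("at least one branch must be enabled")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.conv1_out_height < 1 or self.conv2_out_height < 1:
            raise ValueError(
                "convolution arithmetic yields a non-positive height for "
                f"{self.n_channels} channels"
            )

    @property
    def conv1_out_height(self) -> int:
        return (self.n_channels - self.conv1_size) // self.conv1_stride + 1

    @property
    def conv2_out_height(self) -> int:
        return (self.conv1_out_height - self.conv2_size) // self.conv2_stride + 1

    @property
    def flatten_dim(self) -> int:
        return self.conv2_kernels * self.pool_out[0] * self.pool_out[1]

    @property
    def fused_dim(self) -> int:
        dim = 0
        if self.use_cnn_branch:
            dim += self.cnn_embed_dim
        if self.use_stat_branch:
            dim += self.stat_fc_dims[-1]
        return dim

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_out"] = list(d["pool_out"])
        d["stat_fc_dims"] = list(d["stat_fc_dims"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DBJNetConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown DBJNetConfig keys: {sorted(unknown)}")
        if "pool_out" in d:
            d["pool_out"] = tuple(d["pool_out"])
        if "stat_fc_dims" in d:
            d["stat_fc_dims"] = tuple(d["stat_fc_dims"])
        return cls(**d)


def make_variant(variant: str, n_classes: int = 3, **kwargs) -> DBJNetConfig:
    """Config for the full model or one of its single-branch ablations."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return DBJNetConfig(
        n_classes=n_classes,
        use_cnn_branch=variant in ("full", "cnn_only"),
        use_stat_branch=variant in ("full", "stat_only"),
        **kwargs,
    )


class DBJNet:
    """Forward/backward implementation of the dual-branch network."""

    def __init__(self, config: DBJNetConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(
            config.init_seed if seed is None else seed)
        c = config
        if c.use_cnn_branch:
            self.conv1 = nn.ConvChannel(1, c.conv1_kernels, c.conv1_size,
                                        c.conv1_stride, rng)
            self.elu1 = nn.ELU()
            self.conv2 = nn.ConvChannel(c.conv1_kernels, c.conv2_kernels,
                                        c.conv2_size, c.conv2_stride, rng)
            self.elu2 = nn.ELU()
            self.pool = nn.AdaptiveAvgPool2d(*c.pool_out)
            self.cnn_fc = nn.Linear(c.flatten_dim, c.cnn_embed_dim, rng)
            self.cnn_norm = nn.L2Normalize()
        if c.use_stat_branch:
            dims = (c.n_channels,) + c.stat_fc_dims
            self.stat_fcs = [nn.Linear(dims[i], dims[i + 1], rng)
                             for i in range(len(c.stat_fc_dims))]
            self.stat_elus = [nn.ELU() for _ in c.stat_fc_dims]
            self.stat_norm = nn.L2Normalize()
        self.classifier = nn.Linear(c.fused_dim, c.n_classes, rng)

    # -- forward -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        squeezed = False
        if x.ndim == 2:
            x = x[None]
            squeezed = True
        if x.ndim != 3 or x.shape[1:] != (self.config.n_channels,
                                          self.config.n_samples):
            raise ValueError(
                f"expected input of shape (batch, {self.config.n_channels}, "
                f"{self.config.n_samples}), got {np.asarray(x).shape}"
            )
        self._squeezed = squeezed
        return x

    def cnn_branch(self, x: np.ndarray) -> np.ndarray:
        """x: (B, n_channels, n_samples) -> (B, cnn_embed_dim), unnormalized."""
        h = self.conv1.forward(x[:, None, :, :])
        h = self.elu1.forward(h)
        h = self.conv2.forward(h)
        h = self.elu2.forward(h)
        h = self.pool.forward(h)
        self._pool_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        return self.cnn_fc.forward(h)

    def stat_branch(self, x: np.ndarray) -> np.ndarray:
        """Per-channel temporal mean through the FC stack -> (B, 256)."""
        h = x.mean(axis=2)
        for fc, elu in zip(self.stat_fcs, self.stat_elus):
            h = elu.forward(fc.forward(h))
        return h

    def fuse(self, v_cnn: np.ndarray | None,
             v_stat: np.ndarray | None) -> np.ndarray:
        """L2-normalize each present branch vector, concatenate, classify."""
        parts = []
        if v_cnn is not None:
            parts.append(self.cnn_norm.forward(v_cnn))
        if v_stat is not None:
            parts.append(self.stat_norm.forward(v_stat))
        if not parts:
            raise ValueError("at least one branch representation required")
        fused = np.concatenate(parts, axis=1)
        return self.classifier.forward(fused)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_input(x)
        v_cnn = self.cnn_branch(x) if self.config.use_cnn_branch else None
        v_stat = self.stat_branch(x) if self.config.use_stat_branch else None
        logits = self.fuse(v_cnn, v_stat)
        return logits[0] if self._squeezed else logits

    __call__ = forward

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(logits)."""
        c = self.config
        dfused = self.classifier.backward(dlogits)
        offset = 0
        if c.use_cnn_branch:
            d_cnn = self.cnn_norm.backward(
                dfused[:, offset:offset + c.cnn_embed_dim])
            offset += c.cnn_embed_dim
            d = self.cnn_fc.backward(d_cnn)
            d = d.reshape(self._pool_shape)
            d = self.pool.backward(d)
            d = self.elu2.backward(d)
            d = self.conv2.backward(d)
            d = self.elu1.backward(d)
            self.conv1.backward(d)
        if c.use_stat_branch:
            d_stat = self.stat_norm.backward(dfused[:, offset:])
            d = d_stat
            for fc, elu in zip(reversed(self.stat_fcs),
                               reversed(self.stat_elus)):
                d = fc.backward(elu.backward(d))

    # -- parameters / persistence ------------------------------------------

    def parameters(self) -> list[nn.Param]:
        params: list[nn.Param] = []
        c = self.config
        if c.use_cnn_branch:
            for layer in (self.conv1, self.conv2, self.cnn_fc):
                params.extend(layer.parameters())
        if c.use_stat_branch:
            for fc in self.stat_fcs:
                params.extend(fc.parameters())
        params.extend(self.classifier.parameters())
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match parameter count")
        for p, w in zip(params, weights):
            p.data[...] = w

    def clone(self) -> "DBJNet":
        other = DBJNet(self.config)
        other.set_weights(self.get_weights())
        return other

    def save(self, path) -> None:
        """Single-file .npz weights with the config as a JSON sidecar."""
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        arrays = {f"param_{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, **arrays)
        with open(path[:-4] + ".json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "DBJNet":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with open(path[:-4] + ".json") as fh:
            config = DBJNetConfig.from_dict(json.load(fh))
        model = cls(config)
        with np.load(path) as data:
            weights = [data[f"param_{i}"] for i in range(len(data.files))]
        model.set_weights(weights)
        return model


def describe(config: DBJNetConfig) -> str:
    """Human-readable layer table with the computed output shapes."""
    c = config
    rows: list[tuple[str, str, str, str]] = []
    if c.use_cnn_branch:
        rows += [
            ("CNN branch", "Input", f"shape=({c.n_channels},{c.n_samples})",
             f"(1,{c.n_channels},{c.n_samples})"),
            ("", "Conv2D",
             f"size=({c.conv1_size},1), num={c.conv1_kernels}, ELU, "
             f"stride=({c.conv1_stride},1)",
             f"({c.conv1_kernels},{c.conv1_out_height},{c.n_samples})"),
            ("", "Conv2D",
             f"size=({c.conv2_size},1), num={c.conv2_kernels}, ELU, "
             f"stride=({c.conv2_stride},1)",
             f"({c.conv2_kernels},{c.conv2_out_height},{c.n_samples})"),
            ("", "AdaptiveAvgPool2D", f"output_size={c.pool_out}",
             f"({c.conv2_kernels},{c.pool_out[0]},{c.pool_out[1]})"),
            ("", "Flatten", "", f"({c.flatten_dim})"),
            ("", "FC + L2 norm", f"units={c.cnn_embed_dim}",
             f"({c.cnn_embed_dim})"),
        ]
    if c.use_stat_branch:
        rows += [
            ("Stat branch", "Input", f"shape=({c.n_channels},{c.n_samples})",
             f"({c.n_channels},{c.n_samples})"),
            ("", "Mean", "over time axis", f"({c.n_channels})"),
        ]
        for dim in c.stat_fc_dims:
            rows.append(("", "FC", f"units={dim}, ELU", f"({dim})"))
        rows.append(("", "L2 norm", "", f"({c.stat_fc_dims[-1]})"))
    rows += [
        ("Combine", "Concat", "", f"({c.fused_dim})"),
        ("", "FC", f"units={c.n_classes}", f"({c.n_classes})"),
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    header = ("Branch", "Layer", "Parameters", "Output shape")
    widths = [max(w, len(h)) for w, h in zip(widths, header)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines = [fmt.format(*header), fmt.format(*("-" * w for w in widths))]
    lines += [fmt.format(*r) for r in rows]
    return "\n".join(lines)


def count_parameters(model: DBJNet) -> int:
    return sum(p.data.size for p in model.parameters())
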